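import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr

import statedyn as sd
from statedyn.io_formats import NetworkMap, ValidationError
from statedyn.variability import (
    between_network_variability,
    pattern_variability,
    segment_windows,
    variability_profile,
    window_fc,
    within_network_variability,
)


def loop_pattern_variability(vectors):
    """Independent oracle: explicit double loop over window pairs."""
    n = len(vectors)
    corrs = [
        pearsonr(vectors[i], vectors[j])[0]
        for i in range(n) for j in range(n) if i != j
    ]
    return 1.0 - float(np.mean(corrs))


def loop_within(series, channels, lengths):
    values = []
    for l in lengths:
        windows = segment_windows(series[:, channels], l)
        iu = np.triu_indices(len(channels), k=1)
        vecs = [np.corrcoef(w, rowvar=False)[iu] for w in windows]
        values.append(loop_pattern_variability(vecs))
    return float(np.mean(values))


def loop_between(series, ca, cb, lengths):
    values = []
    for l in lengths:
        windows = segment_windows(series, l)
        vecs = []
        for w in windows:
            corr = np.corrcoef(w, rowvar=False)
            vecs.append(corr[np.ix_(ca, cb)].ravel())
        values.append(loop_pattern_variability(vecs))
    return float(np.mean(values))


class TestSegmentWindows:
    def test_study_length_discards_remainder(self, rng):
        windows = segment_windows(rng.normal(size=(242, 3)), 20)
        assert windows.shape == (12, 20, 3)  # 2 trailing timepoints dropped

    def test_exactly_two_windows(self, rng):
        assert segment_windows(rng.normal(size=(40, 2)), 20).shape[0] == 2

    def test_insufficient_windows(self, rng):
        with pytest.raises(ValueError, match="insufficient"):
            segment_windows(rng.normal(size=(39, 2)), 20)

    def test_minimum_length(self, rng):
        with pytest.raises(ValueError, match=">= 3"):
            segment_windows(rng.normal(size=(50, 2)), 2)


class TestWindowFC:
    def test_identical_channels_correlate_one(self, rng):
        x = rng.normal(size=10)
        w = np.column_stack([x, x, rng.normal(size=10)])
        assert window_fc(w)[0, 1] == pytest.approx(1.0)

    def test_negated_channel(self, rng):
        x = rng.normal(size=10)
        assert window_fc(np.column_stack([x, -x + 2]))[0, 1] == pytest.approx(-1.0)

    def test_matches_direct_computation(self):
        w = np.array([
            [1.0, 2.0, 0.5], [2.0, 1.5, 0.8], [3.0, 3.5, 0.1],
            [4.0, 2.5, 0.9], [5.0, 4.0, 0.2],
        ])
        fc = window_fc(w)
        for a in range(3):
            for b in range(3):
                xa, xb = w[:, a], w[:, b]
                expected = (
                    np.mean((xa - xa.mean()) * (xb - xb.mean())) / (xa.std() * xb.std())
                )
                assert fc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_channel_named(self):
        w = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValidationError, match="channel 1"):
            window_fc(w, window_index=3)

    def test_channel_subsets(self, rng):
        w = rng.normal(size=(15, 5))
        full = window_fc(w)
        sub = window_fc(w, np.array([0, 2]), np.array([1, 3, 4]))
        np.testing.assert_allclose(sub, full[np.ix_([0, 2], [1, 3, 4])])


class TestPatternVariability:
    def test_identical_patterns_zero(self):
        vecs = np.tile([0.2, 0.5, -0.1], (4, 1))
        assert pattern_variability(vecs) == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_patterns_two(self):
        v = np.array([0.4, -0.2, 0.7])
        assert pattern_variability(np.stack([v, -v])) == pytest.approx(2.0)

    def test_matches_loop_oracle(self, rng):
        for _ in range(10):
            vecs = rng.normal(size=(5, 8))
            assert pattern_variability(vecs) == pytest.approx(
                loop_pattern_variability(vecs), abs=1e-12
            )

    def test_constant_pattern_rejected(self):
        with pytest.raises((ValidationError, ValueError)):
            pattern_variability(np.array([[0.5, 0.5, 0.5], [0.1, 0.2, 0.3]]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 6), st.integers(2, 10))
    def test_range_invariant(self, seed, n, d):
        vecs = np.random.default_rng(seed).normal(size=(n, d))
        assert 0.0 <= pattern_variability(vecs) <= 2.0


class TestNetworkVariability:
    def test_periodic_series_zero_variability(self):
        # windows are exact copies -> identical FC patterns -> V = 0
        rng = np.random.default_rng(4)
        block = rng.normal(size=(20, 3))
        series = np.tile(block, (4, 1))
        v = within_network_variability(series, np.arange(3), window_lengths=(20,))
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_vectorized_equals_loop_oracle(self, rng):
        for _ in range(5):
            series = rng.normal(size=(130, 6))
            ca, cb = np.array([0, 1, 2]), np.array([3, 4, 5])
            lengths = (20, 25, 30)
            assert within_network_variability(series, ca, lengths) == pytest.approx(
                loop_within(series, ca, lengths), abs=1e-12
            )
            assert between_network_variability(series, ca, cb, lengths) == pytest.approx(
                loop_between(series, ca, cb, lengths), abs=1e-12
            )

    def test_too_few_channels_rejected_within(self, rng):
        with pytest.raises(ValueError, match=">= 3"):
            within_network_variability(rng.normal(size=(100, 3)), np.array([0, 1]), (20,))

    def test_cross_block_needs_two_entries(self, rng):
        with pytest.raises(ValueError):
            between_network_variability(
                rng.normal(size=(100, 2)), np.array([0]), np.array([1]), (20,)
            )

    def test_affine_rescaling_invariance(self, rng):
        series = rng.normal(size=(120, 6))
        scaled = series * np.array([2.0, 1.5, 3.0, 0.5, 10.0, 1.0]) + 7.0
        ca = np.array([0, 1, 2])
        v1 = within_network_variability(series, ca, (20, 30))
        v2 = within_network_variability(scaled, ca, (20, 30))
        assert v1 == pytest.approx(v2, abs=1e-12)


class TestVariabilityProfile:
    def test_pair_and_feature_counts(self, small_cohort):
        vp = variability_profile(small_cohort.timeseries[0], small_cohort.network_map, (20, 30))
        assert len(vp.within) == 4
        assert len(vp.between_pairs()) == 6
        row = vp.as_row()
        assert len(row) == 1 + 4 + 6

    def test_two_network_single_pair(self, rng):
        labels = ["a1", "a2", "a3", "b1", "b2", "b3"]
        nm = NetworkMap({lab: lab[0].upper() for lab in labels}, ["A", "B"])
        ts = sd.ParcellatedTimeSeries("s", rng.normal(size=(80, 6)), labels)
        vp = variability_profile(ts, nm, (20,))
        assert list(vp.between_pairs()) == ["A__B"]

    def test_profile_matches_per_feature_functions(self, small_cohort):
        ts = small_cohort.timeseries[0]
        nm = small_cohort.network_map
        by_net = nm.channel_indices(ts.channel_labels)
        vp = variability_profile(ts, nm, (20, 30))
        for i, net in enumerate(nm.networks):
            assert vp.within[i] == pytest.approx(
                within_network_variability(ts.data, by_net[net], (20, 30)), abs=1e-12
            )
        a, b = nm.networks[0], nm.networks[1]
        assert vp.between[0, 1] == pytest.approx(
            between_network_variability(ts.data, by_net[a], by_net[b], (20, 30)),
            abs=1e-12,
        )

    def test_invariant_to_channel_order_within_network(self, rng):
        labels = ["a1", "a2", "a3", "b1", "b2", "b3"]
        nm = NetworkMap({lab: lab[0].upper() for lab in labels}, ["A", "B"])
        data = rng.normal(size=(90, 6))
        ts = sd.ParcellatedTimeSeries("s", data, labels)
        perm = [2, 0, 1, 5, 3, 4]  # reorder within each network
        ts_perm = sd.ParcellatedTimeSeries("s", data[:, perm], [labels[i] for i in perm])
        vp, vp2 = (variability_profile(t, nm, (20, 30)) for t in (ts, ts_perm))
        np.testing.assert_allclose(vp.within, vp2.within, atol=1e-12)
        np.testing.assert_allclose(vp.between, vp2.between, atol=1e-12, equal_nan=True)

    def test_transformer_matches_function(self, small_cohort):
        tv = sd.TemporalVariability(small_cohort.network_map, (20, 30))
        table = tv.fit_transform(small_cohort.timeseries[:3])
        direct = sd.cohort_variability_table(
            small_cohort.timeseries[:3], small_cohort.network_map, (20, 30)
        )
        assert table.equals(direct)
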