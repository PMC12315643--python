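"""Temporal variability of windowed functional connectivity.

A subject's series is cut into n non-overlapping windows of length l
(anchored at the series start, remainder discarded).  In each window the
Pearson FC pattern of a network (upper triangle of the within-network
correlation block) or of a network pair (the full cross-block) is
vectorized, and the variability is

    V = 1 - mean over distinct window pairs (i != j) of the Pearson
        correlation between the two FC vectors,

so V in [0, 2]: identical patterns give 0, anticorrelated patterns 2.
Window lengths l = 20, 22, ..., 40 are averaged so no single l drives the
result.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io_formats import NetworkMap, ParcellatedTimeSeries, ValidationError

#: Window lengths (volumes) averaged by default: 20, 22, ..., 40.
DEFAULT_WINDOW_LENGTHS: tuple[int, ...] = tuple(range(20, 41, 2))


def segment_windows(series: np.ndarray, length: int) -> np.ndarray:
    """Split a T x k series into floor(T / l) non-overlapping l x k windows.

    Windows are anchored at t = 0; the trailing ``T mod l`` timepoints are
    discarded.  At least two windows are required, else variability over
    window pairs is undefined.
    """
    series = np.asarray(series, dtype=float)
    if length < 3:
        raise ValueError(f"window length must be >= 3, got {length}")
    t = series.shape[0]
    n = t // length
    if n < 2:
        raise ValueError(
            f"insufficient windows: T={t} gives {n} window(s) of length {length}"
        )
    return series[: n * length].reshape(n, length, -1)


def window_fc(
    window: np.ndarray,
    rows: np.ndarray | None = None,
    cols: np.ndarray | None = None,
    window_index: int | None = None,
) -> np.ndarray:
    """Pearson FC of one l x k window between channel subsets A and B.

    With ``rows``/``cols`` omitted the full k x k matrix is returned.
    """
    window = np.asarray(window, dtype=float)
    sd = window.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        where = f" in window {window_index}" if window_index is not None else ""
        raise ValidationError(f"zero-variance channel {flat[0]}{where}")
    corr = np.corrcoef(window, rowvar=False)
    corr = np.clip(np.atleast_2d(corr), -1.0, 1.0)
    if rows is None and cols is None:
        return corr
    rows = np.arange(window.shape[1]) if rows is None else np.asarray(rows, dtype=int)
    cols = np.arange(window.shape[1]) if cols is None else np.asarray(cols, dtype=int)
    return corr[np.ix_(rows, cols)]


def pattern_variability(vectors: np.ndarray) -> float:
    """1 - mean pairwise Pearson correlation of row vectors (n x d, n, d >= 2)."""
    vectors = np.asarray(vectors, dtype=float)
    n, d = vectors.shape
    if n < 2:
        raise ValueError("need at least 2 window patterns")
    if d < 2:
        raise ValueError("FC pattern must have at least 2 entries")
    sd = vectors.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValidationError(f"constant FC pattern in window {bad}; correlation undefined")
    corr = np.corrcoef(vectors)
    iu = np.triu_indices(n, k=1)
    return float(np.clip(1.0 - corr[iu].mean(), 0.0, 2.0))


def _maybe_fisher_z(fc_values: np.ndarray, fisher_z: bool) -> np.ndarray:
    """Optionally arctanh-transform FC values before pattern correlation.

    Off by default (the variability statistic is already scale-free); exposed
    for sensitivity analyses.  Values are clipped just inside (-1, 1) so the
    transform stays finite.
    """
    if not fisher_z:
        return fc_values
    return np.arctanh(np.clip(fc_values, -1.0 + 1e-12, 1.0 - 1e-12))


def _windowed_fc_stack(series: np.ndarray, length: int) -> np.ndarray:
    """(n, k, k) stack of per-window full-channel Pearson FC matrices."""
    windows = segment_windows(series, length)
    centered = windows - windows.mean(axis=1, keepdims=True)
    sd = windows.std(axis=1)
    bad = np.argwhere(sd == 0)
    if bad.size:
        w, c = bad[0]
        raise ValidationError(f"zero-variance channel {c} in window {w}")
    cov = np.einsum("nli,nlj->nij", centered, centered) / windows.shape[1]
    corr = cov / (sd[:, :, None] * sd[:, None, :])
    return np.clip(corr, -1.0, 1.0)


def within_network_variability(
    series: np.ndarray,
    channels: np.ndarray,
    window_lengths: Sequence[int] = DEFAULT_WINDOW_LENGTHS,
    fisher_z: bool = False,
) -> float:
    """Within-network variability, averaged over window lengths.

    ``channels`` indexes the network's >= 3 columns of ``series``; each
    window's FC pattern is the strict upper triangle of the within-network
    correlation block.
    """
    channels = np.asarray(channels, dtype=int)
    if channels.size < 3:
        raise ValueError(
            "within-network variability needs >= 3 channels "
            "(the window FC pattern must have >= 2 entries)"
        )
    sub = np.asarray(series, dtype=float)[:, channels]
    iu = np.triu_indices(channels.size, k=1)
    values = []
    for length in window_lengths:
        windows = segment_windows(sub, length)
        vecs = np.stack([
            window_fc(windows[i], window_index=i)[iu] for i in range(windows.shape[0])
        ])
        values.append(pattern_variability(_maybe_fisher_z(vecs, fisher_z)))
    return float(np.mean(values))


def between_network_variability(
    series: np.ndarray,
    channels_a: np.ndarray,
    channels_b: np.ndarray,
    window_lengths: Sequence[int] = DEFAULT_WINDOW_LENGTHS,
    fisher_z: bool = False,
) -> float:
    """Between-network variability from vectorized cross-block FC patterns."""
    channels_a = np.asarray(channels_a, dtype=int)
    channels_b = np.asarray(channels_b, dtype=int)
    if channels_a.size < 1 or channels_b.size < 1:
        raise ValueError("both networks need at least one channel")
    if channels_a.size * channels_b.size < 2:
        raise ValueError("cross-block must have at least 2 entries")
    series = np.asarray(series, dtype=float)
    values = []
    for length in window_lengths:
        windows = segment_windows(series, length)
        vecs = np.stack([
            window_fc(windows[i], channels_a, channels_b, window_index=i).ravel()
            for i in range(windows.shape[0])
        ])
        values.append(pattern_variability(_maybe_fisher_z(vecs, fisher_z)))
    return float(np.mean(values))


@dataclasses.dataclass
class VariabilityProfile:
    """Per-subject within-network and pairwise between-network variability."""

    subject_id: str
    networks: list[str]
    within: np.ndarray            # M values in [0, 2]
    between: np.ndarray           # M x M symmetric, NaN diagonal

    def __post_init__(self) -> None:
        if np.any(self.within < 0) or np.any(self.within > 2):
            raise ValueError("within-network variability out of [0, 2]")
        if not np.allclose(self.between, self.between.T, equal_nan=True):
            raise ValueError("between-network matrix must be symmetric")

    def between_pairs(self) -> dict[str, float]:
        """Condensed pair values keyed 'NetA__NetB' in network order."""
        out = {}
        m = len(self.networks)
        for i in range(m):
            for j in range(i + 1, m):
                out[f"{self.networks[i]}__{self.networks[j]}"] = float(self.between[i, j])
        return out

    def as_row(self) -> dict[str, float]:
        row: dict[str, float] = {"subject_id": self.subject_id}
        row.update({net: float(v) for net, v in zip(self.networks, self.within)})
        row.update(self.between_pairs())
        return row


def _batched_pattern_variability(vectors: np.ndarray) -> np.ndarray:
    """``pattern_variability`` over a (F, n, d) stack of feature patterns."""
    f, n, d = vectors.shape
    if d < 2:
        raise ValueError("FC pattern must have at least 2 entries")
    mean = vectors.mean(axis=2, keepdims=True)
    sd = vectors.std(axis=2, keepdims=True)
    if np.any(sd == 0):
        bad = np.argwhere(sd[:, :, 0] == 0)[0]
        raise ValidationError(
            f"constant FC pattern (feature {bad[0]}, window {bad[1]}); "
            "correlation undefined"
        )
    z = (vectors - mean) / sd
    corr = np.einsum("fnd,fmd->fnm", z, z) / d
    iu = np.triu_indices(n, k=1)
    return np.clip(1.0 - corr[:, iu[0], iu[1]].mean(axis=1), 0.0, 2.0)


def _feature_index_pairs(
    network_map: NetworkMap, channel_labels: Sequence[str]
) -> list[tuple[str, str | None, np.ndarray, np.ndarray]]:
    """Flat channel-index pairs per feature: (net_a, net_b|None, i_idx, j_idx)."""
    by_net = network_map.channel_indices(channel_labels)
    nets = network_map.networks
    feats = []
    for net in nets:
        ix = by_net[net]
        if ix.size < 3:
            raise ValueError(
                f"network {net!r} has {ix.size} channel(s); within-network "
                "pattern variability needs >= 3 (>= 2 FC entries per window)"
            )
        iu = np.triu_indices(ix.size, k=1)
        feats.append((net, None, ix[iu[0]], ix[iu[1]]))
    for a in range(len(nets)):
        for b in range(a + 1, len(nets)):
            ia, ib = by_net[nets[a]], by_net[nets[b]]
            grid_i, grid_j = np.meshgrid(ia, ib, indexing="ij")
            feats.append((nets[a], nets[b], grid_i.ravel(), grid_j.ravel()))
    return feats


def variability_profile(
    ts: ParcellatedTimeSeries,
    network_map: NetworkMap,
    window_lengths: Sequence[int] = DEFAULT_WINDOW_LENGTHS,
    fisher_z: bool = False,
) -> VariabilityProfile:
    """All M within-network and M(M-1)/2 between-network values for a subject.

    Shares one windowed-FC stack per window length across features and
    batches the pattern-correlation step over features of equal pattern
    size, so the full 17-network profile (153 values) costs one pass over
    the data per window length.  Equals the per-feature
    ``within_network_variability`` / ``between_network_variability``
    functions to floating-point round-off.
    """
    feats = _feature_index_pairs(network_map, ts.channel_labels)
    nets = network_map.networks
    m = len(nets)
    values = np.zeros(len(feats))
    by_size: dict[int, list[int]] = {}
    for f, (_, _, i_idx, _) in enumerate(feats):
        by_size.setdefault(i_idx.size, []).append(f)
    for length in window_lengths:
        fc = _windowed_fc_stack(ts.data, length)    # (n, k, k)
        for d, feat_ids in by_size.items():
            stack = np.stack([
                fc[:, feats[f][2], feats[f][3]] for f in feat_ids
            ])                                       # (F, n, d)
            values[feat_ids] += _batched_pattern_variability(
                _maybe_fisher_z(stack, fisher_z)
            )
    values /= len(list(window_lengths))
    within = values[:m]
    between = np.full((m, m), np.nan)
    pos = {net: i for i, net in enumerate(nets)}
    for f in range(m, len(feats)):
        a, b = pos[feats[f][0]], pos[feats[f][1]]
        between[a, b] = between[b, a] = values[f]
    return VariabilityProfile(ts.subject_id, list(nets), within, between)


def cohort_variability_table(
    cohort: Sequence[ParcellatedTimeSeries],
    network_map: NetworkMap,
    window_lengths: Sequence[int] = DEFAULT_WINDOW_LENGTHS,
    fisher_z: bool = False,
) -> pd.DataFrame:
    """Subjects x features table: M within columns then M(M-1)/2 pair columns."""
    rows = [
        variability_profile(ts, network_map, window_lengths, fisher_z).as_row()
        for ts in cohort
    ]
    return pd.DataFrame(rows)


class TemporalVariability(BaseEstimator, TransformerMixin):
    """Transformer: list of parcellated series -> variability feature table.

    Stateless (``fit`` is a no-op); exists so the variability stage composes
    with sklearn pipelines and parameter search over ``window_lengths``.
    """

    def __init__(
        self,
        network_map: NetworkMap | None = None,
        window_lengths: Sequence[int] = DEFAULT_WINDOW_LENGTHS,
        fisher_z: bool = False,
    ) -> None:
        self.network_map = network_map
        self.window_lengths = window_lengths
        self.fisher_z = fisher_z

    def fit(self, X: Sequence[ParcellatedTimeSeries], y=None) -> "TemporalVariability":
        if self.network_map is None:
            raise ValueError("network_map is required")
        return self

    def transform(self, X: Sequence[ParcellatedTimeSeries]) -> pd.DataFrame:
        if self.network_map is None:
            raise ValueError("network_map is required")
        return cohort_variability_table(
            X, self.network_map, self.window_lengths, self.fisher_z
        )
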