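"""Synthetic resting-state cohorts with known brain-state dynamics.

The generator emulates the statistical structure the downstream analysis
assumes: each subject's network BOLD series switches among K latent states
following a first-order Markov chain with subject-specific stickiness
theta_s (self-transition probability), each state emitting multivariate
Gaussians with a network-block covariance; a slow sinusoidal drift of
amplitude delta_s modulates off-diagonal covariance structure, planting
higher windowed-FC variability for larger delta_s; and a depression-like
score is coupled, by construction, positively to switching rate and
variability and negatively to maximum fractional occupancy, on top of
small loadings on sex, age and head motion.

Defaults mirror the study conditions the analysis targets: 696 subjects,
242 volumes, 8 states, 17 Schaefer networks, motion in [0, 0.2] mm, age
19.42 +/- 1.38 years.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    NetworkMap,
    ParcellatedTimeSeries,
    PhenotypeTable,
    write_network_map,
    write_phenotypes,
    write_timeseries,
)

import pandas as pd

#: The 17 large-scale networks of the Schaefer 400-parcel atlas.
SCHAEFER17_NETWORKS = (
    "VisCent", "VisPeri", "SomMotA", "SomMotB", "DorsAttnA", "DorsAttnB",
    "SalVentAttnA", "SalVentAttnB", "LimbicA", "LimbicB", "ContA", "ContB",
    "ContC", "DefaultA", "DefaultB", "DefaultC", "TempPar",
)


def sample_transition_matrix(n_states: int, stickiness: float) -> np.ndarray:
    """Row-stochastic K x K matrix with given self-transition probability.

    Diagonal entries equal ``stickiness``; the remaining (1 - stickiness)
    mass is spread uniformly over the off-diagonal entries of each row.
    """
    if not 0.0 < stickiness < 1.0:
        raise ValueError(f"stickiness must be in (0, 1), got {stickiness}")
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_states == 1:
        return np.ones((1, 1))
    off = (1.0 - stickiness) / (n_states - 1)
    trans = np.full((n_states, n_states), off)
    np.fill_diagonal(trans, stickiness)
    return trans


def _check_stochastic(vec_or_mat: np.ndarray, name: str) -> None:
    arr = np.asarray(vec_or_mat, dtype=float)
    sums = arr.sum(axis=-1)
    if np.any(arr < -1e-12) or not np.allclose(sums, 1.0, atol=1e-8):
        raise ValueError(f"{name} is not a probability distribution (rows must sum to 1)")


def simulate_state_path(
    trans: np.ndarray, init: np.ndarray, n_timepoints: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample a latent state path of length T from a first-order Markov chain.

    The state at time t depends only on the state at t - 1.  States are
    0-based integers in [0, K).
    """
    trans = np.asarray(trans, dtype=float)
    init = np.asarray(init, dtype=float)
    _check_stochastic(trans, "transition matrix")
    _check_stochastic(init, "initial distribution")
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    k = trans.shape[0]
    path = np.empty(n_timepoints, dtype=int)
    # inverse-CDF sampling against cumulative rows; one uniform per step
    cum_trans = np.cumsum(trans, axis=1)
    u = rng.random(n_timepoints)
    path[0] = np.searchsorted(np.cumsum(init), u[0], side="right")
    for t in range(1, n_timepoints):
        path[t] = np.searchsorted(cum_trans[path[t - 1]], u[t], side="right")
    return np.minimum(path, k - 1)


def _nearest_spd(cov: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to SPD by flooring its eigenvalues."""
    sym = 0.5 * (cov + cov.T)
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() > floor:
        return sym
    vals = np.clip(vals, floor, None)
    return (vecs * vals) @ vecs.T


def _cholesky_spd(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return np.linalg.cholesky(_nearest_spd(cov))


def simulate_subject_bold(
    path: np.ndarray,
    means: np.ndarray,
    covs: np.ndarray,
    delta: float,
    rng: np.random.Generator,
    subject_id: str = "sub",
    channel_labels: Sequence[str] | None = None,
    drift_period: float = 60.0,
    drift_phase: float = 0.0,
    drift_channels: np.ndarray | None = None,
) -> ParcellatedTimeSeries:
    """Emit Gaussian observations along a state path, with optional FC drift.

    Row t is drawn from N(means[path_t], C_t) where C_t is the active state's
    covariance; when ``delta > 0`` each off-diagonal entry (i, j) (restricted
    to ``drift_channels`` if given) is scaled by ``1 + delta * G_ij *
    sin(2*pi*t / drift_period + drift_phase)`` with G a fixed random
    symmetric +/-1 sign pattern, and the result is projected back to SPD.
    The sign pattern makes the modulation entry-differential, so the window
    FC *pattern* (not just its magnitude) drifts slowly, planting higher
    windowed-FC pattern variability for larger ``delta``.
    """
    path = np.asarray(path, dtype=int)
    means = np.asarray(means, dtype=float)
    covs = np.asarray(covs, dtype=float)
    k, n = means.shape
    if delta < 0:
        raise ValueError("drift amplitude delta must be >= 0")
    for j in range(k):
        try:
            np.linalg.cholesky(covs[j])
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"state {j} covariance is not SPD") from exc
    t_total = len(path)
    if channel_labels is None:
        channel_labels = [f"ch{i:02d}" for i in range(n)]

    z = rng.standard_normal((t_total, n))
    data = np.empty((t_total, n))
    if delta == 0.0:
        chols = [np.linalg.cholesky(covs[j]) for j in range(k)]
        for j in range(k):
            sel = path == j
            if sel.any():
                data[sel] = means[j] + z[sel] @ chols[j].T
        return ParcellatedTimeSeries(subject_id, data, list(channel_labels))

    mask = np.zeros((n, n), dtype=bool)
    if drift_channels is None:
        mask[:, :] = True
    else:
        ix = np.asarray(drift_channels, dtype=int)
        mask[np.ix_(ix, ix)] = True
    np.fill_diagonal(mask, False)

    # symmetric random +/-1 pattern: which entries strengthen vs weaken
    g = np.triu(rng.choice([-1.0, 1.0], size=(n, n)), k=1)
    g = g + g.T

    sins = np.sin(2.0 * np.pi * np.arange(t_total) / drift_period + drift_phase)
    # quantize the sinusoid so timepoints sharing a (state, level) pair can
    # share one Cholesky factor and one batched draw
    n_levels = 41
    levels = np.linspace(-1.0, 1.0, n_levels)
    level_idx = np.abs(sins[:, None] - levels[None, :]).argmin(axis=1)
    keys = path * n_levels + level_idx
    for key in np.unique(keys):
        state, lev = divmod(int(key), n_levels)
        cov_t = covs[state].copy()
        factor = 1.0 + delta * levels[lev] * g
        cov_t[mask] *= factor[mask]
        chol = _cholesky_spd(cov_t)
        sel = keys == key
        data[sel] = means[state] + z[sel] @ chol.T
    return ParcellatedTimeSeries(subject_id, data, list(channel_labels))


def make_block_covariance(
    block_sizes: Sequence[int],
    within_corr: float = 0.5,
    between_corr: float = 0.1,
    flip_blocks: Sequence[int] = (),
) -> np.ndarray:
    """Network-block correlation matrix, optionally sign-flipping blocks.

    Channels within a block correlate at ``within_corr``; channels in
    different blocks at ``between_corr``, with the sign of every cross-block
    entry touching a block in ``flip_blocks`` (exactly one endpoint) flipped.
    The result is projected to SPD with unit diagonal preserved approximately.
    """
    labels = np.concatenate([np.full(s, b) for b, s in enumerate(block_sizes)])
    n = labels.size
    same = labels[:, None] == labels[None, :]
    corr = np.where(same, within_corr, between_corr)
    np.fill_diagonal(corr, 1.0)
    flips = np.isin(labels, np.asarray(flip_blocks, dtype=int))
    odd = flips[:, None] ^ flips[None, :]
    corr = np.where(odd & ~same, -corr, corr)
    return _nearest_spd(corr)


def make_state_emissions(
    n_states: int,
    block_sizes: Sequence[int],
    rng: np.random.Generator,
    separation: float = 2.0,
    within_corr: float = 0.5,
    between_corr: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """State-specific Gaussian emission parameters over network blocks.

    Means are network-level +/- (separation / 2) loadings with state-specific
    random sign patterns, drawn without replacement so no two states share a
    pattern (states must differ in mean activation); covariances
    share the block template with state-specific sign flips on a random
    subset of blocks, giving each state distinguishable second-order FC.
    """
    block_sizes = list(block_sizes)
    m = len(block_sizes)
    n = int(sum(block_sizes))
    labels = np.concatenate([np.full(s, b) for b, s in enumerate(block_sizes)])
    if n_states > 2 ** m:
        raise ValueError(
            f"cannot give {n_states} states distinct sign patterns over {m} networks"
        )
    means = np.empty((n_states, n))
    covs = np.empty((n_states, n, n))
    used: set[tuple[float, ...]] = set()
    for k in range(n_states):
        while True:
            signs = rng.choice([-1.0, 1.0], size=m)
            if tuple(signs) not in used:
                used.add(tuple(signs))
                break
        means[k] = (separation / 2.0) * signs[labels]
        n_flip = rng.integers(0, max(1, m // 3) + 1)
        flip = rng.choice(m, size=n_flip, replace=False)
        covs[k] = make_block_covariance(block_sizes, within_corr, between_corr, flip)
    return means, covs


@dataclasses.dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    state_paths: list[np.ndarray]
    transition_matrices: list[np.ndarray]
    theta: np.ndarray          # per-subject stickiness, in (0, 1)
    delta: np.ndarray          # per-subject drift amplitude, >= 0
    true_sr: np.ndarray        # switches / T, by direct count
    true_fo: np.ndarray        # S x K occupancy proportions
    true_max_fo: np.ndarray
    emission_means: np.ndarray
    emission_covs: np.ndarray
    b_sr: float
    b_var: float
    noise_sd: float

    def __post_init__(self) -> None:
        for trans in self.transition_matrices:
            if not np.allclose(np.asarray(trans).sum(axis=1), 1.0, atol=1e-10):
                raise ValueError("ground-truth transition matrix rows must sum to 1")
        if not np.allclose(self.true_fo.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("ground-truth FO vectors must sum to 1")
        if np.any(self.theta <= 0) or np.any(self.theta >= 1):
            raise ValueError("theta must lie in (0, 1)")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "state_paths": [p.tolist() for p in self.state_paths],
            "transition_matrices": [t.tolist() for t in self.transition_matrices],
            "theta": self.theta.tolist(),
            "delta": self.delta.tolist(),
            "true_sr": self.true_sr.tolist(),
            "true_fo": self.true_fo.tolist(),
            "true_max_fo": self.true_max_fo.tolist(),
            "emission_means": self.emission_means.tolist(),
            "emission_covs": self.emission_covs.tolist(),
            "b_sr": self.b_sr,
            "b_var": self.b_var,
            "noise_sd": self.noise_sd,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        doc = json.loads(Path(path).read_text())
        return cls(
            state_paths=[np.asarray(p, dtype=int) for p in doc["state_paths"]],
            transition_matrices=[np.asarray(t) for t in doc["transition_matrices"]],
            theta=np.asarray(doc["theta"]),
            delta=np.asarray(doc["delta"]),
            true_sr=np.asarray(doc["true_sr"]),
            true_fo=np.asarray(doc["true_fo"]),
            true_max_fo=np.asarray(doc["true_max_fo"]),
            emission_means=np.asarray(doc["emission_means"]),
            emission_covs=np.asarray(doc["emission_covs"]),
            b_sr=doc["b_sr"],
            b_var=doc["b_var"],
            noise_sd=doc["noise_sd"],
        )


@dataclasses.dataclass
class SyntheticCohort:
    timeseries: list[ParcellatedTimeSeries]
    phenotypes: PhenotypeTable
    ground_truth: GroundTruth
    network_map: NetworkMap

    def __post_init__(self) -> None:
        ids_ts = [ts.subject_id for ts in self.timeseries]
        if ids_ts != self.phenotypes.subject_ids:
            raise ValueError("time series and phenotype subject IDs disagree")
        if len(ids_ts) != len(self.ground_truth.state_paths):
            raise ValueError("ground truth and time series subject counts disagree")

    @property
    def subject_ids(self) -> list[str]:
        return [ts.subject_id for ts in self.timeseries]


@dataclasses.dataclass
class CohortConfig:
    """Generator settings; defaults are the target study's conditions."""

    n_subjects: int = 696
    n_timepoints: int = 242
    n_states: int = 8
    networks: tuple[str, ...] = SCHAEFER17_NETWORKS
    channels_per_network: int = 3
    stickiness_range: tuple[float, float] = (0.80, 0.98)
    b_sr: float = 0.3
    b_var: float = 0.3
    delta_max: float = 0.5
    noise_sd: float = 1.0
    state_mean_separation: float = 2.0
    within_corr: float = 0.5
    between_corr: float = 0.1
    covariate_loadings: tuple[float, float, float] = (0.1, 0.1, 0.1)  # sex, age, fd
    drift_period: float | None = None  # None -> one cycle over the scan (T volumes)
    drift_networks: tuple[str, ...] | None = None  # None -> drift on all channels
    male_fraction: float = 204.0 / 696.0
    age_mean: float = 19.42
    age_sd: float = 1.38
    fd_max: float = 0.2
    seed: int = 0


def _path_fo_sr(path: np.ndarray, n_states: int) -> tuple[np.ndarray, float]:
    t = len(path)
    fo = np.bincount(path, minlength=n_states) / t
    sr = float(np.count_nonzero(np.diff(path) != 0)) / t
    return fo, sr


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full cohort: BOLD series, phenotypes and ground truth.

    Per subject s, stickiness theta_s ~ U(stickiness_range) and drift
    delta_s ~ U(0, delta_max); the depression-like score is

        score_s = z(-b_sr * z(theta_s) + b_var * z(delta_s))
                  + loadings . (sex, z(age), z(fd)) + N(0, noise_sd),

    so, by construction, the score rises with true switching rate and
    planted variability and falls with stickiness (hence with MaxFO).
    Stickiness and drift are standardized before weighting so the two
    coupling coefficients have equal leverage regardless of the parameter
    ranges.  Identical config + seed gives a bit-identical cohort.
    """
    cfg = config
    if cfg.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if cfg.channels_per_network < 1:
        raise ValueError("channels_per_network must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    m = len(cfg.networks)
    block_sizes = [cfg.channels_per_network] * m
    n_channels = m * cfg.channels_per_network
    channel_labels = [
        f"{net}_{i + 1:02d}" for net in cfg.networks for i in range(cfg.channels_per_network)
    ]
    network_map = NetworkMap(
        {lab: lab.rsplit("_", 1)[0] for lab in channel_labels}, list(cfg.networks)
    )

    means, covs = make_state_emissions(
        cfg.n_states, block_sizes, rng,
        separation=cfg.state_mean_separation,
        within_corr=cfg.within_corr, between_corr=cfg.between_corr,
    )

    drift_channels = None
    if cfg.drift_networks is not None:
        by_net = network_map.channel_indices(channel_labels)
        drift_channels = np.concatenate([by_net[net] for net in cfg.drift_networks])

    s = cfg.n_subjects
    theta = rng.uniform(*cfg.stickiness_range, size=s)
    delta = rng.uniform(0.0, cfg.delta_max, size=s)
    sex = (rng.random(s) < cfg.male_fraction).astype(int)
    age = rng.normal(cfg.age_mean, cfg.age_sd, size=s)
    mean_fd = rng.uniform(0.0, cfg.fd_max, size=s)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=s)

    init = np.full(cfg.n_states, 1.0 / cfg.n_states)
    timeseries: list[ParcellatedTimeSeries] = []
    paths: list[np.ndarray] = []
    trans_list: list[np.ndarray] = []
    true_fo = np.empty((s, cfg.n_states))
    true_sr = np.empty(s)
    width = max(4, len(str(s)))
    for i in range(s):
        sid = f"sub-{i + 1:0{width}d}"
        trans = sample_transition_matrix(cfg.n_states, theta[i])
        path = simulate_state_path(trans, init, cfg.n_timepoints, rng)
        ts = simulate_subject_bold(
            path, means, covs, delta[i], rng,
            subject_id=sid, channel_labels=channel_labels,
            drift_period=cfg.drift_period or cfg.n_timepoints,
            drift_phase=phases[i],
            drift_channels=drift_channels,
        )
        timeseries.append(ts)
        paths.append(path)
        trans_list.append(trans)
        true_fo[i], true_sr[i] = _path_fo_sr(path, cfg.n_states)

    planted = -cfg.b_sr * _zscore(theta) + cfg.b_var * _zscore(delta)
    score = (
        _zscore(planted)
        + cfg.covariate_loadings[0] * sex
        + cfg.covariate_loadings[1] * _zscore(age)
        + cfg.covariate_loadings[2] * _zscore(mean_fd)
        + rng.normal(0.0, cfg.noise_sd, size=s)
    )

    phenotypes = PhenotypeTable(pd.DataFrame({
        "subject_id": [ts.subject_id for ts in timeseries],
        "score": score,
        "sex": sex,
        "age": age,
        "mean_fd": mean_fd,
    }))
    ground_truth = GroundTruth(
        state_paths=paths,
        transition_matrices=trans_list,
        theta=theta,
        delta=delta,
        true_sr=true_sr,
        true_fo=true_fo,
        true_max_fo=true_fo.max(axis=1),
        emission_means=means,
        emission_covs=covs,
        b_sr=cfg.b_sr,
        b_var=cfg.b_var,
        noise_sd=cfg.noise_sd,
    )
    return SyntheticCohort(timeseries, phenotypes, ground_truth, network_map)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write a cohort directory: per-subject TSVs, phenotypes, map, truth."""
    outdir = Path(outdir)
    (outdir / "timeseries").mkdir(parents=True, exist_ok=True)
    for ts in cohort.timeseries:
        write_timeseries(ts, outdir / "timeseries" / f"{ts.subject_id}.tsv")
    write_phenotypes(cohort.phenotypes, outdir / "phenotypes.tsv")
    write_network_map(cohort.network_map, outdir / "network_map.yaml")
    cohort.ground_truth.to_json(outdir / "ground_truth.json")
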