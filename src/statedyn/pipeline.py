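"""Reproducible orchestration: simulate -> fit-hmm -> profiles -> variability -> associate.

A single ``RunConfig`` (YAML-loadable) drives all stages.  One top-level
seed fans out to stable per-stage child seeds, so each stage is
independently re-runnable from its cached inputs and a full rerun with the
same seed is bit-identical.  Every stage writes plain text (TSV/JSON) into
a run directory, plus a metadata JSON recording the config hash, seed,
package versions and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import network_contribution, run_association_battery
from .hmm import (
    GaussianHMM,
    decode_cohort,
    dynamics_metrics,
    metrics_table,
    network_mean_series,
    standardize_and_concatenate,
)
from .io_formats import (
    DEFAULT_FD_THRESHOLD,
    NetworkMap,
    ParcellatedTimeSeries,
    PhenotypeTable,
    read_network_map,
    read_phenotypes,
    read_timeseries,
    write_association_table,
)
from .state_profiles import state_profiles
from .synthetic import CohortConfig, SyntheticCohort, simulate_cohort, write_cohort
from .variability import cohort_variability_table

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "fit_hmm", "profiles", "variability", "associate")


@dataclasses.dataclass
class RunConfig:
    """All pipeline settings; defaults reproduce the target study's setup.

    K = 8 states, 10 restarts, window lengths 20-40 step 2, alpha = 0.05,
    motion threshold 0.2 mm.
    """

    seed: int = 0
    output_dir: str = "statedyn_run"
    cohort: dict = dataclasses.field(default_factory=dict)  # CohortConfig overrides
    n_states: int = 8
    n_restarts: int = 10
    tol: float = 1e-6
    max_iter: int = 200
    hmm_on_network_means: bool = True
    occupancy: str = "viterbi"
    window_min: int = 20
    window_max: int = 40
    window_step: int = 2
    alpha: float = 0.05
    fd_threshold: float = DEFAULT_FD_THRESHOLD

    def __post_init__(self) -> None:
        if self.window_min < 3 or self.window_step < 1 or self.window_max < self.window_min:
            raise ValueError("invalid window settings")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def window_lengths(self) -> tuple[int, ...]:
        return tuple(range(self.window_min, self.window_max + 1, self.window_step))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed (< 2**31) derived from the run seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([seed, _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# cohort directory IO

def read_cohort_dir(
    cohort_dir: str | Path, fd_threshold: float | None = DEFAULT_FD_THRESHOLD
) -> tuple[list[ParcellatedTimeSeries], PhenotypeTable, NetworkMap]:
    """Load a cohort directory written by the simulate stage (or hand-made).

    Subjects failing the motion filter, and time-series files without a
    phenotype row (or vice versa), are reported and excluded.
    """
    cohort_dir = Path(cohort_dir)
    phenotypes = read_phenotypes(cohort_dir / "phenotypes.tsv", fd_threshold=fd_threshold)
    network_map = read_network_map(cohort_dir / "network_map.yaml")
    ts_files = {p.stem: p for p in sorted((cohort_dir / "timeseries").glob("*.tsv"))}
    kept_ids = [sid for sid in phenotypes.subject_ids if sid in ts_files]
    missing_ts = sorted(set(phenotypes.subject_ids) - set(ts_files))
    missing_ph = sorted(set(ts_files) - set(phenotypes.subject_ids))
    if missing_ts or missing_ph:
        logger.warning(
            "excluding unmatched subjects: %d without time series %s, "
            "%d without phenotypes %s",
            len(missing_ts), missing_ts[:5], len(missing_ph), missing_ph[:5],
        )
    phenotypes = PhenotypeTable(
        phenotypes.aligned(kept_ids), n_dropped_motion=phenotypes.n_dropped_motion
    )
    series = [read_timeseries(ts_files[sid], sid) for sid in kept_ids]
    return series, phenotypes, network_map


# ---------------------------------------------------------------------------
# stages

def stage_simulate(config: RunConfig, run_dir: Path) -> SyntheticCohort:
    overrides = dict(config.cohort)
    overrides.setdefault("seed", stage_seed(config.seed, "simulate"))
    cohort = simulate_cohort(CohortConfig(**overrides))
    write_cohort(cohort, run_dir / "cohort")
    logger.info("simulated %d subjects", len(cohort.timeseries))
    return cohort


def stage_fit_hmm(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    series, phenotypes, network_map = read_cohort_dir(
        run_dir / "cohort", fd_threshold=config.fd_threshold
    )
    if config.hmm_on_network_means and series[0].n_channels != network_map.n_networks:
        series = [network_mean_series(ts, network_map) for ts in series]
    X, lengths, subject_ids = standardize_and_concatenate(series)
    model = GaussianHMM(
        n_states=config.n_states, n_restarts=config.n_restarts,
        max_iter=config.max_iter, tol=config.tol,
        random_state=stage_seed(config.seed, "fit_hmm"),
    ).fit(X, lengths)
    out = run_dir / "hmm"
    out.mkdir(parents=True, exist_ok=True)
    model.to_json(out / "model.json")
    decodings = decode_cohort(model, X, lengths, subject_ids)
    metrics = metrics_table(
        dynamics_metrics(d, config.n_states, occupancy=config.occupancy) for d in decodings
    )
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False, float_format="%.15g")
    paths = pd.DataFrame(
        {sid: d.viterbi_path for sid, d in zip(subject_ids, decodings)}
    )
    paths.to_csv(out / "viterbi_paths.tsv", sep="\t", index=False)
    return metrics


def stage_profiles(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    model = GaussianHMM.from_json(run_dir / "hmm" / "model.json")
    metrics = pd.read_csv(run_dir / "hmm" / "metrics.tsv", sep="\t")
    fo_cols = [c for c in metrics.columns if c.startswith("fo_state")]
    fo_weights = metrics[fo_cols].mean(axis=0).to_numpy()
    fo_weights = fo_weights / fo_weights.sum()
    profiles = state_profiles(model, fo_weights=fo_weights)
    out = run_dir / "profiles"
    out.mkdir(parents=True, exist_ok=True)
    act = pd.DataFrame(
        np.stack([p.mean_activation for p in profiles]),
        index=[f"state{p.state + 1}" for p in profiles],
    )
    act.to_csv(out / "mean_activation.tsv", sep="\t", float_format="%.15g")
    edge_rows = [
        {"state": p.state + 1, "i": i, "j": j, "weight": w}
        for p in profiles for (i, j, w) in p.top_edges
    ]
    edges = pd.DataFrame(edge_rows, columns=["state", "i", "j", "weight"])
    edges.to_csv(out / "top_edges.tsv", sep="\t", index=False, float_format="%.15g")
    return edges


def stage_variability(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    series, phenotypes, network_map = read_cohort_dir(
        run_dir / "cohort", fd_threshold=config.fd_threshold
    )
    table = cohort_variability_table(series, network_map, config.window_lengths)
    out = run_dir / "variability"
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "variability.tsv", sep="\t", index=False, float_format="%.15g")
    return table


def stage_associate(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    _, phenotypes, network_map = read_cohort_dir(
        run_dir / "cohort", fd_threshold=config.fd_threshold
    )
    metrics = pd.read_csv(run_dir / "hmm" / "metrics.tsv", sep="\t")
    variability = pd.read_csv(run_dir / "variability" / "variability.tsv", sep="\t")
    results = run_association_battery(
        metrics, variability, phenotypes, network_map.networks, alpha=config.alpha
    )
    out = run_dir / "associations"
    out.mkdir(parents=True, exist_ok=True)
    write_association_table(results, out / "associations.tsv")
    contrib = network_contribution(results, network_map)
    contrib.df.to_csv(out / "contributions.tsv", sep="\t", index=False,
                      float_format="%.15g")
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def analyze_cohort(
    cohort: SyntheticCohort,
    n_states: int = 8,
    seed: int = 0,
    n_restarts: int = 1,
    max_iter: int = 30,
    window_lengths: Sequence[int] | None = None,
    alpha: float = 0.05,
    model: GaussianHMM | None = None,
):
    """Run fit-hmm -> metrics -> variability -> associations in memory.

    Convenience wrapper over the same stage functions the disk pipeline
    uses; pass a pre-built ``model`` (e.g. the generating truth) to skip
    fitting.  Returns ``(metrics_df, variability_df, results, model)``.
    """
    from .variability import DEFAULT_WINDOW_LENGTHS

    series = [network_mean_series(ts, cohort.network_map) for ts in cohort.timeseries]
    X, lengths, subject_ids = standardize_and_concatenate(series)
    if model is None:
        model = GaussianHMM(
            n_states=n_states, n_restarts=n_restarts, max_iter=max_iter,
            random_state=seed,
        ).fit(X, lengths)
    decodings = decode_cohort(model, X, lengths, subject_ids)
    metrics = metrics_table(dynamics_metrics(d, model.n_states) for d in decodings)
    variability = cohort_variability_table(
        cohort.timeseries, cohort.network_map,
        window_lengths or DEFAULT_WINDOW_LENGTHS,
    )
    results = run_association_battery(
        metrics, variability, cohort.phenotypes, cohort.network_map.networks, alpha=alpha
    )
    return metrics, variability, results, model


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages into ``config.output_dir``; returns the run directory."""
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    counts = {}
    cohort = stage_simulate(config, run_dir)
    counts["simulate_subjects"] = len(cohort.timeseries)
    metrics = stage_fit_hmm(config, run_dir)
    counts["hmm_metrics_rows"] = len(metrics)
    edges = stage_profiles(config, run_dir)
    counts["profile_edges"] = len(edges)
    variability = stage_variability(config, run_dir)
    counts["variability_rows"] = len(variability)
    counts["variability_features"] = variability.shape[1] - 1
    associations = stage_associate(config, run_dir)
    counts["association_rows"] = len(associations)
    metadata = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "versions": {
            "statedyn": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "row_counts": counts,
    }
    (run_dir / "run_metadata.json").write_text(json.dumps(metadata, indent=2))
    return run_dir
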