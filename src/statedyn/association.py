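"""Covariate-adjusted association testing of dynamics features.

Every feature (per-state fractional occupancy, MaxFO, switching rate,
and each within-/between-network variability value) is tested against the
depression score by partial correlation controlling for sex, age and mean
head motion.  Benjamini-Hochberg FDR is applied within each feature
family (the K state-FO tests; the M within-network tests; the M(M-1)/2
between-network tests), while MaxFO and SR are reported at their raw
two-sided p, matching how such global dynamics metrics are conventionally
reported.  Significant between-network r-values are aggregated to their
endpoint networks to rank network-level contributions.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import NetworkMap, PhenotypeTable, ValidationError

FAMILIES = ("state_fo", "hmm_global", "within_net", "between_net")


@dataclasses.dataclass
class AssociationResult:
    """One feature's partial correlation against the phenotype score."""

    feature: str
    r: float
    p: float
    p_fdr: float
    significant: bool
    family: str

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError(f"{self.feature}: |r| > 1")
        if self.p_fdr < self.p - 1e-12:
            raise ValueError(f"{self.feature}: adjusted p below raw p")


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on [1, covariates] by OLS and the
    residuals correlated; the two-sided p comes from
    t = r * sqrt(df / (1 - r^2)) with df = S - 2 - c.  With no covariates
    this reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s = x.size
    if y.size != s:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        covariates = np.empty((s, 0))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    c = covariates.shape[1]
    if s < c + 4:
        raise ValueError(f"need at least {c + 4} subjects for {c} covariates, got {s}")
    design = np.column_stack([np.ones(s), covariates])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank-deficient")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero residual variance; correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    df = s - 2 - c
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-stable)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, *_ = multipletests(p, method="fdr_bh")
    return p_adj


def _battery_features(
    metrics_df: pd.DataFrame, variability_df: pd.DataFrame, networks: Sequence[str]
) -> list[tuple[str, str]]:
    features: list[tuple[str, str]] = []
    for col in metrics_df.columns:
        if col.startswith("fo_state"):
            features.append((col, "state_fo"))
    features += [("max_fo", "hmm_global"), ("sr", "hmm_global")]
    for col in variability_df.columns:
        if col == "subject_id":
            continue
        features.append((col, "within_net" if col in set(networks) else "between_net"))
    return features


def run_association_battery(
    metrics_df: pd.DataFrame,
    variability_df: pd.DataFrame,
    phenotypes: PhenotypeTable,
    networks: Sequence[str],
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Test every dynamics feature against the score, FDR within families.

    ``metrics_df`` (fo_state*, max_fo, sr) and ``variability_df`` must carry
    a ``subject_id`` column; rows are aligned to the phenotype table, and a
    mismatch in subject sets is an error listing the offending IDs.
    """
    ids = metrics_df["subject_id"].astype(str).tolist()
    other = variability_df["subject_id"].astype(str).tolist()
    if set(ids) != set(other):
        raise ValidationError(
            f"subject mismatch between metrics and variability: "
            f"{sorted(set(ids) ^ set(other))}"
        )
    variability_df = variability_df.set_index("subject_id").loc[ids].reset_index()
    metrics_df = metrics_df.reset_index(drop=True)
    score = phenotypes.scores(ids)
    covariates = phenotypes.covariate_matrix(ids)

    merged = pd.concat(
        [metrics_df.drop(columns="subject_id"), variability_df.drop(columns="subject_id")],
        axis=1,
    )
    features = _battery_features(metrics_df, variability_df, networks)

    raw: dict[str, list[tuple[str, float, float]]] = {fam: [] for fam in FAMILIES}
    for name, family in features:
        r, p = partial_correlation(merged[name].to_numpy(), score, covariates)
        raw[family].append((name, r, p))

    results: list[AssociationResult] = []
    for family in FAMILIES:
        entries = raw[family]
        if not entries:
            continue
        pvals = np.array([p for _, _, p in entries])
        if family == "hmm_global":
            # reported unadjusted, like the global dynamics metrics convention
            p_adj = pvals
        else:
            p_adj = bh_fdr(pvals)
        for (name, r, p), pa in zip(entries, p_adj):
            results.append(AssociationResult(
                feature=name, r=r, p=p, p_fdr=float(pa),
                significant=bool(pa < alpha), family=family,
            ))
    return results


@dataclasses.dataclass
class ContributionTable:
    """Cumulative r per network over its significant between-network pairs."""

    df: pd.DataFrame  # columns: network, cumulative_r, n_pairs, rank


def network_contribution(
    results: Sequence[AssociationResult], network_map: NetworkMap
) -> ContributionTable:
    """Aggregate significant between-network r-values to endpoint networks.

    Each significant pair's r is added to both of its networks; networks are
    ranked by cumulative r (descending).
    """
    cumulative = {net: 0.0 for net in network_map.networks}
    counts = {net: 0 for net in network_map.networks}
    for res in results:
        if res.family != "between_net" or not res.significant:
            continue
        parts = res.feature.split("__")
        if len(parts) != 2 or any(p not in cumulative for p in parts):
            raise ValidationError(f"unparseable between-network pair label {res.feature!r}")
        for net in parts:
            cumulative[net] += res.r
            counts[net] += 1
    df = pd.DataFrame({
        "network": list(cumulative),
        "cumulative_r": [cumulative[n] for n in cumulative],
        "n_pairs": [counts[n] for n in cumulative],
    }).sort_values("cumulative_r", ascending=False, kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return ContributionTable(df)
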