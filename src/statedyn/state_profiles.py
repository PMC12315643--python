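"""Characterize fitted brain states: mean-activation profiles and top FC edges.

Each state is summarized by (a) its mean activation relative to the
occupancy-weighted grand mean across states, and (b) the strongest
positive functional-connectivity edges of its state covariance, converted
to correlation and thresholded at a fraction (default the top 5%) of the
strictly positive off-diagonal entries.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from .hmm import GaussianHMM


@dataclasses.dataclass
class StateProfile:
    state: int
    mean_activation: np.ndarray          # N, relative to the grand mean
    fc: np.ndarray                       # N x N correlation matrix
    top_edges: list[tuple[int, int, float]]


def cov_to_corr(cov: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def stationary_distribution(transmat: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(transmat.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _fo_weights(model: GaussianHMM, fo_weights: np.ndarray | None) -> np.ndarray:
    if fo_weights is None:
        # occupancy implied by the fitted chain itself
        return stationary_distribution(model.transmat_)
    fo_weights = np.asarray(fo_weights, dtype=float)
    if fo_weights.shape != (model.n_states,) or abs(fo_weights.sum() - 1.0) > 1e-8:
        raise ValueError("fo_weights must be a K-vector summing to 1")
    return fo_weights


def state_mean_profile(
    model: GaussianHMM, state: int, fo_weights: np.ndarray | None = None
) -> np.ndarray:
    """State mean activation minus the FO-weighted grand mean across states.

    ``fo_weights`` defaults to the stationary distribution of the fitted
    transition matrix; pass empirical cohort FO for a data-driven reference.
    """
    if not 0 <= state < model.n_states:
        raise IndexError(f"state {state} out of range for K={model.n_states}")
    w = _fo_weights(model, fo_weights)
    grand_mean = w @ model.means_
    return model.means_[state] - grand_mean


def top_positive_fc(
    model: GaussianHMM, state: int, fraction: float = 0.05
) -> list[tuple[int, int, float]]:
    """Strongest positive FC edges of a state.

    The state covariance is converted to correlation; among the strictly
    positive off-diagonal upper-triangle entries, the ``ceil(fraction *
    count)`` largest are retained.  Ties break lexicographically by (i, j).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if not 0 <= state < model.n_states:
        raise IndexError(f"state {state} out of range for K={model.n_states}")
    corr = cov_to_corr(model.covars_[state])
    iu, ju = np.triu_indices_from(corr, k=1)
    weights = corr[iu, ju]
    positive = weights > 0
    if not positive.any():
        warnings.warn(f"state {state}: no positive off-diagonal FC entries")
        return []
    iu, ju, weights = iu[positive], ju[positive], weights[positive]
    n_keep = math.ceil(fraction * len(weights))
    order = sorted(range(len(weights)), key=lambda t: (-weights[t], iu[t], ju[t]))
    return [(int(iu[t]), int(ju[t]), float(weights[t])) for t in order[:n_keep]]


def state_profiles(
    model: GaussianHMM, fo_weights: np.ndarray | None = None, fraction: float = 0.05
) -> list[StateProfile]:
    """All K per-state profiles of a fitted model."""
    return [
        StateProfile(
            state=k,
            mean_activation=state_mean_profile(model, k, fo_weights),
            fc=cov_to_corr(model.covars_[k]),
            top_edges=top_positive_fc(model, k, fraction),
        )
        for k in range(model.n_states)
    ]
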