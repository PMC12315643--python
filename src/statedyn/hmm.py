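"""Gaussian-observation hidden Markov model for brain-state inference.

A K-state HMM with full-covariance Gaussian emissions is fitted by
maximum-likelihood EM (Baum-Welch) with random restarts, the restart with
the highest final log-likelihood kept.  Forward-backward runs on scaled
probabilities (Viterbi in log space), so long concatenations cannot
underflow.  Subject boundaries hard-reset
the chain: the initial distribution is re-applied at the start of every
subject and no transition is counted across a boundary.  Sequences of
equal length are batched through the forward-backward and Viterbi
recursions, so cohort-scale fits (hundreds of subjects at a common T)
cost a few hundred vectorized recursion steps per EM iteration.

From the decoded (Viterbi) path per subject the standard dynamics metrics
follow: fractional occupancy FO_k = #{t : x_t = k} / T, its maximum MaxFO,
and switching rate SR = #{t : x_t != x_{t-1}} / T.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .io_formats import ParcellatedTimeSeries, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# data preparation

def standardize_and_concatenate(
    cohort: Sequence[ParcellatedTimeSeries],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Z-score each subject's each channel, then stack along time.

    Returns ``(X, lengths, subject_ids)`` where ``X`` is the (sum T) x N
    matrix and ``lengths`` gives each subject's T so inference can reset at
    subject boundaries.  A zero-variance channel is an error (it cannot be
    z-scored) naming the subject and channel.
    """
    if not cohort:
        raise ValidationError("empty cohort")
    labels = cohort[0].channel_labels
    blocks = []
    lengths = []
    for ts in cohort:
        if ts.channel_labels != labels:
            raise ValidationError(
                f"{ts.subject_id}: channel labels differ from {cohort[0].subject_id}"
            )
        sd = ts.data.std(axis=0)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            raise ValidationError(
                f"{ts.subject_id}: zero-variance channel {labels[flat[0]]!r}"
            )
        blocks.append((ts.data - ts.data.mean(axis=0)) / sd)
        lengths.append(ts.n_timepoints)
    return np.vstack(blocks), np.asarray(lengths, dtype=int), [ts.subject_id for ts in cohort]


def network_mean_series(ts: ParcellatedTimeSeries, network_map) -> ParcellatedTimeSeries:
    """Collapse channels to their network means (one column per network)."""
    by_net = network_map.channel_indices(ts.channel_labels)
    data = np.column_stack([ts.data[:, by_net[net]].mean(axis=1) for net in network_map.networks])
    return ParcellatedTimeSeries(ts.subject_id, data, list(network_map.networks),
                                 tr_seconds=ts.tr_seconds)


# ---------------------------------------------------------------------------
# log-space recursions (batched over sequences of equal length)

def _log_emission(X: np.ndarray, means: np.ndarray, covars: np.ndarray) -> np.ndarray:
    """(T, K) log N(x_t; mean_k, cov_k)."""
    k = means.shape[0]
    out = np.empty((X.shape[0], k))
    for j in range(k):
        try:
            out[:, j] = multivariate_normal(means[j], covars[j]).logpdf(X)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"state {j} covariance is singular; increase regularization"
            ) from exc
    return out


def _forward_backward_batch(
    log_b: np.ndarray, log_start: np.ndarray, log_trans: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward-backward for a batch of sequences sharing length T.

    ``log_b``: (B, T, K) emission log-densities.  The recursion runs on
    rescaled probabilities (emission densities divided by their per-row
    maximum, forward variables renormalized each step), which is the
    classical scaling scheme: arbitrarily long sequences cannot underflow
    and the log-likelihood is recovered from the accumulated scale factors.

    Returns ``(alpha_hat, beta_hat, b_til, c, gamma, loglik)`` where
    ``gamma`` is the (B, T, K) posterior and ``loglik`` the (B,) sequence
    log-likelihoods; the first four are the scaled intermediates needed to
    accumulate expected transition counts.
    """
    b, t_len, k = log_b.shape
    start = np.exp(log_start)
    trans = np.exp(log_trans)
    log_b_max = log_b.max(axis=2)                      # (B, T)
    b_til = np.exp(log_b - log_b_max[:, :, None])      # rescaled, max 1 per row
    alpha_hat = np.empty_like(b_til)
    c = np.empty((b, t_len))
    a = start[None, :] * b_til[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha_hat[:, 0] = a / c[:, 0][:, None]
    for t in range(1, t_len):
        a = (alpha_hat[:, t - 1] @ trans) * b_til[:, t]
        c[:, t] = a.sum(axis=1)
        alpha_hat[:, t] = a / c[:, t][:, None]
    loglik = np.log(c).sum(axis=1) + log_b_max.sum(axis=1)
    beta_hat = np.empty_like(b_til)
    beta_hat[:, -1] = 1.0
    for t in range(t_len - 2, -1, -1):
        beta_hat[:, t] = ((b_til[:, t + 1] * beta_hat[:, t + 1]) @ trans.T) \
            / c[:, t + 1][:, None]
    gamma = alpha_hat * beta_hat
    gamma /= gamma.sum(axis=2, keepdims=True)
    return alpha_hat, beta_hat, b_til, c, gamma, loglik


def _expected_transitions(
    alpha_hat: np.ndarray, beta_hat: np.ndarray, b_til: np.ndarray,
    c: np.ndarray, trans: np.ndarray,
) -> np.ndarray:
    """Sum over sequences and time of the pairwise posteriors xi_t(i, j)."""
    _, t_len, k = b_til.shape
    xi_sum = np.zeros((k, k))
    for t in range(t_len - 1):
        rhs = (b_til[:, t + 1] * beta_hat[:, t + 1]) / c[:, t + 1][:, None]
        xi_sum += trans * np.einsum("bi,bj->ij", alpha_hat[:, t], rhs)
    return xi_sum


def _viterbi_batch(
    log_b: np.ndarray, log_start: np.ndarray, log_trans: np.ndarray
) -> np.ndarray:
    """Most-probable state path per sequence; ties break to the lowest index."""
    b, t_len, k = log_b.shape
    psi = np.empty((b, t_len, k), dtype=int)
    delta = log_start + log_b[:, 0]
    for t in range(1, t_len):
        trellis = delta[:, :, None] + log_trans[None]  # (B, from, to)
        psi[:, t] = trellis.argmax(axis=1)
        delta = log_b[:, t] + trellis.max(axis=1)
    paths = np.empty((b, t_len), dtype=int)
    paths[:, -1] = delta.argmax(axis=1)
    for t in range(t_len - 2, -1, -1):
        paths[:, t] = psi[np.arange(b), t + 1, paths[:, t + 1]]
    return paths


def _group_by_length(lengths: np.ndarray) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Group sequence indices by length; returns (T, seq_idx, row_offsets)."""
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    groups = []
    for t_len in np.unique(lengths):
        idx = np.flatnonzero(lengths == t_len)
        groups.append((int(t_len), idx, offsets[idx]))
    return groups


# ---------------------------------------------------------------------------
# the estimator

class GaussianHMM(BaseEstimator):
    """K-state HMM with full-covariance Gaussian emissions, fitted by EM.

    Parameters
    ----------
    n_states : number of hidden states K.
    n_restarts : independent EM runs; the best final log-likelihood wins.
    max_iter, tol : EM stopping rule (absolute log-likelihood improvement).
    reg_cond : condition-number threshold above which an M-step covariance
        receives a ridge of 1e-6 times its mean diagonal.
    random_state : base seed; restart r uses ``random_state + r``.

    Fitted attributes: ``startprob_`` (K,), ``transmat_`` (K, K),
    ``means_`` (K, N), ``covars_`` (K, N, N), ``loglik_``,
    ``loglik_history_`` (best restart), ``restart_logliks_``, ``n_iter_``,
    ``converged_``.
    """

    def __init__(
        self,
        n_states: int = 8,
        n_restarts: int = 10,
        max_iter: int = 200,
        tol: float = 1e-6,
        reg_cond: float = 1e10,
        random_state: int = 0,
    ) -> None:
        self.n_states = n_states
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.reg_cond = reg_cond
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------
    def _validate_lengths(self, X: np.ndarray, lengths) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (time x channels)")
        if lengths is None:
            lengths = np.array([X.shape[0]])
        lengths = np.asarray(lengths, dtype=int)
        if lengths.sum() != X.shape[0]:
            raise ValueError("lengths must sum to the number of rows of X")
        if np.any(lengths < 1):
            raise ValueError("every sequence must have length >= 1")
        return lengths

    def _check_fitted(self) -> None:
        if not hasattr(self, "transmat_"):
            raise AttributeError("model is not fitted")

    def _regularize(self, cov: np.ndarray, state: int) -> np.ndarray:
        cond = np.linalg.cond(cov)
        if not np.isfinite(cond) or cond > self.reg_cond:
            eps = 1e-6 * float(np.mean(np.diag(cov)))
            if eps <= 0 or not np.isfinite(eps):
                eps = 1e-6
            logger.warning("state %d covariance ill-conditioned (cond=%.3g); adding %.3g*I",
                           state, cond, eps)
            cov = cov + eps * np.eye(cov.shape[0])
        return cov

    def _init_params(self, X: np.ndarray, seed: int):
        k = self.n_states
        km = KMeans(n_clusters=k, n_init=1, random_state=seed).fit(X)
        means = km.cluster_centers_.copy()
        pooled = np.cov(X, rowvar=False)
        pooled = np.atleast_2d(pooled) + 1e-6 * np.eye(X.shape[1])
        covars = np.repeat(pooled[None], k, axis=0)
        startprob = np.full(k, 1.0 / k)
        if k == 1:
            transmat = np.ones((1, 1))
        else:
            transmat = np.full((k, k), (1.0 - 0.9) / (k - 1))
            np.fill_diagonal(transmat, 0.9)
        return startprob, transmat, means, covars

    def _em_run(self, X: np.ndarray, lengths: np.ndarray, seed: int):
        startprob, transmat, means, covars = self._init_params(X, seed)
        groups = _group_by_length(lengths)
        n_seq = len(lengths)
        k, n = means.shape
        history: list[float] = []
        converged = False
        for iteration in range(self.max_iter):
            log_b_all = _log_emission(X, means, covars)
            log_start = np.log(np.maximum(startprob, 1e-300))
            log_trans = np.log(np.maximum(transmat, 1e-300))

            gamma_flat = np.empty((X.shape[0], k))
            xi_sum = np.zeros((k, k))
            start_sum = np.zeros(k)
            total_ll = 0.0
            for t_len, seq_idx, row_off in groups:
                rows = (row_off[:, None] + np.arange(t_len)[None, :]).ravel()
                log_b = log_b_all[rows].reshape(len(seq_idx), t_len, k)
                ah, bh, btil, c, gamma, ll = _forward_backward_batch(
                    log_b, log_start, log_trans
                )
                gamma_flat[rows] = gamma.reshape(-1, k)
                xi_sum += _expected_transitions(ah, bh, btil, c, np.exp(log_trans))
                start_sum += gamma[:, 0].sum(axis=0)
                total_ll += float(ll.sum())
            history.append(total_ll)

            # M step
            startprob = start_sum / n_seq
            if k > 1:
                row_tot = xi_sum.sum(axis=1, keepdims=True)
                transmat = np.where(row_tot > 0, xi_sum / np.maximum(row_tot, 1e-300),
                                    1.0 / k)
            nk = gamma_flat.sum(axis=0)
            collapsed = np.flatnonzero(nk < max(1.0, 1e-6 * X.shape[0]))
            means = (gamma_flat.T @ X) / np.maximum(nk, 1e-300)[:, None]
            for j in range(k):
                if j in collapsed:
                    logger.warning("state %d responsibility collapsed (N_k=%.3g); "
                                   "covariance re-regularized", j, nk[j])
                    covars[j] = self._regularize(
                        covars[j] + 1e-3 * np.eye(n) * np.mean(np.diag(covars[j])), j)
                    continue
                xc = X - means[j]
                cov = (gamma_flat[:, j][:, None] * xc).T @ xc / nk[j]
                covars[j] = self._regularize(0.5 * (cov + cov.T), j)

            if len(history) > 1:
                improvement = history[-1] - history[-2]
                if improvement < -1e-8 * max(1.0, abs(history[-2])):
                    logger.warning("EM log-likelihood decreased by %.3g", -improvement)
                if abs(improvement) < self.tol * max(1.0, abs(history[-2]) * 1e-6):
                    converged = True
                    break
        if not converged and self.max_iter > 1:
            logger.warning("EM did not converge in %d iterations; returning best-so-far",
                           self.max_iter)
        return startprob, transmat, means, covars, history, converged

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X: np.ndarray, lengths: Sequence[int] | None = None) -> "GaussianHMM":
        """Fit by EM with restarts on concatenated sequences.

        ``lengths`` marks subject boundaries; inference restarts the chain
        at each boundary and counts no cross-boundary transitions.
        """
        X = np.asarray(X, dtype=float)
        lengths = self._validate_lengths(X, lengths)
        if self.n_states < 1 or self.n_restarts < 1:
            raise ValueError("n_states and n_restarts must be >= 1")
        best = None
        restart_lls: list[float] = []
        for r in range(self.n_restarts):
            result = self._em_run(X, lengths, seed=self.random_state + r)
            final_ll = result[4][-1]
            restart_lls.append(final_ll)
            if best is None or final_ll > best[4][-1]:
                best = result
        startprob, transmat, means, covars, history, converged = best
        self.startprob_ = startprob
        self.transmat_ = transmat
        self.means_ = means
        self.covars_ = covars
        self.loglik_history_ = np.asarray(history)
        self.loglik_ = float(history[-1])
        self.restart_logliks_ = np.asarray(restart_lls)
        self.n_iter_ = len(history)
        self.converged_ = converged
        self.n_features_in_ = X.shape[1]
        return self

    def score(self, X: np.ndarray, lengths: Sequence[int] | None = None) -> float:
        """Total log-likelihood of the sequences under the fitted model."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        lengths = self._validate_lengths(X, lengths)
        total = 0.0
        log_b_all = _log_emission(X, self.means_, self.covars_)
        log_start = np.log(np.maximum(self.startprob_, 1e-300))
        log_trans = np.log(np.maximum(self.transmat_, 1e-300))
        for t_len, seq_idx, row_off in _group_by_length(lengths):
            rows = (row_off[:, None] + np.arange(t_len)[None, :]).ravel()
            log_b = log_b_all[rows].reshape(len(seq_idx), t_len, -1)
            *_, ll = _forward_backward_batch(log_b, log_start, log_trans)
            total += float(ll.sum())
        return total

    def predict_proba(self, X: np.ndarray, lengths: Sequence[int] | None = None) -> np.ndarray:
        """(sum T) x K posterior state probabilities (forward-backward)."""
        return self.posteriors_and_logliks(X, lengths)[0]

    def posteriors_and_logliks(
        self, X: np.ndarray, lengths: Sequence[int] | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Posterior gamma (sum T, K) and per-sequence log-likelihoods."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        lengths = self._validate_lengths(X, lengths)
        out = np.empty((X.shape[0], self.n_states))
        logliks = np.empty(len(lengths))
        log_b_all = _log_emission(X, self.means_, self.covars_)
        log_start = np.log(np.maximum(self.startprob_, 1e-300))
        log_trans = np.log(np.maximum(self.transmat_, 1e-300))
        for t_len, seq_idx, row_off in _group_by_length(lengths):
            rows = (row_off[:, None] + np.arange(t_len)[None, :]).ravel()
            log_b = log_b_all[rows].reshape(len(seq_idx), t_len, -1)
            *_, gamma, ll = _forward_backward_batch(log_b, log_start, log_trans)
            out[rows] = gamma.reshape(-1, self.n_states)
            logliks[seq_idx] = ll
        return out, logliks

    def predict(self, X: np.ndarray, lengths: Sequence[int] | None = None) -> np.ndarray:
        """Viterbi path per sequence, concatenated ((sum T,) integer array)."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        lengths = self._validate_lengths(X, lengths)
        out = np.empty(X.shape[0], dtype=int)
        log_b_all = _log_emission(X, self.means_, self.covars_)
        log_start = np.log(np.maximum(self.startprob_, 1e-300))
        log_trans = np.log(np.maximum(self.transmat_, 1e-300))
        for t_len, seq_idx, row_off in _group_by_length(lengths):
            rows = (row_off[:, None] + np.arange(t_len)[None, :]).ravel()
            log_b = log_b_all[rows].reshape(len(seq_idx), t_len, -1)
            paths = _viterbi_batch(log_b, log_start, log_trans)
            out[rows] = paths.ravel()
        return out

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "n_states": self.n_states,
            "startprob": self.startprob_.tolist(),
            "transmat": self.transmat_.tolist(),
            "means": self.means_.tolist(),
            "covars": self.covars_.tolist(),
            "loglik": self.loglik_,
            "restart_logliks": self.restart_logliks_.tolist(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, doc: dict) -> "GaussianHMM":
        model = cls(n_states=doc["n_states"])
        model.startprob_ = np.asarray(doc["startprob"])
        model.transmat_ = np.asarray(doc["transmat"])
        model.means_ = np.asarray(doc["means"])
        model.covars_ = np.asarray(doc["covars"])
        model.loglik_ = doc.get("loglik", float("nan"))
        model.restart_logliks_ = np.asarray(doc.get("restart_logliks", []))
        model.n_features_in_ = model.means_.shape[1]
        return model

    @classmethod
    def from_json(cls, path: str | Path) -> "GaussianHMM":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_params(cls, startprob, transmat, means, covars) -> "GaussianHMM":
        """Build a decodable model from explicit parameters (no fitting)."""
        startprob = np.asarray(startprob, dtype=float)
        transmat = np.asarray(transmat, dtype=float)
        means = np.atleast_2d(np.asarray(means, dtype=float))
        covars = np.asarray(covars, dtype=float)
        model = cls(n_states=len(startprob))
        if abs(startprob.sum() - 1.0) > 1e-10:
            raise ValueError("startprob must sum to 1")
        if not np.allclose(transmat.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transmat rows must sum to 1")
        model.startprob_ = startprob
        model.transmat_ = transmat
        model.means_ = means
        model.covars_ = covars
        model.n_features_in_ = means.shape[1]
        return model


# ---------------------------------------------------------------------------
# thin functional wrappers

def fit_hmm(
    X: np.ndarray,
    lengths: Sequence[int] | None,
    n_states: int,
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> GaussianHMM:
    """Fit a ``GaussianHMM`` on concatenated, subject-bounded sequences."""
    return GaussianHMM(
        n_states=n_states, n_restarts=n_restarts, max_iter=max_iter,
        tol=tol, random_state=seed,
    ).fit(X, lengths)


def forward_backward(model: GaussianHMM, series: np.ndarray) -> tuple[np.ndarray, float]:
    """Posterior state probabilities and log-likelihood for one sequence."""
    gamma = model.predict_proba(series)
    return gamma, model.score(series)


def viterbi(model: GaussianHMM, series: np.ndarray) -> np.ndarray:
    """Most-probable state path for one sequence (0-based states)."""
    return model.predict(series)


# ---------------------------------------------------------------------------
# decodings and metrics

@dataclasses.dataclass
class StateDecoding:
    """Per-subject posterior and hard state assignments."""

    subject_id: str
    gamma: np.ndarray
    viterbi_path: np.ndarray
    loglik: float

    def __post_init__(self) -> None:
        row_sums = self.gamma.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-8):
            raise ValueError(f"{self.subject_id}: posterior rows must sum to 1")


@dataclasses.dataclass
class DynamicsMetrics:
    """Fractional occupancy, its maximum, and switching rate for a subject."""

    subject_id: str
    fo: np.ndarray
    max_fo: float
    sr: float


def decode_cohort(
    model: GaussianHMM, X: np.ndarray, lengths: Sequence[int], subject_ids: Sequence[str]
) -> list[StateDecoding]:
    """Decode every subject in a concatenated cohort matrix."""
    lengths = np.asarray(lengths, dtype=int)
    gamma_all, logliks = model.posteriors_and_logliks(X, lengths)
    paths_all = model.predict(X, lengths)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    return [
        StateDecoding(sid, gamma_all[offsets[i]:offsets[i + 1]],
                      paths_all[offsets[i]:offsets[i + 1]], float(logliks[i]))
        for i, sid in enumerate(subject_ids)
    ]


def dynamics_metrics(
    decoding: StateDecoding, n_states: int, occupancy: str = "viterbi"
) -> DynamicsMetrics:
    """FO, MaxFO and SR from a decoding.

    ``occupancy='viterbi'`` counts hard path visits (default; SR is always a
    literal switch count divided by T); ``'posterior'`` averages the
    posterior state probabilities instead.
    """
    path = decoding.viterbi_path
    t = len(path)
    if occupancy == "viterbi":
        fo = np.bincount(path, minlength=n_states) / t
    elif occupancy == "posterior":
        fo = decoding.gamma.mean(axis=0)
    else:
        raise ValueError(f"unknown occupancy mode {occupancy!r}")
    sr = float(np.count_nonzero(np.diff(path) != 0)) / t
    return DynamicsMetrics(decoding.subject_id, fo, float(fo.max()), sr)


def metrics_table(metrics: Iterable[DynamicsMetrics]) -> pd.DataFrame:
    """Tidy per-subject table: fo_state1..fo_stateK, max_fo, sr."""
    rows = []
    for m in metrics:
        row = {"subject_id": m.subject_id}
        row.update({f"fo_state{k + 1}": m.fo[k] for k in range(len(m.fo))})
        row["max_fo"] = m.max_fo
        row["sr"] = m.sr
        rows.append(row)
    return pd.DataFrame(rows)


def hungarian_match(path_true: np.ndarray, path_pred: np.ndarray, n_states: int) -> np.ndarray:
    """Permutation p maximizing agreement of ``p[path_pred]`` with ``path_true``.

    Fitted state labels are arbitrary; this resolves the label switching by
    maximum-overlap assignment (Hungarian algorithm on the confusion matrix).
    """
    from scipy.optimize import linear_sum_assignment

    confusion = np.zeros((n_states, n_states))
    np.add.at(confusion, (path_pred, path_true), 1)
    rows, cols = linear_sum_assignment(-confusion)
    perm = np.empty(n_states, dtype=int)
    perm[rows] = cols
    return perm


# ---------------------------------------------------------------------------
# model-order scan

def scan_states(
    X: np.ndarray,
    lengths: Sequence[int],
    k_values: Sequence[int] = range(8, 13),
    n_runs: int = 10,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stability scan over model orders.

    For each K, ``n_runs`` independent single-restart fits are decoded and
    the mean pairwise adjusted Rand index of their Viterbi paths summarizes
    run-to-run stability (ARI is label-permutation invariant, so no state
    matching is needed).  Returns ``(runs, summary)`` tables; with a single
    run the similarity is undefined and reported as null.
    """
    k_values = list(k_values)
    if not k_values:
        raise ValueError("k_values must be non-empty")
    run_rows = []
    summary_rows = []
    for k in k_values:
        paths = []
        for run in range(n_runs):
            model = GaussianHMM(
                n_states=k, n_restarts=1, random_state=seed + 1000 * k + run,
                **fit_kwargs,
            ).fit(X, lengths)
            path = model.predict(X, lengths)
            paths.append(path)
            run_rows.append({"n_states": k, "run": run, "loglik": model.loglik_})
        if len(paths) < 2:
            similarity = np.nan
        else:
            aris = [
                adjusted_rand_score(paths[i], paths[j])
                for i in range(len(paths)) for j in range(i + 1, len(paths))
            ]
            similarity = float(np.mean(aris))
        summary_rows.append({"n_states": k, "mean_pairwise_ari": similarity})
    return pd.DataFrame(run_rows), pd.DataFrame(summary_rows)
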