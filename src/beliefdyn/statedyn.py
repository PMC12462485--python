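"""Gaussian-HMM brain-state segmentation and consensus transition detection.

The goal is a group-level estimate of *when* an ROI's BOLD signal switches
between latent states, robust to the stochasticity of EM fitting:

1. ``select_n_states`` — bootstrap over subject subsets (drop 10 subjects, 30
   repeats), fit HMMs over K = 2..9, pick the BIC-minimal K per run, take the
   median.
2. ``consensus_transitions`` — refit the chosen model several times (default
   10) from different initialisations, Viterbi-decode the group-mean series,
   mark state changes, average the binary transition tracks into a 0-1
   consensus course, and binarize it at mean + 2 SD with the same
   final-TR-of-run rule used for the behavioural update courses.
3. ``coincidence_proportions`` — fraction of each domain's update points
   falling inside forward windows of 0..8 TRs that open at each transition.

Emissions are univariate Gaussians per state (ROI-mean input).  EM fitting
(Baum-Welch with per-step scaling, k-means++ initial means, a variance floor
against state collapse, and an early stop if the floored M-step would lower
the likelihood) and Viterbi decoding (ties broken toward the lower state
index) are implemented here; states are relabelled by ascending emission
mean so runs are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm
from sklearn.cluster import kmeans_plusplus

from .intersubject import ROISeriesSet
from .ratings import UpdatePointSet, threshold_course

__all__ = [
    "HMMParams",
    "HMMFit",
    "StateSelection",
    "ConsensusTransitions",
    "CoincidenceTable",
    "fit_hmm",
    "forward_loglik",
    "viterbi_path",
    "bic",
    "select_n_states",
    "consensus_transitions",
    "coincidence_proportions",
    "capture_proportions",
]


@dataclass
class HMMParams:
    """Univariate-Gaussian HMM parameters, states ordered by mean."""

    means: np.ndarray
    sds: np.ndarray
    trans: np.ndarray
    init: np.ndarray

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        self.init = np.asarray(self.init, dtype=float)
        k = self.means.size
        if self.trans.shape != (k, k):
            raise ValueError("transition matrix shape mismatch")
        if np.any(np.abs(self.trans.sum(axis=1) - 1) > 1e-9):
            raise ValueError("transition rows must sum to 1")
        if abs(self.init.sum() - 1) > 1e-9:
            raise ValueError("initial distribution must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("state SDs must be positive")

    @property
    def n_states(self) -> int:
        return self.means.size


@dataclass
class HMMFit:
    params: HMMParams
    log_likelihood: float
    ll_history: np.ndarray
    converged: bool
    variance_floored: bool
    n_obs: int


def _as_sequences(data, fit_on: str):
    """(pooled samples (N,1), lengths) from ROISeriesSet / 2-D / 1-D input."""
    if isinstance(data, ROISeriesSet):
        arr = data.data
    else:
        arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        return arr[:, None], [arr.size]
    if fit_on == "mean":
        series = arr.mean(axis=0)
        return series[:, None], [series.size]
    if fit_on == "concat":
        return arr.reshape(-1, 1), [arr.shape[1]] * arr.shape[0]
    raise ValueError("fit_on must be 'mean' or 'concat'")


def _emission_probs(x: np.ndarray, means: np.ndarray, sds: np.ndarray):
    """Gaussian densities (T x K), clipped away from exact zero for scaling."""
    z = (x[:, None] - means[None, :]) / sds[None, :]
    b = np.exp(-0.5 * z ** 2) / (np.sqrt(2 * np.pi) * sds[None, :])
    return np.maximum(b, 1e-300)


def _fb_core(b, init, trans):
    """Scaled forward-backward on emission densities ``b`` (T x K)."""
    n_t, k = b.shape
    alpha = np.empty((n_t, k))
    scale = np.empty(n_t)
    a = init * b[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, n_t):
        a = (alpha[t - 1] @ trans) * b[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    beta = np.empty((n_t, k))
    beta[-1] = 1.0
    xi_sum = np.zeros((k, k))
    for t in range(n_t - 2, -1, -1):
        bb = b[t + 1] * beta[t + 1]
        beta[t] = (trans @ bb) / scale[t + 1]
        xi_sum += np.outer(alpha[t], bb / scale[t + 1]) * trans
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1).reshape(-1, 1)
    return gamma, xi_sum, np.log(scale).sum()


try:  # sequential recursions benefit hugely from compilation
    from numba import njit

    _fb_core = njit(cache=False)(_fb_core)
    _fb_core(np.ones((8, 2)) * 0.5, np.full(2, 0.5), np.full((2, 2), 0.5))
except ImportError:  # pragma: no cover - numpy fallback
    pass


def _forward_backward(x, init, trans, means, sds):
    """Scaled forward-backward; returns (gamma, xi_sum, log-likelihood)."""
    b = _emission_probs(x, means, sds)
    gamma, xi_sum, ll = _fb_core(b, init, trans)
    return gamma, xi_sum, float(ll)


def fit_hmm(
    data,
    n_states: int,
    seed: int = 0,
    fit_on: str = "mean",
    tol: float = 1e-6,
    max_iter: int = 500,
) -> HMMFit:
    """Baum-Welch fit of a univariate-Gaussian HMM.

    ``data`` may be a ROISeriesSet, a subjects x TRs matrix, or a single
    series.  With ``fit_on="mean"`` the subject-mean series is fitted; with
    ``"concat"`` each subject's series enters as an independent sequence
    sharing parameters.  Means are initialised by k-means++ on the pooled
    samples with the given seed; the transition matrix starts sticky
    (diagonal 0.9).  Convergence when the log-likelihood gain falls below
    ``tol``; the per-iteration log-likelihood history is returned and is
    non-decreasing (if the variance floor would ever lower it, fitting stops
    at the best parameters).  Collapsed states (SD under 1e-8 or vanishing
    responsibility) are floored at 1e-6 of the data SD and flagged.
    """
    if n_states < 2:
        raise ValueError("need at least 2 states")
    X, lengths = _as_sequences(data, fit_on)
    if np.unique(X).size < n_states:
        raise ValueError("fewer distinct values than states")
    x_all = X[:, 0]
    data_sd = float(x_all.std())
    sd_floor = max(1e-6 * data_sd, 1e-12)
    seqs = np.split(x_all, np.cumsum(lengths)[:-1])
    k = n_states

    centers, _ = kmeans_plusplus(X, k, random_state=int(seed) % (2 ** 32))
    means = np.sort(centers[:, 0])
    sds = np.full(k, max(data_sd, sd_floor))
    off = 0.1 / max(k - 1, 1)
    trans = np.full((k, k), off) + (0.9 - off) * np.eye(k)
    init = np.full(k, 1.0 / k)

    history: list = []
    converged = False
    floored = False
    prev = (init, trans, means, sds)
    for _ in range(max_iter):
        g0 = np.zeros(k)
        xi = np.zeros((k, k))
        gsum = np.zeros(k)
        gx = np.zeros(k)
        gxx = np.zeros(k)
        ll = 0.0
        for x in seqs:
            gamma, xi_s, seq_ll = _forward_backward(x, init, trans, means, sds)
            ll += seq_ll
            g0 += gamma[0]
            xi += xi_s
            gsum += gamma.sum(axis=0)
            gx += gamma.T @ x
            gxx += gamma.T @ (x ** 2)
        if history and ll < history[-1]:
            # floored M-step lowered the likelihood: keep the best params
            init, trans, means, sds = prev
            converged = True
            break
        history.append(ll)
        if len(history) > 1 and history[-1] - history[-2] < tol:
            converged = True
            break
        prev = (init, trans, means, sds)
        init = g0 / g0.sum()
        denom = xi.sum(axis=1, keepdims=True)
        trans = np.where(denom > 1e-300, xi / np.maximum(denom, 1e-300),
                         1.0 / k)
        ok = gsum > 1e-10
        floored |= bool(np.any(~ok))
        means = np.where(ok, gx / np.maximum(gsum, 1e-300), means)
        var = np.where(ok, gxx / np.maximum(gsum, 1e-300) - means ** 2,
                       sd_floor ** 2)
        small = var < sd_floor ** 2
        floored |= bool(np.any(small & ok & (np.sqrt(np.maximum(var, 0))
                                             < 1e-8)))
        sds = np.sqrt(np.maximum(var, sd_floor ** 2))

    order = np.argsort(means)
    params = HMMParams(means[order], sds[order],
                       trans[np.ix_(order, order)], init[order])
    ll_final = sum(forward_loglik(params, x) for x in seqs)
    return HMMFit(params, float(ll_final), np.asarray(history), converged,
                  floored, X.shape[0])


# ---------------------------------------------------------------------------
# likelihood and decoding
# ---------------------------------------------------------------------------

def _log_emissions(params: HMMParams, series: np.ndarray) -> np.ndarray:
    series = np.asarray(series, dtype=float).ravel()
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    return norm.logpdf(series[:, None], params.means[None, :],
                       params.sds[None, :])


def forward_loglik(params: HMMParams, series: np.ndarray) -> float:
    """Log-likelihood of a series via the forward algorithm (log domain)."""
    logb = _log_emissions(params, series)
    with np.errstate(divide="ignore"):
        log_init = np.log(params.init)
        log_trans = np.log(params.trans)
    alpha = log_init + logb[0]
    for t in range(1, logb.shape[0]):
        alpha = logsumexp(alpha[:, None] + log_trans, axis=0) + logb[t]
    return float(logsumexp(alpha))


def viterbi_path(params: HMMParams, series: np.ndarray) -> np.ndarray:
    """Maximum a-posteriori state path (0-based labels, lower index on ties)."""
    logb = _log_emissions(params, series)
    n_t, k = logb.shape
    with np.errstate(divide="ignore"):
        log_init = np.log(params.init)
        log_trans = np.log(params.trans)
    delta = log_init + logb[0]
    back = np.zeros((n_t, k), dtype=int)
    for t in range(1, n_t):
        scores = delta[:, None] + log_trans
        back[t] = np.argmax(scores, axis=0)       # argmax -> lowest index tie
        delta = scores[back[t], np.arange(k)] + logb[t]
    path = np.empty(n_t, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(n_t - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def bic(ll: float, n_states: int, n_obs: int) -> float:
    """BIC with p = (K-1) + K(K-1) + 2K free parameters."""
    p = (n_states - 1) + n_states * (n_states - 1) + 2 * n_states
    if n_obs <= p:
        raise ValueError(f"n_obs ({n_obs}) must exceed free parameters ({p})")
    return -2.0 * ll + p * np.log(n_obs)


# ---------------------------------------------------------------------------
# bootstrapped selection and consensus
# ---------------------------------------------------------------------------

@dataclass
class StateSelection:
    median_k: int
    best_k_per_run: np.ndarray
    bic_table: pd.DataFrame
    n_failed_runs: int


def select_n_states(
    data: ROISeriesSet,
    k_range: Iterable[int] = range(2, 10),
    n_boot: int = 30,
    n_drop: int = 10,
    seed: int = 0,
    fit_on: str = "mean",
) -> StateSelection:
    """Bootstrapped BIC selection of the number of latent states.

    Each run drops ``n_drop`` random subjects, fits every K in ``k_range``,
    and records the BIC-minimal K; the lower median over runs is returned.
    Runs whose fits all fail are skipped; fewer than min(20, n_boot)
    successful runs is an error.
    """
    ks = list(k_range)
    n_sub = data.n_subjects
    if n_sub <= n_drop:
        raise ValueError("n_subjects must exceed n_drop")
    rng = np.random.default_rng(seed)
    best, rows, failed = [], [], 0
    for b in range(n_boot):
        drop = rng.choice(n_sub, size=n_drop, replace=False)
        keep = np.setdiff1d(np.arange(n_sub), drop)
        sub = ROISeriesSet(data.roi, data.data[keep], data.tr)
        run_seed = int(rng.integers(0, 2 ** 31))
        scores = {}
        for k in ks:
            try:
                fit = fit_hmm(sub, k, seed=run_seed + k, fit_on=fit_on)
                scores[k] = bic(fit.log_likelihood, k, fit.n_obs)
            except (ValueError, np.linalg.LinAlgError):
                continue
        if not scores:
            failed += 1
            continue
        k_best = min(scores, key=lambda k: (scores[k], k))
        best.append(k_best)
        rows.append({"run": b, "best_k": k_best, **{f"bic_{k}": v
                                                    for k, v in scores.items()}})
    if len(best) < min(20, n_boot):
        raise RuntimeError(f"only {len(best)} successful bootstrap runs")
    best = np.asarray(sorted(best))
    median_k = int(best[(best.size - 1) // 2])    # lower median on even ties
    return StateSelection(median_k, np.asarray(best), pd.DataFrame(rows), failed)


@dataclass
class ConsensusTransitions:
    roi: str
    course: np.ndarray            # per-TR transition probability over runs
    transition_trs: np.ndarray    # binarized at mean + 2 SD, final TR per run
    n_runs: int


def consensus_transitions(
    data: ROISeriesSet,
    n_states: int,
    n_runs: int = 10,
    seed: int = 0,
    theta_sd: float = 2.0,
    fit_on: str = "mean",
) -> ConsensusTransitions:
    """Averaged-and-binarized transition course over repeated HMM fits.

    Each run refits from a fresh initialisation, Viterbi-decodes the
    subject-mean series, and marks TR t when state(t) != state(t-1).  The 0-1
    marks are averaged across runs and binarized exactly like the behavioural
    update courses (mean + ``theta_sd`` SD, final TR of each supra-threshold
    run).
    """
    if isinstance(data, ROISeriesSet):
        series = data.data.mean(axis=0)
        roi = data.roi
    else:
        series = np.asarray(data, dtype=float)
        roi = "series"
    rng = np.random.default_rng(seed)
    marks = np.zeros((n_runs, series.size))
    for r in range(n_runs):
        fit = fit_hmm(data, n_states, seed=int(rng.integers(0, 2 ** 31)),
                      fit_on=fit_on)
        path = viterbi_path(fit.params, series)
        marks[r, 1:] = path[1:] != path[:-1]
    course = marks.mean(axis=0)
    if course.max() == 0:
        warnings.warn("no transitions in any run", stacklevel=2)
        trs = np.empty(0, dtype=int)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trs = threshold_course(course, theta_sd)
    trs = trs[trs >= 1]
    return ConsensusTransitions(roi, course, trs, n_runs)


# ---------------------------------------------------------------------------
# coincidence counting
# ---------------------------------------------------------------------------

def capture_proportions(transition_trs: np.ndarray, update_trs: np.ndarray,
                        t_max: int = 8) -> np.ndarray:
    """Fraction of updates inside the union of windows [tr, tr + t], t=0..t_max."""
    tt = np.sort(np.asarray(transition_trs, dtype=int))
    u = np.asarray(update_trs, dtype=int)
    if u.size == 0:
        return np.full(t_max + 1, np.nan)
    if tt.size == 0:
        return np.zeros(t_max + 1)
    idx = np.searchsorted(tt, u, side="right") - 1
    dist = np.where(idx >= 0, u - tt[np.clip(idx, 0, None)], np.inf)
    return (dist[:, None] <= np.arange(t_max + 1)[None, :]).mean(axis=0)


@dataclass
class CoincidenceTable:
    roi: str
    proportions: pd.DataFrame     # index: window size t; columns: domains

    def __post_init__(self):
        vals = self.proportions.to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if np.any((vals[finite] < 0) | (vals[finite] > 1)):
            raise ValueError("proportions must lie in [0, 1]")


def coincidence_proportions(
    trans: ConsensusTransitions | np.ndarray,
    updates: Mapping[str, UpdatePointSet],
    t_max: int = 8,
) -> CoincidenceTable:
    """Per-domain proportion of updates captured by forward transition windows."""
    if isinstance(trans, ConsensusTransitions):
        tt, roi = trans.transition_trs, trans.roi
    else:
        tt, roi = np.asarray(trans, dtype=int), "series"
    cols = {d: capture_proportions(tt, ups.update_trs, t_max)
            for d, ups in updates.items()}
    frame = pd.DataFrame(cols, index=pd.RangeIndex(t_max + 1, name="t"))
    return CoincidenceTable(roi, frame)
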