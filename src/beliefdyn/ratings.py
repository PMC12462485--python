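"""Group belief-update timecourses from continuous rater logs.

Raters watching a naturalistic stimulus press a key whenever they feel their
predictions in one domain (scene *states*, *agents*, or *actions*) have been
updated.  This module turns those per-rater press logs into a smoothed group
update-probability course on the scanner's TR grid, binarizes it into discrete
update points, selects rating-matched non-update control points, and provides
reliability and between-domain association diagnostics.

The processing chain mirrors the standard behavioural pipeline for continuous
annotations of naturalistic stimuli:

1. each press is expanded into a 5 s boxcar (a press marks the tail end of an
   experienced update, so the boxcar runs forward from the press),
2. boxcars are averaged over raters into an update-probability course,
3. the course is smoothed with locally weighted quadratic regression (loess,
   tricube weights, 10 % span — the R default),
4. the smoothed course is thresholded at ``mean + theta_sd * SD``; each
   supra-threshold run is collapsed to its final TR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RaterEventLog",
    "UpdateCourse",
    "UpdatePointSet",
    "ReliabilitySummary",
    "DomainAssociation",
    "rasterize_events",
    "loess_smooth",
    "smooth_course",
    "threshold_course",
    "binarize_updates",
    "select_nonupdates",
    "split_half_reliability",
    "domain_association",
    "mutual_information",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RaterEventLog:
    """Press times (seconds, ascending) of one rater for one domain."""

    rater_id: str
    presses: np.ndarray
    duration: float

    def __post_init__(self):
        presses = np.atleast_1d(np.asarray(self.presses, dtype=float))
        object.__setattr__(self, "presses", presses)
        if presses.size and (presses.min() < 0 or presses.max() >= self.duration):
            raise ValueError(
                f"rater {self.rater_id}: presses must lie in [0, {self.duration})"
            )
        if np.any(np.diff(presses) < 0):
            raise ValueError(f"rater {self.rater_id}: presses must be ascending")


@dataclass
class UpdateCourse:
    """Per-TR group update probability for one domain."""

    domain: str | None
    values: np.ndarray
    tr: float
    smoothing_span: float | None = None
    theta_sd: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("update course contains non-finite values")

    @property
    def n_trs(self) -> int:
        return self.values.size


@dataclass
class UpdatePointSet:
    """Discrete update TRs (0-based, ascending) for one domain."""

    domain: str | None
    update_trs: np.ndarray
    theta_sd: float | None = None

    def __post_init__(self):
        trs = np.atleast_1d(np.asarray(self.update_trs, dtype=int))
        if trs.size and (np.any(np.diff(trs) <= 0) or trs.min() < 0):
            raise ValueError("update TRs must be non-negative, ascending, unique")
        self.update_trs = trs

    def __len__(self) -> int:
        return self.update_trs.size


@dataclass
class ReliabilitySummary:
    mean: float
    se: float
    values: np.ndarray
    n_skipped: int


@dataclass
class DomainAssociation:
    pairwise: pd.DataFrame
    crosscorr: Mapping[tuple, np.ndarray]
    lags: np.ndarray


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _boxcar_trs(press: float, window_s: float, tr: float, n_trs: int):
    """TR indices whose acquisition interval overlaps [press, press + window_s)."""
    t0 = max(int(np.floor(press / tr)), 0)
    t1 = min(int(np.ceil((press + window_s) / tr)), n_trs)
    return t0, t1


def rasterize_events(
    logs: Sequence[RaterEventLog],
    tr: float,
    n_trs: int,
    window_s: float = 5.0,
    domain: str | None = None,
) -> UpdateCourse:
    """Mean over raters of forward 5 s press boxcars, on the TR grid.

    A TR is covered by a press if its acquisition interval
    ``[t*tr, (t+1)*tr)`` overlaps the boxcar ``[press, press + window_s)``.
    """
    if len(logs) == 0:
        raise ValueError("need at least one rater log")
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    acc = np.zeros(n_trs)
    for log in logs:
        box = np.zeros(n_trs, dtype=bool)
        for press in log.presses:
            t0, t1 = _boxcar_trs(press, window_s, tr, n_trs)
            box[t0:t1] = True
        acc += box
    return UpdateCourse(domain or getattr(logs[0], "domain", None),
                        acc / len(logs), tr)


# ---------------------------------------------------------------------------
# loess smoothing
# ---------------------------------------------------------------------------

def loess_smooth(values: np.ndarray, span: float = 0.10, degree: int = 2) -> np.ndarray:
    """Locally weighted polynomial regression on a regular grid.

    Tricube weights over the ``ceil(span * n)`` nearest points, local fit of
    the given degree, evaluated at every grid point (the R ``loess`` default
    of degree 2 used for these ratings).
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if n < 10:
        raise ValueError("need at least 10 samples to smooth")
    q = int(np.ceil(span * n))
    if q < 3:
        raise ValueError(f"span {span} gives {q} points per local fit; need >= 3")
    x = np.arange(n, dtype=float)
    out = np.empty(n)
    powers = np.arange(degree + 1)
    for i in range(n):
        d = np.abs(x - i)
        idx = np.argpartition(d, q - 1)[:q]
        h = d[idx].max()
        w = (1.0 - (d[idx] / h) ** 3) ** 3
        sw = np.sqrt(w)
        X = (x[idx, None] - i) ** powers[None, :]
        beta, *_ = np.linalg.lstsq(sw[:, None] * X, sw * y[idx], rcond=None)
        out[i] = beta[0]
    return out


def smooth_course(course: UpdateCourse, span: float = 0.10) -> UpdateCourse:
    """Loess-smooth an update course; values clamped back into [0, 1]."""
    smoothed = np.clip(loess_smooth(course.values, span=span), 0.0, 1.0)
    return UpdateCourse(course.domain, smoothed, course.tr, smoothing_span=span,
                        theta_sd=course.theta_sd)


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

def threshold_course(values: np.ndarray, theta_sd: float) -> np.ndarray:
    """Supra-threshold runs of ``values`` collapsed to their final indices.

    Threshold is ``mean + theta_sd * SD`` (sample SD).  A zero-variance course
    yields an empty set with a warning.
    """
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    if sd < 1e-12:
        warnings.warn("zero-variance course: no update points", stacklevel=2)
        return np.empty(0, dtype=int)
    mask = values > values.mean() + theta_sd * sd
    run_ends = mask & ~np.append(mask[1:], False)
    return np.flatnonzero(run_ends)


def binarize_updates(course: UpdateCourse, theta_sd: float) -> UpdatePointSet:
    """Threshold a smoothed course at mean + theta_sd*SD; keep final TR per run.

    Conventional thresholds: 2 SD for movie update domains, 1 SD for arousal,
    1.2 SD for the narrative stimulus.
    """
    if theta_sd < 0:
        raise ValueError("theta_sd must be non-negative")
    trs = threshold_course(course.values, theta_sd)
    return UpdatePointSet(course.domain, trs, theta_sd=theta_sd)


def select_nonupdates(
    courses: Mapping[str, UpdateCourse],
    updates: Mapping[str, UpdatePointSet],
    domain: str,
) -> UpdatePointSet:
    """Rating-matched control TRs far from every update in every domain.

    TRs are ranked by ascending update probability in ``domain``; the
    lowest-rated TRs that lie more than one TR away from every update of any
    domain are kept, exactly as many as that domain has updates.  Ties in the
    rating are broken by TR index.
    """
    values = courses[domain].values
    n = values.size
    excluded = np.zeros(n, dtype=bool)
    for ups in updates.values():
        for u in ups.update_trs:
            excluded[max(u - 1, 0):u + 2] = True
    candidates = np.flatnonzero(~excluded)
    k = len(updates[domain])
    if candidates.size < k:
        raise ValueError(
            f"only {candidates.size} eligible non-update TRs for {k} updates "
            f"(shortfall {k - candidates.size})"
        )
    order = candidates[np.lexsort((candidates, values[candidates]))]
    chosen = np.sort(order[:k])
    return UpdatePointSet(domain, chosen, theta_sd=updates[domain].theta_sd)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def split_half_reliability(
    logs: Sequence[RaterEventLog],
    tr: float,
    n_trs: int,
    n_splits: int = 100,
    seed: int = 0,
    span: float = 0.10,
    window_s: float = 5.0,
) -> ReliabilitySummary:
    """Spearman-Brown corrected split-half reliability of the group course.

    Each split divides raters into random halves; each half is rasterized and
    smoothed, the half-courses correlated, and the Pearson r corrected with
    the Spearman-Brown prophecy 2r/(1+r).  Degenerate (constant) half-courses
    skip the split.
    """
    if len(logs) < 4:
        raise ValueError("need at least 4 raters for split-half reliability")
    rng = np.random.default_rng(seed)
    logs = list(logs)
    half = len(logs) // 2
    vals, skipped = [], 0
    for _ in range(n_splits):
        perm = rng.permutation(len(logs))
        course_a = smooth_course(
            rasterize_events([logs[i] for i in perm[:half]], tr, n_trs, window_s),
            span)
        course_b = smooth_course(
            rasterize_events([logs[i] for i in perm[half:]], tr, n_trs, window_s),
            span)
        if course_a.values.std() < 1e-12 or course_b.values.std() < 1e-12:
            skipped += 1
            continue
        r = stats.pearsonr(course_a.values, course_b.values).statistic
        vals.append(2 * r / (1 + r))
    vals = np.asarray(vals)
    if vals.size == 0:
        raise ValueError("all splits degenerate")
    se = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
    return ReliabilitySummary(float(vals.mean()), float(se), vals, skipped)


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int = 8) -> float:
    """Plug-in mutual information (nats) from equal-width 2-D binning."""
    counts, _, _ = np.histogram2d(x, y, bins=n_bins)
    p = counts / counts.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def domain_association(
    courses: Mapping[str, UpdateCourse],
    max_lag: int = 10,
    n_bins: int = 8,
) -> DomainAssociation:
    """Pairwise Pearson r, lagged cross-correlation, and mutual information.

    The cross-correlation at lag k > 0 correlates course a at time t with
    course b at time t + k (b lags a).  Constant courses yield missing r.
    """
    names = list(courses)
    n = {d: courses[d].values.size for d in names}
    if len(set(n.values())) != 1:
        raise ValueError("courses must share length")
    lags = np.arange(-max_lag, max_lag + 1)
    rows, ccf = [], {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            xa, xb = courses[a].values, courses[b].values
            degenerate = xa.std() < 1e-12 or xb.std() < 1e-12
            r = np.nan if degenerate else stats.pearsonr(xa, xb).statistic
            mi = mutual_information(xa, xb, n_bins)
            rows.append({"domain_a": a, "domain_b": b, "pearson_r": r,
                         "mutual_information": mi})
            prof = np.full(lags.size, np.nan)
            if not degenerate:
                for j, k in enumerate(lags):
                    if k >= 0:
                        u, v = xa[:xa.size - k or None], xb[k:]
                    else:
                        u, v = xa[-k:], xb[:xb.size + k]
                    if u.std() > 1e-12 and v.std() > 1e-12:
                        prof[j] = stats.pearsonr(u, v).statistic
            ccf[(a, b)] = prof
    return DomainAssociation(pd.DataFrame(rows), ccf, lags)
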