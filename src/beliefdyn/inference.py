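"""Phase-randomization surrogates and permutation tests.

Surrogate series are built by Fourier transforming a course, drawing fresh
phases uniformly on (-pi, pi) for every non-DC (and non-Nyquist) frequency,
and inverting.  The amplitude spectrum — hence the autocorrelation — is
preserved exactly, so the surrogates embody the null hypothesis that only
the *timing* of fluctuations, not their temporal statistics, is scrambled.

Tests built on this machinery:

* ``coincidence_permutation_test`` — is a region's consensus-transition
  course preferentially aligned with one domain's belief updates?  The
  continuous course is phase-randomized *before* binarization, the update
  points stay fixed, and the conditional statistic per window size is the
  smaller of the two margins by which the preferred domain's capture
  proportion exceeds the other domains'.
* ``ispc_contrast_test`` — does a prefrontal region's pattern-alignment
  course co-fluctuate with the integrator region's specifically during its
  own domain's update windows?  Contrasts of the [own - mean(others)] form
  are compared across regions, with PFC courses phase-randomized and the
  integrator fixed.
* ``arousal_alignment`` — correlation of the sliding-ISC shared-response
  course with continuous arousal, plus the arousal-versus-domains variant of
  the coincidence test.
* ``coupling_experience_correlation`` — across subjects, mean
  integrator-PFC coupling during updates versus whole-run integrator ISC,
  repeated at matched non-update points.

All p-values use the add-one estimator (1 + #{null >= obs}) / (1 + n_perms),
one-tailed in the hypothesised direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intersubject import SlidingISC, segment_indices, _rowwise_r
from .ratings import UpdateCourse, UpdatePointSet, threshold_course
from .statedyn import ConsensusTransitions, capture_proportions

__all__ = [
    "phase_randomize",
    "phase_randomize_rows",
    "ConditionalTestResult",
    "coincidence_permutation_test",
    "ISPCContrastResult",
    "ispc_contrast_test",
    "ArousalAlignment",
    "arousal_alignment",
    "CouplingResult",
    "coupling_experience_correlation",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def phase_randomize_rows(x: np.ndarray, rng) -> np.ndarray:
    """Phase-randomize each row of a 2-D array (vectorised surrogates)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    n = x.shape[1]
    if n < 8:
        raise ValueError("series must have length >= 8")
    rng = _as_rng(rng)
    spec = np.fft.rfft(x, axis=1)
    phases = rng.uniform(-np.pi, np.pi, spec.shape)
    surrogate = np.abs(spec) * np.exp(1j * phases)
    surrogate[:, 0] = spec[:, 0]          # DC kept (mean preserved)
    if n % 2 == 0:
        surrogate[:, -1] = spec[:, -1]    # Nyquist kept real
    return np.fft.irfft(surrogate, n, axis=1)


def phase_randomize(course: np.ndarray, seed=0) -> np.ndarray:
    """FFT phase-randomized surrogate of a single course."""
    return phase_randomize_rows(np.asarray(course, dtype=float)[None, :],
                                _as_rng(seed))[0]


# ---------------------------------------------------------------------------
# transition-update coincidence test
# ---------------------------------------------------------------------------

@dataclass
class ConditionalTestResult:
    observed: np.ndarray          # statistic per window size t
    null: np.ndarray              # n_perms x (t_max + 1)
    p: np.ndarray                 # add-one one-tailed p per t
    criterion_met: np.ndarray     # preferred domain strictly ahead at t
    proportions: pd.DataFrame     # observed capture proportions


def _conditional_stat(props: Mapping[str, np.ndarray], preferred: str,
                      others: Sequence[str], statistic: str) -> np.ndarray:
    if statistic == "min_diff":
        return np.min([props[preferred] - props[o] for o in others], axis=0)
    if statistic == "own":
        return props[preferred]
    raise ValueError("statistic must be 'min_diff' or 'own'")


def coincidence_permutation_test(
    trans_course,
    updates: Mapping[str, UpdatePointSet],
    preferred: str,
    n_perms: int = 10_000,
    seed: int = 0,
    t_max: int = 8,
    theta_sd: float = 2.0,
    statistic: str = "min_diff",
) -> ConditionalTestResult:
    """Domain-specific transition-update coincidence via phase randomization.

    The *continuous* consensus course is phase-randomized before each
    re-binarization (mean + ``theta_sd`` SD, final TR per run), the update
    points stay fixed, and the default statistic per window size t is
    ``min over other domains of (p_preferred - p_other)``.  One-tailed
    add-one p per t.
    """
    if n_perms < 100:
        raise ValueError("need at least 100 permutations")
    if isinstance(trans_course, ConsensusTransitions):
        course = trans_course.course
    else:
        course = np.asarray(trans_course, dtype=float)
    if preferred not in updates or len(updates[preferred]) == 0:
        raise ValueError("preferred domain has no update points")
    usable = {d: u for d, u in updates.items() if len(u) > 0}
    dropped = set(updates) - set(usable)
    if dropped:
        warnings.warn(f"domains without updates excluded: {sorted(dropped)}",
                      stacklevel=2)
    others = [d for d in usable if d != preferred]
    if statistic == "min_diff" and not others:
        raise ValueError("min_diff statistic needs at least one other domain")

    def stat_of(tt):
        props = {d: capture_proportions(tt, usable[d].update_trs, t_max)
                 for d in usable}
        return _conditional_stat(props, preferred, others, statistic), props

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        obs_tt = threshold_course(course, theta_sd)
    obs, obs_props = stat_of(obs_tt)

    rng = _as_rng(seed)
    null = np.empty((n_perms, t_max + 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_perms):
            tt = threshold_course(phase_randomize(course, rng), theta_sd)
            null[i] = stat_of(tt)[0]
    p = (1 + (null >= obs[None, :]).sum(axis=0)) / (1 + n_perms)
    frame = pd.DataFrame(obs_props, index=pd.RangeIndex(t_max + 1, name="t"))
    return ConditionalTestResult(obs, null, p, obs > 0, frame)


# ---------------------------------------------------------------------------
# ISPC multithreading contrast test
# ---------------------------------------------------------------------------

@dataclass
class ISPCContrastResult:
    contrasts: pd.DataFrame       # relative contrast, rows ROI x columns domain
    observed: dict                # domain -> min-difference statistic
    p: dict                       # domain -> add-one one-tailed p
    criterion_met: dict
    correlations: pd.DataFrame    # group-mean ISPC-ISPC r, ROI x domain


def _ispc_corr_table(pfc_courses: Mapping[str, np.ndarray], ref: np.ndarray,
                     windows: Mapping[str, np.ndarray]) -> pd.DataFrame:
    rows = {}
    for roi, course in pfc_courses.items():
        rows[roi] = {
            d: float(np.nanmean(_rowwise_r(course[:, idx], ref[:, idx])))
            for d, idx in windows.items()
        }
    return pd.DataFrame(rows).T  # ROI x domain


def _relative_contrasts(corr: pd.DataFrame) -> pd.DataFrame:
    out = corr.copy()
    for d in corr.columns:
        others = [c for c in corr.columns if c != d]
        out[d] = corr[d] - corr[others].mean(axis=1)
    return out


def ispc_contrast_test(
    ispc_by_roi: Mapping[str, np.ndarray],
    reference: str,
    update_points: Mapping[str, UpdatePointSet],
    preferred_roi: Mapping[str, str],
    half_width: int = 4,
    n_perms: int = 1000,
    seed: int = 0,
) -> ISPCContrastResult:
    """Domain-selective ISPC coupling of PFC regions with a reference region.

    ``ispc_by_roi`` maps ROI to its subjects x TRs ISPC course (the reference
    region included); ``preferred_roi`` maps each domain to the PFC region
    hypothesised to carry it.  Per subject, PFC ROI and domain, the ROI's
    ISPC course is correlated with the reference's over the concatenated
    9-TR update windows; group means give a ROI x domain table.  The relative
    contrast own-domain-minus-others is compared between the preferred ROI
    and each other ROI (min difference), with a null built by
    phase-randomizing the PFC ISPC courses while the reference stays fixed.
    """
    if n_perms < 100:
        raise ValueError("need at least 100 permutations")
    ref = np.asarray(ispc_by_roi[reference], dtype=float)
    n_trs = ref.shape[1]
    pfc = {r: np.asarray(c, dtype=float)
           for r, c in ispc_by_roi.items() if r != reference}
    windows = {}
    for d, ups in update_points.items():
        idx = segment_indices(ups.update_trs, half_width, n_trs)
        if idx.size < 4:
            raise ValueError(f"domain {d!r}: segment shorter than 4 TRs")
        windows[d] = idx

    def stats_of(courses):
        corr = _ispc_corr_table(courses, ref, windows)
        rel = _relative_contrasts(corr)
        out = {}
        for d, roi in preferred_roi.items():
            others = [r for r in rel.index if r != roi]
            out[d] = float(min(rel.loc[roi, d] - rel.loc[o, d] for o in others))
        return out, corr, rel

    obs, corr_obs, rel_obs = stats_of(pfc)
    rng = _as_rng(seed)
    null = {d: np.empty(n_perms) for d in preferred_roi}
    for i in range(n_perms):
        sur = {r: phase_randomize_rows(c, rng) for r, c in pfc.items()}
        s, _, _ = stats_of(sur)
        for d in null:
            null[d][i] = s[d]
    p = {d: float((1 + (null[d] >= obs[d]).sum()) / (1 + n_perms))
         for d in null}
    met = {d: obs[d] > 0 for d in null}
    return ISPCContrastResult(rel_obs, obs, p, met, corr_obs)


# ---------------------------------------------------------------------------
# arousal alignment and coupling-experience correlation
# ---------------------------------------------------------------------------

@dataclass
class ArousalAlignment:
    r_group: float                # sliding-ISC course vs arousal
    r_subjects: np.ndarray        # per-subject variant
    coincidence: ConditionalTestResult


def arousal_alignment(
    sisc: SlidingISC,
    arousal: UpdateCourse | np.ndarray,
    trans: ConsensusTransitions,
    arousal_points: UpdatePointSet,
    updates: Mapping[str, UpdatePointSet],
    n_perms: int = 1000,
    seed: int = 0,
    t_max: int = 8,
) -> ArousalAlignment:
    """Shared-response-vs-arousal correlation and arousal coincidence test.

    The arousal course is sampled at the sliding-window centres before
    correlating.  The coincidence component tests whether high-arousal points
    are captured by transition windows more than every domain's updates
    (hypothesis direction arousal > each domain).
    """
    ar = arousal.values if isinstance(arousal, UpdateCourse) else \
        np.asarray(arousal, dtype=float)
    if sisc.centers.max() >= ar.size:
        raise ValueError("arousal course shorter than the sliding-ISC grid")
    ar_c = ar[sisc.centers]
    r_group = float(stats.pearsonr(sisc.z, ar_c).statistic)
    r_subjects = _rowwise_r(sisc.per_subject_z,
                            np.broadcast_to(ar_c, sisc.per_subject_z.shape))
    test = coincidence_permutation_test(
        trans, {"arousal": arousal_points, **updates}, "arousal",
        n_perms=n_perms, seed=seed, t_max=t_max)
    return ArousalAlignment(r_group, r_subjects, test)


@dataclass
class CouplingResult:
    r_update: float
    r_nonupdate: float
    n_update: int
    n_nonupdate: int


def _pairwise_r(a: np.ndarray, b: np.ndarray):
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 complete subject pairs")
    return float(stats.pearsonr(a[mask], b[mask]).statistic), int(mask.sum())


def coupling_experience_correlation(
    update_isfc: np.ndarray,
    whole_isc: np.ndarray,
    nonupdate_isfc: np.ndarray,
) -> CouplingResult:
    """Across-subject coupling-vs-shared-response correlation.

    ``update_isfc`` (subjects x pairs) holds each subject's integrator-PFC
    ISFC during the respective domains' updates; the per-subject mean is
    correlated with whole-run integrator ISC, and the same at matched
    non-update points.  Missing subject values are handled pairwise-complete.
    """
    update_isfc = np.asarray(update_isfc, dtype=float)
    nonupdate_isfc = np.asarray(nonupdate_isfc, dtype=float)
    whole_isc = np.asarray(whole_isc, dtype=float)
    mean_up = np.nanmean(update_isfc, axis=1) if update_isfc.ndim == 2 \
        else update_isfc
    mean_non = np.nanmean(nonupdate_isfc, axis=1) if nonupdate_isfc.ndim == 2 \
        else nonupdate_isfc
    r_up, n_up = _pairwise_r(mean_up, whole_isc)
    r_non, n_non = _pairwise_r(mean_non, whole_isc)
    return CouplingResult(r_up, r_non, n_up, n_non)
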