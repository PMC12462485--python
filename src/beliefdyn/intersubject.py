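"""Signal cleaning and intersubject statistics (ISC, sISC, ISFC, ISPC).

All intersubject measures are leave-one-out: one subject's signal is
correlated with the mean of the remaining subjects, which isolates
stimulus-driven shared processing from idiosyncratic noise.

* ``loo_isc`` — leave-one-out intersubject correlation of ROI-mean series,
  optionally restricted to concatenated windows around update points.
* ``sliding_isc`` — windowed ISC (default 21 TRs, step 1), Fisher-z averaged
  across subjects into a shared-response timecourse.
* ``isfc`` — intersubject functional connectivity: subject's region i versus
  the left-out group mean of region j.
* ``isfc_seed_map`` — seed ISFC against a bank of target voxels with BH-FDR
  and a display threshold.
* ``ispc_timecourse`` — per-TR spatial correlation of a subject's voxel
  pattern with the leave-one-out group-mean pattern.

Cleaning follows the usual naturalistic-fMRI recipe: least-squares removal of
the six motion parameters, linear detrend, and a zero-phase second-order
Butterworth band-pass in 0.01-0.1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ratings import UpdatePointSet

__all__ = [
    "ROISeriesSet",
    "PatternSeriesSet",
    "SegmentSpec",
    "SlidingISC",
    "SeedMap",
    "Z_CAP",
    "fisher_z",
    "clean_series",
    "segment_indices",
    "extract_segments",
    "loo_isc",
    "sliding_isc",
    "isfc",
    "isfc_seed_map",
    "ispc_timecourse",
]

#: Fisher z is capped here; arctanh(r) reaches this for r within ~1e-16 of 1.
Z_CAP = 18.7


@dataclass
class ROISeriesSet:
    """Subjects x TRs ROI-mean BOLD matrix."""

    roi: str
    data: np.ndarray
    tr: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ROI series must be subjects x TRs")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in ROI series")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_trs(self) -> int:
        return self.data.shape[1]


@dataclass
class PatternSeriesSet:
    """Subjects x TRs x voxels (unsmoothed) BOLD pattern array."""

    roi: str
    data: np.ndarray
    tr: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("pattern series must be subjects x TRs x voxels")
        if self.data.shape[2] < 2:
            raise ValueError("need at least 2 voxels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in pattern series")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_trs(self) -> int:
        return self.data.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[2]


@dataclass
class SegmentSpec:
    """Windows of ``half_width`` TRs either side of each update TR.

    ``half_width=3`` gives the 7-TR windows used for ISC/ISFC, ``half_width=4``
    the 9-TR windows used for ISPC.  Overlapping windows are merged so no TR
    enters twice; windows clipped at the series boundary are kept when at
    least ``min_frac`` of the nominal length survives.
    """

    update_trs: UpdatePointSet | np.ndarray
    half_width: int = 3
    merge_overlaps: bool = True
    min_frac: float = 0.5

    def trs(self) -> np.ndarray:
        if isinstance(self.update_trs, UpdatePointSet):
            return self.update_trs.update_trs
        return np.atleast_1d(np.asarray(self.update_trs, dtype=int))


def fisher_z(r: np.ndarray) -> np.ndarray:
    """arctanh with |z| capped at Z_CAP (guards r = +/-1)."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        z = np.arctanh(r)
    return np.clip(z, -Z_CAP, Z_CAP)


def _rowwise_r(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r along the last axis; zero-variance rows give NaN."""
    a0 = a - a.mean(axis=-1, keepdims=True)
    b0 = b - b.mean(axis=-1, keepdims=True)
    num = (a0 * b0).sum(axis=-1)
    den = np.sqrt((a0 ** 2).sum(axis=-1) * (b0 ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.where(den > 0, r, np.nan)


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def clean_series(
    series: ROISeriesSet,
    motion: np.ndarray | None = None,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
) -> ROISeriesSet:
    """Motion regression, linear detrend, zero-phase Butterworth band-pass.

    ``motion`` is subjects x TRs x 6 (or TRs x 6, shared).  The band-pass is
    a second-order Butterworth applied forward and backward (``filtfilt``) at
    sampling rate 1/TR.
    """
    fs = 1.0 / series.tr
    nyq = fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(f"band edges must satisfy 0 < {low_hz} < {high_hz} < "
                         f"Nyquist ({nyq:.4f} Hz)")
    data = series.data.copy()
    n_sub, n_trs = data.shape
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.ndim == 2:
            motion = np.broadcast_to(motion, (n_sub,) + motion.shape)
        if motion.shape[1] != n_trs:
            raise ValueError("motion rows must equal TRs")
        for s in range(n_sub):
            X = np.column_stack([motion[s], np.ones(n_trs)])
            beta, *_ = np.linalg.lstsq(X, data[s], rcond=None)
            data[s] = data[s] - X @ beta
    data = sps.detrend(data, axis=1, type="linear")
    sos = sps.butter(2, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    data = sps.sosfiltfilt(sos, data, axis=1)
    return ROISeriesSet(series.roi, data, series.tr)


# ---------------------------------------------------------------------------
# segments
# ---------------------------------------------------------------------------

def segment_indices(update_trs: np.ndarray, half_width: int, n_trs: int,
                    merge_overlaps: bool = True,
                    min_frac: float = 0.5) -> np.ndarray:
    """Concatenated TR indices of the windows around each update TR."""
    if half_width < 0:
        raise ValueError("half_width must be non-negative")
    nominal = 2 * half_width + 1
    windows = []
    for u in np.atleast_1d(np.asarray(update_trs, dtype=int)):
        if not 0 <= u < n_trs:
            raise ValueError(f"update TR {u} outside series bounds")
        lo, hi = max(u - half_width, 0), min(u + half_width, n_trs - 1)
        if hi - lo + 1 >= max(1, int(np.ceil(min_frac * nominal))):
            windows.append(np.arange(lo, hi + 1))
    if not windows:
        return np.empty(0, dtype=int)
    idx = np.concatenate(windows)
    if merge_overlaps:
        idx = np.unique(idx)
    return idx


def extract_segments(data, spec: SegmentSpec):
    """Concatenate update windows; returns (windowed data, TR index map).

    Works on ROI series (subjects x TRs) and pattern arrays (subjects x TRs x
    voxels); the index map records the original TR of every concatenated
    sample.
    """
    arr = data.data if hasattr(data, "data") else np.asarray(data)
    n_trs = arr.shape[1]
    idx = segment_indices(spec.trs(), spec.half_width, n_trs,
                          spec.merge_overlaps, spec.min_frac)
    return arr[:, idx], idx


# ---------------------------------------------------------------------------
# ISC family
# ---------------------------------------------------------------------------

def _segment_view(series: ROISeriesSet, segment: SegmentSpec | None):
    if segment is None:
        return series.data
    sub, _ = extract_segments(series, segment)
    return sub


def loo_isc(series: ROISeriesSet, segment: SegmentSpec | None = None) -> np.ndarray:
    """Leave-one-out ISC: per subject, r against the mean of all others."""
    data = _segment_view(series, segment)
    n_sub, n_t = data.shape
    if n_sub < 3:
        raise ValueError("need at least 3 subjects")
    if n_t < 4:
        raise ValueError("segment must span at least 4 TRs")
    total = data.sum(axis=0)
    others = (total[None, :] - data) / (n_sub - 1)
    return _rowwise_r(data, others)


@dataclass
class SlidingISC:
    z: np.ndarray                 # group course, Fisher-z averaged
    r: np.ndarray                 # tanh of the group z course
    centers: np.ndarray           # TR index of each window centre
    per_subject_z: np.ndarray     # subjects x windows


def sliding_isc(series: ROISeriesSet, window: int = 21, step: int = 1) -> SlidingISC:
    """Sliding-window leave-one-out ISC (shared-response timecourse).

    Each window's per-subject r values are Fisher-z transformed (capped at
    Z_CAP for degenerate r = 1) and averaged across subjects; the course is
    indexed at window centres.
    """
    if window < 4:
        raise ValueError("window must be at least 4 TRs")
    data = series.data
    n_sub, n_trs = data.shape
    if n_trs < window:
        raise ValueError("series shorter than the window")
    starts = np.arange(0, n_trs - window + 1, step)
    per_subject = np.empty((n_sub, starts.size))
    total = data.sum(axis=0)
    for i, s0 in enumerate(starts):
        chunk = data[:, s0:s0 + window]
        others = (total[s0:s0 + window][None, :] - chunk) / (n_sub - 1)
        per_subject[:, i] = fisher_z(_rowwise_r(chunk, others))
    group = np.nanmean(per_subject, axis=0)
    return SlidingISC(group, np.tanh(group), starts + window // 2, per_subject)


def isfc(
    series_i: ROISeriesSet,
    series_j: ROISeriesSet,
    segment: SegmentSpec | None = None,
) -> np.ndarray:
    """Intersubject functional connectivity i -> j, one r per subject.

    Subject s's region-i series (over the update windows) is correlated with
    the mean region-j series of all other subjects.  The measure is
    asymmetric; call with swapped arguments for the j -> i direction.
    """
    if series_i.data.shape != series_j.data.shape:
        raise ValueError("series must share subjects and TRs")
    di = _segment_view(series_i, segment)
    dj = _segment_view(series_j, segment)
    n_sub = di.shape[0]
    if n_sub < 3:
        raise ValueError("need at least 3 subjects")
    if di.shape[1] < 4:
        raise ValueError("segment must span at least 4 TRs")
    total_j = dj.sum(axis=0)
    others_j = (total_j[None, :] - dj) / (n_sub - 1)
    return _rowwise_r(di, others_j)


@dataclass
class SeedMap:
    r: np.ndarray                 # group-mean r per voxel
    p: np.ndarray                 # group-mean r vs its segment-length null
    fdr_mask: np.ndarray
    display_mask: np.ndarray      # fdr_mask & (r > r_display)
    per_subject: np.ndarray       # subjects x voxels


def isfc_seed_map(
    seed: ROISeriesSet,
    targets: PatternSeriesSet,
    segment: SegmentSpec | None = None,
    q: float = 0.001,
    r_display: float = 0.1,
) -> SeedMap:
    """Seed ISFC against every target voxel, BH-FDR masked.

    Per voxel: each subject's seed series is correlated with the leave-one-out
    group-mean voxel series and the r values averaged into a group map.
    Because every subject is correlated against (almost) the same group-mean
    target, subject-level values are not independent — a chance correlation
    between the seed's shared course and a voxel's mean course shifts all
    subjects coherently — so the voxel p-value is computed from the
    group-mean r against its finite-segment-length null (dof = segment TRs
    minus 2), not from a one-sample t over subjects.  BH-FDR across voxels at
    ``q``; the display mask additionally requires r > ``r_display``.
    """
    if seed.data.shape[0] != targets.data.shape[0] or \
            seed.data.shape[1] != targets.data.shape[1]:
        raise ValueError("seed and targets must share subjects and TRs")
    seed_seg = _segment_view(seed, segment)
    if segment is None:
        vox = targets.data
    else:
        vox, _ = extract_segments(targets, segment)
    n_t = seed_seg.shape[1]
    if n_t == 0:
        raise ValueError("empty segment")
    n_sub = seed_seg.shape[0]
    total = vox.sum(axis=0)                       # T x V
    r_sv = np.empty((n_sub, targets.n_voxels))
    for s in range(n_sub):
        others = (total - vox[s]) / (n_sub - 1)   # T x V
        r_sv[s] = _rowwise_r(seed_seg[s][None, :], others.T)
    r_mean = np.nanmean(r_sv, axis=0)
    dof = max(n_t - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = r_mean * np.sqrt(dof / np.maximum(1 - r_mean ** 2, 1e-15))
    p = 2 * stats.t.sf(np.abs(t_stat), dof)
    reject = multipletests(p, alpha=q, method="fdr_bh")[0]
    return SeedMap(r_mean, p, reject, reject & (r_mean > r_display), r_sv)


def ispc_timecourse(patterns: PatternSeriesSet) -> np.ndarray:
    """Per-subject, per-TR spatial pattern correlation with the left-out mean.

    Returns subjects x TRs; a zero-variance pattern at some TR yields NaN
    there.
    """
    data = patterns.data
    n_sub = data.shape[0]
    if n_sub < 3:
        raise ValueError("need at least 3 subjects")
    if patterns.n_voxels < 3:
        raise ValueError("need at least 3 voxels")
    total = data.sum(axis=0)                      # T x V
    out = np.empty(data.shape[:2])
    for s in range(n_sub):
        others = (total - data[s]) / (n_sub - 1)
        out[s] = _rowwise_r(data[s], others)
    return out
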