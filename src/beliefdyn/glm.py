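"""Mass-univariate GLM with HRF-convolved event and parametric-modulator
regressors, domain contrasts, and FDR + cluster-extent thresholding.

The design follows the standard parametric-modulation convention: a stimulus
event regressor (events on a 1 s grid) convolved with the canonical
double-gamma HRF, plus one column per update domain formed by multiplying the
mean-centred update-probability course into the event train *before*
convolution (modulation of the neural, not hemodynamic, signal).  Six motion
nuisance regressors and an intercept enter unconvolved.  Domain specificity
is tested with [1, -0.5, -0.5]-type contrasts over the three modulators,
a one-sample t over subject contrast values, Benjamini-Hochberg FDR, and a
cluster extent threshold on the voxel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DesignMatrix",
    "ContrastMap",
    "double_gamma_hrf",
    "hrf_convolve",
    "build_design",
    "fit_glm_contrast",
    "fdr_extent_threshold",
]

_HRF_SUPPORT_S = 32.0
_HRF_PEAK_DELAY = 6.0       # shape of the positive gamma lobe
_HRF_UNDERSHOOT_DELAY = 16.0
_HRF_UNDERSHOOT_RATIO = 1.0 / 6.0
_hrf_peak_value: float | None = None


def _gamma_pdf(t, a):
    # gamma(a, scale=1) density, zero for t <= 0
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = np.exp((a - 1) * np.log(t[pos]) - t[pos] - special.gammaln(a))
    return out


def double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma HRF, unit peak, zero at t = 0.

    Positive lobe gamma(6), undershoot gamma(16) scaled by 1/6 (the
    SPM-conventional parameters), normalised so the peak value is 1.
    """
    global _hrf_peak_value
    if _hrf_peak_value is None:
        dense = np.arange(0.0, _HRF_SUPPORT_S, 1e-3)
        raw = (_gamma_pdf(dense, _HRF_PEAK_DELAY)
               - _HRF_UNDERSHOOT_RATIO * _gamma_pdf(dense, _HRF_UNDERSHOOT_DELAY))
        _hrf_peak_value = float(raw.max())
    raw = (_gamma_pdf(t, _HRF_PEAK_DELAY)
           - _HRF_UNDERSHOOT_RATIO * _gamma_pdf(t, _HRF_UNDERSHOOT_DELAY))
    return raw / _hrf_peak_value


def hrf_convolve(course: np.ndarray, tr: float) -> np.ndarray:
    """Causal convolution with the canonical HRF sampled at spacing ``tr``.

    ``tr`` is the sample spacing of ``course`` in seconds (1.0 for a 1 s
    event grid, the scanner TR for a per-TR course).  The output is truncated
    to the input length.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    course = np.asarray(course, dtype=float)
    kernel = double_gamma_hrf(np.arange(0.0, _HRF_SUPPORT_S + tr, tr))
    return np.convolve(course, kernel)[: course.size]


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    frame: pd.DataFrame
    modulator_names: tuple
    condition_number: float
    rank_deficient: bool

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()


def build_design(
    event_grid: np.ndarray,
    modulators: Mapping[str, np.ndarray],
    motion: np.ndarray | None,
    tr: float,
    n_trs: int,
) -> DesignMatrix:
    """Assemble the TRs x regressors design matrix.

    ``event_grid`` is the stimulus on/off train at 1 s resolution;
    ``modulators`` maps domain name to its per-TR update course.  Each
    modulator is mean-centred, multiplied into the 1 s event train, convolved
    with the HRF, resampled to the TR grid and re-centred (so modulator
    columns are exactly zero-mean).  Rank deficiency is flagged, not fixed.
    """
    eg = np.asarray(event_grid, dtype=float)
    sec = np.arange(eg.size, dtype=float)
    t_acq = np.arange(n_trs) * tr
    if t_acq[-1] > sec[-1] + 1:
        raise ValueError("event grid shorter than the scan")

    ev = np.interp(t_acq, sec, hrf_convolve(eg, 1.0))
    cols = {"event": ev}
    for name, course in modulators.items():
        course = np.asarray(course, dtype=float)
        if course.size != n_trs:
            raise ValueError(f"modulator {name!r} not on the TR grid")
        centred = course - course.mean()
        at_sec = np.interp(sec, t_acq, centred)
        col = np.interp(t_acq, sec, hrf_convolve(at_sec * eg, 1.0))
        if np.abs(col).max() > 0:
            col = col - col.mean()
        cols[f"mod_{name}"] = col
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n_trs:
            raise ValueError("motion rows must equal n_trs")
        for j in range(motion.shape[1]):
            cols[f"motion_{j + 1}"] = motion[:, j]
    cols["intercept"] = np.ones(n_trs)

    frame = pd.DataFrame(cols)
    X = frame.to_numpy()
    sv = np.linalg.svd(X, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    rank_deficient = np.linalg.matrix_rank(X) < X.shape[1]
    return DesignMatrix(frame, tuple(f"mod_{m}" for m in modulators),
                        cond, rank_deficient)


# ---------------------------------------------------------------------------
# fitting and thresholding
# ---------------------------------------------------------------------------

@dataclass
class ContrastMap:
    t_values: np.ndarray
    p_values: np.ndarray
    weights: np.ndarray
    subject_contrasts: np.ndarray
    mask: np.ndarray | None = None


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * X.shape[0] * np.finfo(float).eps
    return [names[i] for i in np.flatnonzero(diag < tol)]


def fit_glm_contrast(
    data: np.ndarray,
    design: DesignMatrix,
    weights: Sequence[float],
) -> ContrastMap:
    """Per-subject OLS voxel betas, contrast over the modulators, group t.

    ``data`` is subjects x TRs x voxels (a single subject may pass TRs x
    voxels).  ``weights`` has one entry per modulator column (e.g.
    [1, -0.5, -0.5]).  The group map is a one-sample t over subject contrast
    values with a two-sided p.
    """
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    X = design.values
    n_trs = X.shape[0]
    if arr.shape[1] != n_trs:
        raise ValueError("data TRs do not match the design")
    if design.rank_deficient:
        bad = _collinear_columns(X, list(design.frame.columns))
        raise ValueError(f"singular design; collinear columns: {bad}")
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(design.modulator_names):
        raise ValueError("one contrast weight per modulator required")
    c = np.zeros(X.shape[1])
    for w, name in zip(weights, design.modulator_names):
        c[design.frame.columns.get_loc(name)] = w

    pinv = np.linalg.pinv(X)
    subject_contrasts = np.stack([c @ (pinv @ y) for y in arr])  # S x V
    tt = stats.ttest_1samp(subject_contrasts, 0.0, axis=0)
    return ContrastMap(np.asarray(tt.statistic), np.asarray(tt.pvalue),
                       c, subject_contrasts)


def fdr_extent_threshold(
    cmap: ContrastMap,
    q: float = 0.05,
    k: int = 25,
    grid_shape: tuple | None = None,
) -> ContrastMap:
    """Benjamini-Hochberg FDR at ``q`` plus a cluster extent threshold.

    Surviving voxels are grouped into connected components on the voxel grid
    (orthogonal neighbours only: 6-connectivity in 3-D, runs in 1-D),
    positive- and negative-t survivors separately, and components smaller
    than ``k`` voxels are removed.
    """
    p = np.asarray(cmap.p_values, dtype=float)
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("invalid p-values")
    reject = multipletests(p, alpha=q, method="fdr_bh")[0]
    shape = grid_shape if grid_shape is not None else (p.size,)
    mask = np.zeros(p.size, dtype=bool)
    for signed in (reject & (cmap.t_values > 0), reject & (cmap.t_values < 0)):
        labels, n_comp = ndimage.label(signed.reshape(shape))
        for comp in range(1, n_comp + 1):
            members = (labels == comp).ravel()
            if members.sum() >= k:
                mask |= members
    return replace(cmap, mask=mask)
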