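"""Synthetic naturalistic-viewing cohorts with planted belief-update structure.

The generator emulates the data layout of a naturalistic movie/narrative fMRI
study paired with continuous behavioural ratings:

* shared stimulus events per update domain (``states``, ``agents``,
  ``actions``), jittered per-rater key presses around them;
* per-ROI latent-state schedules whose state changes coincide with the ROI's
  preferred domain's events (an integrator region changes state at every
  domain's events);
* subjects x TRs ROI-mean BOLD built as Gaussian state emissions plus a
  stimulus-locked shared component (yielding nonzero intersubject
  correlation) plus idiosyncratic noise, with a per-subject gain on the
  shared part that plays the role of an individual "shared processing"
  factor;
* subjects x TRs x voxels pattern arrays built from per-state spatial
  templates whose amplitude is event-locked (and passed through the
  canonical HRF), so pattern alignment across subjects rises around the
  preferred domain's events;
* an arousal course built as loess-smoothed pooled event density rescaled to
  [-1, 1], and small random-walk motion parameter tables.

Everything is deterministic given the config seed: one global seed fans out
into fixed per-component streams, so regenerating any single piece gives
bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .glm import hrf_convolve
from .ratings import RaterEventLog, loess_smooth

__all__ = [
    "DOMAINS",
    "DOMAIN_ROIS",
    "INTEGRATOR_ROI",
    "SynthConfig",
    "GroundTruth",
    "SynthDataset",
    "movie_config",
    "narrative_config",
    "expected_update_trs",
    "simulate_raters",
    "simulate_roi_bold",
    "simulate_roi_patterns",
    "make_dataset",
    "save_dataset",
]

DOMAINS = ("states", "agents", "actions")
DOMAIN_ROIS = {"vmPFC": "states", "amPFC": "agents", "dmPFC": "actions"}
INTEGRATOR_ROI = "PCN"

# fixed stream tags for the per-component child generators
_S_EVENTS, _S_RATERS, _S_GAINS, _S_BOLD, _S_PATTERN, _S_MOTION = range(1, 7)


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(t) for t in tags])


@dataclass(frozen=True)
class SynthConfig:
    """Study-shaped generation parameters.

    Defaults describe the movie-like cohort: 111 subjects, 189 usable TRs at
    TR = 2.47 s, rater panels of 18/21/19 per domain with an 80 % press
    probability and 1 s response jitter, 9/4/5 planted events per domain, and
    three latent states per ROI whose adjacent emission means are separated
    by ``effect_size`` (= 3) against unit idiosyncratic noise.
    """

    n_subjects: int = 111
    n_trs: int = 189
    tr: float = 2.47
    n_raters_per_domain: Mapping[str, int] = field(
        default_factory=lambda: {"states": 18, "agents": 21, "actions": 19})
    n_events_by_domain: Mapping[str, int] = field(
        default_factory=lambda: {"states": 5, "agents": 3, "actions": 4})
    n_voxels_per_roi: int = 36
    rater_press_prob: float = 0.8
    rater_jitter_sd: float = 1.0
    update_window_s: float = 5.0
    n_states: int = 3
    effect_size: float = 1.5
    noise_sd: float = 1.0
    event_bump_amplitude: float = 1.5
    shared_noise_w: float = 0.5
    subject_gain_sd: float = 0.3
    pattern_amplitude: float = 2.0
    pattern_noise_sd: float = 1.0
    hrf_patterns: bool = True
    hemodynamic_delay_s: float = 5.0
    seed: int = 0

    @property
    def duration(self) -> float:
        return self.n_trs * self.tr

    @property
    def bold_delay_trs(self) -> int:
        """Hemodynamic lag of BOLD state shifts behind stimulus events."""
        return int(round(self.hemodynamic_delay_s / self.tr))

    def raters(self, domain: str) -> int:
        if isinstance(self.n_raters_per_domain, int):
            return self.n_raters_per_domain
        return self.n_raters_per_domain[domain]

    def validate(self) -> None:
        if min(self.n_subjects, self.n_trs, self.n_voxels_per_roi,
               self.n_states) < 1:
            raise ValueError("counts must be >= 1")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not 0 < self.rater_press_prob <= 1:
            raise ValueError("rater_press_prob must lie in (0, 1]")
        if self.rater_jitter_sd < 0:
            raise ValueError("rater_jitter_sd must be non-negative")
        for d in DOMAINS:
            if self.raters(d) < 1 or self.n_events_by_domain[d] < 1:
                raise ValueError("counts must be >= 1")


def movie_config(**overrides) -> SynthConfig:
    """Movie-like cohort: 111 subjects x 189 TRs at TR = 2.47 s."""
    return SynthConfig(**overrides)


def narrative_config(**overrides) -> SynthConfig:
    """Narrative-like cohort: 52 subjects x 400 TRs at TR = 1.5 s."""
    base = dict(n_subjects=52, n_trs=400, tr=1.5)
    base.update(overrides)
    return SynthConfig(**base)


def state_planted_config(**overrides) -> SynthConfig:
    """Movie-scale cohort whose BOLD is exactly K Gaussian states (SNR 3).

    Emission means separated by 3 noise SDs and no transient update
    response, so the generative process is precisely a K-state Gaussian HMM;
    the condition for latent-state count and transition recovery studies.
    """
    base = dict(effect_size=3.0, event_bump_amplitude=0.0)
    base.update(overrides)
    return SynthConfig(**base)


@dataclass
class GroundTruth:
    """Planted structure a dataset was generated from."""

    event_times_by_domain: dict
    event_trs_by_domain: dict
    state_schedule_by_roi: dict
    preferred_domain_by_roi: dict
    effect_size: float
    noise_sd: float
    arousal_course: np.ndarray
    subject_gains: np.ndarray


@dataclass
class SynthDataset:
    rater_logs: dict
    roi_series: dict
    pattern_series: dict
    motion: np.ndarray           # subjects x TRs x 6
    arousal: np.ndarray
    truth: GroundTruth
    config: SynthConfig


# ---------------------------------------------------------------------------
# planted structure
# ---------------------------------------------------------------------------

def _sample_event_trs(cfg: SynthConfig, rng: np.random.Generator) -> dict:
    """Event TRs per domain: jittered regular grids, separated across domains.

    Within a domain events are spread over the run (a narrative distributes
    its turning points rather than clustering them), which also keeps the
    smoothed update bumps from merging; across domains a minimum separation
    keeps update points distinguishable.
    """
    margin = max(1, min(8, cfg.n_trs // 10))
    lo, hi = margin, cfg.n_trs - margin - 1
    if hi <= lo:
        raise ValueError("n_trs too small to place events")
    span = hi - lo
    sep_cross = max(1, min(4, span // 8))
    events, placed_all = {}, []
    for d in DOMAINS:
        n_ev = min(cfg.n_events_by_domain[d], max(1, span // 4))
        spacing = span / n_ev
        jit = max(1, min(4, int(spacing // 6)))
        best, best_sep = None, -1
        for _ in range(200):
            cand = np.sort((lo + (np.arange(n_ev) + 0.5) * spacing
                            + rng.integers(-jit, jit + 1, n_ev)).astype(int))
            cand = np.clip(cand, lo, hi - 1)
            min_sep = (min(abs(int(c) - p) for c in cand for p in placed_all)
                       if placed_all else sep_cross)
            if np.any(np.diff(cand) < 2):
                continue
            if min_sep >= sep_cross:
                best = cand
                break
            if min_sep > best_sep:
                best, best_sep = cand, min_sep
        events[d] = best
        placed_all.extend(int(c) for c in best)
    return events


def expected_update_trs(truth: GroundTruth, cfg: SynthConfig,
                        domain: str) -> np.ndarray:
    """TR where the detection pipeline should place each planted event.

    Binarized update points mark the final TR of the supra-threshold run,
    i.e. the tail of the 5 s update window that follows a press; the
    generative counterpart is the final TR covered by the event's window.
    """
    times = truth.event_times_by_domain[domain]
    return np.minimum((times + cfg.update_window_s) // cfg.tr,
                      cfg.n_trs - 1).astype(int)


def _schedule_from_changes(change_trs: np.ndarray, n_trs: int, k: int) -> np.ndarray:
    """Latent labels 1..k cycling, advancing at each change TR."""
    sched = np.ones(n_trs, dtype=int)
    state = 0
    changes = set(int(t) for t in change_trs)
    for t in range(n_trs):
        if t in changes and t > 0:
            state = (state + 1) % k
        sched[t] = state + 1
    return sched


def build_truth(cfg: SynthConfig) -> GroundTruth:
    cfg.validate()
    events = _sample_event_trs(cfg, _rng(cfg.seed, _S_EVENTS))
    event_times = {d: trs * cfg.tr for d, trs in events.items()}
    # BOLD latent-state shifts lag the stimulus events hemodynamically
    delay = cfg.bold_delay_trs
    bold_events = {d: np.clip(trs + delay, 0, cfg.n_trs - 1)
                   for d, trs in events.items()}
    schedules, preferred = {}, {}
    for roi, dom in DOMAIN_ROIS.items():
        schedules[roi] = _schedule_from_changes(bold_events[dom], cfg.n_trs,
                                                cfg.n_states)
        preferred[roi] = dom
    all_events = np.sort(np.concatenate([bold_events[d] for d in DOMAINS]))
    schedules[INTEGRATOR_ROI] = _schedule_from_changes(all_events, cfg.n_trs,
                                                       cfg.n_states)

    density = np.zeros(cfg.n_trs)
    density[all_events] = 1.0
    smoothed = loess_smooth(density, span=0.10) if cfg.n_trs >= 30 else density
    lo_v, hi_v = smoothed.min(), smoothed.max()
    arousal = (2 * (smoothed - lo_v) / (hi_v - lo_v) - 1
               if hi_v > lo_v else np.zeros(cfg.n_trs))

    gains = 1.0 + cfg.subject_gain_sd * _rng(cfg.seed, _S_GAINS).standard_normal(
        cfg.n_subjects)
    gains = np.clip(gains, 0.1, None)
    return GroundTruth(event_times, events, schedules, preferred,
                       cfg.effect_size, cfg.noise_sd, arousal, gains)


# ---------------------------------------------------------------------------
# component simulators
# ---------------------------------------------------------------------------

def simulate_raters(truth: GroundTruth, cfg: SynthConfig, domain: str) -> list:
    """Jittered per-rater press logs around a domain's shared events.

    Each rater responds to each true event with probability
    ``rater_press_prob``; a response occurs at the event time plus Normal(0,
    ``rater_jitter_sd``) seconds, clipped into the stimulus.
    """
    if domain not in truth.event_times_by_domain:
        raise ValueError(f"unknown domain {domain!r}")
    rng = _rng(cfg.seed, _S_RATERS, DOMAINS.index(domain))
    events = truth.event_times_by_domain[domain]
    logs = []
    for r in range(cfg.raters(domain)):
        responds = rng.random(events.size) < cfg.rater_press_prob
        jitter = rng.normal(0.0, cfg.rater_jitter_sd, events.size)
        presses = np.clip((events + jitter)[responds], 0.0,
                          np.nextafter(cfg.duration, 0.0))
        logs.append(RaterEventLog(f"{domain}_r{r:02d}", np.sort(presses),
                                  cfg.duration))
    return logs


def state_means(k: int, effect_size: float) -> np.ndarray:
    """Centred per-state emission means with adjacent separation effect_size."""
    return (np.arange(1, k + 1) - (k + 1) / 2.0) * effect_size


def _preferred_event_trs(truth: GroundTruth, roi: str) -> np.ndarray:
    dom = truth.preferred_domain_by_roi.get(roi)
    if dom is None:
        return np.sort(np.concatenate(
            [truth.event_trs_by_domain[d] for d in DOMAINS]))
    return truth.event_trs_by_domain[dom]


def simulate_roi_bold(truth: GroundTruth, cfg: SynthConfig, roi: str):
    """Subjects x TRs ROI-mean BOLD with planted states and shared signal.

    Subject s at TR t is ``g_s * (state_mean[schedule(t)] + bump(t) +
    w * shared(t)) + Normal(0, noise_sd)``: Gaussian state emissions plus a
    transient HRF-shaped shared response around the ROI's preferred domain's
    events (shared activity rises around updates), a common stimulus-locked
    noise course ``shared`` (nonzero baseline ISC), and the subject's
    shared-signal gain ``g_s`` (mean 1).
    """
    from .intersubject import ROISeriesSet

    if roi not in truth.state_schedule_by_roi:
        raise ValueError(f"unknown ROI {roi!r}")
    sched = truth.state_schedule_by_roi[roi]
    if sched.size != cfg.n_trs:
        raise ValueError("schedule length does not match n_trs")
    roi_idx = sorted(truth.state_schedule_by_roi).index(roi)
    rng = _rng(cfg.seed, _S_BOLD, roi_idx)
    means = state_means(int(sched.max()), truth.effect_size)
    course = means[sched - 1]
    bump = _event_bump_course(_preferred_event_trs(truth, roi), cfg.n_trs)
    bump = cfg.event_bump_amplitude * hrf_convolve(bump, cfg.tr)
    shared = rng.standard_normal(cfg.n_trs)
    noise = rng.standard_normal((cfg.n_subjects, cfg.n_trs))
    data = (truth.subject_gains[:, None]
            * (course + bump + cfg.shared_noise_w * shared)[None, :]
            + truth.noise_sd * noise)
    return ROISeriesSet(roi, data, cfg.tr)


def _event_bump_course(event_trs: np.ndarray, n_trs: int,
                       width_tr: float = 1.5) -> np.ndarray:
    t = np.arange(n_trs)
    bump = np.zeros(n_trs)
    for e in event_trs:
        bump += np.exp(-0.5 * ((t - e) / width_tr) ** 2)
    return bump


def simulate_roi_patterns(truth: GroundTruth, cfg: SynthConfig, roi: str):
    """Subjects x TRs x voxels patterns with event-locked shared templates.

    Each latent state has a spatial template; its amplitude follows an
    event-locked bump course around the ROI's preferred domain's events (all
    domains for the integrator region), passed through the canonical HRF when
    ``cfg.hrf_patterns``.  Per-subject Gaussian voxel noise is added, so the
    intersubject pattern correlation rises specifically around those events.
    """
    from .intersubject import PatternSeriesSet

    if roi not in truth.state_schedule_by_roi:
        raise ValueError(f"unknown ROI {roi!r}")
    sched = truth.state_schedule_by_roi[roi]
    roi_idx = sorted(truth.state_schedule_by_roi).index(roi)
    rng = _rng(cfg.seed, _S_PATTERN, roi_idx)

    dom = truth.preferred_domain_by_roi.get(roi)
    if dom is None:
        event_trs = np.sort(np.concatenate(
            [truth.event_trs_by_domain[d] for d in DOMAINS]))
    else:
        event_trs = truth.event_trs_by_domain[dom]
    amp = _event_bump_course(event_trs, cfg.n_trs)
    if cfg.hrf_patterns:
        amp = hrf_convolve(amp, cfg.tr)

    # fixed domain-response map: the state-independent part of the update
    # response, which a parametric-modulation GLM can recover voxelwise;
    # uniformly positive, as for a compact region activating with updates
    mod_template = np.ones(cfg.n_voxels_per_roi) / np.sqrt(cfg.n_voxels_per_roi)
    # per-state templates, orthogonal to the fixed map so state dynamics do
    # not bias voxelwise modulator estimates
    k = int(sched.max())
    templates = rng.standard_normal((k, cfg.n_voxels_per_roi))
    templates -= np.outer(templates @ mod_template, mod_template)
    templates /= np.linalg.norm(templates, axis=1, keepdims=True)
    # fixed map carries most of the response; state templates add the
    # state-specific pattern dynamics without drowning voxelwise estimates
    mixed = (0.5 * templates[sched - 1] + mod_template[None, :]) / np.sqrt(1.25)
    signal = cfg.pattern_amplitude * amp[:, None] * mixed
    noise = rng.standard_normal((cfg.n_subjects, cfg.n_trs,
                                 cfg.n_voxels_per_roi))
    data = (truth.subject_gains[:, None, None] * signal[None]
            + cfg.pattern_noise_sd * noise)
    return PatternSeriesSet(roi, data, cfg.tr)


def make_dataset(cfg: SynthConfig) -> SynthDataset:
    """Full synthetic cohort: rater logs, ROI series, patterns, motion, arousal."""
    cfg.validate()
    truth = build_truth(cfg)
    rater_logs = {d: simulate_raters(truth, cfg, d) for d in DOMAINS}
    rois = sorted(truth.state_schedule_by_roi)
    roi_series = {r: simulate_roi_bold(truth, cfg, r) for r in rois}
    pattern_series = {r: simulate_roi_patterns(truth, cfg, r) for r in rois}
    motion = np.cumsum(
        0.02 * _rng(cfg.seed, _S_MOTION).standard_normal(
            (cfg.n_subjects, cfg.n_trs, 6)), axis=1)
    ds = SynthDataset(rater_logs, roi_series, pattern_series, motion,
                      truth.arousal_course.copy(), truth, cfg)
    for series in ds.roi_series.values():
        if not np.all(np.isfinite(series.data)):
            raise RuntimeError("non-finite values in generated series")
    return ds


def assemble_voxel_volume(
    ds: SynthDataset,
    rois: tuple = ("vmPFC", "amPFC", "dmPFC"),
    block_planes: int = 4,
    gap_planes: int = 1,
    tail_planes: int = 5,
):
    """Stack ROI pattern blocks into a synthetic 3-D voxel volume.

    Each ROI's voxels fill ``block_planes`` full planes of a plane_shape x z
    volume; blocks are separated by null planes and followed by a null tail,
    so cluster-extent thresholding sees compact 6-connected blocks against a
    noise background.  Returns ``(data, grid_shape, block_indices)`` with
    ``data`` subjects x TRs x voxels (flattened z-major) and
    ``block_indices`` mapping ROI to its flat voxel indices.
    """
    v = ds.config.n_voxels_per_roi
    if v % block_planes:
        raise ValueError("n_voxels_per_roi must divide into block_planes")
    per_plane = v // block_planes
    side = int(np.sqrt(per_plane))
    plane_shape = (side, per_plane // side)
    if plane_shape[0] * plane_shape[1] != per_plane:
        raise ValueError("voxels per plane must factor into a 2-D plane")
    nz = len(rois) * (block_planes + gap_planes) + tail_planes
    n_vox = nz * per_plane
    rng = _rng(ds.config.seed, _S_PATTERN, 99)
    data = rng.standard_normal((ds.config.n_subjects, ds.config.n_trs, n_vox))
    blocks = {}
    z0 = 0
    for roi in rois:
        start = z0 * per_plane
        idx = np.arange(start, start + v)
        data[:, :, idx] = ds.pattern_series[roi].data
        blocks[roi] = idx
        z0 += block_planes + gap_planes
    return data, (nz,) + plane_shape, blocks


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def save_dataset(ds: SynthDataset, outdir) -> None:
    """Write the cohort to disk: TSV rater logs, npy arrays, CSV courses."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for domain, logs in ds.rater_logs.items():
        rows = [{"rater_id": log.rater_id, "time_s": t}
                for log in logs for t in log.presses]
        pd.DataFrame(rows, columns=["rater_id", "time_s"]).to_csv(
            out / f"raters_{domain}.tsv", sep="\t", index=False)
    for roi, series in ds.roi_series.items():
        np.save(out / f"bold_{roi}.npy", series.data)
    for roi, pats in ds.pattern_series.items():
        np.save(out / f"patterns_{roi}.npy", pats.data)
    np.save(out / "motion.npy", ds.motion)
    pd.DataFrame({
        "tr_index": np.arange(ds.config.n_trs),
        "time_s": np.arange(ds.config.n_trs) * ds.config.tr,
        "value": ds.arousal,
    }).to_csv(out / "arousal.csv", index=False)
    cfg_dict = dataclasses.asdict(ds.config)
    with open(out / "config.txt", "w") as fh:
        for key, val in cfg_dict.items():
            fh.write(f"{key}={json.dumps(val)}\n")
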