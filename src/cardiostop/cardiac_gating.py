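"""Cardiac-cycle gating: R-peak detection, next-R prediction, and
phase-locked stimulus scheduling.

Stimuli are timed to cardiac systole (R + 290 ms, near the T-wave peak) or
diastole (R - 10 ms). The next R-wave is predicted from the median of the
last three inter-beat intervals, mirroring online ECG-triggered designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .synthetic_cohort import ECGTrace, RRSeries

__all__ = [
    "SYSTOLE_OFFSET_MS",
    "DIASTOLE_OFFSET_MS",
    "GatingState",
    "ScheduledEvent",
    "TimingPrecision",
    "detect_r_peaks",
    "predict_next_r",
    "schedule_trial_events",
    "achieved_offsets",
    "timing_precision",
]

logger = logging.getLogger(__name__)

SYSTOLE_OFFSET_MS = 290.0
DIASTOLE_OFFSET_MS = -10.0

#: detection refractory window, ms — prevents T-wave double counting
REFRACTORY_MS = 250.0

TRIAL_TYPES = ("go-systole", "go-diastole", "go-control-s", "go-control-d",
               "stop-systole", "stop-diastole")

_PHASE_OFFSET = {
    "go-systole": SYSTOLE_OFFSET_MS,
    "go-control-s": SYSTOLE_OFFSET_MS,
    "stop-systole": SYSTOLE_OFFSET_MS,
    "go-diastole": DIASTOLE_OFFSET_MS,
    "go-control-d": DIASTOLE_OFFSET_MS,
    "stop-diastole": DIASTOLE_OFFSET_MS,
}


def intended_offset(trial_type: str) -> float:
    """Intended stimulus offset from the R-peak (ms) for a trial type."""
    try:
        return _PHASE_OFFSET[trial_type]
    except KeyError:
        raise ValueError(f"unknown trial type {trial_type!r}") from None


def phase_of(trial_type: str) -> str:
    return "systole" if _PHASE_OFFSET[trial_type] > 0 else "diastole"


@dataclass(frozen=True)
class GatingState:
    """Recent R-peak history used for prediction."""

    recent_r_times: np.ndarray  # ms, strictly increasing, last >= 4 beats

    def __post_init__(self):
        object.__setattr__(self, "recent_r_times",
                           np.asarray(self.recent_r_times, dtype=float))

    @property
    def median_ibi(self) -> float:
        """Median of the last three inter-beat intervals, ms."""
        d = np.diff(self.recent_r_times)
        if d.size < 3:
            raise ValueError("insufficient beats: need >= 3 inter-beat intervals")
        return float(np.median(d[-3:]))


@dataclass(frozen=True)
class ScheduledEvent:
    """One trial's scheduled stimulus onsets, phase-locked to a predicted R."""

    trial_id: str
    trial_type: str
    intended_offset: float        # ms relative to R: +290 or -10
    predicted_r: float            # ms
    scheduled_go_onset: float     # ms
    scheduled_stop_onset: float | None = None
    achieved_offset: float | None = None  # filled post hoc against true R times

    @property
    def phase_onset(self) -> float:
        """Onset of the phase-timed stimulus: stop cue on stop trials, go cue
        otherwise."""
        return (self.scheduled_stop_onset if self.scheduled_stop_onset is not None
                else self.scheduled_go_onset)


def detect_r_peaks(trace: ECGTrace, threshold: float) -> RRSeries:
    """Threshold-based R-peak detection with a 250 ms refractory window.

    Each detection is a local maximum exceeding ``threshold``. With the
    threshold between the T and R amplitudes this yields one detection per
    beat; below the T amplitude, T-waves produce extra detections (logged).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    samples = np.asarray(trace.samples, dtype=float)
    if samples.size == 0 or np.all(samples < threshold):
        logger.warning("detect_r_peaks: flat or sub-threshold trace, no peaks")
        return RRSeries(r_times=np.array([]),
                        duration=samples.size * 1000.0 / trace.sampling_rate
                        if samples.size else 0.0)
    distance = max(1, int(round(REFRACTORY_MS * trace.sampling_rate / 1000.0)))
    idx, _ = find_peaks(samples, height=threshold, distance=distance)
    times = idx * (1000.0 / trace.sampling_rate)
    if trace.true_r_times.size and times.size > trace.true_r_times.size:
        logger.warning(
            "detect_r_peaks: %d detections for %d true beats — threshold "
            "likely below T-wave amplitude", times.size, trace.true_r_times.size)
    return RRSeries(r_times=times,
                    duration=samples.size * 1000.0 / trace.sampling_rate)


def predict_next_r(state: GatingState) -> float:
    """Predict the next R-peak: last R plus the median of the last 3 IBIs.

    The median makes the prediction robust to a single ectopic-like interval.
    """
    r = state.recent_r_times
    if r.size < 4:
        raise ValueError("insufficient beats: need >= 4 R times (3 intervals)")
    return float(r[-1] + state.median_ibi)


def schedule_trial_events(prediction: float, trial_type: str, ssd: float | None = None,
                          trial_id: str = "", not_before: float | None = None,
                          median_ibi: float | None = None) -> ScheduledEvent:
    """Schedule go (and stop) onsets for one trial around a predicted R-peak.

    Stop trials place the stop cue at the phase point (R+290 or R-10) and the
    go cue SSD earlier. Control go trials place the go cue where the matching
    stop trial's go cue would fall (phase point minus the tracker's current
    SSD) with no stop cue. If the go onset would precede ``not_before`` (the
    end of ECG monitoring), the whole event rolls to the next predicted beat
    (requires ``median_ibi``); rescheduling is logged, never an exception.
    """
    off = intended_offset(trial_type)
    is_stop = trial_type.startswith("stop")
    is_control = trial_type.startswith("go-control")
    if (is_stop or is_control) and (ssd is None or ssd < 0):
        raise ValueError(f"{trial_type} requires ssd >= 0")

    def build(pred: float) -> ScheduledEvent:
        phase_point = pred + off
        if is_stop:
            return ScheduledEvent(trial_id, trial_type, off, pred,
                                  scheduled_go_onset=phase_point - ssd,
                                  scheduled_stop_onset=phase_point)
        shift = ssd if is_control else 0.0
        return ScheduledEvent(trial_id, trial_type, off, pred,
                              scheduled_go_onset=phase_point - shift)

    ev = build(float(prediction))
    if not_before is not None:
        pred = float(prediction)
        while ev.scheduled_go_onset < not_before:
            if median_ibi is None or median_ibi <= 0:
                raise ValueError("go onset precedes scheduling time and no "
                                 "median_ibi given to roll to the next beat")
            pred += median_ibi
            logger.debug("trial %s rescheduled to next predicted beat at %.0f ms",
                         trial_id, pred)
            ev = build(pred)
    return ev


@dataclass(frozen=True)
class TimingPrecision:
    """Per-trial-type timing summary of achieved vs intended cardiac offsets."""

    per_type: dict          # trial_type -> dict(mean, sd, n, frac_within_200, offsets)
    per_phase: dict         # "systole"/"diastole" -> frac_within_200
    bin_edges: np.ndarray   # 50 ms histogram bins
    histograms: dict        # trial_type -> counts per bin


def achieved_offsets(event_times: np.ndarray, true_r: RRSeries) -> np.ndarray:
    """Signed offset of each event time to the nearest true R-peak (the one
    minimizing the absolute offset)."""
    r = np.asarray(true_r.r_times, dtype=float)
    t = np.asarray(event_times, dtype=float)
    if r.size == 0:
        raise ValueError("true_r is empty")
    i = np.clip(np.searchsorted(r, t), 1, r.size - 1)
    lo, hi = r[i - 1], r[np.minimum(i, r.size - 1)]
    use_hi = np.abs(t - hi) < np.abs(t - lo)
    return t - np.where(use_hi, hi, lo)


def timing_precision(events: list[ScheduledEvent], true_r: RRSeries,
                     tolerance_ms: float = 200.0,
                     bin_range: tuple[float, float] = (-500.0, 800.0),
                     bin_width: float = 50.0) -> TimingPrecision:
    """Summarise how precisely phase-timed stimuli landed in the cardiac cycle.

    For each event, the achieved offset is the signed distance from the
    phase-timed stimulus onset (stop cue on stop trials, go cue otherwise) to
    the nearest true R-peak. The fraction of events within ``tolerance_ms``
    of the intended timing is measured by the R-prediction error (predicted R
    vs nearest true R): for phase-locked go and stop events this equals
    achieved offset minus intended offset, and it remains the correct error
    for control-go events, whose go cue is deliberately scheduled one SSD
    before the phase point. Reports per-type mean/SD of achieved offsets,
    per-phase within-tolerance fractions, and 50 ms-bin histograms.
    """
    edges = np.arange(bin_range[0], bin_range[1] + bin_width, bin_width)
    if not events:
        return TimingPrecision(per_type={}, per_phase={}, bin_edges=edges,
                               histograms={})
    per_type: dict = {}
    per_phase_hits: dict = {"systole": [0, 0], "diastole": [0, 0]}
    histograms: dict = {}
    by_type: dict[str, list[ScheduledEvent]] = {}
    for ev in events:
        by_type.setdefault(ev.trial_type, []).append(ev)
    for ttype, evs in by_type.items():
        times = np.array([e.phase_onset for e in evs])
        offs = achieved_offsets(times, true_r)
        pred_err = achieved_offsets(np.array([e.predicted_r for e in evs]), true_r)
        within = np.abs(pred_err) <= tolerance_ms
        per_type[ttype] = {
            "n": len(evs),
            "mean": float(offs.mean()),
            "sd": float(offs.std(ddof=1)) if len(evs) > 1 else 0.0,
            "frac_within_200": float(within.mean()),
            "offsets": offs,
        }
        hits = per_phase_hits[phase_of(ttype)]
        hits[0] += int(within.sum())
        hits[1] += len(evs)
        # clip into range so bin counts always sum to the event count
        histograms[ttype], _ = np.histogram(
            np.clip(offs, edges[0], edges[-1] - 1e-9), bins=edges)
    per_phase = {ph: (h / n if n else float("nan"))
                 for ph, (h, n) in per_phase_hits.items()}
    return TimingPrecision(per_type=per_type, per_phase=per_phase,
                           bin_edges=edges, histograms=histograms)


def fill_achieved_offsets(events: list[ScheduledEvent],
                          true_r: RRSeries) -> list[ScheduledEvent]:
    """Return events with ``achieved_offset`` filled from the true R series."""
    if not events:
        return []
    offs = achieved_offsets(np.array([e.phase_onset for e in events]), true_r)
    return [replace(e, achieved_offset=float(o)) for e, o in zip(events, offs)]
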