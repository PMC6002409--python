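"""Trial schedule, adaptive SSD staircases, and race-model trial simulation.

The session comprises 360 trials: 240 go (60 phase-timed at systole, 60 at
diastole, 120 control go trials whose onset borrows the current tracker SSD)
and 120 stop trials (60 per phase). Two independent one-up/one-down
staircases (start 200 ms, step 50 ms, floor 0) track the stop-signal delay
separately for systole- and diastole-timed stop cues, converging stop
success toward 50%.

Trial outcomes follow the independent horse-race model: a response occurs
iff the ex-Gaussian go process finishes before SSD + stop latency (+ noise),
within the 1000 ms response window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import cardiac_gating as cg
from .synthetic_cohort import ParticipantProfile, RRSeries, generate_rr_series

__all__ = [
    "N_TRIALS",
    "TrialSpec",
    "StaircaseTracker",
    "TrialRecord",
    "SessionResult",
    "build_schedule",
    "update_staircase",
    "simulate_trial",
    "simulate_outcomes",
    "run_session",
]

logger = logging.getLogger(__name__)

N_TRIALS = 360
N_PER_TYPE = 60
N_BLOCKS = 4
BLOCK_SIZE = N_TRIALS // N_BLOCKS

START_SSD_MS = 200.0
SSD_STEP_MS = 50.0
SSD_FLOOR_MS = 0.0
RESPONSE_WINDOW_MS = 1000.0
ITI_MS = 1000.0
MONITOR_BEATS = 3  # inter-beat intervals monitored before each trial

# non-converger phenotype: per-trial stop latency is a bimodal mixture whose
# dominant component never finishes within the response window, capping stop
# success below 50% so the staircase cannot track it
NONCONVERGER_MISS_PROB = 0.65
NONCONVERGER_MISS_LATENCY_MS = 1500.0


@dataclass(frozen=True)
class TrialSpec:
    index: int        # 1..360
    trial_type: str   # one of cardiac_gating.TRIAL_TYPES
    block: int        # 1..4

    @property
    def is_stop(self) -> bool:
        return self.trial_type.startswith("stop")

    @property
    def is_control(self) -> bool:
        return self.trial_type.startswith("go-control")

    @property
    def tracker(self) -> str:
        """Which SSD tracker this trial reads: 'systole' or 'diastole'."""
        return cg.phase_of(self.trial_type)


@dataclass
class StaircaseTracker:
    """One-up/one-down SSD staircase for one cardiac condition."""

    condition: str                       # "systole" | "diastole"
    ssd: float = START_SSD_MS
    step: float = SSD_STEP_MS
    history: list = field(default_factory=list)  # (trial index, ssd used, success)


def update_staircase(tracker: StaircaseTracker, stop_success: bool,
                     trial_index: int | None = None) -> StaircaseTracker:
    """Apply one staircase step in place: +step after a successful stop,
    -step (floored at 0) after a failed stop. Returns the tracker."""
    tracker.history.append((trial_index, tracker.ssd, bool(stop_success)))
    if stop_success:
        tracker.ssd = tracker.ssd + tracker.step
    else:
        tracker.ssd = max(tracker.ssd - tracker.step, SSD_FLOOR_MS)
    return tracker


@dataclass(frozen=True)
class TrialRecord:
    """Realized outcome of one trial."""

    spec: TrialSpec
    ssd_used: float | None       # ms; stop trials only
    go_rt: float | None          # ms from go onset; None if no response
    responded: bool
    stop_success: bool | None    # defined iff stop trial
    go_onset: float | None = None
    stop_onset: float | None = None
    achieved_offset: float | None = None


def build_schedule(seed: int) -> list[TrialSpec]:
    """Pseudo-random 360-trial schedule: 60 trials of each of the six types,
    shuffled reproducibly, split into four blocks of 90."""
    rng = np.random.default_rng(seed)
    types = np.repeat(np.array(cg.TRIAL_TYPES, dtype=object), N_PER_TYPE)
    rng.shuffle(types)
    return [TrialSpec(index=i + 1, trial_type=str(t), block=i // BLOCK_SIZE + 1)
            for i, t in enumerate(types)]


def _draw_go_finish(profile: ParticipantProfile, rng: np.random.Generator) -> float:
    return (rng.normal(profile.go_mu, profile.go_sigma)
            + rng.exponential(profile.go_tau))


def _draw_stop_latency(profile: ParticipantProfile, phase: str,
                       rng: np.random.Generator) -> float:
    base = (profile.stop_latency_systole if phase == "systole"
            else profile.stop_latency_diastole)
    if profile.is_nonconverger and rng.random() < NONCONVERGER_MISS_PROB:
        return NONCONVERGER_MISS_LATENCY_MS
    return base + rng.normal(0.0, profile.stop_latency_sd_within)


def simulate_trial(profile: ParticipantProfile, spec: TrialSpec,
                   ssd: float | None, phase_at_stop: str | None,
                   seed: int | np.random.Generator) -> TrialRecord:
    """Simulate one trial under the independent race model.

    Go finishing time is ex-Gaussian; on stop trials the participant responds
    iff the go process finishes before SSD + stop latency. Go finishes beyond
    the 1000 ms window (or spontaneous omissions) are recorded as omissions.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if spec.is_stop and ssd is None:
        raise ValueError("stop trial requires an SSD")

    omitted = rng.random() < profile.omission_rate
    go_finish = _draw_go_finish(profile, rng)

    if spec.is_stop:
        stop_finish = ssd + _draw_stop_latency(profile, phase_at_stop, rng)
        responds = (not omitted) and go_finish < stop_finish \
            and go_finish <= RESPONSE_WINDOW_MS
        return TrialRecord(spec=spec, ssd_used=float(ssd),
                           go_rt=float(go_finish) if responds else None,
                           responded=responds, stop_success=not responds)
    responds = (not omitted) and go_finish <= RESPONSE_WINDOW_MS
    return TrialRecord(spec=spec, ssd_used=None,
                       go_rt=float(go_finish) if responds else None,
                       responded=responds, stop_success=None)


def _make_trackers() -> dict[str, StaircaseTracker]:
    return {"systole": StaircaseTracker("systole"),
            "diastole": StaircaseTracker("diastole")}


def simulate_outcomes(profile: ParticipantProfile, schedule: list[TrialSpec],
                      seed: int | np.random.Generator,
                      trackers: dict[str, StaircaseTracker] | None = None,
                      ) -> tuple[list[TrialRecord], dict[str, StaircaseTracker]]:
    """Run the behavioural session (race model + staircases) without cardiac
    scheduling. Stimulus onsets are left unset; everything the behavioural
    summaries need (RTs, responses, SSDs) is produced by the same trial rule
    as the fully gated session."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    trackers = trackers or _make_trackers()
    records = []
    for spec in schedule:
        ssd = trackers[spec.tracker].ssd if spec.is_stop else None
        rec = simulate_trial(profile, spec, ssd,
                             spec.tracker if spec.is_stop else None, rng)
        if spec.is_stop:
            update_staircase(trackers[spec.tracker], rec.stop_success, spec.index)
        records.append(rec)
    return records, trackers


@dataclass(frozen=True)
class SessionResult:
    records: list[TrialRecord]
    trackers: dict[str, StaircaseTracker]
    events: list[cg.ScheduledEvent]
    rr: RRSeries


def run_session(profile: ParticipantProfile, rr: RRSeries | None,
                seed: int, schedule: list[TrialSpec] | None = None,
                ) -> SessionResult:
    """Run one full cardiac-gated session.

    Before each trial the ECG is monitored for 3 beats (4 R-peaks) to form a
    median inter-beat interval, the next R is predicted, and the trial's
    stimuli are scheduled at the phase point (systole R+290 / diastole R-10),
    shifted by the tracker SSD for stop and control-go trials. Trials are
    separated by a 1000 ms inter-trial interval. If ``rr`` is None a task RR
    series long enough for 360 trials is generated from the profile.
    """
    rng = np.random.default_rng(seed)
    schedule = schedule or build_schedule(seed)
    if rr is None:
        ibi = 60000.0 / profile.hr_rest
        est = len(schedule) * (ITI_MS + (MONITOR_BEATS + 2.5) * ibi
                               + RESPONSE_WINDOW_MS) * 1.3
        rr = generate_rr_series(profile, est, seed=int(rng.integers(2 ** 31)),
                                context="task")
    r = np.asarray(rr.r_times, dtype=float)
    trackers = _make_trackers()
    records: list[TrialRecord] = []
    events: list[cg.ScheduledEvent] = []
    t = float(r[0])

    for spec in schedule:
        i = int(np.searchsorted(r, t, side="right"))
        if i + MONITOR_BEATS + 1 > r.size:
            raise RuntimeError(
                f"RR series exhausted at trial {spec.index}: extend the task "
                "recording or pass rr=None to generate one")
        beats = r[i:i + MONITOR_BEATS + 1]
        state = cg.GatingState(recent_r_times=beats)
        pred = cg.predict_next_r(state)
        ssd = (trackers[spec.tracker].ssd
               if (spec.is_stop or spec.is_control) else None)
        ev = cg.schedule_trial_events(pred, spec.trial_type, ssd=ssd,
                                      trial_id=f"t{spec.index:03d}",
                                      not_before=float(beats[-1]),
                                      median_ibi=state.median_ibi)
        rec = simulate_trial(profile, spec,
                             ssd if spec.is_stop else None,
                             spec.tracker if spec.is_stop else None, rng)
        rec = TrialRecord(spec=rec.spec, ssd_used=rec.ssd_used, go_rt=rec.go_rt,
                          responded=rec.responded, stop_success=rec.stop_success,
                          go_onset=ev.scheduled_go_onset,
                          stop_onset=ev.scheduled_stop_onset)
        if spec.is_stop:
            update_staircase(trackers[spec.tracker], rec.stop_success, spec.index)
        records.append(rec)
        events.append(ev)
        trial_end = ev.scheduled_go_onset + (rec.go_rt if rec.go_rt is not None
                                             else RESPONSE_WINDOW_MS)
        t = trial_end + ITI_MS

    events = cg.fill_achieved_offsets(events, rr)
    records = [TrialRecord(spec=rec.spec, ssd_used=rec.ssd_used, go_rt=rec.go_rt,
                           responded=rec.responded, stop_success=rec.stop_success,
                           go_onset=rec.go_onset, stop_onset=rec.stop_onset,
                           achieved_offset=ev.achieved_offset)
               for rec, ev in zip(records, events)]
    return SessionResult(records=records, trackers=trackers, events=events, rr=rr)


def staircase_success_rate(profile: ParticipantProfile, n_trials: int,
                           phase: str, seed: int, burn_in: int = 0) -> float:
    """Long-run stop-success fraction of one condition's staircase over
    ``n_trials`` simulated stop trials (discarding ``burn_in`` initial
    trials). The one-up/one-down rule converges this toward 0.5 for
    race-model participants."""
    rng = np.random.default_rng(seed)
    tracker = StaircaseTracker(phase)
    spec = TrialSpec(index=0, trial_type=f"stop-{phase}", block=1)
    successes = 0
    for k in range(n_trials):
        rec = simulate_trial(profile, spec, tracker.ssd, phase, rng)
        update_staircase(tracker, rec.stop_success, k)
        if k >= burn_in and rec.stop_success:
            successes += 1
    return successes / (n_trials - burn_in)
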