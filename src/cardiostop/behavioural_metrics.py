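"""Per-participant behavioural summaries, integration-method SSRT, and the
cohort-level two-pass exclusion filters.

SSRT (stop-signal reaction time) is estimated by the integration method:
go RTs are rank ordered (omissions replaced by the 1000 ms maximum), the RT
at rank ceil(n * p(respond|stop)) is read off, and the mean SSD of the
condition's stop trials is subtracted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .task_engine import RESPONSE_WINDOW_MS, TrialRecord

__all__ = [
    "ConditionSummary",
    "condition_summaries",
    "ssrt_integration",
    "summarize_session",
    "apply_exclusions",
]

logger = logging.getLogger(__name__)

PHASES = ("systole", "diastole")


@dataclass(frozen=True)
class ConditionSummary:
    """Per-participant condition-level indices feeding the statistics layer.

    Missing conditions (e.g. a session with no stop trials of one phase) are
    represented as NaN.
    """

    participant_id: str
    go_rt_systole: float = math.nan     # mean RT, phase-timed go trials, ms
    go_rt_diastole: float = math.nan
    p_respond_systole: float = math.nan  # P(respond | stop), per tracker
    p_respond_diastole: float = math.nan
    mean_ssd_systole: float = math.nan   # mean SSD over stop trials, ms
    mean_ssd_diastole: float = math.nan
    ssrt_systole: float = math.nan
    ssrt_diastole: float = math.nan
    inhibition_success_overall: float = math.nan
    go_omissions: int = 0
    notes: tuple[str, ...] = field(default=())

    def inhibition_success(self, phase: str) -> float:
        return 1.0 - getattr(self, f"p_respond_{phase}")


def condition_summaries(records: list[TrialRecord],
                        participant_id: str = "") -> ConditionSummary:
    """Summarise one session: per-phase go RT means (phase-timed go trials),
    response probabilities and mean SSDs on stop trials. SSRT fields are left
    NaN; see :func:`summarize_session`."""
    vals: dict = {"participant_id": participant_id}
    notes = []
    go_omissions = sum(1 for r in records
                       if not r.spec.is_stop and not r.responded)
    vals["go_omissions"] = go_omissions

    stop_resp_all = []
    for phase in PHASES:
        go_rts = [r.go_rt for r in records
                  if r.spec.trial_type == f"go-{phase}" and r.go_rt is not None]
        stops = [r for r in records if r.spec.trial_type == f"stop-{phase}"]
        suffix = phase
        if go_rts:
            vals[f"go_rt_{suffix}"] = float(np.mean(go_rts))
        if stops:
            vals[f"p_respond_{suffix}"] = float(np.mean([r.responded for r in stops]))
            vals[f"mean_ssd_{suffix}"] = float(np.mean([r.ssd_used for r in stops]))
            stop_resp_all += [r.responded for r in stops]
        else:
            notes.append(f"no stop-{phase} trials")
            logger.warning("participant %s: no stop-%s trials; fields missing",
                           participant_id, phase)
    if stop_resp_all:
        vals["inhibition_success_overall"] = 1.0 - float(np.mean(stop_resp_all))
    return ConditionSummary(notes=tuple(notes), **vals)


def ssrt_integration(go_rts, omissions: int, p_respond: float,
                     mean_ssd: float) -> float:
    """Integration-method SSRT estimate, ms.

    Omitted go trials enter the distribution at the 1000 ms maximum; RTs are
    sorted ascending; the 1-based rank is ceil(n * p_respond), clamped to
    [1, n]; SSRT = RT[rank] - mean_ssd.

    p_respond == 0 is undefined (returns NaN with a warning); p_respond == 1
    is computed at rank n but flagged unreliable.
    """
    go_rts = list(go_rts)
    if not go_rts:
        raise ValueError("need at least one go RT")
    if not 0.0 <= p_respond <= 1.0:
        raise ValueError("p_respond must be in [0, 1]")
    if p_respond == 0.0:
        logger.warning("ssrt_integration: p_respond = 0, SSRT undefined")
        return math.nan
    if p_respond == 1.0:
        logger.warning("ssrt_integration: p_respond = 1, estimate unreliable")
    pooled = sorted(go_rts + [RESPONSE_WINDOW_MS] * int(omissions))
    n = len(pooled)
    rank = min(max(math.ceil(n * p_respond), 1), n)
    return float(pooled[rank - 1] - mean_ssd)


def summarize_session(records: list[TrialRecord], participant_id: str = "",
                      ssrt_go_pool: str = "all") -> ConditionSummary:
    """Full per-participant summary including per-phase SSRT.

    ``ssrt_go_pool``: "all" pools every go trial of the session (phase-timed
    and control) into the SSRT go-RT distribution; "per-phase" restricts it
    to the matching phase's go trials (phase-timed plus that tracker's
    control trials).
    """
    if ssrt_go_pool not in ("all", "per-phase"):
        raise ValueError("ssrt_go_pool must be 'all' or 'per-phase'")
    summ = condition_summaries(records, participant_id)
    go_records = [r for r in records if not r.spec.is_stop]
    updates: dict = {}
    for phase in PHASES:
        p = getattr(summ, f"p_respond_{phase}")
        ssd = getattr(summ, f"mean_ssd_{phase}")
        if math.isnan(p) or math.isnan(ssd):
            continue
        pool = (go_records if ssrt_go_pool == "all"
                else [r for r in go_records if r.spec.tracker == phase])
        rts = [r.go_rt for r in pool if r.go_rt is not None]
        omis = sum(1 for r in pool if not r.responded)
        if not rts or p == 0.0:
            continue
        updates[f"ssrt_{phase}"] = ssrt_integration(rts, omis, p, ssd)
    return replace(summ, **updates) if updates else summ


@dataclass(frozen=True)
class ExclusionResult:
    retained: list            # ConditionSummary
    excluded: dict            # participant_id -> reason string
    flow: dict                # entrants / after_pass1 / after_pass2 counts


def apply_exclusions(summaries: list[ConditionSummary]) -> ExclusionResult:
    """Two-pass cohort exclusion filter.

    Pass 1 ("waiters"): exclude participants whose mean go RT (either phase)
    or mean SSD (either tracker) exceeds the group mean by more than 2 SD —
    evidence of slowing to await the stop cue. Statistics are computed over
    all entrants; the rule is one-sided ("long" RTs/SSDs).

    Pass 2 ("non-convergence"): on pass-1 survivors only, exclude
    participants whose per-tracker inhibition success deviates from the
    survivor group mean by more than 2 SD on either tracker — staircases that
    failed to converge to ~50%. Two-sided.
    """
    if len(summaries) < 3:
        raise ValueError("apply_exclusions needs >= 3 participants "
                         "(group SD is meaningless below that)")
    excluded: dict[str, str] = {}

    def high_outliers(vals: np.ndarray) -> np.ndarray:
        ok = ~np.isnan(vals)
        mean, sd = np.nanmean(vals), np.nanstd(vals, ddof=1)
        return ok & (vals > mean + 2.0 * sd)

    # pass 1: long go RTs and/or long SSDs
    metrics1 = {
        "go RT (systole)": np.array([s.go_rt_systole for s in summaries]),
        "go RT (diastole)": np.array([s.go_rt_diastole for s in summaries]),
        "SSD (systole)": np.array([s.mean_ssd_systole for s in summaries]),
        "SSD (diastole)": np.array([s.mean_ssd_diastole for s in summaries]),
    }
    for name, vals in metrics1.items():
        for i in np.flatnonzero(high_outliers(vals)):
            pid = summaries[i].participant_id
            reason = f"waiting: {name} > group mean + 2 SD"
            excluded.setdefault(pid, reason)
    survivors = [s for s in summaries if s.participant_id not in excluded]
    after_pass1 = len(survivors)

    # pass 2: per-tracker inhibition success, statistics over survivors only
    for phase in PHASES:
        vals = np.array([s.inhibition_success(phase) for s in survivors])
        ok = ~np.isnan(vals)
        mean, sd = np.nanmean(vals), np.nanstd(vals, ddof=1)
        out = ok & (np.abs(vals - mean) > 2.0 * sd)
        for i in np.flatnonzero(out):
            pid = survivors[i].participant_id
            reason = (f"non-convergence: {phase} tracker inhibition success "
                      "beyond 2 SD of group mean")
            excluded.setdefault(pid, reason)
    retained = [s for s in survivors if s.participant_id not in excluded]

    flow = {"entrants": len(summaries), "after_pass1": after_pass1,
            "after_pass2": len(retained), "retained": len(retained)}
    return ExclusionResult(retained=retained, excluded=excluded, flow=flow)
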