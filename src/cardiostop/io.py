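"""Delimited-text input/output for cohort simulations and analysis results.

File formats (all plain CSV):
  rr_<id>.csv        r_time_ms
  counting_<id>.csv  window_s, actual_beats, counted_beats, confidence
  bpq_<id>.csv       item, score
  trials_<id>.csv    per-trial behavioural record
  events_<id>.csv    per-trial scheduled/achieved cardiac timing
  profile_manifest.csv, summaries.csv, table1.csv, fig2_means.csv,
  fig1d_hist.csv, exclusion_flow.json, report.md
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic_cohort import CohortConfig, CountingTrial, RRSeries

__all__ = [
    "load_config",
    "write_rr", "read_rr",
    "write_counting", "read_counting",
    "write_trials", "write_events",
    "write_cohort_outputs", "write_reports",
]


def load_config(path) -> CohortConfig:
    """Read a YAML cohort configuration mirroring CohortConfig field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "rmssd_range" in raw:
        raw["rmssd_range"] = tuple(raw["rmssd_range"])
    if "counting_windows" in raw:
        raw["counting_windows"] = tuple(raw["counting_windows"])
    if "effect_structure" in raw:
        raw["effect_structure"] = {tuple(k.split("~")): float(v)
                                   for k, v in raw["effect_structure"].items()}
    return CohortConfig(**raw)


def write_rr(rr: RRSeries, path) -> None:
    pd.DataFrame({"r_time_ms": np.asarray(rr.r_times)}).to_csv(path, index=False)


def read_rr(path, context: str = "rest") -> RRSeries:
    df = pd.read_csv(path)
    times = df["r_time_ms"].to_numpy(dtype=float)
    duration = float(times[-1]) if times.size else 0.0
    return RRSeries(r_times=times, duration=duration, context=context)


def write_counting(trials: list[CountingTrial], path) -> None:
    pd.DataFrame([dataclasses.asdict(t) for t in trials]).to_csv(path, index=False)


def read_counting(path) -> list[CountingTrial]:
    df = pd.read_csv(path)
    return [CountingTrial(window_s=float(r.window_s),
                          actual_beats=int(r.actual_beats),
                          counted_beats=int(r.counted_beats),
                          confidence=float(r.confidence))
            for r in df.itertuples()]


def write_trials(records, path) -> None:
    rows = []
    for r in records:
        rows.append({
            "index": r.spec.index, "block": r.spec.block,
            "trial_type": r.spec.trial_type,
            "ssd_ms": r.ssd_used, "go_rt_ms": r.go_rt,
            "responded": r.responded, "stop_success": r.stop_success,
            "go_onset_ms": r.go_onset, "stop_onset_ms": r.stop_onset,
            "achieved_offset_ms": r.achieved_offset,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_events(events, path) -> None:
    rows = [{
        "trial_id": e.trial_id, "trial_type": e.trial_type,
        "intended_offset_ms": e.intended_offset, "predicted_r_ms": e.predicted_r,
        "go_onset_ms": e.scheduled_go_onset, "stop_onset_ms": e.scheduled_stop_onset,
        "achieved_offset_ms": e.achieved_offset,
    } for e in events]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_cohort_outputs(run, outdir) -> None:
    """Write per-participant and cohort-level CSVs for a CohortRun."""
    from .synthetic_cohort import profile_manifest
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    profile_manifest([pr.profile for pr in run.participants]).to_csv(
        out / "profile_manifest.csv", index=False)
    for pr in run.participants:
        pid = pr.profile.id
        write_rr(pr.rest_rr, out / f"rr_{pid}.csv")
        write_counting(pr.counting_trials, out / f"counting_{pid}.csv")
        pd.DataFrame({"item": range(1, len(pr.profile.bpq_items) + 1),
                      "score": pr.profile.bpq_items}
                     ).to_csv(out / f"bpq_{pid}.csv", index=False)
        write_trials(pr.session.records, out / f"trials_{pid}.csv")
        if pr.session.events:
            write_events(pr.session.events, out / f"events_{pid}.csv")
    summaries = run.results.copy()
    summaries["excluded"] = ~summaries["id"].isin(
        {s.participant_id for s in run.exclusions.retained})
    summaries["exclusion_reason"] = summaries["id"].map(
        run.exclusions.excluded).fillna("")
    summaries.to_csv(out / "summaries.csv", index=False)


def write_reports(bundle, outdir) -> None:
    from .stats_reporting import render_report_md
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.table1.to_csv(out / "table1.csv", index=False)
    bundle.fig2_means.to_csv(out / "fig2_means.csv", index=False)
    if bundle.fig1d_hist is not None:
        bundle.fig1d_hist.to_csv(out / "fig1d_hist.csv", index=False)
    with open(out / "exclusion_flow.json", "w") as fh:
        json.dump(bundle.exclusion_flow, fh, indent=2)
    with open(out / "report.md", "w") as fh:
        fh.write(render_report_md(bundle))
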