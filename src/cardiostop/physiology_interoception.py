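"""Resting cardiac indices (RMSSD, heart rate) and the three dimensions of
interoception: accuracy (heartbeat counting), awareness (accuracy-confidence
correlation), and sensibility (questionnaire mean).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic_cohort import BPQ_ITEMS, CountingTrial, RRSeries

__all__ = [
    "REST_WINDOW_MS",
    "InteroceptionScores",
    "rmssd",
    "heart_rate_bpm",
    "rmssd_bpm",
    "interoception_scores",
]

logger = logging.getLogger(__name__)

#: resting analysis window: 2.5 minutes from the start of rest
REST_WINDOW_MS = 150_000.0


def _rest_window(rr: RRSeries, window_ms: float | None) -> np.ndarray:
    r = np.asarray(rr.r_times, dtype=float)
    if window_ms is not None and r.size:
        r = r[r <= r[0] + window_ms]
    return r


def rmssd(rr: RRSeries, window_ms: float | None = REST_WINDOW_MS) -> float:
    """Root mean square of successive inter-beat-interval differences, ms.

    Longer recordings are truncated to the first ``window_ms`` (default the
    2.5-minute resting window); pass ``window_ms=None`` to use the full
    series. Requires >= 3 beats (two IBIs, one difference).
    """
    r = _rest_window(rr, window_ms)
    if r.size < 3:
        raise ValueError("rmssd needs >= 3 R times")
    d = np.diff(np.diff(r))
    return float(np.sqrt(np.mean(d ** 2)))


def heart_rate_bpm(rr: RRSeries, window_ms: float | None = REST_WINDOW_MS) -> float:
    """Mean heart rate over the analysis window: 60000 / mean IBI, bpm."""
    r = _rest_window(rr, window_ms)
    if r.size < 2:
        raise ValueError("heart_rate_bpm needs >= 2 R times")
    return float(60000.0 / np.mean(np.diff(r)))


def rmssd_bpm(rr: RRSeries, window_ms: float | None = REST_WINDOW_MS
              ) -> tuple[float, float]:
    """Convenience: (RMSSD in ms, heart rate in bpm) over the rest window."""
    return rmssd(rr, window_ms), heart_rate_bpm(rr, window_ms)


@dataclass(frozen=True)
class InteroceptionScores:
    accuracy: float          # mean Schandry-style counting score
    awareness: float         # Pearson r(per-trial accuracy, confidence); NaN if undefined
    sensibility: float       # mean of the 45 questionnaire items
    per_trial_accuracy: tuple[float, ...]
    per_trial_confidence: tuple[float, ...]


def interoception_scores(counting_trials: list[CountingTrial],
                         bpq_items) -> InteroceptionScores:
    """Score the heartbeat-counting task and questionnaire.

    Per-trial accuracy is the Schandry-style score 1 - |actual - counted| /
    actual (unclipped: wild overcounting can go negative); accuracy is its
    mean over trials. Awareness is the Pearson correlation between per-trial
    accuracy and confidence (NaN, with a warning, when either has zero
    variance). Sensibility is the mean of the 45 questionnaire items.
    """
    if len(counting_trials) < 2:
        raise ValueError("need >= 2 counting trials for awareness")
    items = np.asarray(bpq_items, dtype=float)
    if items.size != BPQ_ITEMS:
        raise ValueError(f"expected {BPQ_ITEMS} questionnaire items, got {items.size}")
    actual = np.array([t.actual_beats for t in counting_trials], dtype=float)
    counted = np.array([t.counted_beats for t in counting_trials], dtype=float)
    conf = np.array([t.confidence for t in counting_trials], dtype=float)
    if np.any(actual == 0):
        raise ValueError("counting trial with zero actual beats")
    acc = 1.0 - np.abs(actual - counted) / actual
    if np.std(acc) == 0.0 or np.std(conf) == 0.0:
        logger.warning("interoception_scores: zero variance in accuracy or "
                       "confidence; awareness undefined")
        awareness = math.nan
    else:
        awareness = float(stats.pearsonr(acc, conf).statistic)
    return InteroceptionScores(
        accuracy=float(np.mean(acc)),
        awareness=awareness,
        sensibility=float(np.mean(items)),
        per_trial_accuracy=tuple(float(a) for a in acc),
        per_trial_confidence=tuple(float(c) for c in conf),
    )
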