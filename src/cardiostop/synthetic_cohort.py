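"""Synthetic cohort generation for the cardiac-gated stop-signal task.

Generates race-model participants (ex-Gaussian go process, phase-dependent
stop latency), resting/task RR-interval series with controllable RMSSD,
minimal synthetic ECG traces with ground-truth R-peak times, and heartbeat
counting + questionnaire data with a configurable latent correlation
structure between HRV, interoceptive sensibility, and stopping ability.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CohortConfig",
    "ParticipantProfile",
    "RRSeries",
    "ECGTrace",
    "CountingTrial",
    "sample_cohort",
    "generate_rr_series",
    "render_ecg",
    "generate_interoception_data",
]

#: item count of the Body Perception Questionnaire awareness section
BPQ_ITEMS = 45
#: heartbeat-counting window durations, seconds
DEFAULT_COUNTING_WINDOWS = (25.0, 30.0, 35.0, 40.0, 45.0, 50.0)


@dataclass(frozen=True)
class CohortConfig:
    """Population parameters of a synthetic cohort.

    Defaults reproduce the study conditions this package emulates: resting
    heart rate 58 bpm (between-participant SD 10.05), go RTs around 470 ms,
    true stop latencies 203 ms at systole / 221 ms at diastole, a 60-entrant
    cohort containing 8 "waiters" and 6 staircase non-convergers.
    """

    n_participants: int = 60
    seed: int = 0
    hr_mean: float = 58.0            # bpm
    hr_sd_between: float = 10.05     # bpm
    rmssd_range: tuple[float, float] = (20.0, 60.0)  # ms, uniform per participant
    go_mu: float = 370.0             # ms, ex-Gaussian Gaussian mean
    go_mu_sd: float = 40.0
    go_sigma: float = 50.0           # ms, ex-Gaussian Gaussian SD
    go_sigma_sd: float = 10.0
    go_tau: float = 100.0            # ms, ex-Gaussian exponential mean
    go_tau_sd: float = 25.0
    stop_latency_systole_mean: float = 203.0   # ms
    stop_latency_diastole_mean: float = 221.0  # ms
    stop_latency_sd_between: float = 30.0      # ms
    stop_latency_sd_within: float = 20.0       # ms, per-trial noise
    omission_rate: float = 0.02
    waiter_fraction: float = 8.0 / 60.0
    nonconverger_fraction: float = 6.0 / 60.0
    bpq_item_count: int = BPQ_ITEMS
    counting_windows: tuple[float, ...] = DEFAULT_COUNTING_WINDOWS
    # latent correlation targets; keys are pairs of
    # {hrv, sensibility, stop_systole, stop_diastole}
    effect_structure: dict = field(
        default_factory=lambda: {
            ("hrv", "sensibility"): 0.32,
            ("hrv", "stop_diastole"): 0.308,
            ("sensibility", "stop_systole"): 0.366,
            ("stop_systole", "stop_diastole"): 0.62,
        }
    )

    def __post_init__(self):
        def bad(name, msg):
            raise ValueError(f"CohortConfig.{name}: {msg}")

        if self.n_participants < 0:
            bad("n_participants", "must be >= 0")
        for name in ("hr_mean", "hr_sd_between", "go_mu", "go_sigma", "go_tau",
                     "stop_latency_systole_mean", "stop_latency_diastole_mean"):
            if getattr(self, name) <= 0:
                bad(name, "must be > 0")
        for name in ("omission_rate", "waiter_fraction", "nonconverger_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad(name, "must be in [0, 1]")
        lo, hi = self.rmssd_range
        if not (0 <= lo <= hi):
            bad("rmssd_range", "must satisfy 0 <= low <= high")
        if self.waiter_fraction + self.nonconverger_fraction > 1.0:
            bad("waiter_fraction", "waiter + nonconverger fractions exceed 1")
        if len(self.counting_windows) == 0 or min(self.counting_windows) <= 0:
            bad("counting_windows", "must be non-empty and positive")
        if self.bpq_item_count <= 0:
            bad("bpq_item_count", "must be > 0")


@dataclass(frozen=True)
class ParticipantProfile:
    """Generative ground truth for one synthetic participant."""

    id: str
    hr_rest: float               # bpm
    rmssd_true: float            # ms
    go_mu: float                 # ms
    go_sigma: float              # ms
    go_tau: float                # ms
    stop_latency_systole: float  # ms
    stop_latency_diastole: float # ms
    stop_latency_sd_within: float
    omission_rate: float
    is_waiter: bool
    is_nonconverger: bool
    bpq_items: tuple[int, ...]   # 45 ordinal scores, 1..5
    bis_total: int               # Barratt total, 30..120
    counting_ability: float      # fraction of true beats perceived
    confidence_coupling: float   # accuracy-confidence correlation target

    def __post_init__(self):
        if self.go_mu <= 0 or self.stop_latency_systole <= 0 or self.stop_latency_diastole <= 0:
            raise ValueError("go_mu and stop latencies must be > 0")
        if len(self.bpq_items) != BPQ_ITEMS:
            raise ValueError(f"bpq_items must have length {BPQ_ITEMS}")


@dataclass(frozen=True)
class RRSeries:
    """Ordered R-peak event times for one participant, ms from recording start."""

    r_times: np.ndarray          # strictly increasing, ms
    duration: float              # ms
    context: str = "rest"        # "rest" | "task"

    def __post_init__(self):
        object.__setattr__(self, "r_times", np.asarray(self.r_times, dtype=float))
        if self.r_times.size > 1 and not np.all(np.diff(self.r_times) > 0):
            raise ValueError("r_times must be strictly increasing")

    @property
    def ibis(self) -> np.ndarray:
        """Successive inter-beat intervals, ms."""
        return np.diff(self.r_times)

    def __len__(self) -> int:
        return int(self.r_times.size)


@dataclass(frozen=True)
class ECGTrace:
    """Rendered single-lead ECG with ground-truth R-peak times for testing."""

    sampling_rate: float         # Hz
    samples: np.ndarray          # amplitude, arbitrary units
    true_r_times: np.ndarray     # ms

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "true_r_times", np.asarray(self.true_r_times, dtype=float))


@dataclass(frozen=True)
class CountingTrial:
    """One heartbeat-counting trial."""

    window_s: float
    actual_beats: int
    counted_beats: int
    confidence: float            # 0..100


# latent trait order for the Gaussian copula
_LATENTS = ("hrv", "sensibility", "stop_systole", "stop_diastole")


def _latent_correlation(effect_structure: dict) -> np.ndarray:
    corr = np.eye(len(_LATENTS))
    idx = {name: i for i, name in enumerate(_LATENTS)}
    for (a, b), rho in effect_structure.items():
        if a not in idx or b not in idx:
            raise ValueError(f"effect_structure: unknown latent pair ({a}, {b})")
        if not -1.0 <= rho <= 1.0:
            raise ValueError(f"effect_structure: correlation {rho} outside [-1, 1]")
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    # guard against non-PSD user targets: clip eigenvalues and renormalise
    w, v = np.linalg.eigh(corr)
    if w.min() < 1e-10:
        w = np.clip(w, 1e-10, None)
        corr = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    return corr


def sample_cohort(config: CohortConfig) -> list[ParticipantProfile]:
    """Draw ``config.n_participants`` participant profiles.

    Waiter / non-converger phenotypes are assigned to disjoint random subsets
    whose sizes are the configured fractions rounded to the nearest count.
    Waiters have go_mu inflated by 3 between-participant SDs (they slow down
    to await stop cues); non-convergers draw a per-trial stop latency from a
    bimodal mixture dominated by an effectively-infinite component, so their
    staircase success pins far from 50%.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    if n == 0:
        return []

    corr = _latent_correlation(config.effect_structure)
    z = rng.multivariate_normal(np.zeros(len(_LATENTS)), corr, size=n,
                                method="cholesky")
    z_hrv, z_sens, z_ss, z_sd = z.T

    # resting HR: truncated normal keeps the cohort mean at hr_mean
    a = (35.0 - config.hr_mean) / config.hr_sd_between
    b = (110.0 - config.hr_mean) / config.hr_sd_between
    hr = stats.truncnorm.rvs(a, b, loc=config.hr_mean, scale=config.hr_sd_between,
                             size=n, random_state=rng)

    lo, hi = config.rmssd_range
    rmssd = lo + (hi - lo) * stats.norm.cdf(z_hrv)

    go_mu = np.maximum(rng.normal(config.go_mu, config.go_mu_sd, n), 150.0)
    go_sigma = np.maximum(rng.normal(config.go_sigma, config.go_sigma_sd, n), 5.0)
    go_tau = np.maximum(rng.normal(config.go_tau, config.go_tau_sd, n), 5.0)

    sls = np.maximum(config.stop_latency_systole_mean
                     + config.stop_latency_sd_between * z_ss, 50.0)
    sld = np.maximum(config.stop_latency_diastole_mean
                     + config.stop_latency_sd_between * z_sd, 50.0)

    # phenotype flags: disjoint random subsets, counts rounded to nearest
    n_wait = round(n * config.waiter_fraction)
    n_nonc = round(n * config.nonconverger_fraction)
    order = rng.permutation(n)
    waiters = set(order[:n_wait].tolist())
    noncs = set(order[n_wait:n_wait + n_nonc].tolist())

    # sensibility: participant-level BPQ item mean driven by the latent
    bpq_mean = np.clip(2.5 + 0.6 * z_sens, 1.0, 5.0)
    counting_ability = rng.uniform(0.4, 1.0, n)
    confidence_coupling = rng.uniform(0.0, 0.8, n)
    bis = np.clip(np.rint(rng.normal(62.0, 10.0, n)), 30, 120).astype(int)

    profiles = []
    for i in range(n):
        items = np.clip(np.rint(rng.normal(bpq_mean[i], 0.8, config.bpq_item_count)),
                        1, 5).astype(int)
        mu_i = go_mu[i] + (3.0 * config.go_mu_sd if i in waiters else 0.0)
        profiles.append(ParticipantProfile(
            id=f"p{i:03d}",
            hr_rest=float(hr[i]),
            rmssd_true=float(rmssd[i]),
            go_mu=float(mu_i),
            go_sigma=float(go_sigma[i]),
            go_tau=float(go_tau[i]),
            stop_latency_systole=float(sls[i]),
            stop_latency_diastole=float(sld[i]),
            stop_latency_sd_within=config.stop_latency_sd_within,
            omission_rate=config.omission_rate,
            is_waiter=i in waiters,
            is_nonconverger=i in noncs,
            bpq_items=tuple(int(x) for x in items),
            bis_total=int(bis[i]),
            counting_ability=float(counting_ability[i]),
            confidence_coupling=float(confidence_coupling[i]),
        ))
    return profiles


# AR(1) coefficient of the IBI series; RMSSD fixes the innovation scale
_AR_PHI = 0.3
_IBI_BOUNDS = (300.0, 2000.0)


def generate_rr_series(profile: ParticipantProfile, duration: float,
                       seed: int, context: str = "rest") -> RRSeries:
    """Generate an RR-interval series of at least ``duration`` ms.

    IBIs follow a lag-1 autoregressive Gaussian around 60000/hr_rest, with the
    stationary variance chosen so the population RMSSD equals
    ``profile.rmssd_true``: for AR(1) with coefficient phi and stationary SD
    s, E[(x_t - x_{t-1})^2] = 2 s^2 (1 - phi), so s = rmssd / sqrt(2(1-phi)).
    IBIs are clipped to physiological bounds [300, 2000] ms.
    """
    mean_ibi = 60000.0 / profile.hr_rest
    if duration < 2 * mean_ibi:
        raise ValueError(
            f"duration {duration:.0f} ms too short: need at least two expected "
            f"inter-beat intervals ({2 * mean_ibi:.0f} ms) at {profile.hr_rest:.1f} bpm")
    rng = np.random.default_rng(seed)
    s = profile.rmssd_true / np.sqrt(2.0 * (1.0 - _AR_PHI))
    innov_sd = s * np.sqrt(1.0 - _AR_PHI ** 2)

    n_max = int(np.ceil(duration / max(mean_ibi - 4 * s, _IBI_BOUNDS[0]))) + 8
    eps = rng.normal(0.0, innov_sd, n_max) if innov_sd > 0 else np.zeros(n_max)
    dev = np.empty(n_max)
    prev = rng.normal(0.0, s) if s > 0 else 0.0
    for k in range(n_max):
        prev = _AR_PHI * prev + eps[k]
        dev[k] = prev
    ibis = np.clip(mean_ibi + dev, *_IBI_BOUNDS)
    r_times = np.concatenate(([0.0], np.cumsum(ibis)))
    # keep the first beat at/after covering the requested duration
    stop = int(np.searchsorted(r_times, duration, side="left"))
    r_times = r_times[: min(stop + 1, r_times.size)]
    return RRSeries(r_times=r_times, duration=float(max(duration, r_times[-1])),
                    context=context)


# ECG morphology: Gaussian deflections (amplitude, center offset ms, width ms)
_R_AMP, _R_SD = 1.0, 12.0
_T_AMP, _T_OFFSET, _T_SD = 0.3, 290.0, 45.0


def render_ecg(rr: RRSeries, sampling_rate: float) -> ECGTrace:
    """Render a minimal ECG trace: a tall narrow R deflection at each beat and
    a lower, wider T deflection ~290 ms later (systole).

    Not a morphologically realistic ECG; it exists so that threshold-based
    R-peak detection — including R-vs-T confusability — is testable against
    ground truth.
    """
    if sampling_rate < 250:
        raise ValueError("sampling_rate must be >= 250 Hz for the peak "
                         "localization contract")
    n = int(round(rr.duration * sampling_rate / 1000.0)) + 1
    t = np.arange(n) * (1000.0 / sampling_rate)  # ms
    samples = np.zeros(n)
    for r in np.atleast_1d(rr.r_times):
        for amp, off, sd in ((_R_AMP, 0.0, _R_SD), (_T_AMP, _T_OFFSET, _T_SD)):
            c = r + off
            sl = slice(*np.searchsorted(t, (c - 6 * sd, c + 6 * sd)))
            samples[sl] += amp * np.exp(-0.5 * ((t[sl] - c) / sd) ** 2)
    return ECGTrace(sampling_rate=float(sampling_rate), samples=samples,
                    true_r_times=np.array(rr.r_times, dtype=float))


def generate_interoception_data(profile: ParticipantProfile, rr: RRSeries,
                                seed: int,
                                windows: tuple[float, ...] = DEFAULT_COUNTING_WINDOWS,
                                count_noise_sd: float = 1.0) -> list[CountingTrial]:
    """Simulate the heartbeat-counting task over the configured windows.

    Windows tile the series back to back. Counted beats are a binomial
    thinning of the true beat count at ``profile.counting_ability`` plus
    rounded Gaussian integer noise (floored at 0). Confidence (0-100 VAS) is
    coupled to per-trial counting accuracy at ``profile.confidence_coupling``.
    """
    total_ms = 1000.0 * float(np.sum(windows))
    if rr.duration < total_ms or rr.r_times.size == 0 or rr.r_times[-1] < total_ms:
        raise ValueError(
            f"RR series ({rr.duration:.0f} ms) shorter than total counting "
            f"window time ({total_ms:.0f} ms)")
    rng = np.random.default_rng(seed)

    edges = 1000.0 * np.concatenate(([0.0], np.cumsum(windows)))
    actual = np.diff(np.searchsorted(rr.r_times, edges, side="right")).astype(int)
    counted = rng.binomial(actual, profile.counting_ability)
    if count_noise_sd > 0:
        counted = counted + np.rint(rng.normal(0, count_noise_sd, counted.size)).astype(int)
    counted = np.maximum(counted, 0)

    acc = 1.0 - np.abs(actual - counted) / np.where(actual > 0, actual, 1)
    sd = acc.std()
    z_acc = (acc - acc.mean()) / sd if sd > 0 else np.zeros_like(acc)
    rho = profile.confidence_coupling
    z_conf = rho * z_acc + np.sqrt(max(0.0, 1 - rho ** 2)) * rng.normal(0, 1, acc.size)
    confidence = np.clip(55.0 + 20.0 * z_conf, 0.0, 100.0)

    return [CountingTrial(window_s=float(w), actual_beats=int(a),
                          counted_beats=int(c), confidence=float(cf))
            for w, a, c, cf in zip(windows, actual, counted, confidence)]


def profile_manifest(profiles: list[ParticipantProfile]):
    """Flatten profiles into a pandas DataFrame (one row per participant)."""
    import pandas as pd
    rows = []
    for p in profiles:
        d = dataclasses.asdict(p)
        d["bpq_mean"] = float(np.mean(p.bpq_items))
        del d["bpq_items"]
        rows.append(d)
    return pd.DataFrame(rows)
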