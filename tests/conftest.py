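import numpy as np
import pytest

from cardiostop import CohortConfig, sample_cohort
from cardiostop import task_engine as te
from cardiostop.behavioural_metrics import ConditionSummary
from cardiostop.synthetic_cohort import BPQ_ITEMS, ParticipantProfile


def make_profile(**overrides) -> ParticipantProfile:
    """A hand-set participant profile for deterministic unit tests."""
    fields = dict(
        id="unit", hr_rest=60.0, rmssd_true=40.0,
        go_mu=370.0, go_sigma=50.0, go_tau=100.0,
        stop_latency_systole=203.0, stop_latency_diastole=221.0,
        stop_latency_sd_within=20.0, omission_rate=0.0,
        is_waiter=False, is_nonconverger=False,
        bpq_items=tuple([3] * BPQ_ITEMS), bis_total=62,
        counting_ability=0.8, confidence_coupling=0.5,
    )
    fields.update(overrides)
    return ParticipantProfile(**fields)


def deterministic_profile(go_rt: float, stop_latency: float) -> ParticipantProfile:
    """Race-model participant with (near-)deterministic go and stop processes."""
    return make_profile(go_mu=go_rt, go_sigma=1e-9, go_tau=1e-9,
                        stop_latency_systole=stop_latency,
                        stop_latency_diastole=stop_latency,
                        stop_latency_sd_within=0.0)


@pytest.fixture(scope="session")
def clean_config():
    """Cohort config without pathological phenotypes."""
    return CohortConfig(n_participants=8, waiter_fraction=0.0,
                        nonconverger_fraction=0.0, seed=11)


@pytest.fixture(scope="session")
def profile(clean_config):
    return sample_cohort(clean_config)[0]


@pytest.fixture(scope="session")
def gated_session(profile):
    """One full cardiac-gated 360-trial session, shared across tests."""
    return te.run_session(profile, None, seed=42)


@pytest.fixture(scope="session")
def gated_cohort():
    """46 clean participants run through full gated sessions (shared)."""
    cfg = CohortConfig(n_participants=46, waiter_fraction=0.0,
                       nonconverger_fraction=0.0, seed=3)
    profiles = sample_cohort(cfg)
    rng = np.random.default_rng(9)
    return [(p, te.run_session(p, None, seed=int(rng.integers(2 ** 31))))
            for p in profiles]


def build_exclusion_fixture(seed: int = 5) -> list[ConditionSummary]:
    """60-entrant cohort of summaries: 46 well-behaved participants, 8
    'waiters' (4 with long go RTs, 4 with long SSDs; all with extreme
    inhibition success that must NOT leak into pass-2 statistics), and 6
    staircase non-convergers (per-tracker inhibition success far from 50%).
    """
    rng = np.random.default_rng(seed)
    summaries = []

    def normal(pid, **over):
        base = dict(
            participant_id=pid,
            go_rt_systole=float(rng.normal(470, 20)),
            go_rt_diastole=float(rng.normal(474, 20)),
            p_respond_systole=float(rng.normal(0.5, 0.02)),
            p_respond_diastole=float(rng.normal(0.5, 0.02)),
            mean_ssd_systole=float(rng.normal(243, 20)),
            mean_ssd_diastole=float(rng.normal(227, 20)),
        )
        base.update(over)
        return ConditionSummary(**base)

    for i in range(46):
        summaries.append(normal(f"ok{i:02d}"))
    for i in range(4):  # waiters caught by long go RTs
        summaries.append(normal(f"waitRT{i}", go_rt_systole=700.0,
                                go_rt_diastole=700.0, p_respond_systole=0.9))
    for i in range(4):  # waiters caught by long SSDs
        summaries.append(normal(f"waitSSD{i}", mean_ssd_systole=450.0,
                                mean_ssd_diastole=450.0, p_respond_systole=0.9))
    for i in range(3):  # non-convergers, systole tracker stuck low
        summaries.append(normal(f"noncS{i}", p_respond_systole=0.75))
    for i in range(3):  # non-convergers, diastole tracker stuck high
        summaries.append(normal(f"noncD{i}", p_respond_diastole=0.30))
    rng.shuffle(summaries)
    return summaries
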