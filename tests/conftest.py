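import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rehabcea as r

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def paper_model():
    """The published CH/DT arms and sensitivity ranges."""
    return r.paper_fixture()


def make_toy_instance(
    survival: float = 0.9,
    utility: float = 1.0,
    monthly_cost_annual: float = 0.0,
    discount_rate: float = 0.0,
    cycles: int = 12,
) -> r.ModelInstance:
    """A two-state toy embedded in the five-state structure: everyone starts
    in NYHA I, survives each month with probability ``survival``, and moves to
    death otherwise. Closed forms are geometric series."""
    P = np.zeros((5, 5))
    P[0, 0] = survival
    P[0, 4] = 1.0 - survival
    for i in (1, 2, 3):
        P[i, i] = 1.0
    P[4, 4] = 1.0
    return r.ModelInstance(
        arm="TOY",
        matrix=r.TransitionMatrix(P),
        hospitalization=r.HospitalizationProfile(np.zeros(4)),
        costs=r.CostProfile(
            np.zeros(4), np.full(4, monthly_cost_annual), np.zeros(4), 0.0
        ),
        utilities=r.UtilityProfile(np.full(4, utility), np.full(4, 1e-4)),
        cohort=r.CohortSpec(np.array([1.0, 0, 0, 0, 0])),
        settings=r.EconomicSettings(
            annual_discount_rate=discount_rate,
            cycles=cycles,
            cycles_per_year=12,
            horizon_years=cycles / 12,
        ),
    )


def naive_strategy_outcomes(instance: r.ModelInstance) -> tuple[float, float]:
    """Deliberately independent accrual implementation (plain loops, no shared
    helpers): per-capita total discounted cost and QALYs."""
    P = r.normalize_rows(instance.matrix, instance.settings.normalization).probs
    st = instance.settings
    occ = list(instance.cohort.initial_counts)
    n = sum(occ)
    total_cost = 0.0
    total_qaly = 0.0
    for t in range(1, st.cycles + 1):
        nxt = [sum(occ[i] * P[i][j] for i in range(5)) for j in range(5)]
        if st.half_cycle:
            w = [(a + b) / 2 for a, b in zip(occ, nxt)]
        else:
            w = occ
        d = (1.0 + st.annual_discount_rate) ** (-(t - 1) / st.cycles_per_year)
        for s in range(4):
            monthly = (
                instance.costs.direct_nonmedical_annual[s]
                + instance.costs.indirect_annual[s]
                + instance.costs.dtx_annual
            ) / 12.0
            monthly += (
                instance.hospitalization.monthly_prob[s]
                * instance.costs.direct_medical_per_admission[s]
            )
            total_cost += d * w[s] * monthly
            total_qaly += d * w[s] * instance.utilities.mean[s] / 12.0
        occ = nxt
    return total_cost / n, total_qaly / n
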