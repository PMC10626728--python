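"""Shared helpers for the analysis drivers."""

import numpy as np

import rehabcea as r


def make_two_state_toy(survival: float = 0.9, cycles: int = 12) -> r.ModelInstance:
    """Everyone starts in NYHA I with utility 1 and survives each month with
    probability ``survival``; life-years follow a geometric series."""
    P = np.zeros((5, 5))
    P[0, 0] = survival
    P[0, 4] = 1.0 - survival
    for i in (1, 2, 3, 4):
        P[i, i] = 1.0
    return r.ModelInstance(
        arm="TOY",
        matrix=r.TransitionMatrix(P),
        hospitalization=r.HospitalizationProfile(np.zeros(4)),
        costs=r.CostProfile(np.zeros(4), np.zeros(4), np.zeros(4), 0.0),
        utilities=r.UtilityProfile(np.ones(4), np.full(4, 1e-4)),
        cohort=r.CohortSpec(np.array([1.0, 0, 0, 0, 0])),
        settings=r.EconomicSettings(
            annual_discount_rate=0.0, cycles=cycles, cycles_per_year=12,
            horizon_years=cycles / 12,
        ),
    )
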