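"""Closed-cohort Markov simulation with discounted cost and QALY accrual.

The cohort is propagated through monthly cycles by left-multiplication with
the transition matrix. Each cycle accrues, per alive state,

* cost: ``(direct_nonmedical_annual + indirect_annual + dtx_annual) / 12
  + monthly_hospitalization_prob * direct_medical_per_admission``
* QALYs: ``utility_mean / 12``

weighted by the occupancy at the start of the cycle (or the start/end mean
when half-cycle correction is switched on) and by a discount factor of
``(1 + r) ** (-(t - 1) / cycles_per_year)`` — the first cycle is undiscounted.
Death accrues nothing. Results are reported per capita (divided by the
initial cohort size) and annualized either per horizon year or per
discounted life-year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    ALIVE_STATES,
    N_ALIVE,
    N_STATES,
    CohortSpec,
    CostProfile,
    EconomicSettings,
    HealthState,
    HospitalizationProfile,
    ModelInstance,
    TransitionMatrix,
    UtilityProfile,
    normalize_rows,
)

__all__ = [
    "CohortTrace",
    "StrategyResult",
    "run_cohort",
    "discount_factor",
    "discount_factors",
    "accrue_cycle_cost",
    "accrue_cycle_qaly",
    "monthly_state_cost",
    "evaluate_strategy",
    "accrual_weights",
    "discounted_state_time",
]


@dataclass(eq=False)
class CohortTrace:
    """Per-cycle occupancy of each health state; row 0 is the initial
    distribution, row ``t`` the occupancy after ``t`` cycles."""

    occupancy: np.ndarray  # (cycles + 1, N_STATES)

    @property
    def cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def cohort_size(self) -> float:
        return float(self.occupancy[0].sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.occupancy, columns=[s.name for s in HealthState]
        ).rename_axis("cycle").reset_index()


@dataclass(eq=False)
class StrategyResult:
    """Per-capita discounted outcomes of one arm.

    ``cycle_costs`` / ``cycle_qalys`` are the per-capita discounted accruals
    of each cycle (length ``cycles``); the totals are their sums.
    ``life_years`` is the per-capita discounted time alive, in years.
    """

    arm: str
    total_discounted_cost: float
    total_discounted_qaly: float
    cycle_costs: np.ndarray
    cycle_qalys: np.ndarray
    life_years: float
    annualized_cost: float
    annualized_qaly: float
    settings: EconomicSettings

    def to_frame(self):
        import pandas as pd

        t = np.arange(1, len(self.cycle_costs) + 1)
        return pd.DataFrame(
            {
                "cycle": t,
                "discount_factor": discount_factors(
                    len(t), self.settings.annual_discount_rate, self.settings.cycles_per_year
                ),
                "cycle_cost": self.cycle_costs,
                "cycle_qaly": self.cycle_qalys,
            }
        )


def run_cohort(
    matrix: TransitionMatrix,
    initial: CohortSpec,
    cycles: int,
    row_sum_tolerance: float = 1e-9,
) -> CohortTrace:
    """Propagate the cohort: ``occupancy[t + 1] = occupancy[t] @ P``.

    The matrix must be row-stochastic within ``row_sum_tolerance`` (apply
    :func:`~rehabcea.parameters.normalize_rows` first if it is not).
    """
    if cycles < 1:
        raise ValueError(f"cycles must be >= 1, got {cycles}")
    if not matrix.is_row_stochastic(row_sum_tolerance):
        raise ValueError(
            "transition matrix is not row-stochastic within tolerance "
            f"{row_sum_tolerance:g} (row sums {matrix.row_sums().tolist()})"
        )
    occ = np.empty((cycles + 1, N_STATES))
    occ[0] = initial.initial_counts
    P = matrix.probs
    for t in range(cycles):
        occ[t + 1] = occ[t] @ P
    return CohortTrace(occ)


def discount_factor(cycle_index: int, annual_rate: float, cycles_per_year: int = 12) -> float:
    """Discount factor for one cycle: ``(1 + r) ** (-(t - 1) / cpy)``.

    Cycle 1 is undiscounted; a full year of cycles later the factor is
    ``1 / (1 + r)``.
    """
    if np.any(np.asarray(cycle_index) < 1):
        raise ValueError("cycle_index must be >= 1 (cycle 1 is the first accrual cycle)")
    if annual_rate < 0:
        raise ValueError(f"annual_rate must be >= 0, got {annual_rate}")
    return float((1.0 + annual_rate) ** (-(cycle_index - 1) / cycles_per_year))


def discount_factors(cycles: int, annual_rate: float, cycles_per_year: int = 12) -> np.ndarray:
    """Vector of discount factors for cycles ``1..cycles``."""
    if annual_rate < 0:
        raise ValueError(f"annual_rate must be >= 0, got {annual_rate}")
    t = np.arange(1, cycles + 1)
    return (1.0 + annual_rate) ** (-(t - 1) / cycles_per_year)


def monthly_state_cost(costs: CostProfile, hosp: HospitalizationProfile) -> np.ndarray:
    """Expected cost of one person-month in each alive state: prorated annual
    costs plus hospitalization probability times per-admission cost.

    This single accrual definition is shared by the cohort engine, the PSA and
    the microsimulation oracle (the oracle replaces the expectation with
    per-patient Bernoulli admission events).
    """
    fixed = (
        costs.direct_nonmedical_annual + costs.indirect_annual + costs.dtx_annual
    ) / 12.0
    return fixed + hosp.monthly_prob * costs.direct_medical_per_admission


def accrue_cycle_cost(
    occupancy: np.ndarray, costs: CostProfile, hosp: HospitalizationProfile
) -> float:
    """Undiscounted cost of one cycle given a per-state occupancy vector."""
    occ = np.asarray(occupancy, dtype=float)
    if occ.shape != (N_STATES,):
        raise ValueError(f"occupancy must have {N_STATES} entries")
    if np.any(occ < 0):
        raise ValueError(f"negative occupancy: {occ.tolist()}")
    return float(occ[:N_ALIVE] @ monthly_state_cost(costs, hosp))


def accrue_cycle_qaly(occupancy: np.ndarray, utilities: UtilityProfile) -> float:
    """Undiscounted QALYs of one cycle (one month of quality-adjusted time)."""
    occ = np.asarray(occupancy, dtype=float)
    if occ.shape != (N_STATES,):
        raise ValueError(f"occupancy must have {N_STATES} entries")
    if np.any(occ < 0):
        raise ValueError(f"negative occupancy: {occ.tolist()}")
    if np.any(utilities.mean < 0) or np.any(utilities.mean > 1):
        raise ValueError(f"utility outside [0, 1]: {utilities.mean.tolist()}")
    return float(occ[:N_ALIVE] @ (utilities.mean / 12.0))


def accrual_weights(trace: CohortTrace, half_cycle: bool = False) -> np.ndarray:
    """Occupancy used for accrual in cycles ``1..cycles``: start-of-cycle by
    default, start/end mean under half-cycle correction."""
    occ = trace.occupancy
    if half_cycle:
        return 0.5 * (occ[:-1] + occ[1:])
    return occ[:-1]


def discounted_state_time(trace: CohortTrace, settings: EconomicSettings) -> np.ndarray:
    """Per-capita discounted person-cycles spent in each state under the
    trace's accrual convention. Costs and QALYs are linear in the parameters
    given these weights, which the PSA exploits."""
    w = accrual_weights(trace, settings.half_cycle)
    d = discount_factors(trace.cycles, settings.annual_discount_rate, settings.cycles_per_year)
    return (d[:, None] * w).sum(axis=0) / trace.cohort_size


def evaluate_strategy(instance: ModelInstance, trace: CohortTrace | None = None) -> StrategyResult:
    """Run one arm end to end and return per-capita discounted outcomes.

    The transition matrix is repaired according to
    ``instance.settings.normalization`` before simulation; with mode ``none``
    the matrix is used verbatim (row-sum tolerance relaxed to 5e-3, which the
    published DT matrix needs).
    """
    st = instance.settings
    if trace is None:
        P = normalize_rows(instance.matrix, st.normalization)
        tol = 1e-9 if st.normalization != "none" else 5e-3
        trace = run_cohort(P, instance.cohort, st.cycles, row_sum_tolerance=tol)

    n = trace.cohort_size
    if n <= 0:
        raise ValueError("cohort size must be positive")
    w = accrual_weights(trace, st.half_cycle)
    d = discount_factors(trace.cycles, st.annual_discount_rate, st.cycles_per_year)
    mc = monthly_state_cost(instance.costs, instance.hospitalization)
    mq = instance.utilities.mean / 12.0

    alive = w[:, :N_ALIVE]
    cycle_costs = d * (alive @ mc) / n
    cycle_qalys = d * (alive @ mq) / n
    life_years = float((d * alive.sum(axis=1)).sum() / n / st.cycles_per_year)
    total_cost = float(cycle_costs.sum())
    total_qaly = float(cycle_qalys.sum())

    if st.annualization_mode == "per_horizon_year":
        denom = st.horizon_years
    elif st.annualization_mode == "per_life_year":
        denom = life_years
    else:
        raise ValueError(f"unknown annualization_mode {st.annualization_mode!r}")
    return StrategyResult(
        arm=instance.arm,
        total_discounted_cost=total_cost,
        total_discounted_qaly=total_qaly,
        cycle_costs=cycle_costs,
        cycle_qalys=cycle_qalys,
        life_years=life_years,
        annualized_cost=total_cost / denom,
        annualized_qaly=total_qaly / denom,
        settings=st,
    )
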