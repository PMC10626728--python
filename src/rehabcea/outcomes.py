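"""Incremental cost-effectiveness comparison of two strategy arms.

The headline statistic is the incremental cost-effectiveness ratio
ICER = (C_DT - C_CH) / (Q_DT - Q_CH); the decision rule against a
willingness-to-pay threshold lambda is the incremental net monetary benefit
NMB = lambda * dQ - dC, which remains well defined when dQ <= 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .engine import StrategyResult

__all__ = [
    "Dominance",
    "CEAResult",
    "NMBResult",
    "compare_strategies",
    "net_monetary_benefit",
    "summary_table",
]


class Dominance:
    """Labels for the sign pattern of (dCost, dQALY)."""

    INTERVENTION_DOMINATES = "intervention_dominates"  # cheaper and more effective
    COMPARATOR_DOMINATES = "comparator_dominates"  # dearer and less effective
    TRADEOFF = "tradeoff"
    EQUIVALENT = "equivalent"


@dataclass(frozen=True)
class CEAResult:
    """Paired comparison of the DT (intervention) arm against CH (comparator).

    ``icer`` is NaN when ``delta_qaly`` is zero; for dominance cases it is
    stored but flagged — reports must print the dominance label, not a bare
    negative ratio.
    """

    cost_ch: float
    cost_dt: float
    qaly_ch: float
    qaly_dt: float
    delta_cost: float
    delta_qaly: float
    icer: float
    dominance: str
    basis: str = "annualized"

    @property
    def icer_defined(self) -> bool:
        return self.delta_qaly != 0.0


@dataclass(frozen=True)
class NMBResult:
    wtp: float
    nmb_ch: float
    nmb_dt: float
    incremental_nmb: float
    cost_effective: bool


def compare_strategies(
    ch: StrategyResult, dt: StrategyResult, basis: str = "annualized"
) -> CEAResult:
    """Incremental comparison of two arms computed under identical settings.

    ``basis`` selects annualized per-capita values (the default, matching how
    such results are reported per year) or total discounted values; the ICER
    is identical for both when annualization is per horizon year, since
    numerator and denominator scale by the same factor.
    """
    if ch.settings != dt.settings:
        raise ValueError("strategies were evaluated under different economic settings")
    if basis == "annualized":
        cost_ch, qaly_ch = ch.annualized_cost, ch.annualized_qaly
        cost_dt, qaly_dt = dt.annualized_cost, dt.annualized_qaly
    elif basis == "total":
        cost_ch, qaly_ch = ch.total_discounted_cost, ch.total_discounted_qaly
        cost_dt, qaly_dt = dt.total_discounted_cost, dt.total_discounted_qaly
    else:
        raise ValueError(f"unknown basis {basis!r}")

    delta_cost = cost_dt - cost_ch
    delta_qaly = qaly_dt - qaly_ch
    icer = delta_cost / delta_qaly if delta_qaly != 0.0 else math.nan

    if delta_cost == 0.0 and delta_qaly == 0.0:
        dominance = Dominance.EQUIVALENT
    elif delta_cost < 0.0 and delta_qaly > 0.0:
        dominance = Dominance.INTERVENTION_DOMINATES
    elif delta_cost > 0.0 and delta_qaly < 0.0:
        dominance = Dominance.COMPARATOR_DOMINATES
    else:
        dominance = Dominance.TRADEOFF
    return CEAResult(
        cost_ch=cost_ch,
        cost_dt=cost_dt,
        qaly_ch=qaly_ch,
        qaly_dt=qaly_dt,
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icer=icer,
        dominance=dominance,
        basis=basis,
    )


def net_monetary_benefit(result: CEAResult, wtp: float) -> NMBResult:
    """Net monetary benefit at willingness-to-pay ``wtp`` (CNY/QALY)."""
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp}")
    inc = wtp * result.delta_qaly - result.delta_cost
    return NMBResult(
        wtp=wtp,
        nmb_ch=wtp * result.qaly_ch - result.cost_ch,
        nmb_dt=wtp * result.qaly_dt - result.cost_dt,
        incremental_nmb=inc,
        cost_effective=inc > 0.0,
    )


def summary_table(result: CEAResult):
    """Two-row summary frame with the conventional CEA columns: cost,
    incremental cost, QALYs, incremental QALY, ICER."""
    import pandas as pd

    icer = "" if not result.icer_defined else result.icer
    if result.dominance in (Dominance.INTERVENTION_DOMINATES, Dominance.COMPARATOR_DOMINATES):
        icer = result.dominance
    return pd.DataFrame(
        [
            {
                "group": "CH",
                "cost": result.cost_ch,
                "incremental_cost": "",
                "qalys": result.qaly_ch,
                "incremental_qaly": "",
                "icer": "",
            },
            {
                "group": "DT",
                "cost": result.cost_dt,
                "incremental_cost": result.delta_cost,
                "qalys": result.qaly_dt,
                "incremental_qaly": result.delta_qaly,
                "icer": icer,
            },
        ]
    )
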