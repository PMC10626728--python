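"""Model parameters: domain types, validation, serialization, and the built-in
published parameter set.

The model compares two home-based cardiac-rehabilitation strategies for chronic
heart failure — conventional management (``CH``) and management augmented with a
digital-therapeutics app (``DT``) — on a five-state Markov structure: NYHA
functional classes I–IV plus an absorbing death state. Cycles are monthly.

Every number in :func:`paper_fixture` is a published input: the baseline NYHA
distribution of a 2,315-patient hospital cohort, per-state costs in CNY,
monthly transition matrices and hospitalization probabilities for both arms,
hospitalization risk ratios (DT vs CH), health-state utilities with variances,
and the sensitivity ranges with their distribution families.

A note on the two annual cost categories: the source tables disagree on which
of the two non-hospitalization cost columns is "direct non-medical" and which
is "indirect". Field labels here follow the cost table's header order
(direct non-medical = 1012.25 … 5333 CNY/year); the sensitivity ranges are
attached to base values by midpoint, which is unambiguous — each published
range brackets exactly one published base value.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "HealthState",
    "N_STATES",
    "ALIVE_STATES",
    "TransitionMatrix",
    "HospitalizationProfile",
    "CostProfile",
    "UtilityProfile",
    "EconomicSettings",
    "CohortSpec",
    "ModelInstance",
    "ParameterRange",
    "ValidationReport",
    "ConfigError",
    "paper_fixture",
    "validate_model",
    "normalize_rows",
    "load_model_config",
    "save_model_config",
    "export_tables",
]


class HealthState(IntEnum):
    """NYHA functional classes I (mildest) to IV (most severe), plus death."""

    NYHA_I = 0
    NYHA_II = 1
    NYHA_III = 2
    NYHA_IV = 3
    DEATH = 4


N_STATES = 5
ALIVE_STATES = tuple(s for s in HealthState if s is not HealthState.DEATH)
N_ALIVE = len(ALIVE_STATES)

NORMALIZATION_MODES = ("adjust_diagonal", "proportional", "none")
ANNUALIZATION_MODES = ("per_horizon_year", "per_life_year")
DISTRIBUTION_FAMILIES = ("gamma", "beta", "lognormal")


def _as_array(values, n, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"{name}: expected {n} values, got shape {arr.shape}")
    return arr


@dataclass(eq=False)
class TransitionMatrix:
    """Row-stochastic 5x5 matrix of monthly transition probabilities.

    Row/column order follows :class:`HealthState`; the death row must be
    absorbing, i.e. ``(0, 0, 0, 0, 1)``.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.probs, dtype=float)
        if arr.shape != (N_STATES, N_STATES):
            raise ValueError(f"transition matrix must be {N_STATES}x{N_STATES}, got {arr.shape}")
        self.probs = arr

    def row_sums(self) -> np.ndarray:
        return self.probs.sum(axis=1)

    def is_row_stochastic(self, tolerance: float = 1e-9) -> bool:
        return bool(
            np.all(self.probs >= 0)
            and np.all(self.probs <= 1)
            and np.all(np.abs(self.row_sums() - 1.0) <= tolerance)
        )

    def __eq__(self, other) -> bool:  # value equality for config round-trips
        return isinstance(other, TransitionMatrix) and np.array_equal(self.probs, other.probs)


@dataclass(eq=False)
class HospitalizationProfile:
    """Monthly hospitalization probability per alive state, and the DT-vs-CH
    risk ratio used wherever DT probabilities must be regenerated from CH ones
    (one-way sensitivity, PSA)."""

    monthly_prob: np.ndarray
    risk_ratio: np.ndarray = field(default_factory=lambda: np.ones(N_ALIVE))

    def __post_init__(self) -> None:
        self.monthly_prob = _as_array(self.monthly_prob, N_ALIVE, "monthly_prob")
        self.risk_ratio = _as_array(self.risk_ratio, N_ALIVE, "risk_ratio")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, HospitalizationProfile)
            and np.array_equal(self.monthly_prob, other.monthly_prob)
            and np.array_equal(self.risk_ratio, other.risk_ratio)
        )


@dataclass(eq=False)
class CostProfile:
    """Per-state costs in CNY.

    ``direct_medical_per_admission`` is a per-hospitalization cost; the two
    annual categories accrue monthly at 1/12 of their value; ``dtx_annual`` is
    the yearly digital-therapeutics fee (0 for the comparator arm).
    """

    direct_medical_per_admission: np.ndarray
    direct_nonmedical_annual: np.ndarray
    indirect_annual: np.ndarray
    dtx_annual: float = 0.0

    def __post_init__(self) -> None:
        self.direct_medical_per_admission = _as_array(
            self.direct_medical_per_admission, N_ALIVE, "direct_medical_per_admission"
        )
        self.direct_nonmedical_annual = _as_array(
            self.direct_nonmedical_annual, N_ALIVE, "direct_nonmedical_annual"
        )
        self.indirect_annual = _as_array(self.indirect_annual, N_ALIVE, "indirect_annual")
        self.dtx_annual = float(self.dtx_annual)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CostProfile)
            and np.array_equal(self.direct_medical_per_admission, other.direct_medical_per_admission)
            and np.array_equal(self.direct_nonmedical_annual, other.direct_nonmedical_annual)
            and np.array_equal(self.indirect_annual, other.indirect_annual)
            and self.dtx_annual == other.dtx_annual
        )


@dataclass(eq=False)
class UtilityProfile:
    """Health-state utilities (QALY weights in [0, 1]) per alive state with
    their variances; death has utility 0 by construction."""

    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = _as_array(self.mean, N_ALIVE, "utility mean")
        self.variance = _as_array(self.variance, N_ALIVE, "utility variance")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, UtilityProfile)
            and np.array_equal(self.mean, other.mean)
            and np.array_equal(self.variance, other.variance)
        )


@dataclass(frozen=True)
class EconomicSettings:
    """Time horizon, discounting and accounting conventions.

    annual_discount_rate
        Fractional yearly discount rate (0.03 = 3%/year), compounded per cycle
        as ``(1 + r) ** (-(t - 1) / cycles_per_year)`` with the first cycle
        undiscounted.
    annualization_mode
        ``per_horizon_year`` divides discounted totals by ``horizon_years``;
        ``per_life_year`` divides by discounted life-years lived.
    half_cycle
        When True, accrual weights each cycle by the mean of start- and
        end-of-cycle occupancy instead of start-of-cycle occupancy.
    normalization
        How rows of a transition matrix that do not sum to one are repaired
        before simulation (see :func:`normalize_rows`).
    """

    annual_discount_rate: float = 0.03
    cycles: int = 120
    cycles_per_year: int = 12
    horizon_years: float = 10.0
    wtp: float = 85_698.0
    annualization_mode: str = "per_horizon_year"
    half_cycle: bool = False
    normalization: str = "adjust_diagonal"


@dataclass(eq=False)
class CohortSpec:
    """Closed-cohort initial occupancy (persons per state at cycle 0)."""

    initial_counts: np.ndarray

    def __post_init__(self) -> None:
        self.initial_counts = _as_array(self.initial_counts, N_STATES, "initial_counts")

    @property
    def size(self) -> float:
        return float(self.initial_counts.sum())

    def __eq__(self, other) -> bool:
        return isinstance(other, CohortSpec) and np.array_equal(
            self.initial_counts, other.initial_counts
        )


@dataclass(eq=False)
class ModelInstance:
    """One strategy arm's complete parameter set."""

    arm: str
    matrix: TransitionMatrix
    hospitalization: HospitalizationProfile
    costs: CostProfile
    utilities: UtilityProfile
    cohort: CohortSpec
    settings: EconomicSettings

    def __eq__(self, other) -> bool:
        return isinstance(other, ModelInstance) and all(
            getattr(self, f.name) == getattr(other, f.name) for f in dataclasses.fields(self)
        )

    def replace(self, **changes) -> "ModelInstance":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ParameterRange:
    """One sensitivity-analysis range: a parameter group (optionally one
    state's entry of it), its low/high bounds and distribution family."""

    group: str
    state: HealthState | None
    low: float
    high: float
    family: str

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.group}: low ({self.low}) must be < high ({self.high})")
        if self.family not in DISTRIBUTION_FAMILIES:
            raise ValueError(f"{self.group}: unknown distribution family {self.family!r}")


@dataclass
class ValidationReport:
    """Accumulated invariant violations; empty means valid."""

    violations: list[str] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.violations

    def add(self, message: str) -> None:
        self.violations.append(message)

    def __str__(self) -> str:
        if self.is_valid:
            return "valid: no violations"
        return "\n".join(self.violations)


class ConfigError(ValueError):
    """Raised when a model configuration cannot be parsed or violates hard
    constraints (missing fields, negative costs, out-of-range utilities)."""


# ---------------------------------------------------------------------------
# Published parameter set
# ---------------------------------------------------------------------------

#: Baseline NYHA I-IV / death counts of the source cohort (n = 2315).
INITIAL_COUNTS = (1795.0, 172.0, 280.0, 68.0, 0.0)

_CH_MATRIX = (
    (0.981, 0.004, 0.0, 0.0, 0.015),
    (0.068, 0.872, 0.017, 0.0, 0.043),
    (0.004, 0.094, 0.777, 0.041, 0.084),
    (0.0, 0.006, 0.095, 0.777, 0.122),
    (0.0, 0.0, 0.0, 0.0, 1.0),
)
# As published the NYHA II/III/IV rows sum to 0.999/1.001/0.999; they are kept
# verbatim here and repaired by normalize_rows() at simulation time.
_DT_MATRIX = (
    (0.986, 0.003, 0.0, 0.0, 0.011),
    (0.068, 0.885, 0.013, 0.0, 0.033),
    (0.004, 0.096, 0.804, 0.032, 0.065),
    (0.0, 0.006, 0.098, 0.801, 0.094),
    (0.0, 0.0, 0.0, 0.0, 1.0),
)

_CH_HOSP = (0.004, 0.020, 0.053, 0.085)
_DT_HOSP = (0.003, 0.015, 0.040, 0.064)
_RISK_RATIO = (0.75, 0.75, 0.7547, 0.7529)

_DIRECT_MEDICAL = (35_587.73, 39_014.21, 53_577.65, 59_547.03)
_DIRECT_NONMEDICAL = (1012.25, 2032.93, 2040.54, 5333.0)
_INDIRECT = (45_720.0, 21_342.13, 31_370.21, 23_085.54)
_DTX_ANNUAL = 180.0

_UTILITY_MEAN = (0.87976, 0.71178, 0.61405, 0.49228)
_UTILITY_VAR = (0.00827, 0.00944, 0.01349, 0.03032)

# Sensitivity ranges. Cost ranges are paired to base values by midpoint (each
# published range brackets exactly one base value); utility and risk-ratio
# rows are single global envelopes.
_DIRECT_MEDICAL_RANGES = (
    (6942.58, 42_705.28),
    (26_095.71, 46_817.06),
    (42_862.12, 64_293.19),
    (42_488.95, 71_456.43),
)
_DIRECT_NONMEDICAL_RANGES = (
    (809.8, 1214.7),
    (1626.34, 2439.52),
    (1632.43, 2448.65),
    (4266.4, 6399.6),
)
_INDIRECT_RANGES = (
    (36_576.0, 54_864.0),
    (17_073.7, 25_610.56),
    (25_096.17, 37_644.25),
    (18_468.43, 27_702.65),
)
_DTX_RANGE = (144.0, 216.0)
_UTILITY_RANGE = (0.66, 0.96)
_RISK_RATIO_RANGE = (0.36, 0.85)


def paper_fixture(
    settings: EconomicSettings | None = None,
) -> tuple[ModelInstance, ModelInstance, list[ParameterRange]]:
    """Return the published CH and DT arms and the sensitivity-range table.

    Both arms share the cohort and economic settings. Values are stored
    exactly as printed, including the DT transition rows whose sums are
    0.999/1.001/0.999 (handled by :func:`normalize_rows` downstream).
    """
    settings = settings or EconomicSettings()
    cohort = CohortSpec(np.array(INITIAL_COUNTS))
    utilities = UtilityProfile(np.array(_UTILITY_MEAN), np.array(_UTILITY_VAR))

    ch = ModelInstance(
        arm="CH",
        matrix=TransitionMatrix(np.array(_CH_MATRIX)),
        hospitalization=HospitalizationProfile(np.array(_CH_HOSP)),
        costs=CostProfile(
            np.array(_DIRECT_MEDICAL),
            np.array(_DIRECT_NONMEDICAL),
            np.array(_INDIRECT),
            dtx_annual=0.0,
        ),
        utilities=utilities,
        cohort=cohort,
        settings=settings,
    )
    dt = ModelInstance(
        arm="DT",
        matrix=TransitionMatrix(np.array(_DT_MATRIX)),
        hospitalization=HospitalizationProfile(np.array(_DT_HOSP), np.array(_RISK_RATIO)),
        costs=CostProfile(
            np.array(_DIRECT_MEDICAL),
            np.array(_DIRECT_NONMEDICAL),
            np.array(_INDIRECT),
            dtx_annual=_DTX_ANNUAL,
        ),
        utilities=UtilityProfile(np.array(_UTILITY_MEAN), np.array(_UTILITY_VAR)),
        cohort=CohortSpec(np.array(INITIAL_COUNTS)),
        settings=settings,
    )

    ranges: list[ParameterRange] = []
    for state, (lo, hi) in zip(ALIVE_STATES, _DIRECT_MEDICAL_RANGES):
        ranges.append(ParameterRange("direct_medical", state, lo, hi, "gamma"))
    for state, (lo, hi) in zip(ALIVE_STATES, _DIRECT_NONMEDICAL_RANGES):
        ranges.append(ParameterRange("direct_nonmedical", state, lo, hi, "gamma"))
    for state, (lo, hi) in zip(ALIVE_STATES, _INDIRECT_RANGES):
        ranges.append(ParameterRange("indirect", state, lo, hi, "gamma"))
    ranges.append(ParameterRange("dtx_cost", None, *_DTX_RANGE, "gamma"))
    ranges.append(ParameterRange("utility", None, *_UTILITY_RANGE, "beta"))
    ranges.append(ParameterRange("hospitalization_rr", None, *_RISK_RATIO_RANGE, "lognormal"))
    return ch, dt, ranges


# ---------------------------------------------------------------------------
# Validation and matrix repair
# ---------------------------------------------------------------------------

def validate_model(instance: ModelInstance, row_sum_tolerance: float = 1e-9) -> ValidationReport:
    """Check every structural invariant; report violations instead of raising.

    Checks row-stochasticity of the transition matrix (within
    ``row_sum_tolerance``), the absorbing death row, probability bounds,
    cost signs, utility bounds and variances, cohort non-negativity, and the
    economic-settings invariants.
    """
    report = ValidationReport()
    P = instance.matrix.probs

    if np.any(P < 0) or np.any(P > 1):
        bad = np.argwhere((P < 0) | (P > 1))
        for i, j in bad:
            report.add(
                f"transition_matrix[{HealthState(i).name},{HealthState(j).name}] = "
                f"{P[i, j]} outside [0, 1]"
            )
    for i, s in enumerate(P.sum(axis=1)):
        if abs(s - 1.0) > row_sum_tolerance:
            report.add(
                f"transition_matrix row {HealthState(i).name} sums to {s:.6f} "
                f"(deviation {s - 1.0:+.3e} exceeds tolerance {row_sum_tolerance:g})"
            )
    death = P[HealthState.DEATH]
    expected = np.zeros(N_STATES)
    expected[HealthState.DEATH] = 1.0
    if not np.array_equal(death, expected):
        report.add(f"death row is not absorbing: {death.tolist()}")

    h = instance.hospitalization
    if np.any(h.monthly_prob < 0) or np.any(h.monthly_prob > 1):
        report.add(f"hospitalization monthly_prob outside [0, 1]: {h.monthly_prob.tolist()}")
    if np.any(h.risk_ratio <= 0):
        report.add(f"hospitalization risk_ratio not positive: {h.risk_ratio.tolist()}")

    c = instance.costs
    for name in ("direct_medical_per_admission", "direct_nonmedical_annual", "indirect_annual"):
        arr = getattr(c, name)
        if np.any(arr < 0):
            report.add(f"costs.{name} has negative entries: {arr.tolist()}")
    if c.dtx_annual < 0:
        report.add(f"costs.dtx_annual is negative: {c.dtx_annual}")

    u = instance.utilities
    if np.any(u.mean < 0) or np.any(u.mean > 1):
        report.add(f"utility means outside [0, 1]: {u.mean.tolist()}")
    if np.any(u.variance <= 0):
        report.add(f"utility variances not positive: {u.variance.tolist()}")

    counts = instance.cohort.initial_counts
    if np.any(counts < 0):
        report.add(f"cohort initial_counts negative: {counts.tolist()}")
    if counts[HealthState.DEATH] != 0:
        report.add(f"cohort starts with {counts[HealthState.DEATH]} persons in DEATH")

    st = instance.settings
    if st.annual_discount_rate < 0:
        report.add(f"annual_discount_rate negative: {st.annual_discount_rate}")
    if st.cycles != st.cycles_per_year * st.horizon_years:
        report.add(
            f"cycles ({st.cycles}) != cycles_per_year ({st.cycles_per_year}) "
            f"x horizon_years ({st.horizon_years})"
        )
    if st.annualization_mode not in ANNUALIZATION_MODES:
        report.add(f"unknown annualization_mode {st.annualization_mode!r}")
    if st.normalization not in NORMALIZATION_MODES:
        report.add(f"unknown normalization mode {st.normalization!r}")
    return report


def normalize_rows(matrix: TransitionMatrix, mode: str = "adjust_diagonal") -> TransitionMatrix:
    """Repair rows that do not sum to one.

    ``proportional`` divides each row by its sum, preserving within-row
    ratios. ``adjust_diagonal`` moves the whole residual onto the
    stay-probability, preserving the off-diagonal transition and death
    probabilities as printed. ``none`` returns the matrix unchanged.
    Idempotent in all modes; a zero-sum row is malformed and raises.
    """
    if mode == "none":
        return TransitionMatrix(matrix.probs.copy())
    P = matrix.probs.copy()
    if np.any(P < 0):
        raise ValueError("normalize_rows requires non-negative entries")
    sums = P.sum(axis=1)
    if np.any(sums <= 0):
        raise ValueError(f"zero-sum transition row(s): {np.where(sums <= 0)[0].tolist()}")
    if mode == "proportional":
        P = P / sums[:, None]
    elif mode == "adjust_diagonal":
        P[np.diag_indices(N_STATES)] += 1.0 - sums
        if np.any(np.diag(P) < 0) or np.any(np.diag(P) > 1):
            raise ValueError("adjust_diagonal pushed a stay-probability outside [0, 1]")
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return TransitionMatrix(P)


# ---------------------------------------------------------------------------
# Config serialization
# ---------------------------------------------------------------------------

_SCHEMA_DOC = """Model config schema (YAML or JSON):

model:
  cohort: {initial_counts: [5 floats]}
  settings: {annual_discount_rate, cycles, cycles_per_year, horizon_years,
             wtp, annualization_mode, half_cycle, normalization}
arms:
  ch: &arm
    transition_matrix: [[5x5 floats]]
    hospitalization: {monthly_prob: [4], risk_ratio: [4]}
    costs: {direct_medical_per_admission: [4], direct_nonmedical_annual: [4],
            indirect_annual: [4], dtx_annual: float}
    utilities: {mean: [4], variance: [4]}
  dt: *arm
ranges:
  - {group, state (name or null), low, high, family}
"""


def _arm_to_dict(instance: ModelInstance) -> dict:
    return {
        "transition_matrix": instance.matrix.probs.tolist(),
        "hospitalization": {
            "monthly_prob": instance.hospitalization.monthly_prob.tolist(),
            "risk_ratio": instance.hospitalization.risk_ratio.tolist(),
        },
        "costs": {
            "direct_medical_per_admission": instance.costs.direct_medical_per_admission.tolist(),
            "direct_nonmedical_annual": instance.costs.direct_nonmedical_annual.tolist(),
            "indirect_annual": instance.costs.indirect_annual.tolist(),
            "dtx_annual": instance.costs.dtx_annual,
        },
        "utilities": {
            "mean": instance.utilities.mean.tolist(),
            "variance": instance.utilities.variance.tolist(),
        },
    }


def model_to_dict(
    ch: ModelInstance, dt: ModelInstance, ranges: Sequence[ParameterRange]
) -> dict:
    st = ch.settings
    return {
        "model": {
            "cohort": {"initial_counts": ch.cohort.initial_counts.tolist()},
            "settings": dataclasses.asdict(st),
        },
        "arms": {"ch": _arm_to_dict(ch), "dt": _arm_to_dict(dt)},
        "ranges": [
            {
                "group": r.group,
                "state": r.state.name if r.state is not None else None,
                "low": r.low,
                "high": r.high,
                "family": r.family,
            }
            for r in ranges
        ],
    }


def _require(mapping: dict, key: str, context: str):
    if not isinstance(mapping, dict) or key not in mapping:
        raise ConfigError(f"missing field {context}.{key}")
    return mapping[key]


def _arm_from_dict(arm_label: str, data: dict, cohort: CohortSpec, settings: EconomicSettings) -> ModelInstance:
    ctx = f"arms.{arm_label.lower()}"
    try:
        matrix = TransitionMatrix(np.array(_require(data, "transition_matrix", ctx), dtype=float))
        hosp_d = _require(data, "hospitalization", ctx)
        hosp = HospitalizationProfile(
            np.array(_require(hosp_d, "monthly_prob", ctx + ".hospitalization"), dtype=float),
            np.array(
                hosp_d.get("risk_ratio", np.ones(N_ALIVE).tolist()), dtype=float
            ),
        )
        cost_d = _require(data, "costs", ctx)
        costs = CostProfile(
            np.array(_require(cost_d, "direct_medical_per_admission", ctx + ".costs"), dtype=float),
            np.array(_require(cost_d, "direct_nonmedical_annual", ctx + ".costs"), dtype=float),
            np.array(_require(cost_d, "indirect_annual", ctx + ".costs"), dtype=float),
            float(cost_d.get("dtx_annual", 0.0)),
        )
        util_d = _require(data, "utilities", ctx)
        utilities = UtilityProfile(
            np.array(_require(util_d, "mean", ctx + ".utilities"), dtype=float),
            np.array(_require(util_d, "variance", ctx + ".utilities"), dtype=float),
        )
    except ValueError as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"{ctx}: {exc}") from exc
    return ModelInstance(arm_label, matrix, hosp, costs, utilities, cohort, settings)


def model_from_dict(data: dict) -> tuple[ModelInstance, ModelInstance, list[ParameterRange]]:
    model = _require(data, "model", "config")
    cohort = CohortSpec(np.array(_require(_require(model, "cohort", "model"), "initial_counts", "model.cohort"), dtype=float))
    settings_d = dict(_require(model, "settings", "model"))
    try:
        settings = EconomicSettings(**settings_d)
    except TypeError as exc:
        raise ConfigError(f"model.settings: {exc}") from exc
    arms = _require(data, "arms", "config")
    ch = _arm_from_dict("CH", _require(arms, "ch", "arms"), cohort, settings)
    dt = _arm_from_dict("DT", _require(arms, "dt", "arms"), cohort, settings)

    ranges = []
    for i, r in enumerate(data.get("ranges", [])):
        state_name = _require(r, "state", f"ranges[{i}]")
        state = HealthState[state_name] if state_name is not None else None
        try:
            ranges.append(
                ParameterRange(
                    _require(r, "group", f"ranges[{i}]"),
                    state,
                    float(_require(r, "low", f"ranges[{i}]")),
                    float(_require(r, "high", f"ranges[{i}]")),
                    _require(r, "family", f"ranges[{i}]"),
                )
            )
        except ValueError as exc:
            if isinstance(exc, ConfigError):
                raise
            raise ConfigError(f"ranges[{i}]: {exc}") from exc

    # Hard content constraints are surfaced at load time.
    for inst in (ch, dt):
        rep = validate_model(inst, row_sum_tolerance=5e-3)
        if not rep.is_valid:
            raise ConfigError(f"arm {inst.arm}: " + "; ".join(rep.violations))
    return ch, dt, ranges


def save_model_config(
    path: str | Path, ch: ModelInstance, dt: ModelInstance, ranges: Sequence[ParameterRange]
) -> None:
    """Write both arms and the sensitivity ranges to YAML (default) or JSON.

    Numeric fields round-trip bit-exactly through :func:`load_model_config`.
    """
    path = Path(path)
    data = model_to_dict(ch, dt, ranges)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_model_config(source: str | Path) -> tuple[ModelInstance, ModelInstance, list[ParameterRange]]:
    """Parse a model config file; raise :class:`ConfigError` naming the
    offending field on schema violations or invalid content."""
    path = Path(source)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return model_from_dict(data)


def export_tables(
    ch: ModelInstance, dt: ModelInstance, ranges: Sequence[ParameterRange], outdir: str | Path
) -> dict[str, Path]:
    """Write each parameter table (cohort, costs, transitions, hospitalization,
    utilities, ranges) as a CSV for inspection; returns the written paths."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state_names = [s.name for s in HealthState]
    alive_names = [s.name for s in ALIVE_STATES]
    written: dict[str, Path] = {}

    def _write(name: str, frame: "pd.DataFrame") -> None:
        p = outdir / f"{name}.csv"
        frame.to_csv(p, index=False)
        written[name] = p

    _write("cohort", pd.DataFrame({"state": state_names, "initial_count": ch.cohort.initial_counts}))
    rows = []
    for arm, inst in (("CH", ch), ("DT", dt)):
        for i, s in enumerate(state_names):
            rows.append({"arm": arm, "from_state": s, **dict(zip(state_names, inst.matrix.probs[i]))})
    _write("transitions", pd.DataFrame(rows))
    rows = []
    for arm, inst in (("CH", ch), ("DT", dt)):
        for i, s in enumerate(alive_names):
            rows.append(
                {
                    "arm": arm,
                    "state": s,
                    "monthly_hospitalization_prob": inst.hospitalization.monthly_prob[i],
                    "risk_ratio": inst.hospitalization.risk_ratio[i],
                    "direct_medical_per_admission": inst.costs.direct_medical_per_admission[i],
                    "direct_nonmedical_annual": inst.costs.direct_nonmedical_annual[i],
                    "indirect_annual": inst.costs.indirect_annual[i],
                    "dtx_annual": inst.costs.dtx_annual,
                }
            )
    _write("costs", pd.DataFrame(rows))
    _write(
        "utilities",
        pd.DataFrame(
            {"state": alive_names, "mean": ch.utilities.mean, "variance": ch.utilities.variance}
        ),
    )
    _write(
        "ranges",
        pd.DataFrame(
            [
                {
                    "group": r.group,
                    "state": r.state.name if r.state else None,
                    "low": r.low,
                    "high": r.high,
                    "family": r.family,
                }
                for r in ranges
            ]
        ),
    )
    return written
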