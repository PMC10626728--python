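"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) and two-way analyses re-evaluate both arms with a parameter
group pinned to the bounds of its published range. The probabilistic
sensitivity analysis (PSA) draws parameters from distributions fitted by
method of moments — gamma for costs, beta for utilities, lognormal for the
hospitalization risk ratio — re-evaluates both arms per draw, and summarizes
the (dCost, dQALY) cloud as a cost-effectiveness acceptability curve (CEAC).

Range semantics: a published (low, high) range is read as a central 95%
interval, SD = (high - low) / (2 * 1.96). Gamma fits match the base value as
mean, beta fits match mean and variance, lognormal fits match the base value
as median with sigma = ln(high/low) / (2 * 1.96).

Because transition matrices are not varied (no published uncertainty), the
cohort traces are fixed across draws and per-draw outcomes are exact linear
functionals of the sampled parameters; the PSA evaluates them through the
same discounted state-time weights the engine uses, so a collapsed draw
reproduces the base case identically.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .engine import discounted_state_time, evaluate_strategy, normalize_rows, run_cohort
from .outcomes import compare_strategies
from .parameters import (
    ALIVE_STATES,
    N_ALIVE,
    HospitalizationProfile,
    ModelInstance,
    ParameterRange,
)

__all__ = [
    "DistributionFit",
    "TornadoEntry",
    "CEPoint",
    "CEACPoint",
    "PSAFits",
    "PSAResult",
    "fit_gamma_from_mean_range",
    "fit_beta_from_mean_variance",
    "fit_lognormal_from_median_range",
    "build_psa_fits",
    "run_psa",
    "ceac",
    "ceac_frame",
    "default_wtp_grid",
    "apply_parameter_group",
    "one_way_sensitivity",
    "tornado",
    "two_way_sensitivity",
    "PARAMETER_GROUPS",
]

PARAMETER_GROUPS = (
    "direct_medical",
    "direct_nonmedical",
    "indirect",
    "dtx_cost",
    "hospitalization_rr",
    "utility",
)

_Z95 = 2.0 * 1.96  # full width of a central 95% normal interval, in SDs


@dataclass(frozen=True)
class DistributionFit:
    """A fitted parameter distribution.

    ``params`` holds the family's natural parameters (gamma: shape/scale;
    beta: a/b; lognormal: mu/sigma). ``support`` optionally restricts draws
    to an interval via rejection sampling. A degenerate range yields a
    ``near_deterministic`` fit whose draws are the point mass at the mean.
    """

    family: str
    params: dict
    source: dict = field(default_factory=dict)
    support: tuple[float, float] | None = None
    near_deterministic: bool = False

    def mean(self) -> float:
        if self.near_deterministic:
            return self.source["mean"]
        if self.family == "gamma":
            return self.params["shape"] * self.params["scale"]
        if self.family == "beta":
            a, b = self.params["a"], self.params["b"]
            return a / (a + b)
        if self.family == "lognormal":
            return math.exp(self.params["mu"] + 0.5 * self.params["sigma"] ** 2)
        raise ValueError(self.family)

    def variance(self) -> float:
        if self.near_deterministic:
            return 0.0
        if self.family == "gamma":
            return self.params["shape"] * self.params["scale"] ** 2
        if self.family == "beta":
            a, b = self.params["a"], self.params["b"]
            return a * b / ((a + b) ** 2 * (a + b + 1.0))
        if self.family == "lognormal":
            s2 = self.params["sigma"] ** 2
            return (math.exp(s2) - 1.0) * math.exp(2 * self.params["mu"] + s2)
        raise ValueError(self.family)

    def median(self) -> float:
        if self.family == "lognormal":
            return math.exp(self.params["mu"])
        return self.frozen().median()

    def frozen(self):
        """The equivalent frozen scipy.stats distribution."""
        from scipy import stats

        if self.family == "gamma":
            return stats.gamma(self.params["shape"], scale=self.params["scale"])
        if self.family == "beta":
            return stats.beta(self.params["a"], self.params["b"])
        if self.family == "lognormal":
            return stats.lognorm(self.params["sigma"], scale=math.exp(self.params["mu"]))
        raise ValueError(self.family)

    def _draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.near_deterministic:
            return np.full(size, self.source["mean"])
        if self.family == "gamma":
            return rng.gamma(self.params["shape"], self.params["scale"], size)
        if self.family == "beta":
            return rng.beta(self.params["a"], self.params["b"], size)
        if self.family == "lognormal":
            return rng.lognormal(self.params["mu"], self.params["sigma"], size)
        raise ValueError(self.family)

    def sample(self, rng: np.random.Generator, size: int, max_attempts: int = 100):
        """Draw ``size`` values; out-of-support draws are rejection-resampled
        (at most ``max_attempts`` rounds). Returns (draws, n_resampled)."""
        x = self._draw(rng, size)
        n_resampled = 0
        if self.support is not None:
            lo, hi = self.support
            bad = (x < lo) | (x > hi)
            attempts = 0
            while bad.any():
                attempts += 1
                if attempts > max_attempts:
                    raise RuntimeError(
                        f"{self.family} fit: support {self.support} rejection "
                        f"sampling failed after {max_attempts} rounds"
                    )
                n_resampled += int(bad.sum())
                x[bad] = self._draw(rng, int(bad.sum()))
                bad = (x < lo) | (x > hi)
        return x, n_resampled


def fit_gamma_from_mean_range(mean: float, low: float, high: float) -> DistributionFit:
    """Gamma fit matching ``mean`` with SD read from a 95% range.

    shape = mean^2 / SD^2, scale = SD^2 / mean. A collapsed range yields a
    near-deterministic point mass.
    """
    if mean <= 0:
        raise ValueError(f"gamma fit requires mean > 0, got {mean}")
    if high < low:
        raise ValueError(f"invalid range ({low}, {high})")
    sd = (high - low) / _Z95
    source = {"mean": mean, "low": low, "high": high, "sd": sd}
    if sd == 0.0:
        return DistributionFit("gamma", {"shape": math.inf, "scale": 0.0}, source, near_deterministic=True)
    shape = mean**2 / sd**2
    return DistributionFit("gamma", {"shape": shape, "scale": sd**2 / mean}, source)


def fit_beta_from_mean_variance(
    mean: float, variance: float, support: tuple[float, float] | None = None
) -> DistributionFit:
    """Beta fit matching mean and variance by method of moments:
    a = m * (m(1-m)/v - 1), b = (1-m) * (m(1-m)/v - 1)."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta fit requires 0 < mean < 1, got {mean}")
    if variance <= 0:
        raise ValueError(f"beta fit requires variance > 0, got {variance}")
    if variance >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible beta moments: variance {variance} >= mean(1-mean) = "
            f"{mean * (1.0 - mean):.6f}"
        )
    c = mean * (1.0 - mean) / variance - 1.0
    return DistributionFit(
        "beta",
        {"a": mean * c, "b": (1.0 - mean) * c},
        {"mean": mean, "variance": variance},
        support=support,
    )


def fit_lognormal_from_median_range(median: float, low: float, high: float) -> DistributionFit:
    """Lognormal fit with exact median and sigma = ln(high/low) / (2*1.96)."""
    if median <= 0 or low <= 0 or high <= 0:
        raise ValueError("lognormal fit requires positive median and bounds")
    if high <= low:
        raise ValueError(f"invalid range ({low}, {high})")
    sigma = math.log(high / low) / _Z95
    return DistributionFit(
        "lognormal",
        {"mu": math.log(median), "sigma": sigma},
        {"median": median, "low": low, "high": high},
    )


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CEPoint:
    delta_cost: float
    delta_qaly: float


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probability_cost_effective: float


@dataclass
class PSAFits:
    """The full set of fitted distributions used by one PSA run.

    ``utility_mode`` ``per_state`` draws each state's utility independently;
    ``global`` maps a single shared quantile through every state's beta
    (comonotone draws), for the reading where one draw moves all utilities.
    ``rr_mode`` analogously couples the per-state risk-ratio draws.
    """

    direct_medical: list[DistributionFit]
    direct_nonmedical: list[DistributionFit]
    indirect: list[DistributionFit]
    dtx_cost: DistributionFit
    utilities: list[DistributionFit]
    hospitalization_rr: list[DistributionFit]
    utility_mode: str = "per_state"
    rr_mode: str = "per_state"


def _range_map(ranges: list[ParameterRange], group: str) -> dict:
    out = {}
    for r in ranges:
        if r.group == group:
            out[r.state] = (r.low, r.high)
    if not out:
        raise ValueError(f"no ranges found for group {group!r}")
    return out


def build_psa_fits(
    ch: ModelInstance,
    dt: ModelInstance,
    ranges: list[ParameterRange],
    utility_envelope: bool = True,
    utility_mode: str = "per_state",
    rr_mode: str = "per_state",
) -> PSAFits:
    """Fit every PSA distribution from the base values and published ranges.

    Cost groups get per-state gamma fits (mean = base value, SD from the
    state's range). Utilities get per-state beta fits from their published
    mean/variance; when ``utility_envelope`` is on, draws for states whose
    mean lies inside the global utility range are truncated to it. The
    risk ratio gets per-state lognormal fits (median = base ratio, sigma from
    the global range); the DTx fee a gamma fit.
    """
    dm = _range_map(ranges, "direct_medical")
    nm = _range_map(ranges, "direct_nonmedical")
    ind = _range_map(ranges, "indirect")
    (u_lo, u_hi) = _range_map(ranges, "utility")[None]
    (r_lo, r_hi) = _range_map(ranges, "hospitalization_rr")[None]
    (x_lo, x_hi) = _range_map(ranges, "dtx_cost")[None]

    utilities = []
    for i, s in enumerate(ALIVE_STATES):
        mean = float(ch.utilities.mean[i])
        support = (u_lo, u_hi) if (utility_envelope and u_lo <= mean <= u_hi) else None
        utilities.append(fit_beta_from_mean_variance(mean, float(ch.utilities.variance[i]), support))
    return PSAFits(
        direct_medical=[
            fit_gamma_from_mean_range(float(ch.costs.direct_medical_per_admission[i]), *dm[s])
            for i, s in enumerate(ALIVE_STATES)
        ],
        direct_nonmedical=[
            fit_gamma_from_mean_range(float(ch.costs.direct_nonmedical_annual[i]), *nm[s])
            for i, s in enumerate(ALIVE_STATES)
        ],
        indirect=[
            fit_gamma_from_mean_range(float(ch.costs.indirect_annual[i]), *ind[s])
            for i, s in enumerate(ALIVE_STATES)
        ],
        dtx_cost=fit_gamma_from_mean_range(dt.costs.dtx_annual, x_lo, x_hi),
        utilities=utilities,
        hospitalization_rr=[
            fit_lognormal_from_median_range(float(dt.hospitalization.risk_ratio[i]), r_lo, r_hi)
            for i in range(N_ALIVE)
        ],
        utility_mode=utility_mode,
        rr_mode=rr_mode,
    )


@dataclass(eq=False)
class PSAResult:
    """Per-draw incremental outcomes of a Monte Carlo PSA (annualized,
    per capita, same accounting as the base case)."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    cost_ch: np.ndarray
    cost_dt: np.ndarray
    qaly_ch: np.ndarray
    qaly_dt: np.ndarray
    seed: int | None
    resample_counts: dict

    @property
    def n_iterations(self) -> int:
        return len(self.delta_cost)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.delta_cost, self.delta_qaly])

    def ce_points(self) -> list[CEPoint]:
        return [CEPoint(float(c), float(q)) for c, q in self.points]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "draw": np.arange(self.n_iterations),
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
                "cost_ch": self.cost_ch,
                "cost_dt": self.cost_dt,
                "qaly_ch": self.qaly_ch,
                "qaly_dt": self.qaly_dt,
            }
        )


def _sample_coupled(
    fits: list[DistributionFit],
    rng: np.random.Generator,
    n: int,
    mode: str,
    counts: dict,
    label: str,
) -> np.ndarray:
    """Sample an (n, 4) block of per-state values, independently or through a
    single shared quantile (comonotone)."""
    out = np.empty((n, N_ALIVE))
    if mode == "per_state":
        for i, f in enumerate(fits):
            out[:, i], res = f.sample(rng, n)
            counts[f"{label}[{ALIVE_STATES[i].name}]"] = res
    elif mode == "global":
        q = rng.random(n)
        for i, f in enumerate(fits):
            frozen = f.frozen()
            if f.support is not None:
                lo, hi = frozen.cdf(f.support[0]), frozen.cdf(f.support[1])
                out[:, i] = frozen.ppf(lo + q * (hi - lo))
            else:
                out[:, i] = frozen.ppf(q)
            counts[f"{label}[{ALIVE_STATES[i].name}]"] = 0
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    return out


def run_psa(
    base: tuple[ModelInstance, ModelInstance],
    fits: PSAFits,
    n_iterations: int = 10_000,
    seed: int | None = None,
    collapse: bool = False,
    independent_utility_arms: bool = False,
) -> PSAResult:
    """Monte Carlo PSA: per draw, sample cost groups, utilities, the DTx fee
    and the hospitalization risk ratio, re-evaluate both arms, and record the
    incremental (dCost, dQALY).

    Cost and utility draws are shared across arms; the risk-ratio draw
    regenerates the DT hospitalization probabilities as
    ``clip(CH_prob * RR, 0, 1)``, and the DTx fee applies to the DT arm only
    (``independent_utility_arms`` draws each arm's utilities separately
    instead, for exploring the unidentified across-arm correlation).
    ``collapse`` replaces every distribution by its base value, reproducing
    the base-case deltas exactly. Fixed ``seed`` gives bit-identical output.
    """
    if n_iterations < 1:
        raise ValueError(f"n_iterations must be >= 1, got {n_iterations}")
    ch, dt = base
    st = ch.settings
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}

    # Transition dynamics are fixed across draws: precompute each arm's
    # discounted per-capita state-time under the configured accounting.
    weights = {}
    life_years = {}
    for arm in (ch, dt):
        P = normalize_rows(arm.matrix, st.normalization)
        tol = 1e-9 if st.normalization != "none" else 5e-3
        trace = run_cohort(P, arm.cohort, st.cycles, row_sum_tolerance=tol)
        w = discounted_state_time(trace, st)
        weights[arm.arm] = w[:N_ALIVE]
        life_years[arm.arm] = w[:N_ALIVE].sum() / st.cycles_per_year

    n = n_iterations
    if collapse:
        DM = np.broadcast_to(ch.costs.direct_medical_per_admission, (n, N_ALIVE))
        NM = np.broadcast_to(ch.costs.direct_nonmedical_annual, (n, N_ALIVE))
        IND = np.broadcast_to(ch.costs.indirect_annual, (n, N_ALIVE))
        DTX = np.full(n, dt.costs.dtx_annual)
        U_ch = U_dt = np.broadcast_to(ch.utilities.mean, (n, N_ALIVE))
        p_ch = np.broadcast_to(ch.hospitalization.monthly_prob, (n, N_ALIVE))
        p_dt = np.broadcast_to(dt.hospitalization.monthly_prob, (n, N_ALIVE))
    else:
        DM = _sample_coupled(fits.direct_medical, rng, n, "per_state", counts, "direct_medical")
        NM = _sample_coupled(fits.direct_nonmedical, rng, n, "per_state", counts, "direct_nonmedical")
        IND = _sample_coupled(fits.indirect, rng, n, "per_state", counts, "indirect")
        DTX, res = fits.dtx_cost.sample(rng, n)
        counts["dtx_cost"] = res
        U_ch = _sample_coupled(fits.utilities, rng, n, fits.utility_mode, counts, "utility")
        if independent_utility_arms:
            U_dt = _sample_coupled(fits.utilities, rng, n, fits.utility_mode, counts, "utility_dt")
        else:
            U_dt = U_ch
        RR = _sample_coupled(
            fits.hospitalization_rr, rng, n, fits.rr_mode, counts, "hospitalization_rr"
        )
        p_ch = np.broadcast_to(ch.hospitalization.monthly_prob, (n, N_ALIVE))
        p_dt = np.clip(ch.hospitalization.monthly_prob * RR, 0.0, 1.0)

    w_ch, w_dt = weights["CH"], weights["DT"]
    cost_ch = ((NM + IND + ch.costs.dtx_annual) / 12.0 + p_ch * DM) @ w_ch
    cost_dt = ((NM + IND + DTX[:, None]) / 12.0 + p_dt * DM) @ w_dt
    qaly_ch = (U_ch / 12.0) @ w_ch
    qaly_dt = (U_dt / 12.0) @ w_dt

    if st.annualization_mode == "per_horizon_year":
        den_ch = den_dt = st.horizon_years
    else:
        den_ch, den_dt = life_years["CH"], life_years["DT"]
    cost_ch, qaly_ch = cost_ch / den_ch, qaly_ch / den_ch
    cost_dt, qaly_dt = cost_dt / den_dt, qaly_dt / den_dt
    return PSAResult(
        delta_cost=cost_dt - cost_ch,
        delta_qaly=qaly_dt - qaly_ch,
        cost_ch=cost_ch,
        cost_dt=cost_dt,
        qaly_ch=qaly_ch,
        qaly_dt=qaly_dt,
        seed=seed,
        resample_counts=counts,
    )


def default_wtp_grid(stop: float = 300_000.0, step: float = 1000.0) -> np.ndarray:
    """WTP grid 0..stop (inclusive) in ``step`` increments."""
    return np.arange(0.0, stop + step / 2, step)


def ceac(points, wtp_grid) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve: for each WTP value, the
    fraction of draws with positive incremental net monetary benefit."""
    pts = points.points if isinstance(points, PSAResult) else np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("ceac requires at least one CE point")
    dc, dq = pts[:, 0], pts[:, 1]
    out = []
    for wtp in np.asarray(wtp_grid, dtype=float):
        prob = float(np.mean(wtp * dq - dc > 0.0))
        out.append(CEACPoint(float(wtp), prob))
    return out


def ceac_frame(points, wtp_grid):
    import pandas as pd

    curve = ceac(points, wtp_grid)
    return pd.DataFrame(
        {
            "wtp": [p.wtp for p in curve],
            "probability_cost_effective": [p.probability_cost_effective for p in curve],
        }
    )


# ---------------------------------------------------------------------------
# Deterministic sensitivity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TornadoEntry:
    group: str
    icer_at_low: float
    icer_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _with_costs(inst: ModelInstance, **changes) -> ModelInstance:
    return inst.replace(costs=dataclasses.replace(inst.costs, **changes))


def apply_parameter_group(
    ch: ModelInstance, dt: ModelInstance, group: str, value
) -> tuple[ModelInstance, ModelInstance]:
    """Return a new arm pair with one parameter group pinned to ``value``
    (a scalar, broadcast to all states, or a per-state vector).

    Cost and utility groups apply to both arms; ``dtx_cost`` only to DT;
    ``hospitalization_rr`` regenerates the DT hospitalization probabilities
    from the CH ones.
    """
    if group not in PARAMETER_GROUPS:
        raise ValueError(f"unknown parameter group {group!r}; valid: {PARAMETER_GROUPS}")
    vec = np.broadcast_to(np.asarray(value, dtype=float), (N_ALIVE,)).copy()
    if group == "direct_medical":
        return (
            _with_costs(ch, direct_medical_per_admission=vec),
            _with_costs(dt, direct_medical_per_admission=vec.copy()),
        )
    if group == "direct_nonmedical":
        return (
            _with_costs(ch, direct_nonmedical_annual=vec),
            _with_costs(dt, direct_nonmedical_annual=vec.copy()),
        )
    if group == "indirect":
        return (
            _with_costs(ch, indirect_annual=vec),
            _with_costs(dt, indirect_annual=vec.copy()),
        )
    if group == "dtx_cost":
        return ch, _with_costs(dt, dtx_annual=float(np.asarray(value, dtype=float).reshape(-1)[0]))
    if group == "utility":
        new_u = lambda inst: dataclasses.replace(inst.utilities, mean=vec.copy())  # noqa: E731
        return ch.replace(utilities=new_u(ch)), dt.replace(utilities=new_u(dt))
    # hospitalization_rr
    probs = np.clip(ch.hospitalization.monthly_prob * vec, 0.0, 1.0)
    return ch, dt.replace(hospitalization=HospitalizationProfile(probs, vec.copy()))


def _icer(ch: ModelInstance, dt: ModelInstance) -> float:
    return compare_strategies(evaluate_strategy(ch), evaluate_strategy(dt)).icer


def one_way_sensitivity(
    base: tuple[ModelInstance, ModelInstance], group: str, low, high
) -> TornadoEntry:
    """Pin ``group`` to its low and high bounds (all states simultaneously),
    re-run both strategies, and record the two ICERs."""
    ch, dt = base
    return TornadoEntry(
        group=group,
        icer_at_low=_icer(*apply_parameter_group(ch, dt, group, low)),
        icer_at_high=_icer(*apply_parameter_group(ch, dt, group, high)),
    )


def _group_bounds(ranges: list[ParameterRange], group: str):
    m = _range_map(ranges, group)
    if None in m:
        return m[None]
    lows = np.array([m[s][0] for s in ALIVE_STATES])
    highs = np.array([m[s][1] for s in ALIVE_STATES])
    return lows, highs


def tornado(
    base: tuple[ModelInstance, ModelInstance],
    ranges: list[ParameterRange],
    groups: tuple[str, ...] = PARAMETER_GROUPS,
) -> list[TornadoEntry]:
    """Full one-way analysis over every parameter group, sorted by descending
    ICER swing (the tornado-diagram ordering)."""
    entries = []
    for g in groups:
        low, high = _group_bounds(ranges, g)
        entries.append(one_way_sensitivity(base, g, low, high))
    return sorted(entries, key=lambda e: e.swing, reverse=True)


def tornado_frame(entries: list[TornadoEntry]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "parameter": e.group,
                "icer_at_low": e.icer_at_low,
                "icer_at_high": e.icer_at_high,
                "swing": e.swing,
            }
            for e in entries
        ]
    )


def two_way_sensitivity(
    base: tuple[ModelInstance, ModelInstance], group1: str, grid1, group2: str, grid2
) -> np.ndarray:
    """ICER at every combination of two parameter grids; entry [i, j] applies
    ``grid1[i]`` to ``group1`` and ``grid2[j]`` to ``group2``."""
    ch, dt = base
    out = np.empty((len(grid1), len(grid2)))
    for i, v1 in enumerate(grid1):
        ch1, dt1 = apply_parameter_group(ch, dt, group1, v1)
        for j, v2 in enumerate(grid2):
            out[i, j] = _icer(*apply_parameter_group(ch1, dt1, group2, v2))
    return out
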