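# Methods

## Model

`rehabcea` implements a five-state Markov cohort model of chronic heart
failure under two home-based cardiac-rehabilitation strategies: conventional
management (CH) and management augmented with a digital-therapeutics app
(DT). States are the NYHA functional classes I–IV plus absorbing death; the
cycle length is one month and the horizon 120 cycles (10 years). A closed
cohort of 2,315 patients (1795 / 172 / 280 / 68 / 0 at baseline) is
propagated by `occupancy[t+1] = occupancy[t] @ P`, with arm-specific monthly
transition matrices.

Each cycle accrues, per alive state and per person,

* cost = (direct non-medical + indirect + DTx fee, all annual) / 12
  + P(hospitalization this month) × cost per admission,
* QALYs = state utility / 12,

weighted by the start-of-cycle occupancy and discounted at 3%/year
compounded per cycle, `(1.03)^(-(t-1)/12)`, with the first cycle
undiscounted. Death accrues nothing. Hospitalization is an expected
per-cycle cost, not a separate state, mirroring how the source tabulates a
monthly hospitalization probability alongside (not inside) the matrix.
Totals are per capita; the headline comparison is

ICER = (C_DT − C_CH) / (Q_DT − Q_CH),

with cost-effectiveness at a willingness-to-pay λ decided by the incremental
net monetary benefit NMB = λ·ΔQ − ΔC (well defined even when ΔQ ≤ 0, which
is why the PSA uses it rather than an ICER-vs-threshold rule).

## Key conventions and tunable parameters

| parameter | default | notes |
|---|---|---|
| annual discount rate | 0.03 /year | applied identically to costs and QALYs, including hospitalization costs |
| cycles / horizon | 120 / 10 years | monthly cycles |
| accrual | start-of-cycle | `half_cycle=True` uses the start/end mean |
| annualization | `per_horizon_year` | total discounted value ÷ 10; `per_life_year` divides by discounted life-years instead |
| row repair | `adjust_diagonal` | see below; `proportional` and `none` selectable |
| WTP | 85,698 CNY/QALY | 1× 2022 GDP per capita; 257,094 = 3× |

The published DT matrix rows for NYHA II/III/IV sum to 0.999 / 1.001 /
0.999. The package stores them verbatim and repairs them at simulation time.
The default, `adjust_diagonal`, absorbs the residual into the
stay-probability, because the off-diagonal transition and death
probabilities are the clinically meaningful printed quantities;
`proportional` rescales whole rows; `none` uses the rows as printed (the
engine then tolerates row sums within 5e-3). The choice moves the ICER by
less than 0.01% (see `results/base_case_modes.csv`).

The two annual cost categories carry a labelling conflict in the source: the
cost table's header order makes direct non-medical the small values
(1012.25 … 5333 CNY/yr) and indirect the large ones (45,720 … 23,085.54),
while the sensitivity-range table labels them the other way around. Field
names here follow the cost table; sensitivity ranges are attached to base
values by midpoint, which is unambiguous because each published range
brackets exactly one base value. Only the group labels, not any number, are
affected.

## Base-case discrepancy

The published per-capita per-year results (CH 38,442.11 CNY and 0.71959
QALYs; DT 42,300.26 CNY and 0.81686 QALYs; ΔC 3857.86, ΔQ 0.09727, ICER
39,661.32) are **not reproducible from the published inputs** under any
accounting convention this package exposes. `analysis/01_base_case.py`
sweeps all 12 documented modes (3 row-repair × 2 accrual × 2 annualization);
the two annualization families give:

| quantity | published | per-horizon-year | per-life-year |
|---|---|---|---|
| CH cost (CNY/yr) | 38,442.11 | 17,400.77 | 48,209.94 |
| CH QALY (/yr) | 0.71959 | 0.31145 | 0.86289 |
| DT cost (CNY/yr) | 42,300.26 | 20,931.73 | 47,654.18 |
| DT QALY (/yr) | 0.81686 | 0.37976 | 0.86457 |

Half-cycle correction moves these by under 1%. The published values lie
between the two families and match neither; in particular the published
incremental QALY rate (0.09727/yr, i.e. 0.97 QALYs over 10 years) exceeds
the largest incremental QALY the published transition matrices can generate
under any of these conventions (0.68 discounted QALYs per capita). The
publication's own numbers are also internally inconsistent at the 0.01–2
level (ΔC 3857.86 vs 3858.15; ICER 39,661.32 vs 39,663.5; DT QALY 0.81686 vs
0.81687), suggesting undocumented post-processing. The package therefore
reports the default per-horizon-year accounting (ICER 51,691.5 CNY/QALY) and
treats the structural and oracle-based checks, which all pass, as the
correctness evidence. Both annualizations are first-class so users can
reproduce either scale; per-life-year comparisons divide the arms by
different life-year denominators and should not be summarized as an ICER.

## Sensitivity analysis

Published (low, high) ranges are read as central 95% intervals:
SD = (high − low) / (2 × 1.96). Fitting is closed-form method of moments —
gamma for costs (mean = base value, shape = mean²/SD²), beta for utilities
(matching the published mean and variance), lognormal for the
hospitalization risk ratio (median = base ratio, σ = ln(high/low)/3.92).
The DTx-fee gamma (mean 180, range 144–216) has shape 96.04, scale 1.8742.

PSA design (10,000 draws by default, single fixed seed, bit-reproducible):

* Cost groups and utilities are drawn once per iteration and **shared across
  arms**; only the risk-ratio draw and the DTx fee differentiate the arms.
* The risk ratio regenerates the DT hospitalization probabilities as
  `clip(CH_prob × RR, 0, 1)`; transition matrices are not varied (no
  published uncertainty).
* Utility draws for states whose mean lies inside the global utility
  envelope [0.66, 0.96] (NYHA I and II) are truncated to it by rejection
  resampling (≤ 100 rounds, counts logged); the envelope is a config switch
  because a single published utility row must serve four states. A `global`
  utility mode draws one shared quantile through every state's beta instead
  of independent per-state draws; both readings are implemented.
* Parameters are sampled independently — no correlation structure is
  published.

With shared draws, ΔQ is nearly deterministic (the utility draw multiplies
both arms' occupancy weights), so the acceptance probability at any WTP
above the base-case ICER is essentially 1: the 10,000-draw CEAC gives 100.0%
at both 85,698 and 257,094 CNY/QALY (seed 1), against published values of
82.7% and 96.6%. An `independent_utility_arms` switch draws each arm's
utilities separately, which widens the ΔQ spread and yields 77.0% / 91.1%
under the same seed; the published probabilities sit between the two
designs and are consistent with arm-independent draws combined with the
(irreproducible) larger published base-case deltas. The across-arm
correlation is not identifiable from the publication, so the shared-draw
design — the conventional choice when both arms use one utility source — is
the default and the variant is reported by `analysis/03_psa.py`.

The tornado analysis pins each of the six groups (direct medical,
direct non-medical, indirect, DTx fee, hospitalization RR, utility) to its
range bounds in all states simultaneously. Under this package's base case
the ranking is utility (swing 21,351) > indirect (20,592) > risk ratio
(9,406) > direct medical (1,362) > direct non-medical (484) > DTx fee (463);
the publication ranks the risk ratio first (utility unranked), a difference
expected given the irreproducible base case. The DTx fee's swing is
closed-form checkable: with effectiveness fixed, it equals
(216 − 144) × discounted alive person-years ÷ 12 ÷ 10 ÷ ΔQ.

## Synthetic data and oracles

`random_model_instance` generates arm pairs with severity-ordered utilities,
a monthly mortality gradient, positive costs, and an intervention arm
derived via a hospitalization risk ratio < 1 plus proportional shrinkage of
off-diagonal (progression + death) mass. Rows are built on the simplex, so
every instance passes validation at tolerance 1e-12 by construction. The
generator emulates the *structure* of the real tables, not Chinese hospital
cost distributions; passing tests demonstrate correctness of the machinery,
not calibration to any real population.

Two independent oracles guard the engine: (1) a two-state toy whose
discounted life-years equal the geometric series Σ sᵗdᵗ (matched to 1e-12),
and (2) a 50,000-patient microsimulation that replays state paths by
categorical sampling and hospitalizations as Bernoulli events, sharing the
engine's accrual constants but not its cohort arithmetic (a deliberately
independent loop-based accrual lives in the test suite as a third check).
Cohort and microsimulation agree within 3 standard errors on the published
fixture and 20 random instances. A parameter-recovery experiment verifies
that the PSA cloud mean recovers known synthetic truths within 3 SE and that
the CEAC crosses 0.5 within ~2% of the true ICER when draws concentrate.

## Numerical choices

* Row-stochasticity tolerance 1e-9 for simulation inputs; repaired matrices
  are exact to 1e-12; occupancy conservation asserted to 1e-9.
* Zero-sum transition rows, negative occupancies, utilities outside [0, 1],
  infeasible beta moments (variance ≥ mean(1−mean)) and non-positive
  lognormal bounds raise immediately; content problems in configs surface as
  `ConfigError` naming the offending field.
* A collapsed PSA (`collapse=True`) bypasses sampling and reproduces the
  base-case deltas exactly, which pins the PSA's accrual path to the
  engine's.
* Degenerate ranges (high = low) produce point-mass fits flagged
  `near_deterministic`.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give bit-identical PSA scatters, microsimulations and synthetic
  instances.

Problem sizes: 120-cycle cohort runs are instantaneous; the default suite
uses 10,000 PSA draws, 50,000-patient microsimulations and 2,000-draw
recovery PSAs, chosen so every Monte Carlo comparison operates at ≤ 3
standard errors with comfortable margin.

## Limitations

* No tunnel states, time-varying transitions, patient covariates,
  correlated/copula sampling, EVPI, or multi-way frontier.
* The cost model has no currency conversion or inflation indexing.
* The published base case and CEAC are not reproducible from the published
  inputs (see above); this package documents the gap rather than tuning
  toward it.
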