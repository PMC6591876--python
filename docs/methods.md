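# Methods

## Decision model

The model is a deterministic 3-state Markov cohort simulation with states
disease-free survival (DFS), progressive disease (PD) and death. The entire
cohort starts in DFS (the post-treatment, post-surgery state); each 1-month
cycle a DFS patient may progress (`p_dfs_pd`), die (`p_dfs_death`) or stay,
and a PD patient may die (`p_pd_death`) or stay. Death is absorbing and
there is no return from PD to DFS. Transition probabilities are constant in
time — a homogeneous-chain assumption that trades realism (hazards for
cancer recurrence typically fall with time) for identifiability from the
summary survival figures available.

State occupancy is accumulated over cycles 0..H with trapezoid (half-cycle)
weights — half weight at cycle 0 and at the horizon H, full weight between —
and discounted at `(1 + r)^(−t/12)` per cycle, anchored at model start.
Half-cycle correction is on by default: the source analysis does not state
its cycle-weighting convention, but only trapezoid-weighted occupancy at
120 cycles reproduces its printed state-level results (e.g. SCRT DFS
occupancy 25.85 person-months against the 25.83 implied by the printed
QALM/utility ratio; uncorrected start- or end-of-cycle sums give 26.35 or
25.35). This inference is numeric, not textual, and the flag is exposed in
`EconomicSettings`.

## Parameters

| parameter | SCRT | LCCRT | units / notes |
|---|---|---|---|
| `p_dfs_pd` | 0.0204 | 0.0244 | monthly probability |
| `p_dfs_death` | 0.0148 | 0.0148 | monthly probability |
| `p_pd_death` | 0.0348 | 0.1020 | monthly probability |
| `cost_dfs_cycle` | 444.85 | 461.34 | USD (2018) per cycle |
| `cost_pd_cycle` | 4920.50 | 4920.50 | USD per cycle, shared (borrowed from a published metastatic-CRC analysis) |
| `u_dfs` / `u_pd` / `u_death` | 0.84 / 0.6 / 0 | same | utility weights |
| horizon | 120 | | cycles (10 years) |
| discount rate | 0.03 | | per year, costs and effects |
| WTP | 2370.47 | | USD per QALM (3 × monthly per-capita GDP) |

Two published utility sets exist for this model: the narrative values
(0.84 DFS / 0.6 PD, each with its own citation) and a conflicting tabulated
set (0.65/0.56 DFS by arm, 0.47 PD). The narrative values are the default
fixtures because only they are arithmetically consistent with the printed
state-level results (21.70 QALM / 0.84 = 25.83 occupancy = 11,490 / 444.85);
the tabulated set ships as the `*_table_utilities` fixture variants. The
published monthly probabilities are likewise mutually inconsistent with the
tabulated 3-year survival fractions under any constant-hazard reading
((1 − 0.0352)^36 ≈ 0.27, not 0.53); the probabilities are taken as the
canonical inputs and no agreement is forced.

Upfront (first-cycle) costs default to 0: the itemized per-patient resource
costs cannot be unambiguously amortized into the published per-cycle DFS
costs, and a zero upfront cost makes DFS-state cost exactly per-cycle cost ×
occupancy, which matches the printed totals. The item table is retained as
reference data (`cost_line_items`) and is not a model input.

## Survival calibration

For new inputs the calibration workflow starts from digitized Kaplan-Meier
points. Choices:

- **Parameterization** `S(t) = exp(−(t/scale)^shape)` — the standard
  two-parameter Weibull survival form (shape dimensionless, scale in
  months).
- **Objective**: sum over the monthly grid t = 1..72 (6-year fit horizon,
  configurable) of squared deviations between the Weibull curve and the
  digitized curve step-interpolated KM-style (last value carried forward;
  duplicate digitized times resolved by keeping the last reading).
- **Preprocessing**: running-minimum monotone repair, since a true KM curve
  is non-increasing and digitization noise is not.
- **Optimizer**: Nelder-Mead from three shape starts (0.5, 1, 2) with the
  scale started at the time whose digitized survival is nearest `exp(−1)`;
  convergence tolerances 1e-8 on parameters and 1e-12 on the objective.
  Least squares on curve points (not an event-time likelihood) is the right
  objective here because the data are pixels read off a published figure,
  not patient-level times.

Fitted curves become constant monthly probabilities by horizon matching:
`q = 1 − S(h)^(1/h)` reproduces the fitted survival at h months. The PD
mortality, which no published curve gives directly, is calibrated by
bisection: the `p_pd_death` at which the 3-state model's alive fraction at
h months equals the fitted overall-survival value (the alive fraction is
monotone in `p_pd_death`, so bisection to |Δsurvival| < 1e-8 is safe;
infeasible targets raise rather than silently clip). When nobody enters PD
the equation is degenerate and 0 is returned by convention.

## Sensitivity analyses

**Tornado.** Each scalar input is set to base × (1 ∓ 0.2) with everything
else fixed, both cohorts re-run, and the incremental net monetary benefit
(intervention − comparator at the base WTP) recorded; bars are sorted by
range. The shared PD-state cost is one externally borrowed parameter and
its two copies move together; transition probabilities, DFS per-cycle costs
and utilities are treated as per-arm model inputs and vary independently,
as in a per-branch decision-tree parameterization. Under this treatment the
SCRT DFS-state utility is the most influential parameter, consistent with
the published qualitative finding; with utilities forced to move jointly
across arms their bars nearly cancel in the incremental NMB and the finding
is not reproducible. Probability-like values are capped at 1 after scaling
and the DFS exit-probability sum is clipped with a warning.

**PSA.** Every varied input is drawn independently per trial: beta
distributions for probabilities and utilities, gamma for costs, each
moment-matched so the mean equals the base value and ±20% of base spans
approximately the central 95% interval (sd = 0.2 · base / 1.96); a
`uniform(0.8 · base, 1.2 · base)` alternative is available. These
distributions are declared package defaults — the source analysis does not
state its PSA distributions — bounded to the same ±20% range as the
deterministic analysis. Draws are clipped to valid ranges and DFS exit
probabilities renormalized if they overrun 1. Two evaluation modes: per
trial either the deterministic cohort (default, fast) or a microsimulation
averaging n individually simulated patient paths (default 10,000), which
agrees with the cohort in expectation and is checked against it to
Monte-Carlo error. Everything is reproducible from a single seed
(`numpy.random.default_rng`).

**CEAC.** At each willingness-to-pay value on a grid (default 0..3 × WTP in
100 steps) the acceptability of a strategy is the fraction of PSA trials in
which it attains the strictly highest NMB, with exact ties split equally so
probabilities sum to 1.

**Threshold.** The common PD per-cycle cost at which the full-model ICER
equals the WTP, found by bisection to ±$0.01 within a bracket (default
[0, base PD cost]) after verifying the ICER−WTP gap changes sign across the
bracket. Because occupancies are cost-independent the ICER is linear in the
PD cost, and the bisection is cross-checked against the closed-form root of
`(ΔC_dfs + c · ΔO_pd) / ΔE = WTP`.

## Synthetic data

`generate_km_points` emulates figure digitization: a known Weibull curve
sampled on a regular monthly (or irregular random) grid, perturbed with
Gaussian noise (default sd 0.01 survival units, roughly pixel-reading
error), clipped to [0, 1] and monotone-repaired. It reproduces the
*process* of reading a printed curve, not real trial data: there is no
censoring, no step heights tied to numbers at risk, and noise is
independent across points (real digitization errors are serially
correlated). Passing the recovery tests therefore shows the estimator is
consistent under the stated noise model, not that any particular published
curve was digitized accurately. `generate_parameter_set` draws random
internally valid two-arm parameter sets (probability sums ≤ 1, utility
ordering enforced) for property-based tests; degenerate ranges pin exact
values, so the published inputs are a reproducible special case.

## Numerical choices and problem sizes

- Cohort arithmetic is plain dense linear recursion; mass conservation to
  1e-12 and agreement with the geometric-series closed form to 1e-10 are
  tested.
- ICERs are reported only in the costlier-and-more-effective quadrant;
  dominated pairs are flagged (`intervention_dominates` /
  `comparator_dominates`) instead of producing meaningless negative ratios,
  and a zero effectiveness difference yields an undefined (None) ICER, not
  an exception.
- Utility ordering `u_pd ≤ u_dfs` warns rather than fails (PSA draws may
  legitimately cross it); genuinely invalid inputs (probabilities outside
  [0, 1], negative costs) raise.
- The test suite runs the PSA at reduced sizes (tens to hundreds of trials,
  ≤10,000 individuals) chosen so that each check resolves its target effect
  within Monte-Carlo error while the whole suite completes in seconds; the
  full published configuration (1,000 trials × 10,000 individuals) remains
  available through `run_psa`/CLI flags.

## Known limitations

- Constant monthly transition probabilities; no tunnel states, time-varying
  hazards or age effects.
- Exactly two strategies; no efficiency frontier or extended dominance.
- Only the Weibull family is implemented for curve calibration
  (log-logistic, Gompertz etc. are out of scope), and curves must already
  be digitized to numbers — no image reading.
- Costs are fixed 2018 USD; no inflation or currency machinery.
- The bundled itemized cost table is documentation, not a validated costing
  model; per-cycle costs are taken as published.
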