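# Methods

## Model structure

The cohort model is a homogeneous discrete-time Markov chain over three
states — GOLD 1-2, GOLD 3-4, death — with a one-year cycle. GOLD 1-2
patients may remain, progress to GOLD 3-4, or die; GOLD 3-4 patients may
remain or die (no recovery of lung function); death is absorbing. The
annual transition matrix per arm is

|            | GOLD 1-2            | GOLD 3-4 | death |
|------------|---------------------|----------|-------|
| GOLD 1-2   | 1 − prog − m₁₂      | prog     | m₁₂   |
| GOLD 3-4   | 0                   | 1 − m₃₄  | m₃₄   |
| death      | 0                   | 0        | 1     |

with arm-specific progression (0.215 / 0.170 / 0.124 for Western, TCM and
combined therapy) and shared mortalities m₁₂ = 0.0286 (near-population,
mean age ≈ 64) and m₃₄ = 0.126 (literature-derived).

Acute exacerbations are within-cycle transient events, not states: an
AECOPD episode lasts roughly half a month against a one-year cycle, so
promoting it to a state would distort occupancy. Each living state carries
annual probabilities of a mild AE (outpatient) and a severe AE
(hospitalization). The bundled per-state values sum to exactly 1, which we
read as: every person-year experiences one AE whose severity follows the
mild/severe split; an `ae_incidence` scaling factor (default 1) relaxes
this if a separate incidence estimate is available.

Severe AEs additionally carry a 3.2% case-fatality. The source tables list
this alongside the GOLD 3-4 all-cause mortality without stating their
interaction; we apply it multiplicatively to the severe-AE fraction of
each living state *before* the annual transition (so the effective
transition matrix is row-mixed with the death column), with
`apply_ae_fatality=False` available to avoid double counting if the
all-cause mortalities are believed to already include AE deaths.

### Rewards and discounting

Rewards accrue on start-of-cycle occupancy (an optional half-cycle
correction averages start and end occupancy; default off, as the source
evaluation used none). Cycle k is discounted by (1+i)^−k, i.e. costs and
outcomes fall due at year end; base rate 5%/year, sensitivity range 0–8%
per the Chinese pharmacoeconomic guidelines. During an AE the state
utility is multiplied by 0.85 (mild) or 0.30 (severe) for the episode
duration d = 0.5/12 years; costs add the per-episode AE cost weighted by
the annual AE probability.

CUR and ICUR use discounted totals. Incremental life-year ratios use the
same (discounted) convention as costs, the only convention under which the
published incremental table is internally consistent. Currency is kept in
full precision and rounded half-up to integer Yuan only at presentation.

### What the engine does and does not reproduce

The published 100 000-patient / 40-year cohort totals are used as *given
inputs* for the incremental worked examples (ICURs 8 707 and 155 833 /
27 810 Yuan per incremental QALY / life year). They are not regenerated by
this engine: the printed inputs underdetermine them (no separate annual AE
incidence, unstated interaction of the 0.032 and 0.126 mortality figures,
unstated life-year discounting), and the published headline CURs are
exactly 10× the ratio of the published totals, an internal inconsistency
we do not attempt to resolve. The engine is instead validated against
exact oracles: occupancy conservation, closed-form geometric sums for
zero-progression parameter sets, matrix-power equivalence on random
parameter draws, and discount monotonicity.

## SF-6D utility scoring

SF-36 responses are recoded to the six SF-6D dimensions (PF 1–6, RL 1–4,
SF 1–5, PAIN 1–6, MH 1–5, VIT 1–5) and valued with the UK additive model:
utility = 1 + Σ level decrements + MOST, where MOST = −0.070 applies once
if any dimension sits at its most severe level. Full health scores 1.0;
the all-worst state scores 0.296.

Two properties of the published decrements matter for users:

- They are **not monotone** in the level index (e.g. PF3 = −0.011 vs
  PF2 = −0.053; RL4 = −0.050 vs RL3 = −0.055). Worsening a single
  dimension can therefore *raise* the score, and the attainable minimum
  over all 18 000 states is 0.291 (PF6/RL3/SF5/PAIN6/MH5/VIT5), slightly
  below the all-worst score. These are features of the econometric
  valuation estimates, preserved verbatim.
- The model is fully additive, so scoring is exact and order-independent.

The SF-36→SF-6D item recoding is not part of the source material; we ship
the standard Brazier item selection (11 items: 3a/3b/3j, 4c, 5b, 7, 8,
9b/9e/9f, 10) with worst-first precedence, assuming the standard-recall
SF-36 form. Ambiguous patterns (vigorous-only limitation "a lot";
non-interfering pain) resolve to the less severe level and are logged.
Classifications may also be supplied directly, bypassing the recoding.

## Synthetic trial generator

The generator emulates the three-arm trial the analysis assumes: 79/79/78
patients with fixed GOLD strata (45/34, 43/36, 39/39), observed over two
26-week windows, with SF-6D utilities at baseline, month 3 and month 6.

- **Utilities**: normal, moment-matched after truncation to [0.296, 1]
  (the attainable band of the all-worst anchor), per arm × stratum ×
  visit. Month-3 cells default to the midpoint of baseline and month 6,
  which are the two published visits; month 3 is never used by the
  estimators. Each utility is back-filled to the SF-6D state with the
  nearest achievable score (ties to the less severe state) so the
  classification→score path is exercisable end to end.
- **Costs**: gamma, moment-matched. Several cost cells have SD > mean,
  which a truncated normal cannot represent without badly distorting the
  moments; the gamma keeps mean, SD and nonnegativity. Stable-period costs
  are drawn semiannually at half the annual mean/SD.
- **Events**: one AE opportunity per patient per window, with semiannual
  mild/severe probabilities obtained by inverting the constant-hazard
  annualization of the configured annual values; progression likewise, per
  window while at risk. The single-opportunity design is an assumption
  (the source reports no per-patient AE counts or dropout), and the
  generator models no dropout, center effects or adherence.
- **Point-mass (expectation) mode**: every drawn quantity is replaced by
  its expectation — cell means for costs/utilities, and event rows carried
  with fractional `weight` equal to their per-window probability instead
  of Bernoulli draws. Because the estimators are weight-aware, an
  expectation-mode trial reproduces its generating configuration exactly
  (to floating-point round-off), giving the estimation pipeline a built-in
  closed-form oracle. With integer patient counts, no realization of the
  Bernoulli process could do this (e.g. 0.426 × 90 windows is not an
  integer), which is why exactness is defined at the expectation rather
  than per-draw level.

What passing tests on this generator show — and don't: they verify the
estimators invert the generating process and converge at the expected
n^(−1/2) rate under the stated distributional families. Real trial data
add missingness, dropout, center heterogeneity, non-gamma cost tails and
informative AE recurrence, none of which are emulated.

## Parameter estimation

Costs and utilities are (weighted) cell means; stable semiannual costs are
annualized by doubling, AE costs stay per-episode because the engine
multiplies them by annual AE probabilities. Semiannual event proportions
(events over observed person-windows, with window presence taken from the
stable-cost records) are annualized per severity under the constant
hazard; if sampling noise pushes a state's annualized mild + severe above
1 the pair is renormalized and logged. Progression pools both windows with
the window-2 at-risk set reduced by window-1 events, treating the
proportion at the cohort (not per-patient) level. Mortalities and the
severe-AE case-fatality are not identifiable from a one-year trial and
enter as literature defaults, flagged as such in the report.

The across-arm utility comparison is a classic one-way ANCOVA — month-6
utility on arm with the baseline utility as a single shared-slope
covariate — fitted by OLS (statsmodels), reporting the type-II F for the
arm effect and means adjusted to the grand baseline mean. A degenerate
(zero-variance) covariate falls back to a plain one-way ANOVA with a
warning.

## Sensitivity analysis

One-way sweeps follow the evaluation's range rules: costs ±30%, utilities
and probabilities ±20% (clamped to [0, 1], clamping logged), discount rate
over its absolute 0–8% band. Because a state's mild/severe AE
probabilities form a unit-sum split, an AE parameter is swept jointly with
its complement so every grid point remains a valid parameterization.
Sweeps operate on immutable scenario copies (no mutation leakage) and the
engine is deterministic, so repeated tornados are bit-identical. Grids
default to 21 points, always containing the exact baseline; crossings of
willingness-to-pay multiples are located by linear interpolation between
adjacent grid points, which is adequate because each curve is smooth
(costs: exactly affine) at this resolution. Tornado rows are ranked by
ICUR range; endpoint ICURs are compared to 1×/2×/3× GDP for the crossing
flags, and undefined ICURs (ΔU = 0) are typed results, not infinities, so
dominance reversals are visible rather than fatal.

## Numerical choices

- Probability/rate conversions use `log1p`/`expm1` for accuracy near 0;
  the round-trip identity holds to 1e-12 over p ∈ [0, 0.99].
- Nearest-score back-fill rounds scores to 9 decimals so algebraically
  equal level combinations coincide despite float summation order.
- Scenario digests hash the canonical JSON form (sorted keys); parameter
  files re-serialize canonically, so save(load(f)) is byte-stable.
- Exactness claims in tests are asserted at 1e-12 relative tolerance
  (IEEE round-off through mean and annualize/semiannualize round-trips).

## Problem sizes used in the test suite

The suite exercises the full 40-cycle, 100 000-person base case for all
three arms; random-draw properties use 100 parameter sets at 8–12 cycles;
parameter-recovery runs use trials of 236, 2 360 and 23 600 patients with
fixed seeds, with the largest run checked for calibration against the
estimators' delta-method standard errors (multiplicity-aware: among the 33
independent recovery quantities at most the expected single |z| may exceed
3 and none may reach 5).

## Known limitations

- Cohort (not individual-level) simulation; no time-varying transition
  probabilities, no probabilistic sensitivity analysis, no two-way grids.
- The published cohort totals cannot be regenerated from the published
  inputs (see above); conclusions drawn from this engine's own base case
  agree qualitatively (combined therapy very cost-effective vs Western
  medicine) but not numerically with the published totals.
- The SF-36 recoding assumes the standard-recall instrument; no imputation
  of missing items, and no other utility instruments.
- Utilities in the base case are the month-6 post-treatment cell means;
  the ANCOVA adjustment informs inference but does not feed the engine.
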