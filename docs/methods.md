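# Methods

## Overview

`rankwatch` reimplements, as a tested pipeline, a two-stage analysis of
visitor-directed aggression in a zoo-housed macaque troop:

1. **Dominance rank** is measured by sequential Elo-rating of dyadic
   non-contact aggression ("wins" for the aggressor), with ratings
   retroactively extracted as weekly snapshots.
2. **Visitor-directed aggression** (a binary per-individual, per-session
   outcome: did the animal threaten visitors at least once in a ten-minute
   session) is modeled by random-intercept logistic regression on the
   standardized weekly rating and two crowd covariates, with AICc candidate
   comparison, drop-one likelihood-ratio tests, and Tukey-type contrasts
   among crowd-activity levels.

Because no raw data of this kind are publicly deposited, the package ships
a synthetic-data generator whose defaults reproduce the statistical
structure of such a study, so that every stage is testable by parameter
recovery.

## Elo rating

Each individual enters at a start rating of 1000 points.  For an event in
which the aggressor ("winner") has pre-event rating `R_w` and the recipient
`R_l`, let `p` be the win expectation of the *higher*-rated member of the
pair, a function of the rating difference `d ≥ 0`:

- normal form (default): `p = Φ(d / (200√2))`,
- logistic form: `p = (1 + 10^(−d/400))⁻¹`.

If the higher-rated individual won, both ratings move by `(1 − p)·k`;
if the lower-rated won, by `p·k`.  The update is zero-sum, each exchange is
strictly positive and below `k`, and upsets move ratings further than
expected outcomes.  At equal ratings the branches coincide at `p = 0.5`,
so no tie-break is needed.  The printed source equations are ambiguous
about parenthesization ("1 − p × k"); `(1 − p)·k` is the only reading under
which the aggressor gains points.

Parameters (all in rating points unless noted):

| parameter | default | meaning |
|---|---|---|
| `start_rating` | 1000 | entry rating of every individual |
| `k` | 100 | maximal per-event rating change |
| `expectation_form` | `normal` | shape of the win-expectation curve |
| `expectation_scale` | 200·√2 (normal), 400 (logistic) | steepness of the curve |

`k = 100` and the start rating follow the source study; the normal form is
the convention of the R Elo-rating package that study used, with the
classic logistic form selectable because the study does not print its
expectation function and its tables cannot adjudicate it.

Weeks are consecutive 7-day blocks from the study start (week 1 = days
0–6); a week's snapshot is the rating after the last event inside the
block, carried forward through event-free weeks.  Events at the same
timestamp are processed in input order for determinism.  An individual's
rating participates only inside its presence interval (one troop member
left the source study mid-year, so the data model supports departures);
ratings are frozen, not removed, after departure.  Standardization of the
weekly ratings is global over all subject-weeks (sample SD), preserving
between-week dynamics as covariate signal rather than re-centering each
week.

## The mixed model

For individual `i` in session `j`:

    y_ij ~ Bernoulli(μ_ij),  logit(μ_ij) = x_ij'β + b_i,  b_i ~ N(0, σ_b²)

Fixed-effect candidates: standardized rating `elo_z`, crowd size
(persons; each ten-person observation band coded to its printed midpoint,
lower bound + 5, so "0–9" → 5), and crowd activity (three-level factor,
reference `calm`).  Rank enters as a fixed continuous slope plus the
per-subject random intercept: the source description ("Elo-rating nested in
subjects as a random factor") is internally ambiguous, and this structure
supports both the directional rank claim and standard likelihood-ratio
tests.  An independent random slope on `elo_z` is available
(`random_slope=True`) but is not the default.  Crowd size enters per
person, unscaled.

### Estimation

The marginal likelihood integrates each `b_i` out by **adaptive
Gauss–Hermite quadrature**: per group, the integrand is re-centered at its
posterior mode (found by damped Newton on a strictly concave objective)
and re-scaled by the mode curvature before applying the Gauss–Hermite
rule.  This keeps 25 nodes (the default) accurate even when one group
contributes thousands of Bernoulli terms and its posterior is far from the
prior; the non-adaptive rule fails badly in that regime.  With the random
slope the integral is two-dimensional and uses a tensor grid capped at 11
nodes per dimension.

Optimization is L-BFGS-B over `(β, σ)` with `σ ≥ 0`, analytic score
(posterior-weighted residuals at the quadrature nodes), deterministic
starts (plain-logistic `β` via statsmodels, `σ = 1`), and a relative
log-likelihood tolerance of 1e−8.  The Newton mode-finder uses a stopping
rule proportional to group size, since score round-off grows with the
number of terms.  Wald standard errors come from the inverse observed
information, obtained by central differences of the analytic score
(one-sided in `σ` at the zero boundary); `ci95 = β̂ ± 1.96·SE`, matching
the symmetric intervals the source tables print.  Complete separation by a
single covariate is detected up front and raised as an error naming the
term; non-convergence returns a flagged fit, never a silent one.

`fix_sigma=0` pins the variance component and reduces the model exactly to
ordinary logistic regression — this limit, and agreement of the marginal
log-likelihood with brute-force fixed-grid integration, are both under
test.

### Model comparison and tests

- **AICc** = `−2ℓ + 2k + 2k(k+1)/(n − k − 1)` with `n` = outcome rows and
  `k` = intercept + fixed slopes + 1 variance component; rows are the
  likelihood's sample unit here.  The candidate set is the seven non-empty
  subsets of the three predictors, each with the random intercept; ties
  break toward fewer parameters, then label, making ranking invariant to
  submission order.  An intercept-plus-random-intercept null model is
  fitted internally for nesting but not listed by default.
- **LRT**: `χ² = max(0, 2Δℓ)`, df = parameter-count difference, upper-tail
  chi-square p.  The rank test uses df = 1 (one fixed slope);
  boundary-corrected variance-component testing is out of scope.
- **Tukey contrasts**: the three pairwise log-odds differences among
  activity levels, `z = c'β̂ / √(c'Vc)`.  The single-step adjusted p-value
  `P(max|Z| ≥ |z_obs|)` under the joint normal of the contrasts is
  evaluated by scrambled-Sobol quasi-Monte-Carlo (2¹⁴ points, fixed
  internal seed); because the three contrasts are linearly dependent, the
  correlation matrix is factored by eigendecomposition.  Estimates are
  clipped to the provable `[p_unadjusted, min(1, 3·p_unadjusted)]`
  envelope, so a family of one is exactly unadjusted.
- **Diagnostics**: Pearson residuals conditional on posterior-mode
  intercepts, binned by fitted probability (quantile bins), with a ±2/√n
  reference band — a machine-readable stand-in for a residual plot.

## Synthetic data generator

Defaults emulate the study the analysis design assumes: 12 subjects
(8 adults — 5 female, 3 male — and 4 juveniles), 52 weeks, 2663 ten-minute
sessions in daytime hours, 1150 clean dyadic non-contact aggression events.
Crowd activity is drawn 0.6/0.3/0.1 (calm/moderate/frenetic) and the
six size bands 0.35/0.30/0.15/0.10/0.06/0.04, giving mostly small, calm
crowds with an occasional large or frenetic one.  Aggression pairs are
uniform over dyads and directed down a latent hierarchy with directional
consistency 0.9 (a despotic-species value; no published analogue exists
for this quantity).  Outcome coefficients default to the fitted values the
source study prints — intercept −4.313, moderate 0.075, frenetic 0.552,
random-intercept SD 1.272 — plus a rating effect of −0.5 per SD (invented;
lower-ranked individuals aggress more) and a null crowd-size effect,
mirroring the study's conclusions.  Small non-threatening visitor-event
rates (0.004 per juvenile-session, 0.0004 per adult-session) reproduce the
~94% threatening share and the predominantly juvenile origin of the rest.

Outcomes are driven by the `elo_z` computed from the *simulated* aggression
stream, not by the latent rank labels, so the estimation stage uses exactly
the covariate that generated the data: recovery tests then isolate the
correctness of the mixed-model machinery from Elo measurement attenuation,
and the rating engine is exercised inside the generator.  A single master
seed spawns independent substreams per stage (roster, sessions, aggression,
outcomes, non-threatening noise), so bundles are byte-identical across runs
with the same seed.

The generator deliberately omits features of real observation data: kin or
adjacent-rank bias in dyad selection, weekday/holiday session structure,
observer error, feedback between macaque behavior and crowd activity, and
any contact-aggression stream.  Passing recovery tests therefore shows the
pipeline is correct under its own assumptions, not that those assumptions
hold in a real zoo dataset.

`inject_contamination` appends multi-aggressor, multi-recipient, and
unknown-identity events at given rates and returns the exclusion report the
dyadic filter must reproduce, giving an exact bookkeeping oracle for the
filtering rules (the three exclusion counters are non-exclusive, but each
excluded event counts once).

## Problem sizes under test

The default suite runs the Elo oracle on 1000 random sequences, the
likelihood oracle on 100 small instances, parameter recovery and model
selection on 20 replicates at full generator scale (≈32k rows each), null
calibration of the drop-one crowd-size LRT on 200 reduced-scale datasets
(300 sessions, 8 weeks, σ_b = 0.5), and Wald-interval coverage on 50
reduced-scale datasets; the reduced sizes are chosen so the whole suite
completes in a few minutes while leaving the full-scale recovery checks at
study scale.

## Known limitations

- The exact random-effects formula and the expectation function of the
  source analysis are not recoverable from its text; both defaults are
  documented choices, and the logistic expectation and random-slope
  variants are provided.
- Wald intervals and df = 1 rank tests ignore the boundary behavior of the
  variance component; profile likelihood and mixture-χ² tests are not
  implemented.
- The single-covariate separation check does not detect separation by a
  linear combination of covariates; such fits surface as non-converged or
  implausibly large estimates instead.
- AICc uses the row count as `n`; with clustered binary data the effective
  sample size is smaller, so comparisons should be read as the source
  study's convention, not an endorsement.
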