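# rankwatch

Dominance rank and visitor-directed aggression in zoo-housed primates:
sequential Elo-rating of dyadic aggression, and random-intercept logistic
mixed models of per-session visitor-directed aggression with AICc model
comparison, likelihood-ratio tests, and Tukey-adjusted contrasts.

The package is aimed at behavioral researchers and zoo scientists who
collect all-occurrence observation logs (aggressor/recipient events,
session-level crowd covariates, visitor-directed behaviors) and want a
reproducible route from raw CSV logs to a ranked model table — plus a
synthetic-data generator with known ground truth, so the whole pipeline can
be validated by parameter recovery without any proprietary data.

## The model

**Rank.** Individuals start at 1000 rating points.  For each directed
non-contact aggression event the aggressor gains, and the recipient loses,

- `(1 − p)·k` points if the aggressor was the higher-rated of the pair,
- `p·k` points if the lower-rated aggressed (an upset),

where `p = Φ(d / 200√2)` is the win expectation of the higher-rated member
at rating gap `d`, and `k = 100` caps the per-event change (a logistic
expectation curve is selectable).  Ratings are extracted weekly and
standardized globally into `elo_z`.

**Outcome.** For individual *i* in ten-minute session *j*, the binary
outcome `y_ij` (≥1 threatening visitor-directed behavior in the session)
follows

    y_ij ~ Bernoulli(μ_ij),   logit(μ_ij) = x_ij'β + b_i,   b_i ~ N(0, σ_b²),

with candidate fixed effects `elo_z`, crowd size (band midpoints, persons),
and crowd activity (calm / moderate / frenetic, reference calm).  The
marginal likelihood is maximized by adaptive Gauss–Hermite quadrature; the
seven candidate models are ranked by AICc; terms are tested by drop-one
likelihood-ratio tests; activity levels are compared with single-step
(Tukey-type) adjusted contrasts.  See `docs/methods.md` for the full
account.

## Worked example

Simulate a year-long study at default scale (12 macaques, 52 weeks, 2663
sessions) and run the full analysis:

```python
from rankwatch.simulate import SyntheticConfig, generate
from rankwatch.pipeline import outcome_table_from_bundle
from rankwatch import glmm

cfg = SyntheticConfig(seed=1)
bundle, truth = generate(cfg)
table, snaps, report = outcome_table_from_bundle(bundle, cfg.start_date, cfg.n_weeks)

comp = glmm.compare_models(table)
print(comp.table[["model", "AICc", "rank"]].round(1).to_string(index=False))
```

```
                             model   AICc  rank
             Rank + Crowd Activity 7551.4   1.0
Rank + Crowd Size + Crowd Activity 7553.0   2.0
                              Rank 7562.0   3.0
                 Rank + Crowd Size 7563.7   4.0
                    Crowd Activity 7563.9   5.0
       Crowd Size + Crowd Activity 7565.6   6.0
                        Crowd Size 7576.0   7.0
```

The generator's crowd-size effect is zero, and AICc correctly prefers the
model without it.  The best model's coefficients (log-odds):

```python
best = comp.fits["Rank + Crowd Activity"]
print(best.coefficient_frame().round(3).to_string(index=False))
```

```
                    term   beta  lower95  upper95    se
               Intercept -4.282   -5.074   -3.489 0.404
                   elo_z -0.348   -0.528   -0.168 0.092
crowd_activity[moderate]  0.076   -0.071    0.223 0.075
crowd_activity[frenetic]  0.402    0.203    0.601 0.102
```

The negative `elo_z` slope says lower-ranked individuals threaten visitors
more often; frenetic crowds raise the log-odds relative to calm ones
(generating values: intercept −4.313, moderate 0.075, frenetic 0.552,
rating slope −0.5).  Tukey-adjusted contrasts:

```
moderate - calm:     est +0.076  z +1.02  p_adj 0.559
frenetic - calm:     est +0.402  z +3.96  p_adj 0.000
frenetic - moderate: est +0.325  z +2.99  p_adj 0.008
```

The same analysis runs from the shell on real or simulated CSV logs:

```bash
rankwatch simulate --seed 1 --out data/          # 4 CSVs + truth.json
rankwatch run --config config.yaml --out report/ # tables as json/csv/markdown
```

where `config.yaml` names either the four input CSVs (`individuals.csv`,
`sessions.csv`, `agonistic_events.csv`, `visitor_events.csv`) or a
`simulate:` block; see `rankwatch --help`.

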