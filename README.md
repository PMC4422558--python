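# cocarbon

Growth-rate composition modelling for *Escherichia coli* growing on
co-utilized carbon substrates.

When *E. coli* grows exponentially in minimal medium with two saturating
carbon substrates that it consumes simultaneously, the resulting growth
rate is not the sum of the single-substrate rates — catabolite repression
through the cAMP-Crp system throttles every carbon-uptake system in
response to the *total* carbon influx. Because the expression of
Crp-activated catabolic operons falls linearly with growth rate
(the "C-line", `E = E⁰(1 − λ/λ_C)`, with horizontal intercept
`λ_C ≈ 1.16/h` for the K-12 reference strain), the steady state of this
negative feedback loop can be solved in closed form. Each substrate *i* is
summarized by an effective capacity

```
a_i = λ_i / (1 − λ_i/λ_C)
```

and the mixed-substrate growth rate is

```
λ_mix = S / (1 + S/λ_C),   S = Σ_i a_i ,
```

a prediction with **no free parameters** beyond the strain constant `λ_C`.
The package implements this model, the C-line calibration (OLS with a
bootstrap interval for `λ_C = −intercept/slope`), the validation pipeline
against a table of measured growth rates (regression of measured on
predicted rates, per-group relative deviations, exact Mann–Whitney U
comparison), a synthetic-study generator, and a `λ_C` recovery estimator
with a parametric-bootstrap confidence interval. The reference growth
table (8 substrates; 15 co-utilized "group A" pairs and 7 "group B" pairs
with known uptake interactions such as glucose inducer exclusion) ships
embedded, so the whole analysis runs offline.

Intended users: systems/quantitative biologists studying bacterial growth
physiology and catabolite repression, and anyone needing a calibrated null
model for mixed-substrate growth in biotechnology settings.

## Worked example

Predict the growth rate on succinate (0.46/h) plus pyruvate (0.61/h):

```
$ cocarbon compose --lambda-c 1.16 --rates 0.46 0.61
0.740657
```

The measured rate on this pair is 0.71/h — a 4% deviation. Run the full
validation on the embedded reference table:

```
$ cocarbon analyze --table1 --lambda-c 1.16 -o out/
```

`out/report.json` then contains (abridged):

```json
"regression_group_a": { "slope": 0.9912, "offset_per_h": 0.0029, "r_squared": 0.9158 },
"group_comparison":   { "mean_relative_deviation_a": 0.0259,
                        "mean_relative_deviation_b": 0.1179,
                        "u_statistic": 0.0, "p_two_sided": 1.17e-05, "method": "exact" }
```

Reading: over the 15 co-utilized pairs the measured rates track the
zero-parameter predictions on the identity line (slope ≈ 0.99, offset
≈ 0.00/h, R² ≈ 0.92) with a mean deviation of ~3%, at the scale of
replicate noise. The 7 pairs with known extra uptake interactions deviate
by ~12%, and the exact rank test separates the two groups at
p ≈ 1.2 × 10⁻⁵. `out/predictions.csv` holds the per-pair numbers;
`--plot` adds a measured-vs-predicted scatter.

Other entry points: `cocarbon fit-cline` (calibrate `λ_C` from
expression-vs-rate data), `cocarbon simulate` (synthetic studies),
`cocarbon recover-lambda-c` (re-estimate `λ_C` from growth data alone).
Every command also works through the library API (`cocarbon.compose_growth_rates`,
`cocarbon.run_full_analysis`, ...); see `docs/methods.md` for the model
details and design choices.

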