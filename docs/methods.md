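# Methods

## The model

The package describes steady-state exponential growth of *E. coli* on one
or more saturating, co-utilized carbon substrates, under three
assumptions:

1. **Uptake flux is expression-limited.** At saturating substrate
   concentration the carbon uptake flux of substrate *i* is proportional
   to the expression level of its catabolic enzymes, `J_i = k_i E_i`.
2. **Growth is carbon-flux-limited.** The growth rate is a weighted sum of
   the uptake fluxes, `λ = Σ c_i J_i`, with substrate-specific carbon
   efficiencies `c_i` assumed growth-rate independent over the range
   studied (acetate overflow at high rates is neglected; it is a small
   fraction of total uptake).
3. **One global repression signal.** cAMP-Crp activity — and with it every
   catabolic expression level — depends only on the growth rate through
   the C-line `E_i(λ) = E_i⁰ (1 − λ/λ_C)`, because the α-ketoacid pool
   that inhibits cAMP synthesis senses total carbon influx, not the
   identity of the substrates.

These close into a negative feedback loop whose steady state satisfies
`λ = (1 − λ/λ_C) Σ a_i` with the composite capacity `a_i = c_i k_i E_i⁰`.
The three factors of `a_i` are not separately identifiable from growth
data, so the package exposes only their product (units 1/h). For a single
substrate, `a_i = λ_i/(1 − λ_i/λ_C)`; eliminating the capacities gives the
growth-rate composition formula

```
λ_mix = S / (1 + S/λ_C),   S = Σ_i λ_i/(1 − λ_i/λ_C).
```

The formula is stated by the underlying theory for two substrates; the
N ≥ 3 case implemented here is the same flux argument applied to more
terms and should be read as a model-consistent extrapolation, not an
experimentally validated claim. Structural consequences, all tested:
`max(λ_i) ≤ λ_mix < λ_C` (the C-line intercept is a hard "speed limit"),
`λ_mix < Σ λ_i`, permutation symmetry, and strict monotonicity in each
rate. Growth at or above `λ_C` on a single carbon source is outside the
model's domain; such inputs raise an error rather than being clamped,
since the capacity transform diverges there.

## Parameters

| Parameter | Units | Default | Meaning |
|---|---|---|---|
| `lambda_c` | 1/h | 1.16 | C-line horizontal intercept for the K-12 reference strain; the carbon-limited maximum growth rate. The published strain constant is used as-is for the headline analysis — the raw expression data behind it are not re-fit here. |
| `e0` | Miller units/OD (arbitrary) | — | Operon-specific unrepressed expression; scales out of every growth-rate prediction. |
| `a_i` | 1/h | — | Effective substrate capacity at zero repression. |

## Validation pipeline

`predict_pairs` applies the composition formula to each substrate pair of
a growth table; `run_full_analysis` adds the summary statistics:

* **Regression.** OLS of measured on predicted rates over the co-utilized
  (group A) pairs, via statsmodels; 95% CIs from the t distribution with
  n−2 df. A perfect model gives slope 1, offset 0.
* **Relative deviation.** `|measured − predicted| / predicted`. The
  denominator is a convention choice; `denominator="measured"` is
  available. On the reference table the switch is negligible for group A
  (2.59% vs 2.61%) but raises the group-B mean from 11.8% to 13.7%, since
  group-B measurements sit well below their predictions.
* **Group comparison.** Arithmetic mean deviation per group, plus a
  two-sided Mann–Whitney U test between the group-A and group-B deviation
  samples. For combined sizes ≤ 30 the p-value is exact: the permutation
  distribution of the rank sum over all C(n+m, n) group assignments is
  computed by a subset-sum dynamic programme over doubled midranks
  (ties handled by midranks within the exact distribution; counts fit in
  int64 up to n+m = 30). Two-sided p = 2·min(tail probabilities), capped
  at 1. Larger samples fall back to the tie-corrected normal
  approximation with continuity correction (scipy), flagged in the
  result. The exact path is cross-checked in the tests against full
  enumeration (n+m ≤ 10, with ties) and against scipy's exact method
  (tie-free cases).
* **Sensitivity.** The report also recomputes the group deviation means
  with the speed limit shifted by ±0.05/h (the published uncertainty of
  the strain constant), as a robustness read-out; the headline statistics
  always use the constant itself.
* **Property checks.** Predictions below `λ_C` and sub-additive; for each
  group-A pair, the inferred uptake flux ratio
  `(1 − λ_mix/λ_C)/(1 − λ_i/λ_C)` < 1 for both substrates — co-utilization
  must *reduce* each substrate's uptake under the shared feedback.

The reference table ships embedded (printed two-decimal values, stored
verbatim; full float precision is carried everywhere else). The
glucose+glycerol pair, printed under both group-B columns, is ingested
once: it is a single unordered pair, and the group comparison is robust to
either convention.

## C-line fitting

`fit_cline` regresses expression on growth rate (the direction in which
such data are plotted; errors in the rate variable are ignored) and
reports `λ_C = −intercept/slope`. This ratio has no exact finite-sample
distribution, so the 95% CI is a case-resampling bootstrap (default
10 000 replicates, fixed default seed; replicates without a negative
slope are discarded and > 50% discards is an error). Fieller's theorem
would be the classical closed-form alternative. Whether the published
"± 0.05/h" on the strain constant is a standard error or a 95% CI is not
stated in the source; the package reports its own bootstrap interval and
never equates the two.

## Synthetic studies

`generate_growth_study` emulates the reference study design: 3 "lower" ×
5 "upper" substrates (group A = lower×upper pairs, group B = upper×upper
pairs), true single rates uniform on (0.30, 0.95)/h, true mixed rates from
the composition formula, and observed rates = truth × unit-mean log-normal
noise with cv 0.05 (the documented between-replicate variability; the
log-normal keeps rates positive, and draws that would cross `λ_C` — a
multi-sigma event — are redrawn). Everything is deterministic given the
master seed, with independent sub-streams for rates and noise.

Group-B interference is modelled as the slower member's capacity being
multiplied by `suppression_factor` (the faster substrate excludes the
slower one's uptake, as glucose does). The default 0.2 reproduces the
qualitative signature of the reference data, where a group-B mixed rate
falls near the faster substrate's single rate; milder factors shrink the
group-B bias smoothly to zero at 1.0. For strongly asymmetric pairs the
bias is small regardless (the fast substrate dominates `S` and saturation
near `λ_C` compresses differences), so group separation is an
on-average property across studies, not a per-study guarantee. No
mechanistic fidelity to inducer exclusion or FBP feedback is claimed; the
generator exists to exercise the pipeline and calibrate estimators.
Synthetic data lack several features of real growth experiments —
replicate structure (one observation per condition), shared batch
effects, substrate-specific noise, and deviations of real singles from
exact C-line behaviour — so passing tests demonstrate correctness of the
machinery and calibration under the stated noise model, not experimental
validity.

## Recovering the speed limit from growth data

`recover_lambda_c` minimizes `Σ_A (measured − λ_mix(λ_1, λ_2; λ_C))²`
over group-A pairs by bounded Brent search on
`(max single rate + 10⁻⁶, 10/h)` (xatol 10⁻¹⁰). If the objective is
numerically flat over the bracket, or the minimizer lands on a bracket
endpoint (e.g. measured rates above `λ_1 + λ_2`, which push the estimate
to the upper bound), the data are declared uninformative and an error is
raised rather than a meaningless estimate returned.

The 95% CI is a **parametric bootstrap** under the generative measurement
model rather than case resampling of pairs, for a structural reason: a
substrate's single-rate measurement error is shared by every pair
containing it, and resampling pairs treats those correlated errors as
independent — in calibration runs at the study conditions (15 group-A
pairs, 5% noise) pair resampling covered the truth in only ~82% of
nominal-95% intervals. The parametric scheme estimates the noise cv from
the group-A relative residuals, deflated by the model's log-sensitivity
to the single rates (finite-difference `∂log λ_mix/∂log λ_i`, since
singles noise propagates into the predictions), then redraws unit-mean
log-normal noise *per substrate* (singles) and *per pair* (mixed
measurements) around the fitted model and re-estimates; the percentile
interval over replicates covers the truth in ~93% of calibration runs.
The whole estimator is exploratory: the strain constant is properly
calibrated from expression data, and growth data alone identify it less
sharply (on the reference table it lands at ≈ 1.14/h with a CI of roughly
±0.07).

## Numerical choices

* `solve_steady_state` exists as an independent oracle for the closed
  form: damped fixed-point iteration from λ = 0 with residual tolerance
  10⁻¹², iteration cap 10⁴, and damping `min(0.5, 0.9/(1 + S/λ_C))` — the
  adaptive factor keeps the affine map a contraction for every capacity
  sum (a fixed damping of 0.5 diverges once `S > 3λ_C`).
* Capacity sums use compensated summation (`math.fsum`), which makes the
  composition exactly permutation-invariant.
* The composition round trip (rate → capacity → rate) is exact to 10⁻¹²
  relative over `λ ∈ [0, 0.99 λ_C]`.
* CSV rates are serialized with `repr` (shortest exact decimal), so
  write/read round trips are bit-lossless.
* Degenerate inputs fail loudly and specifically: empty rate lists,
  negative rates or capacities, rates at/above `λ_C`, C-line fits with
  < 3 points, < 2 distinct rates, or non-negative slope, empty comparison
  groups, and unordered duplicate pairs (deduplicated with a warning at
  ingest, rejected in the validated table type).

## Problem sizes

The test suite runs the full reference-table analysis (22 pairs),
1000-instance oracle-equivalence checks, and two 200-replication coverage
studies (C-line bootstrap with 1000 replicates each; growth-table recovery
with 200 bootstrap refits each) — together about half a minute on one
core. These replication counts resolve coverage claims at the ±3% level,
which is what the ≥ 90% assertions require.

## Known limitations

* Steady-state co-utilization only: no diauxie, substrate depletion,
  time-dependent expression, or batch dynamics.
* The model presumes cAMP-Crp is the only regulator of the relevant
  catabolic systems; pairs with additional interactions (inducer
  exclusion, FBP feedback) are expected to deviate and are carried as
  group B data, not modelled mechanistically.
* `c_i`, `k_i`, `E_i⁰` are never exposed individually — only their
  product is identifiable from growth data.
* The N ≥ 3 composition and the growth-data `λ_C` estimator are
  extrapolations beyond what the underlying experiments established.
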