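# Methods

## Model

The package prices an ultra-orphan drug as an exponential function of the
expected number of treated patients `Npt`:

```
PRICE(Npt) = fPRICE · exp[(k / PDP) · (baseline − Npt)],   0 < Npt
```

This is the pricing analogue of first-order exponential decay: the
log-price is linear in the patient count with slope `−k / PDP`, and a
decrease of `PDP` patients multiplies the price by `e^k`. Parameters, with
defaults:

| parameter | units | default | meaning |
|---|---|---|---|
| `f_price` | EUR/patient | 10,000 | full (undiscounted) price at the baseline population |
| `pdp` | patients | 378.9 | price-doubling population |
| `baseline_n` | patients | 1000 | population above which the drug is priced as a normal drug |
| `k` | — | 0.693 | doubling constant |

Assumptions the model makes explicit: a single PDP applies to all orphan
drugs in the jurisdiction under analysis (the premium is uniform, which is
the point — equity across agents); the premium depends only on the treated
population, not on therapeutic value; prices are per-patient annualized
treatment costs in a single currency with no conversion.

**The exponent's parenthesisation.** The function is evaluated as
`exp[(k / PDP) · (baseline − Npt)]`. This is the only reading under which
the reference value for a 330-patient drug (355,740 EUR at PDP = 130) and
the slope identity `−k / PDP` both hold, and it is the one adopted
throughout.

**The doubling constant.** The default `k = 0.693` follows the half-life
convention of rounding `ln 2` to three decimals; it reproduces the reference
prices digit for digit but makes the per-PDP ratio `e^0.693 ≈ 1.9997`
(within 1.5 × 10⁻⁴ of 2). Passing `k = orphanpdp.LN2` gives exact doubling.
All calibrators take `k` as an argument so estimates stay consistent with
whichever convention the caller prices with.

**Above the baseline.** Drugs treating more than `baseline_n` patients are
outside the orphan regime and carry no premium. `price_at` evaluates the raw
formula there (useful for plotting the mathematical curve) but emits an
`OrphanRegimeWarning`; with `strict=True` it clamps the price to `f_price`,
the policy-faithful behaviour. Calibration retains above-baseline points
with the same warning rather than silently dropping data.

Patient counts are real-valued throughout: estimators legitimately return
non-integer populations (e.g. 378.9), and rounding to whole patients is a
reporting step, not a model step.

## Calibration

**Two-point estimation.** For observations `(n₁, p₁)` and `(n₂, p₂)` with
`n₁ < n₂`, solving the model for the unique PDP through both points gives

```
PDP = k · (n₂ − n₁) / ln(p₁ / p₂)
```

(derived by taking the log-ratio of the two model prices). The estimate is
order-invariant and exact on model-generated points. Degenerate inputs are
rejected with specific errors: equal patient counts (no slope), equal prices
(infinite PDP), or a cheaper drug treating fewer patients (positive
log-price slope, inconsistent with the model).

**Log-linear regression.** With three or more observations,
`ln(price)` is regressed on the patient count by unweighted ordinary least
squares (statsmodels OLS) and `PDP = −k / slope`, rejecting non-negative
slopes. Natural logarithms are required: the slope-to-PDP inversion
`−k / slope` only yields patient-count units when slope and `k` share the
natural-log scale. Unweighted OLS is the deliberate estimand; weighting by
population or price changes the target quantity and is out of scope. Two
points are redirected to the closed form — OLS through two points adds
nothing and hides the degeneracy diagnostics.

By default both slope and intercept are free, and the implied full price
`f_price_hat = exp(intercept + slope · baseline_n)` is reported. A
constrained mode (`fix_f_price`) forces the line through
`(baseline_n, ln f_price)` and estimates the slope alone, via through-origin
OLS on shifted coordinates. For that constrained fit the reported `R²` is
the squared correlation between observed and fitted log-prices — the centred
`R²` of a constrained fit can be negative, and a diagnostic bounded in
[0, 1] is more useful for a goodness screen. Residuals, `R²` and the slope
standard error are all on the log-price scale; no further inference
(intervals, robust fits, model selection across PDP scenarios) is provided.

## Synthetic data

`generate(SyntheticConfig)` emulates the kind of nationwide orphan-drug
dataset the model is calibrated on: by default 17 drugs with patient counts
on [50, 999] — strictly inside the orphan regime — priced from a known
`PricingModel` with multiplicative log-normal noise,
`price_i = PRICE(n_i) · exp(ε_i)`, `ε_i ~ N(0, σ_log²)`, using numpy's
seeded PCG64 generator for cross-run determinism. Log-normal noise is the
natural choice here because it is additive on exactly the scale the
regression fits, so the noiseless generator → regression round trip is an
identity and σ_log is directly the residual standard deviation the fit
should report. Patient counts are drawn as uniform integers without
replacement by default (duplicate-x designs at n = 17 are avoided); an
evenly-spaced scheme is available for grid-style designs.

What the generator does **not** emulate: real orphan-drug tables mix
indications, dosing schedules and launch years, their "expected patients"
are themselves estimates, and their deviations from any single-PDP curve are
structural, not i.i.d. log-normal. Passing recovery tests therefore shows
the estimators are correct and well-conditioned under the model's own
assumptions — not that any real market obeys a single PDP.

## Numerical and testing choices

* Recovery tolerances in the stochastic tests were fixed by simulation
  before being frozen: at 100 drugs with σ_log = 0.3 and true PDP = 200,
  single-seed calibration errors are ~1–3%, so the test asserts 10%; over
  200 seeded replicates of 17 drugs with σ_log = 0.2 the median estimate
  sits within ~2% of truth, so the test asserts 5% on the median.
* The replicate study uses 200 seeds of a 17-drug table — large enough for a
  stable median, small enough that the whole suite runs in about a second.
* Analytic identities (inverse round trip, slope/finite-difference
  agreement, noiseless recovery) are asserted at 10⁻⁶–10⁻⁹ relative;
  property tests run derandomised (hypothesis profile in `tests/conftest.py`).
* CSV tables are comma-separated UTF-8 with dot decimals and no thousands
  separators, so read ∘ write is an identity; formatted amounts like
  "355,740 EUR" appear only in rendered CLI text, never in files.
* Reported rounding conventions: prices to the nearest EUR, PDP to one
  decimal (two-point fits additionally to whole patients). JSON output
  always carries full precision.

## Extension: price-halving population (PHP)

For high-volume drugs under price-volume agreements the relationship runs
the other way: price falls as the treated population grows past the
baseline. `php_price_at` implements the sign-mirrored form
`f_price · exp[−(k / PHP) · (n − baseline)]` for `n ≥ baseline`, halving
every PHP additional patients (exactly under `k = ln 2`). It is a
reconstruction of the price-volume counterpart from the shared conceptual
framework, provided for symmetry; it is not part of the orphan pricing
equation and is guarded by a domain error below the baseline.

## Limitations

* The model is single-country by construction (the baseline of 1000 patients
  is a nationwide count for a country of roughly 60 million people);
  adapting it elsewhere means re-choosing `baseline_n` and recalibrating.
* No uncertainty quantification beyond the OLS slope standard error.
* The choice of PDP is a policy decision; the package calibrates and
  evaluates candidate values but does not select among them.
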