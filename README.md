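# orphanpdp

Exponential pricing model for orphan drugs, with calibration of its one free
shape parameter — the **price-doubling population (PDP)** — from observed
price/patient data.

## The problem

Orphan-drug prices are set above value-based levels precisely because the
treated populations are tiny, but in practice the price-vs-population
relationship is negotiated case by case with no quantitative rule. This
package implements an explicit rule for national pricing authorities and
health-technology-assessment analysts: below a baseline population (default
1000 patients nationwide, the "ultra-orphan" regime), the cost of treatment
per patient grows exponentially as the number of treated patients shrinks,

```
PRICE(Npt) = fPRICE · exp[(k / PDP) · (baseline − Npt)]
```

where `Npt` is the expected number of treated patients, `fPRICE` is the full
(undiscounted) price per patient at the baseline population, `k` is the
doubling constant (0.693 by convention; an exact-`ln 2` switch is provided),
and `PDP` is the decrease in patients that doubles the price. On a log-price
axis the curve is a straight line with slope `−k / PDP`, so the model is
calibrated two ways:

* **two-point estimation** — the unique PDP through two observations, in
  closed form: `PDP = k · (n₂ − n₁) / ln(price₁ / price₂)`;
* **log-linear regression** — ordinary least squares of `ln(price)` on the
  patient count over a drug table, with `PDP = −k / slope`.

A seeded synthetic generator produces drug tables from a known model with
multiplicative log-normal noise, so every estimator is testable end to end
with no external data.

## Worked example

Price a drug expected to treat 330 patients under PDP = 130 (full price
10,000 EUR at a 1000-patient baseline):

```
$ orphanpdp price --patients 330 --pdp 130
355,740 EUR
```

Recover the PDP from two observed drugs — one treating 330 patients at
355,740 EUR, one treating 990 patients at 10,491 EUR:

```
$ orphanpdp fit2 --point 330:355740 --point 990:10491
PDP = 129.8 patients (~130)
```

The second drug does not lie exactly on the PDP = 130 curve, so the estimate
is 129.8 rather than 130.0 — a minimal estimation error.

Generate a noiseless 17-drug table from a known model and calibrate it back
by regression:

```
$ orphanpdp simulate --pdp 378.9 --n 17 --sigma 0 --seed 1 -o t.csv
wrote 17 drugs to t.csv (true PDP=378.9, f_price=10000, sigma_log=0, seed=1)
$ orphanpdp fit --input t.csv
n_obs     = 17
slope     = -0.0018290 per patient
intercept = 11.0393 (ln EUR)
PDP       = 378.9 patients
f_price   = 10,000 EUR at baseline 1000
R^2       = 1.0000
```

The fitted log-price slope of −0.001829 per patient inverts to a PDP of
378.9 patients: at that calibration, every 379 fewer treated patients
doubles the per-patient price. Tabulate scenario curves (smaller PDP means a
steeper premium):

```
$ orphanpdp curve --pdp-list 150,200,300 --from 700 --to 1000 --step 100
patients,price_pdp_150,price_pdp_200,price_pdp_300
700,39988.23,28278.03,19997.06
800,25193.48,19997.06,15872.45
900,15872.45,14141.09,12598.59
1000,10000.00,10000.00,10000.00
```

The same operations are available as library functions
(`orphanpdp.price_at`, `two_point_pdp`, `fit_regression`, `pdp_from_slope`,
`generate`, …); drug tables are plain CSV with columns
`drug,patients,cost_per_patient_eur`, fit results serialize to JSON.

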