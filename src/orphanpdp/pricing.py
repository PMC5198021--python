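"""Exponential orphan-drug pricing: model, calibration, I/O and simulation.

The core relationship prices an orphan drug as a function of the expected
number of treated patients ``Npt``::

    PRICE(Npt) = fPRICE * exp((k / PDP) * (baseline_n - Npt))

where ``fPRICE`` is the full (undiscounted) price per patient assumed at the
baseline population, ``PDP`` is the *price-doubling population* -- the
decrease in treated patients that doubles the price -- and ``k`` is the
doubling constant (0.693 by convention, ``ln 2`` for exact doubling).  On a
log-price axis the curve is a straight line with slope ``-k / PDP``, which is
what makes both calibration routes below elementary:

* two-point estimation: the unique PDP through two (patients, price)
  observations, in closed form;
* log-linear calibration: ordinary least squares of ``ln(price)`` on the
  patient count over a drug table, with ``PDP = -k / slope``.

The module is laid out in the order the method runs: model evaluation,
calibration, table/report I/O, synthetic data generation.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "LN2",
    "DEFAULT_K",
    "DEFAULT_BASELINE_N",
    "DEFAULT_F_PRICE",
    "PricingError",
    "InvalidFitError",
    "InsufficientDataError",
    "SchemaError",
    "OrphanRegimeWarning",
    "PricingModel",
    "PricePoint",
    "price_at",
    "patients_at_price",
    "price_curve",
    "log_price_slope",
    "php_price_at",
    "TwoPointFit",
    "RegressionFit",
    "two_point_pdp",
    "fit_regression",
    "pdp_from_slope",
    "DrugTable",
    "read_drug_table",
    "write_drug_table",
    "write_fit_report",
    "read_fit_report",
    "SyntheticConfig",
    "generate",
]

# --------------------------------------------------------------------------
# Constants, errors, warnings
# --------------------------------------------------------------------------

#: Doubling constant as conventionally printed (half-life style rounding).
DEFAULT_K: float = 0.693

#: Exact doubling constant, for users who want price(n - PDP) == 2 * price(n)
#: to machine precision rather than to ~1.5e-4 relative.
LN2: float = math.log(2.0)

#: Default baseline population: drugs treating more patients than this are
#: handled as "normal" drugs with no orphan price premium.
DEFAULT_BASELINE_N: float = 1000.0

#: Default full price (EUR per patient) at the baseline population.
DEFAULT_F_PRICE: float = 10_000.0

DRUG_TABLE_COLUMNS = ("drug", "patients", "cost_per_patient_eur")


class PricingError(ValueError):
    """Domain error: an argument violates a model precondition."""


class InvalidFitError(PricingError):
    """The data admit no valid (positive, finite) PDP."""


class InsufficientDataError(InvalidFitError):
    """Too few observations for the requested estimator."""


class SchemaError(PricingError):
    """A drug table does not satisfy the column contract."""


class OrphanRegimeWarning(UserWarning):
    """Raised when evaluating the orphan model above the baseline population."""


def _require_finite_positive(**named: float) -> None:
    for name, value in named.items():
        if not math.isfinite(value) or value <= 0:
            raise PricingError(f"{name} must be a finite positive number, got {value!r}")


# --------------------------------------------------------------------------
# Model: exact evaluation of the exponential price function
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PricingModel:
    """Parameter set of the exponential orphan pricing function.

    Parameters
    ----------
    f_price : float
        Full price in EUR per patient at the baseline population.
    pdp : float
        Price-doubling population in patients.
    baseline_n : float
        Population above which the drug is priced as a normal drug.
    k : float
        Doubling constant; 0.693 by default, use :data:`LN2` for exact
        doubling.
    """

    f_price: float = DEFAULT_F_PRICE
    pdp: float = 378.9
    baseline_n: float = DEFAULT_BASELINE_N
    k: float = DEFAULT_K

    def __post_init__(self) -> None:
        _require_finite_positive(
            f_price=self.f_price, pdp=self.pdp, baseline_n=self.baseline_n, k=self.k
        )


@dataclass(frozen=True)
class PricePoint:
    """One observed drug: label, expected treated patients, EUR per patient."""

    drug: str
    n_patients: float
    price: float

    def __post_init__(self) -> None:
        _require_finite_positive(n_patients=self.n_patients, price=self.price)


def price_at(model: PricingModel, n_patients: float, *, strict: bool = False) -> float:
    """Cost of treatment (EUR per patient) for ``n_patients`` treated patients.

    Evaluates ``f_price * exp((k / pdp) * (baseline_n - n_patients))``.  The
    function is strictly decreasing in the patient count and equals
    ``f_price`` exactly at the baseline.

    Above the baseline population the drug is formally outside the orphan
    regime: with ``strict=True`` the price is clamped to ``f_price`` (no
    orphan premium, no discount); otherwise the raw formula is evaluated and
    an :class:`OrphanRegimeWarning` is emitted.
    """
    _require_finite_positive(n_patients=n_patients)
    if n_patients > model.baseline_n:
        if strict:
            return model.f_price
        warnings.warn(
            f"n_patients={n_patients:g} exceeds the baseline population "
            f"{model.baseline_n:g}; the drug is outside the orphan regime",
            OrphanRegimeWarning,
            stacklevel=2,
        )
    return model.f_price * math.exp(model.k / model.pdp * (model.baseline_n - n_patients))


def patients_at_price(model: PricingModel, price: float) -> float:
    """Analytic inverse of :func:`price_at`: patient count at a given price.

    Returns a real-valued population, ``baseline_n - (pdp / k) * ln(price /
    f_price)``; round-trips with :func:`price_at` to floating precision.
    """
    _require_finite_positive(price=price)
    return model.baseline_n - model.pdp / model.k * math.log(price / model.f_price)


def price_curve(
    model: PricingModel, n_min: float, n_max: float, step: float
) -> list[tuple[float, float]]:
    """Tabulate the price function on the inclusive grid ``n_min..n_max``.

    Returns ``(n, price)`` pairs ordered by ascending patient count, with
    ``floor((n_max - n_min) / step) + 1`` rows.
    """
    _require_finite_positive(n_min=n_min, step=step)
    if not math.isfinite(n_max) or n_max < n_min:
        raise PricingError(f"invalid grid: n_min={n_min!r}, n_max={n_max!r}")
    count = math.floor((n_max - n_min) / step) + 1
    grid = n_min + step * np.arange(count)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OrphanRegimeWarning)
        return [(float(n), price_at(model, float(n))) for n in grid]


def log_price_slope(model: PricingModel) -> float:
    """Slope of ``ln(price)`` versus patient count: ``-k / pdp`` per patient.

    The matching intercept (log-price extrapolated to zero patients) is
    ``ln(f_price) + k * baseline_n / pdp``.
    """
    return -model.k / model.pdp


def php_price_at(
    model: PricingModel, php: float, n_patients: float
) -> float:
    """Price under the mirrored price-volume (price-halving) model.

    For populations at or above the baseline, price-volume agreements reduce
    the unit price as volume grows; here the price halves for every ``php``
    additional patients (exactly when ``k = ln 2``):
    ``f_price * exp(-(k / php) * (n_patients - baseline_n))``.

    This mirror form is a reconstruction of the price-volume counterpart to
    the orphan model; it is not part of the orphan pricing equation itself.
    """
    _require_finite_positive(php=php, n_patients=n_patients)
    if n_patients < model.baseline_n:
        raise PricingError(
            f"n_patients={n_patients:g} is below the baseline population "
            f"{model.baseline_n:g}: use the orphan (PDP) model price_at instead"
        )
    return model.f_price * math.exp(-model.k / php * (n_patients - model.baseline_n))


# --------------------------------------------------------------------------
# Calibration: estimating PDP from observed (patients, price) data
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoPointFit:
    """Closed-form PDP estimate through exactly two observations."""

    pdp_hat: float
    points: tuple[PricePoint, PricePoint]
    k: float

    @property
    def pdp_rounded(self) -> float:
        """PDP rounded to whole patients, the scale used for reporting."""
        return float(round(self.pdp_hat))


@dataclass(frozen=True)
class RegressionFit:
    """Log-linear calibration result: OLS of ln(price) on patient count."""

    slope: float
    intercept: float
    pdp_hat: float
    f_price_hat: float
    n_obs: int
    r_squared: float
    residuals: tuple[float, ...]
    k: float
    slope_stderr: float
    baseline_n: float


def two_point_pdp(
    p1: PricePoint, p2: PricePoint, k: float = DEFAULT_K
) -> TwoPointFit:
    """Estimate PDP from two (patients, price) observations, in closed form.

    With the points ordered so that ``n1 < n2``, the unique PDP through both
    is ``k * (n2 - n1) / ln(price1 / price2)``.  The estimate is invariant to
    the order in which the points are passed; two points generated from a
    :class:`PricingModel` recover its PDP exactly.

    Raises
    ------
    InvalidFitError
        If the patient counts coincide (no slope), the prices coincide
        (infinite PDP), or the cheaper drug treats fewer patients (positive
        log-price slope, inconsistent with the orphan model).
    """
    _require_finite_positive(k=k)
    lo, hi = sorted((p1, p2), key=lambda p: p.n_patients)
    if lo.n_patients == hi.n_patients:
        raise InvalidFitError(
            f"degenerate input: both points have n_patients={lo.n_patients:g}"
        )
    if lo.price == hi.price:
        raise InvalidFitError(
            "equal prices at different patient counts imply an infinite PDP"
        )
    if lo.price < hi.price:
        raise InvalidFitError(
            f"price must decrease as patients increase, but "
            f"{lo.drug!r} ({lo.n_patients:g} patients, {lo.price:g} EUR) is cheaper "
            f"than {hi.drug!r} ({hi.n_patients:g} patients, {hi.price:g} EUR)"
        )
    pdp_hat = k * (hi.n_patients - lo.n_patients) / math.log(lo.price / hi.price)
    return TwoPointFit(pdp_hat=pdp_hat, points=(p1, p2), k=k)


def fit_regression(
    data: Sequence[PricePoint],
    k: float = DEFAULT_K,
    fix_f_price: float | None = None,
    baseline_n: float = DEFAULT_BASELINE_N,
) -> RegressionFit:
    """Calibrate PDP by ordinary least squares of ln(price) on patient count.

    The natural-log transform turns the exponential price curve into a line
    with slope ``-k / PDP``, so ``pdp_hat = -k / slope``.  By default both
    slope and intercept are free and the implied full price at ``baseline_n``
    is reported as ``f_price_hat``.  With ``fix_f_price`` the line is
    constrained through ``(baseline_n, ln(fix_f_price))`` and only the slope
    is estimated.

    Residuals and the fit diagnostics are on the log-price scale.  In the
    constrained mode ``r_squared`` is the squared correlation between
    observed and fitted log-prices.

    Raises
    ------
    InsufficientDataError
        With fewer than 3 points (two points reduce to :func:`two_point_pdp`).
    InvalidFitError
        If the fitted slope is non-negative: prices that do not fall with the
        patient count are inconsistent with the orphan model.
    """
    _require_finite_positive(k=k, baseline_n=baseline_n)
    if len(data) < 3:
        raise InsufficientDataError(
            f"log-linear calibration needs at least 3 points, got {len(data)}; "
            "for exactly two points use two_point_pdp"
        )
    n = np.asarray([p.n_patients for p in data], dtype=float)
    y = np.log([p.price for p in data])
    if np.ptp(n) == 0:
        raise InvalidFitError("all observations share one patient count; no slope")
    n_above = n[n >= baseline_n]
    if n_above.size:
        warnings.warn(
            f"{n_above.size} point(s) at or above the baseline population "
            f"{baseline_n:g} retained in the calibration",
            OrphanRegimeWarning,
            stacklevel=2,
        )

    if fix_f_price is None:
        res = sm.OLS(y, sm.add_constant(n)).fit()
        intercept, slope = res.params
        r_squared = float(res.rsquared)
        resid = res.resid
        slope_se = float(res.bse[1])
    else:
        _require_finite_positive(fix_f_price=fix_f_price)
        # Constrain the line through (baseline_n, ln fix_f_price): regress the
        # shifted response on the shifted regressor with no intercept.
        res = sm.OLS(y - math.log(fix_f_price), (n - baseline_n)[:, None]).fit()
        slope = float(res.params[0])
        intercept = math.log(fix_f_price) - slope * baseline_n
        fitted = intercept + slope * n
        resid = y - fitted
        r_squared = float(np.corrcoef(y, fitted)[0, 1] ** 2) if np.ptp(fitted) else 0.0
        slope_se = float(res.bse[0])

    if slope >= 0:
        raise InvalidFitError(
            f"fitted slope {slope:.6g} is non-negative: prices do not decrease "
            "with patient count, inconsistent with the orphan model"
        )
    return RegressionFit(
        slope=float(slope),
        intercept=float(intercept),
        pdp_hat=pdp_from_slope(slope, k),
        f_price_hat=float(math.exp(intercept + slope * baseline_n)),
        n_obs=len(data),
        r_squared=r_squared,
        residuals=tuple(float(r) for r in resid),
        k=k,
        slope_stderr=slope_se,
        baseline_n=baseline_n,
    )


def pdp_from_slope(slope: float, k: float = DEFAULT_K) -> float:
    """Invert a log-price slope (per patient) into a PDP: ``-k / slope``."""
    _require_finite_positive(k=k)
    if not math.isfinite(slope) or slope >= 0:
        raise PricingError(f"slope must be finite and negative, got {slope!r}")
    return -k / slope


# --------------------------------------------------------------------------
# I/O: drug tables (CSV) and fit reports (JSON)
# --------------------------------------------------------------------------


@dataclass
class DrugTable:
    """Ordered collection of drug observations with a provenance label."""

    rows: list[PricePoint] = field(default_factory=list)
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug": [p.drug for p in self.rows],
                "patients": [p.n_patients for p in self.rows],
                "cost_per_patient_eur": [p.price for p in self.rows],
            }
        )


def read_drug_table(path: str | Path) -> DrugTable:
    """Read a drug table CSV with columns drug, patients, cost_per_patient_eur.

    Rejects missing columns (:class:`SchemaError`) and non-numeric or
    non-positive cells (:class:`PricingError` naming the offending row and
    column).  Input order is preserved; an empty-but-headed file yields an
    empty table with a warning.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in DRUG_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; "
            f"expected {list(DRUG_TABLE_COLUMNS)}"
        )
    if frame.empty:
        warnings.warn(f"{path}: drug table has a header but no rows", stacklevel=2)
        return DrugTable(rows=[], source_label=str(path))
    rows: list[PricePoint] = []
    for i, rec in enumerate(frame.itertuples(index=False), start=2):  # header is row 1
        point_kwargs = {}
        for column, attr in (("patients", "n_patients"), ("cost_per_patient_eur", "price")):
            raw = getattr(rec, column)
            value = pd.to_numeric(raw, errors="coerce")
            if pd.isna(value):
                raise PricingError(
                    f"{path}, row {i}, column {column!r}: unparsable value {raw!r}"
                )
            if value <= 0:
                raise PricingError(
                    f"{path}, row {i}, column {column!r}: must be positive, got {value}"
                )
            point_kwargs[attr] = float(value)
        rows.append(PricePoint(drug=str(rec.drug), **point_kwargs))
    return DrugTable(rows=rows, source_label=str(path))


def write_drug_table(table: DrugTable, path: str | Path) -> None:
    """Write a drug table to CSV (comma-separated, dot decimals, no grouping)."""
    table.to_frame().to_csv(path, index=False)


def _fit_to_dict(fit: TwoPointFit | RegressionFit) -> dict:
    payload = dataclasses.asdict(fit)
    if isinstance(fit, TwoPointFit):
        payload["fit_type"] = "two_point"
        payload["pdp_rounded"] = fit.pdp_rounded
    else:
        payload["fit_type"] = "regression"
        payload["residuals"] = list(fit.residuals)
    return payload


def write_fit_report(fit: TwoPointFit | RegressionFit, path: str | Path) -> None:
    """Serialize a fit to a JSON report; read back with :func:`read_fit_report`."""
    report = _fit_to_dict(fit)
    report["metadata"] = {
        "generator": "orphanpdp",
        "created_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def read_fit_report(path: str | Path) -> dict:
    """Load a JSON fit report written by :func:`write_fit_report`."""
    return json.loads(Path(path).read_text())


# --------------------------------------------------------------------------
# Synthetic data: seeded drug tables from a known model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticConfig:
    """Settings for generating a drug table from a known pricing model.

    Patient counts are drawn on ``n_range`` (inclusive) either as uniform
    integers without replacement (default, avoids duplicate-x designs at
    small n) or evenly spaced; prices are the model prices perturbed by
    multiplicative log-normal noise, ``price_i = price_at(n_i) * exp(eps_i)``
    with ``eps_i ~ Normal(0, sigma_log^2)``.  The defaults mirror the kind of
    nationwide orphan-drug dataset the model is calibrated on: 17 drugs, all
    below the 1000-patient baseline.
    """

    true_model: PricingModel = PricingModel()
    n_drugs: int = 17
    n_range: tuple[float, float] = (50.0, 999.0)
    sigma_log: float = 0.0
    seed: int = 0
    sampling: Literal["uniform", "even"] = "uniform"

    def __post_init__(self) -> None:
        lo, hi = self.n_range
        if not (0 < lo <= hi):
            raise PricingError(f"invalid n_range {self.n_range!r}")
        if hi >= self.true_model.baseline_n:
            raise PricingError(
                f"n_range upper bound {hi:g} must stay below the baseline "
                f"population {self.true_model.baseline_n:g} (orphan regime)"
            )
        if self.sigma_log < 0:
            raise PricingError(f"sigma_log must be >= 0, got {self.sigma_log!r}")
        if self.n_drugs < 2:
            raise PricingError(f"n_drugs must be >= 2, got {self.n_drugs}")
        if self.sampling not in ("uniform", "even"):
            raise PricingError(f"unknown sampling scheme {self.sampling!r}")
        if self.sampling == "uniform" and self.n_drugs > int(hi) - int(lo) + 1:
            raise PricingError(
                f"cannot draw {self.n_drugs} distinct integer patient counts "
                f"from [{lo:g}, {hi:g}] without replacement"
            )


def generate(config: SyntheticConfig) -> DrugTable:
    """Generate a seeded synthetic drug table from ``config.true_model``.

    Deterministic for a fixed seed; with ``sigma_log=0`` every price lies
    exactly on the model curve, so a subsequent regression recovers the true
    PDP to floating precision.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.n_range
    if config.sampling == "uniform":
        counts = np.sort(
            rng.choice(np.arange(int(lo), int(hi) + 1), size=config.n_drugs, replace=False)
        ).astype(float)
    else:
        counts = np.linspace(lo, hi, config.n_drugs)
    eps = rng.normal(0.0, config.sigma_log, size=config.n_drugs)
    rows = [
        PricePoint(
            drug=f"drug_{i + 1:03d}",
            n_patients=float(n),
            price=price_at(config.true_model, float(n)) * math.exp(float(e)),
        )
        for i, (n, e) in enumerate(zip(counts, eps))
    ]
    return DrugTable(rows=rows, source_label=f"synthetic(seed={config.seed})")
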