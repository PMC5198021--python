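"""Two-point and log-linear estimation of the price-doubling population."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from orphanpdp import (
    InsufficientDataError,
    InvalidFitError,
    OrphanRegimeWarning,
    PricePoint,
    PricingError,
    PricingModel,
    SyntheticConfig,
    fit_regression,
    generate,
    log_price_slope,
    pdp_from_slope,
    price_at,
    two_point_pdp,
)


def model_points(model: PricingModel, counts) -> list[PricePoint]:
    return [
        PricePoint(drug=f"d{i}", n_patients=n, price=price_at(model, n))
        for i, n in enumerate(counts)
    ]


class TestTwoPointPdp:
    def test_eculizumab_bosentan_recovers_pdp_130(self, eculizumab, bosentan):
        """The printed pairs reproduce PDP = 130 with minimal estimation error."""
        fit = two_point_pdp(eculizumab, bosentan)
        assert fit.pdp_hat == pytest.approx(129.8, abs=0.05)
        assert fit.pdp_rounded == 130

    def test_order_invariance(self, eculizumab, bosentan):
        assert two_point_pdp(eculizumab, bosentan).pdp_hat == pytest.approx(
            two_point_pdp(bosentan, eculizumab).pdp_hat, rel=1e-15
        )

    @given(pdp=st.floats(50, 600), n1=st.floats(30, 400), n2=st.floats(450, 999))
    def test_exact_recovery_from_model_generated_points(self, pdp, n1, n2):
        model = PricingModel(pdp=pdp)
        p1, p2 = model_points(model, [n1, n2])
        assert two_point_pdp(p1, p2).pdp_hat == pytest.approx(pdp, rel=1e-12)

    def test_equal_patient_counts_rejected(self):
        a = PricePoint("a", 100, 20_000)
        b = PricePoint("b", 100, 30_000)
        with pytest.raises(InvalidFitError, match="degenerate"):
            two_point_pdp(a, b)

    def test_equal_prices_rejected(self):
        a = PricePoint("a", 100, 5_000)
        b = PricePoint("b", 300, 5_000)
        with pytest.raises(InvalidFitError, match="infinite"):
            two_point_pdp(a, b)

    def test_increasing_prices_rejected_naming_monotonicity(self):
        cheap_rare = PricePoint("cheap_rare", 100, 1_000)
        dear_common = PricePoint("dear_common", 900, 50_000)
        with pytest.raises(InvalidFitError, match="decrease"):
            two_point_pdp(cheap_rare, dear_common)


class TestFitRegression:
    def test_noiseless_17_points_reproduce_printed_slope_and_pdp(self):
        model = PricingModel(f_price=10_000, pdp=378.9)
        data = model_points(model, np.linspace(50, 990, 17))
        fit = fit_regression(data)
        assert fit.slope == pytest.approx(-0.0018290, abs=5e-8)
        assert fit.pdp_hat == pytest.approx(378.9, abs=0.05)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.f_price_hat == pytest.approx(10_000, rel=1e-9)

    @given(pdp=st.floats(50, 600))
    def test_noiseless_round_trip_randomized_pdp(self, pdp):
        data = model_points(PricingModel(pdp=pdp), np.linspace(60, 950, 12))
        assert fit_regression(data).pdp_hat == pytest.approx(pdp, rel=1e-6)

    def test_noisy_recovery_within_ten_percent(self):
        cfg = SyntheticConfig(
            true_model=PricingModel(pdp=200),
            n_drugs=100,
            sigma_log=0.3,
            seed=42,
        )
        fit = fit_regression(generate(cfg).rows)
        assert fit.pdp_hat == pytest.approx(200, rel=0.10)

    def test_median_recovery_over_200_replicates(self):
        """Repeated noisy calibrations centre on the true PDP."""
        true_pdp = 378.9
        estimates = [
            fit_regression(
                generate(
                    SyntheticConfig(
                        true_model=PricingModel(pdp=true_pdp),
                        n_drugs=17,
                        sigma_log=0.2,
                        seed=10_000 + rep,
                    )
                ).rows
            ).pdp_hat
            for rep in range(200)
        ]
        assert float(np.median(estimates)) == pytest.approx(true_pdp, rel=0.05)

    def test_consistent_with_two_point_on_noiseless_data(self):
        model = PricingModel(pdp=250)
        data = model_points(model, np.linspace(80, 900, 9))
        reg = fit_regression(data)
        two = two_point_pdp(data[0], data[-1])
        assert reg.pdp_hat == pytest.approx(two.pdp_hat, rel=1e-6)

    def test_scale_equivariance_of_slope(self):
        model = PricingModel(pdp=300)
        data = model_points(model, np.linspace(70, 850, 8))
        rng = np.random.default_rng(7)
        noisy = [
            PricePoint(p.drug, p.n_patients, p.price * math.exp(rng.normal(0, 0.2)))
            for p in data
        ]
        scaled = [PricePoint(p.drug, p.n_patients, p.price * 3.7) for p in noisy]
        f1, f2 = fit_regression(noisy), fit_regression(scaled)
        assert f1.slope == pytest.approx(f2.slope, rel=1e-12)
        assert f1.pdp_hat == pytest.approx(f2.pdp_hat, rel=1e-12)
        assert f2.intercept - f1.intercept == pytest.approx(math.log(3.7), rel=1e-9)

    def test_constrained_fit_passes_through_fixed_full_price(self):
        rng = np.random.default_rng(3)
        model = PricingModel(f_price=10_000, pdp=200)
        data = [
            PricePoint(f"d{i}", n, price_at(model, n) * math.exp(rng.normal(0, 0.1)))
            for i, n in enumerate(np.linspace(100, 900, 10))
        ]
        fit = fit_regression(data, fix_f_price=10_000)
        assert fit.f_price_hat == pytest.approx(10_000, rel=1e-12)
        assert 0.0 <= fit.r_squared <= 1.0
        assert fit.pdp_hat == pytest.approx(200, rel=0.2)

    def test_fewer_than_three_points_directs_to_two_point(self, eculizumab, bosentan):
        with pytest.raises(InsufficientDataError, match="two_point"):
            fit_regression([eculizumab, bosentan])

    def test_positive_slope_rejected(self):
        data = [PricePoint(f"d{i}", n, p) for i, (n, p) in
                enumerate([(100, 1_000), (500, 5_000), (900, 9_000)])]
        with pytest.raises(InvalidFitError, match="non-negative"):
            fit_regression(data)

    def test_points_above_baseline_retained_with_warning(self):
        model = PricingModel(pdp=200)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OrphanRegimeWarning)
            data = model_points(model, [100, 500, 900, 1100])
        with pytest.warns(OrphanRegimeWarning):
            fit = fit_regression(data)
        assert fit.n_obs == 4

    def test_duplicate_patient_counts_allowed(self):
        model = PricingModel(pdp=150)
        data = model_points(model, [200, 200, 600, 800])
        assert fit_regression(data).pdp_hat == pytest.approx(150, rel=1e-9)


class TestPdpFromSlope:
    def test_printed_slope_gives_378_9(self):
        assert pdp_from_slope(-0.001829) == pytest.approx(378.9, abs=0.05)

    def test_unit_case(self):
        assert pdp_from_slope(-0.693) == pytest.approx(1.0)

    @given(pdp=st.floats(1, 10_000), k=st.floats(0.1, 2))
    def test_algebraic_inverse(self, pdp, k):
        assert pdp_from_slope(-k / pdp, k) == pytest.approx(pdp, rel=1e-12)

    @given(model=st.builds(PricingModel, pdp=st.floats(20, 2000)))
    def test_inverts_log_price_slope(self, model):
        assert pdp_from_slope(log_price_slope(model), model.k) == pytest.approx(
            model.pdp, rel=1e-12
        )

    @pytest.mark.parametrize("bad", [0.0, 0.001, math.nan])
    def test_rejects_nonnegative_or_nonfinite(self, bad):
        with pytest.raises(PricingError):
            pdp_from_slope(bad)
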