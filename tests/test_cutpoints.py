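"""Cut-point derivation chain: quantiles, SEE inflation, inversion, calibration."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from adipocut.cutpoints import (
    derive_cutpoint,
    derive_vat_cutpoint,
    inflate_see,
    invert_regression,
    required_predicted,
    t_quantile,
    vat_tertile_threshold,
)
from adipocut.errors import DomainError, InsufficientDataError

from conftest import make_fit


MALE_FM_FIT = dict(slope=99.7, intercept=-24.7, n=41, see=4.1)


class TestTQuantile:
    def test_reference_value(self):
        assert t_quantile(0.75, 39) == pytest.approx(0.681, abs=5e-4)

    @pytest.mark.parametrize("df", [1, 5, 39, 1000])
    def test_median_is_zero(self, df):
        assert t_quantile(0.5, df) == pytest.approx(0.0, abs=1e-12)

    def test_against_density_integration_oracle(self):
        """Lower-tail area of the t density up to the returned quantile equals p."""
        for p, df in [(0.75, 39), (0.975, 10_000), (0.9, 7)]:
            q = t_quantile(p, df)
            area, _ = integrate.quad(stats.t(df).pdf, -np.inf, q)
            assert area == pytest.approx(p, abs=1e-6)
        assert t_quantile(0.975, 10_000) == pytest.approx(1.960, abs=5e-4)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.3])
    def test_out_of_range_probability(self, p):
        with pytest.raises(DomainError):
            t_quantile(p, 10)


class TestInflateSee:
    def test_worked_value(self):
        assert inflate_see(4.1, 41) == pytest.approx(4.2, abs=0.05)
        assert round(inflate_see(4.1, 41), 1) == 4.2

    def test_direct_evaluation(self):
        assert inflate_see(5.0, 50) == pytest.approx(5.0 * math.sqrt(1 + 1 / 50 + 1 / 47), rel=1e-12)
        assert inflate_see(5.0, 50) == pytest.approx(5.102, abs=5e-4)

    def test_literal_factor_variant_inflates_more(self):
        # the non-root convention roughly doubles the adjustment (4.1 -> ~4.3)
        literal = inflate_see(4.1, 41, literal_factor=True)
        assert literal == pytest.approx(4.1 * (1 + 1 / 41 + 1 / 38), rel=1e-12)
        assert round(literal, 1) == 4.3
        assert literal > inflate_see(4.1, 41)

    def test_large_n_limit(self):
        assert inflate_see(4.1, 10**9) == pytest.approx(4.1, rel=1e-6)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            inflate_see(0.0, 41)
        with pytest.raises(DomainError):
            inflate_see(4.1, 3)


def test_required_predicted_values():
    assert required_predicted(25, 0.681, 4.2) == pytest.approx(27.9, abs=0.05)
    assert required_predicted(30.0, 0.0, 5.0) == 30.0
    assert required_predicted(35, 0.681, 5.25) == pytest.approx(35 + 0.681 * 5.25, rel=1e-12)
    assert required_predicted(35, 0.681, 5.25) == pytest.approx(38.575, abs=5e-4)
    with pytest.raises(DomainError):
        required_predicted(25, 0.681, 0.0)


def test_invert_regression():
    fit = make_fit(**MALE_FM_FIT)
    assert invert_regression(fit, 27.9) == pytest.approx((27.9 + 24.7) / 99.7, rel=1e-12)
    assert invert_regression(make_fit(1.0, 0.0, 41, 4.0), 7.7) == pytest.approx(7.7)
    assert invert_regression(make_fit(2.0, 10.0, 41, 4.0), 20.0) == pytest.approx(5.0)
    with pytest.raises(DomainError):
        invert_regression(make_fit(-3.0, 10.0, 41, 4.0), 20.0)


class TestDeriveCutpoint:
    def test_male_fat_chain_with_desk_rounding(self):
        result = derive_cutpoint(make_fit(**MALE_FM_FIT), threshold=25.0, p=0.75, paper_mode=True)
        assert result.t_value == 0.681
        assert result.see_adjusted == 4.2
        assert result.required_predicted == 27.9
        assert round(result.cutpoint, 2) == 0.53

    def test_full_precision_close_to_rounded_chain(self):
        result = derive_cutpoint(make_fit(**MALE_FM_FIT), threshold=25.0, p=0.75)
        assert result.cutpoint == pytest.approx(0.53, abs=0.005)

    def test_probability_half_collapses_to_plain_inversion(self):
        fit = make_fit(**MALE_FM_FIT)
        result = derive_cutpoint(fit, threshold=25.0, p=0.5)
        assert result.cutpoint == pytest.approx((25.0 + 24.7) / 99.7, rel=1e-12)

    def test_round_trip_prediction(self):
        fit = make_fit(**MALE_FM_FIT)
        result = derive_cutpoint(fit, threshold=25.0, p=0.75)
        assert fit.predict(result.cutpoint) == pytest.approx(result.required_predicted, abs=1e-9)

    def test_monotone_in_probability_threshold_and_see(self):
        fit = make_fit(**MALE_FM_FIT)
        cuts_p = [derive_cutpoint(fit, 25.0, p).cutpoint for p in (0.55, 0.6, 0.75, 0.9, 0.95)]
        assert all(a < b for a, b in zip(cuts_p, cuts_p[1:]))
        cuts_thr = [derive_cutpoint(fit, thr, 0.75).cutpoint for thr in (20.0, 25.0, 30.0)]
        assert all(a < b for a, b in zip(cuts_thr, cuts_thr[1:]))
        cuts_see = [
            derive_cutpoint(make_fit(99.7, -24.7, 41, see), 25.0, 0.75).cutpoint
            for see in (2.0, 4.1, 6.0)
        ]
        assert all(a <= b for a, b in zip(cuts_see, cuts_see[1:]))

    def test_vanishing_see_collapses_to_plain_inversion(self):
        for p in (0.6, 0.75, 0.9):
            result = derive_cutpoint(make_fit(99.7, -24.7, 41, 1e-9), 25.0, p)
            assert result.cutpoint == pytest.approx((25.0 + 24.7) / 99.7, abs=1e-8)

    @pytest.mark.parametrize("p", [0.6, 0.75, 0.9])
    def test_monte_carlo_calibration(self, p):
        """At the cut-point, the simulated exceedance probability equals p.

        True outcomes are drawn as predicted value plus scaled t_{n-2} errors,
        the error law under which the one-tailed t-area argument is exact.
        """
        fit = make_fit(**MALE_FM_FIT)
        result = derive_cutpoint(fit, threshold=25.0, p=p)
        rng = np.random.default_rng(2024)
        draws = result.required_predicted + result.see_adjusted * stats.t.rvs(
            df=fit.df, size=1_000_000, random_state=rng
        )
        frac = float(np.mean(draws > result.threshold))
        assert abs(frac - p) < 3 * math.sqrt(p * (1 - p) / 1_000_000)


class TestVatTertile:
    def test_small_exact_case(self):
        d = vat_tertile_threshold([1, 2, 3, 4, 5, 6, 7, 8, 9], "M")
        assert 6 <= d.tertile_boundary < 7
        assert sum(v > d.tertile_boundary for v in range(1, 10)) == 3
        assert d.source_n == 9

    def test_obese_third_size(self):
        rng = np.random.default_rng(8)
        values = np.exp(rng.normal(6.4, 1.06, 41))
        d = vat_tertile_threshold(values, "M")
        n_above = int(np.sum(values > d.tertile_boundary))
        assert abs(n_above - math.ceil(41 / 3)) <= 1

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(DomainError):
            vat_tertile_threshold([5.0] * 9, "M")  # all equal: nobody strictly above
        with pytest.raises(DomainError):
            vat_tertile_threshold([1.0, 0.0, 2.0], "F")  # zeros must be pre-excluded
        with pytest.raises(InsufficientDataError):
            vat_tertile_threshold([1.0, 2.0], "F")


class TestDeriveVatCutpoint:
    def test_zero_error_identity_limit(self):
        from adipocut.cutpoints import VatObesityDefinition

        fit = make_fit(1.0, 0.0, 10**6, 1e-9, outcome="log_vat")
        tert = VatObesityDefinition(sex="M", tertile_boundary=math.exp(3.0), source_n=100)
        result = derive_vat_cutpoint(fit, tert)
        assert result.cutpoint == pytest.approx(3.0, abs=1e-6)

    def test_closed_form_chain(self):
        from adipocut.cutpoints import VatObesityDefinition

        fit = make_fit(12.9, -0.04, 41, 0.588, outcome="log_vat")
        tert = VatObesityDefinition(sex="M", tertile_boundary=1108.0, source_n=41)
        result = derive_vat_cutpoint(fit, tert, p=0.75)
        t = stats.t.ppf(0.75, 39)
        see_adj = 0.588 * math.sqrt(1 + 1 / 41 + 1 / 38)
        expected = (math.log(1108.0) + t * see_adj + 0.04) / 12.9
        assert result.cutpoint == pytest.approx(expected, abs=1e-9)
        assert result.threshold == pytest.approx(math.log(1108.0), rel=1e-12)

    def test_requires_log_scale_fit_and_matching_sex(self):
        from adipocut.cutpoints import VatObesityDefinition

        tert = VatObesityDefinition(sex="M", tertile_boundary=1108.0, source_n=41)
        with pytest.raises(DomainError):
            derive_vat_cutpoint(make_fit(12.9, -0.04, 41, 0.588, outcome="fat_pct"), tert)
        with pytest.raises(DomainError):
            derive_vat_cutpoint(
                make_fit(12.9, -0.04, 41, 0.588, outcome="log_vat", sex="F"), tert
            )
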