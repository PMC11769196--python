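"""Per-family estimators, normalization, and pdf/cdf/sample behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

import thermofall as tf
from thermofall.families import ConvergenceError, DegenerateDataError, FitError


class TestNormalizeUnit:
    def test_endpoints_map_to_clipped_unit_range(self):
        y, rec = tf.normalize_unit([10.0, 20.0], eps=1e-6)
        np.testing.assert_allclose(y, [1e-6, 1 - 1e-6])
        assert (rec.x_min, rec.x_max) == (10.0, 20.0)

    def test_identity_on_unit_range(self):
        y, _ = tf.normalize_unit([0.0, 0.5, 1.0], eps=0.0)
        np.testing.assert_allclose(y, [0.0, 0.5, 1.0])

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateDataError):
            tf.normalize_unit([5.0, 5.0, 5.0])

    def test_record_round_trip(self):
        x = np.array([3.0, 9.0, 4.5])
        y, rec = tf.normalize_unit(x, eps=0.0)
        np.testing.assert_allclose(rec.inverse(y), x)


class TestClosedFormEstimators:
    def test_exponential_rate_is_reciprocal_mean(self):
        fit = tf.fit_family([2.0, 4.0, 3.0], "exponential")
        assert fit.params["lam"] == pytest.approx(1.0 / 3.0)

    def test_uniform_bounds(self):
        fit = tf.fit_family([3.0, 7.0, 5.0], "uniform")
        assert (fit.params["a"], fit.params["b"]) == (3.0, 7.0)

    def test_pareto_closed_form(self):
        # alpha = n / sum(log(x_i / x_m)) = 3 / 1
        fit = tf.fit_family([1.0, 1.0, math.e], "pareto")
        assert fit.params["x_m"] == 1.0
        assert fit.params["alpha"] == pytest.approx(3.0)

    def test_normal_population_mle(self):
        fit = tf.fit_family([1.0, 2.0, 3.0], "normal")
        assert fit.params["mu"] == 2.0
        assert fit.params["sigma"] == pytest.approx(math.sqrt(2.0 / 3.0))

    def test_laplace_median_and_mad(self):
        fit = tf.fit_family([1.0, 2.0, 6.0], "laplace")
        assert fit.params["mu"] == 2.0
        assert fit.params["b"] == pytest.approx((1.0 + 0.0 + 4.0) / 3.0)

    @given(
        values=st.lists(
            st.floats(0.1, 1e4), min_size=3, max_size=60, unique=True
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_estimator_identities(self, values):
        x = np.array(values)
        assert tf.fit_family(x, "exponential").params["lam"] * x.mean() == pytest.approx(1.0)
        uni = tf.fit_family(x, "uniform").params
        assert (uni["a"], uni["b"]) == (x.min(), x.max())
        assert tf.fit_family(x, "pareto").params["x_m"] == x.min()


class TestPreconditions:
    def test_positivity_required(self):
        for fam in ("exponential", "pareto", "f"):
            with pytest.raises(FitError):
                tf.fit_family([-1.0, 2.0, 3.0, 4.0, 5.0], fam)

    def test_minimum_sample_size(self):
        with pytest.raises(FitError):
            tf.fit_family([1.0, 2.0], "normal")
        with pytest.raises(FitError):
            tf.fit_family([1.0, 2.0, 3.0, 4.0], "student_t")

    def test_degenerate_data(self):
        with pytest.raises(DegenerateDataError):
            tf.fit_family([5.0, 5.0, 5.0], "beta")

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            tf.fit_family([1.0, 2.0, 3.0], "cauchy")


class TestEvaluation:
    def test_pdf_closed_forms(self):
        norm = tf.FitParams("normal", {"mu": 0.0, "sigma": 1.0}, "closed_form")
        assert tf.pdf(norm, 0.0) == pytest.approx(1.0 / math.sqrt(2 * math.pi))
        uni = tf.FitParams("uniform", {"a": 0.0, "b": 2.0}, "closed_form")
        assert tf.pdf(uni, 1.0) == 0.5
        expo = tf.FitParams("exponential", {"lam": 1.0}, "closed_form")
        assert tf.pdf(expo, 0.0) == 1.0

    def test_pdf_zero_outside_support(self):
        expo = tf.FitParams("exponential", {"lam": 1.0}, "closed_form")
        assert tf.pdf(expo, -1.0) == 0.0

    def test_cdf_symmetry_and_linearity(self):
        norm = tf.FitParams("normal", {"mu": 3.0, "sigma": 2.0}, "closed_form")
        assert tf.cdf(norm, 3.0) == pytest.approx(0.5)
        lap = tf.FitParams("laplace", {"mu": 3.0, "b": 1.0}, "closed_form")
        assert tf.cdf(lap, 3.0) == pytest.approx(0.5)
        uni = tf.FitParams("uniform", {"a": 0.0, "b": 2.0}, "closed_form")
        assert tf.cdf(uni, 0.5) == pytest.approx(0.25)

    @pytest.mark.parametrize("family", tf.FAMILIES)
    def test_pdf_cdf_consistency_all_families(self, family, walking_sums):
        """Numerical derivative of the CDF matches the PDF inside the support."""
        fit = tf.fit_family(walking_sums, family)
        lo, hi = tf.ppf(fit, 0.01), tf.ppf(fit, 0.99)
        xs = np.linspace(lo, hi, 100)
        h = (hi - lo) * 1e-7
        deriv = (tf.cdf(fit, xs + h) - tf.cdf(fit, xs - h)) / (2 * h)
        dens = tf.pdf(fit, xs)
        scale = max(dens.max(), 1e-12)
        np.testing.assert_allclose(deriv / scale, dens / scale, atol=1e-4)

    @pytest.mark.parametrize("family", tf.FAMILIES)
    def test_pdf_integrates_to_one(self, family, walking_sums):
        fit = tf.fit_family(walking_sums, family)
        lo, hi = tf.ppf(fit, 1e-9), tf.ppf(fit, 1 - 1e-9)
        mass, _ = integrate.quad(lambda t: tf.pdf(fit, t), lo, hi, limit=300)
        assert mass == pytest.approx(1.0, abs=1e-4)

    def test_sample_seed_reproducible(self):
        fit = tf.FitParams("normal", {"mu": 5.0, "sigma": 2.0}, "closed_form")
        np.testing.assert_array_equal(tf.sample(fit, 100, seed=4), tf.sample(fit, 100, seed=4))

    def test_uniform_sample_mean_clt_bound(self):
        fit = tf.FitParams("uniform", {"a": 0.0, "b": 1.0}, "closed_form")
        assert abs(tf.sample(fit, 10_000, seed=8).mean() - 0.5) < 0.02

    def test_sample_requires_positive_n(self):
        fit = tf.FitParams("uniform", {"a": 0.0, "b": 1.0}, "closed_form")
        with pytest.raises(ValueError):
            tf.sample(fit, 0)

    def test_normalized_fits_evaluate_on_original_scale(self, walking_sums):
        fit = tf.fit_family(walking_sums, "beta")
        x = walking_sums.values
        med = float(np.median(x))
        # cdf near the data median should be mid-range on the original scale
        assert 0.2 < tf.cdf(fit, med) < 0.8
        draws = tf.sample(fit, 2000, seed=1)
        assert x.min() - 1 <= draws.min() and draws.max() <= x.max() + 1

    def test_fit_record_is_flat_text(self, walking_sums):
        rec = tf.fit_to_record(tf.fit_family(walking_sums, "beta"))
        assert rec["family"] == "beta" and "alpha" in rec and "x_min" in rec
        assert all(isinstance(v, str) for v in rec.values())
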