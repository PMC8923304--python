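import math

import numpy as np
import pytest

from predval import (
    ConstraintCase,
    DegenerateDataError,
    PairedPredictions,
    ValidationError,
    evaluate,
    fit_line,
    pearson_r,
    r_squared,
    rmse,
)

VAL, BIAS, PEARSON = ConstraintCase.VAL, ConstraintCase.BIAS, ConstraintCase.PEARSON


class TestPairedPredictions:
    def test_rejects_short_unequal_and_nonfinite_inputs(self):
        with pytest.raises(ValidationError, match="at least 3"):
            PairedPredictions(y_obs=[1.0, 2.0], x_calc=[1.0, 2.0])
        with pytest.raises(ValidationError, match="length"):
            PairedPredictions(y_obs=[1.0, 2.0, 3.0], x_calc=[1.0, 2.0])
        with pytest.raises(ValidationError, match="non-finite"):
            PairedPredictions(y_obs=[1.0, np.nan, 3.0], x_calc=[1.0, 2.0, 3.0])

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValidationError, match="unique"):
            PairedPredictions(
                y_obs=[1.0, 2.0, 3.0], x_calc=[1.0, 2.0, 3.0],
                ids=("a", "a", "b"),
            )


class TestFitLine:
    def test_perfect_fit_identity_case(self):
        """y identical to x: the identity line fits exactly."""
        p = PairedPredictions(y_obs=[-3.0, -2.0, -1.0], x_calc=[-3.0, -2.0, -1.0])
        fit = fit_line(p, VAL)
        assert (fit.a, fit.b) == (0.0, 1.0)
        assert fit.ss_res == 0.0

    def test_constant_shift_recovered_as_bias(self):
        x = np.array([-5.0, -4.0, -3.0, -2.0])
        p = PairedPredictions(y_obs=x + 0.5, x_calc=x)
        fit = fit_line(p, BIAS)
        assert fit.b == 1.0
        assert fit.a == pytest.approx(0.5, abs=1e-12)
        assert fit.ss_res == pytest.approx(0.0, abs=1e-20)

    def test_unconstrained_fit_matches_grid_oracle(self, five_pairs):
        # frozen from a refining grid search over (a, b), resolution << 1e-3
        fit = fit_line(five_pairs, PEARSON)
        assert fit.a == pytest.approx(0.120, abs=1e-3)
        assert fit.b == pytest.approx(0.970, abs=1e-3)

    def test_nested_residual_sums(self, five_pairs):
        ss = {c: fit_line(five_pairs, c).ss_res for c in ConstraintCase}
        assert ss[PEARSON] <= ss[BIAS] <= ss[VAL]

    def test_constant_x_is_degenerate_for_unconstrained_fit(self):
        p = PairedPredictions(y_obs=[1.0, 2.0, 3.0], x_calc=[2.0, 2.0, 2.0])
        with pytest.raises(DegenerateDataError, match="x_calc"):
            fit_line(p, PEARSON)


class TestRSquared:
    def test_perfect_fit_gives_one(self):
        p = PairedPredictions(y_obs=[-3.0, -2.0, -1.0], x_calc=[-3.0, -2.0, -1.0])
        assert r_squared(p, fit_line(p, VAL)) == 1.0

    def test_anticorrelated_offset_data_give_negative_value(self):
        """An anti-correlated prediction scores below zero against y = x."""
        p = PairedPredictions(y_obs=[1.0, 2.0, 3.0], x_calc=[-3.0, -4.0, -5.0])
        assert r_squared(p, fit_line(p, VAL)) < 0

    def test_unconstrained_r2_equals_squared_pearson_r(self, five_pairs):
        r2 = r_squared(five_pairs, fit_line(five_pairs, PEARSON))
        assert r2 == pytest.approx(pearson_r(five_pairs) ** 2, abs=1e-10)
        assert r2 == pytest.approx(0.9829711659, abs=1e-9)  # direct formula

    def test_constant_observed_values_error(self):
        p = PairedPredictions(y_obs=[2.0, 2.0, 2.0], x_calc=[1.0, 2.0, 3.0])
        with pytest.raises(DegenerateDataError, match="constant"):
            r_squared(p, fit_line(p, VAL))


class TestRmse:
    def test_zero_for_perfect_fit_any_case(self):
        x = np.array([-6.0, -4.0, -2.0, 0.0])
        p = PairedPredictions(y_obs=x, x_calc=x)
        for case in ConstraintCase:
            assert rmse(p, fit_line(p, case)) == 0.0

    def test_constant_residual_gives_its_magnitude(self):
        x = np.array([-6.0, -4.0, -2.0])
        p = PairedPredictions(y_obs=x - 0.7, x_calc=x)
        assert rmse(p, fit_line(p, VAL)) == pytest.approx(0.7, abs=1e-12)

    def test_bias_case_matches_direct_enumeration(self, five_pairs):
        # sqrt(mean((y - x - mean(y - x))**2)) computed by hand
        value = rmse(five_pairs, fit_line(five_pairs, BIAS), "n")
        assert value == pytest.approx(0.1854723699, abs=1e-9)

    def test_see_convention_uses_n_minus_two_for_fitted_lines(self, five_pairs):
        n = five_pairs.n
        for case in (BIAS, PEARSON):
            fit = fit_line(five_pairs, case)
            expected = math.sqrt(fit.ss_res / (n - 2))
            assert rmse(five_pairs, fit, "see") == pytest.approx(expected, abs=1e-12)
        fit = fit_line(five_pairs, VAL)
        assert rmse(five_pairs, fit, "see") == pytest.approx(
            math.sqrt(fit.ss_res / n), abs=1e-12
        )

    def test_unknown_convention_rejected(self, five_pairs):
        with pytest.raises(ValueError, match="dof_convention"):
            rmse(five_pairs, fit_line(five_pairs, VAL), "n-1")


class TestPearsonR:
    @pytest.mark.parametrize(
        "transform, expected",
        [(lambda x: x, 1.0), (lambda x: -x, -1.0)],
        ids=["self", "negated"],
    )
    def test_exact_correlation_limits(self, transform, expected):
        x = np.array([-5.0, -3.0, -1.0, 0.0])
        p = PairedPredictions(y_obs=transform(x), x_calc=x)
        assert pearson_r(p) == expected

    def test_matches_direct_product_moment_formula(self, five_pairs):
        assert pearson_r(five_pairs) == pytest.approx(0.9914490233, abs=1e-9)

    def test_zero_variance_column_is_degenerate(self):
        p = PairedPredictions(y_obs=[1.0, 2.0, 3.0], x_calc=[2.0, 2.0, 2.0])
        with pytest.raises(DegenerateDataError):
            pearson_r(p)


class TestEvaluate:
    def test_random_scatter_makes_the_three_families_agree(self, random_pairs_factory):
        """With no systematic error the choice of definition is immaterial."""
        rng = np.random.default_rng(7)
        rep = evaluate(random_pairs_factory(5000, rng))
        assert rep.r2_pearson - rep.r2_val < 0.01
        assert rep.rmse_val - rep.rmse_pearson < 0.01
        assert abs(rep.bias) < 0.02
        assert rep.slope == pytest.approx(1.0, abs=0.02)

    def test_pure_shift_forgiven_by_bias_and_pearson_cases(self, random_pairs_factory):
        rng = np.random.default_rng(8)
        rep = evaluate(random_pairs_factory(5000, rng, bias=-0.6))
        assert rep.r2_bias == pytest.approx(rep.r2_pearson, abs=0.01)
        assert rep.r2_bias > rep.r2_val + 0.02
        assert rep.bias == pytest.approx(-0.6, abs=0.02)

    def test_shift_plus_tilt_gives_strict_three_way_ordering(self, random_pairs_factory):
        rng = np.random.default_rng(9)
        rep = evaluate(random_pairs_factory(5000, rng, bias=0.4, tilt=0.7))
        assert rep.r2_pearson > rep.r2_bias > rep.r2_val
        assert rep.rmse_pearson < rep.rmse_bias < rep.rmse_val

    def test_errors_name_the_offending_case(self):
        p = PairedPredictions(y_obs=[1.0, 2.0, 3.0], x_calc=[2.0, 2.0, 2.0])
        with pytest.raises(DegenerateDataError, match="pearson"):
            evaluate(p)
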