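import math

import numpy as np
import pytest
from scipy import integrate, stats

from elicitbn import (Family, FamilyParams, cdf, density, format_params,
                      moments, parse_params, quantile)
from elicitbn.families import params_from_json, params_to_json, sample
from elicitbn.errors import DomainError, ParameterError, UndefinedMomentError

from conftest import FAMILY_EXAMPLES

GRID = np.array([0.01, 0.1, 0.25, 0.5, 0.75, 0.9, 0.99])


class TestQuantile:
    def test_standard_normal_lower_quartile(self):
        p = FamilyParams(Family.NORMAL, {"loc": 0.0, "scale": 1.0})
        assert quantile(p, 0.25) == pytest.approx(-0.6744898, abs=1e-6)

    def test_uniform_beta_quantile_is_identity(self):
        p = FamilyParams(Family.SHIFTED_SCALED_BETA, {"alpha": 1.0, "beta": 1.0},
                         support_lower=0.0, support_upper=1.0)
        assert quantile(p, 0.37) == pytest.approx(0.37, abs=1e-12)

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_mirror_gamma_reflects_the_base_gamma(self, p):
        params = FamilyParams(Family.MIRROR_GAMMA, {"shape": 2.0, "rate": 0.5},
                              support_upper=10.0)
        base = stats.gamma(a=2.0, scale=2.0)
        assert quantile(params, p) == pytest.approx(10.0 - base.ppf(1.0 - p),
                                                    abs=1e-10)

    @pytest.mark.parametrize("family", list(Family))
    def test_strictly_increasing_within_support(self, family):
        params = FAMILY_EXAMPLES[family]
        q = np.asarray(quantile(params, GRID))
        assert np.all(np.diff(q) > 0)
        lo, hi = params.support
        assert q[0] >= lo - 1e-9 and q[-1] <= hi + 1e-9

    @pytest.mark.parametrize("family", list(Family))
    def test_agrees_with_numeric_cdf_inversion(self, family):
        """Quantile and CDF are mutual inverses on a probability grid."""
        params = FAMILY_EXAMPLES[family]
        q = np.asarray(quantile(params, GRID))
        assert np.asarray(cdf(params, q)) == pytest.approx(GRID, abs=1e-6)

    def test_mirror_of_mirror_restores_quantiles(self):
        base = FamilyParams(Family.SHIFTED_GAMMA, {"shape": 2.5, "rate": 0.5},
                            support_lower=0.0)
        mirrored = FamilyParams(Family.MIRROR_GAMMA, {"shape": 2.5, "rate": 0.5},
                                support_upper=20.0)
        # reflecting the mirror about the same bound recovers the base
        back = 20.0 - np.asarray(quantile(mirrored, 1.0 - GRID))
        assert back == pytest.approx(np.asarray(quantile(base, GRID)), abs=1e-10)

    def test_probability_outside_open_interval_rejected(self):
        p = FamilyParams(Family.NORMAL, {"loc": 0.0, "scale": 1.0})
        with pytest.raises(DomainError):
            quantile(p, 1.0)


class TestDensity:
    def test_standard_normal_mode(self):
        p = FamilyParams(Family.NORMAL, {"loc": 0.0, "scale": 1.0})
        assert density(p, 0.0) == pytest.approx(0.3989423, abs=1e-6)

    def test_beta_2_2_mode(self):
        p = FamilyParams(Family.SHIFTED_SCALED_BETA, {"alpha": 2.0, "beta": 2.0},
                         support_lower=0.0, support_upper=1.0)
        assert density(p, 0.5) == pytest.approx(1.5, abs=1e-10)

    def test_mirror_log_t_is_the_reflected_log_t(self):
        """Change of variables: f_mirror(x) = f_log(U - x + L) on a grid."""
        U = 10.0
        mirror = FamilyParams(Family.MIRROR_LOG_T,
                              {"mu": 1.0, "sigma": 0.3, "df": 3.0},
                              support_upper=U)
        straight = FamilyParams(Family.LOG_T,
                                {"mu": 1.0, "sigma": 0.3, "df": 3.0},
                                support_lower=0.0)
        xs = np.linspace(1.0, 9.5, 20)
        assert np.asarray(density(mirror, xs)) == pytest.approx(
            np.asarray(density(straight, U - xs)), rel=1e-10)

    @pytest.mark.parametrize("family", [Family.MIRROR_GAMMA, Family.LOG_T,
                                        Family.SHIFTED_SCALED_BETA])
    def test_integrates_to_the_enclosed_mass(self, family):
        """The density over a central quantile range carries exactly that mass
        (heavy-tailed families make full-support quadrature hopeless)."""
        params = FAMILY_EXAMPLES[family]
        lo = quantile(params, 0.001)
        hi = quantile(params, 0.999)
        mass, _ = integrate.quad(lambda x: density(params, x), lo, hi, limit=200)
        assert mass == pytest.approx(0.998, abs=1e-6)

    def test_zero_outside_support(self):
        params = FAMILY_EXAMPLES[Family.SHIFTED_SCALED_BETA]
        assert density(params, -0.5) == 0.0
        assert density(params, 1.5) == 0.0


class TestMoments:
    def test_normal_closed_form(self):
        p = FamilyParams(Family.NORMAL, {"loc": 3.0, "scale": 2.0})
        m = moments(p)
        assert (m.mean, m.sd) == (3.0, 2.0) and m.method == "closed_form"

    def test_beta_closed_form(self):
        p = FamilyParams(Family.SHIFTED_SCALED_BETA, {"alpha": 2.0, "beta": 2.0},
                         support_lower=0.0, support_upper=1.0)
        m = moments(p)
        assert m.mean == pytest.approx(0.5)
        assert m.sd == pytest.approx(math.sqrt(1.0 / 20.0), abs=1e-12)

    @pytest.mark.parametrize("family", [Family.LOG_T, Family.MIRROR_LOG_T])
    def test_log_t_type_moments_are_undefined(self, family):
        with pytest.raises(UndefinedMomentError):
            moments(FAMILY_EXAMPLES[family])

    def test_student_t_low_df_moments_are_undefined(self):
        p = FamilyParams(Family.STUDENT_T, {"loc": 0.0, "scale": 1.0, "df": 2.0})
        with pytest.raises(UndefinedMomentError):
            moments(p)

    def test_truncated_fallback_is_flagged(self):
        m = moments(FAMILY_EXAMPLES[Family.LOG_T], allow_truncated=True)
        assert m.method == "truncated" and np.isfinite(m.mean)

    @pytest.mark.parametrize("family", [Family.NORMAL, Family.STUDENT_T,
                                        Family.SHIFTED_GAMMA, Family.MIRROR_GAMMA,
                                        Family.LOGNORMAL,
                                        Family.SHIFTED_SCALED_BETA])
    def test_agrees_with_monte_carlo(self, family):
        """Closed-form moments match seeded simulation within 3 SE."""
        params = FAMILY_EXAMPLES[family]
        m = moments(params)
        rng = np.random.default_rng(20240317)
        draws = sample(params, 1_000_000, rng)
        se_mean = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - m.mean) < 3.0 * se_mean
        # SE of the SD via the delta method with the empirical fourth moment
        centered = draws - draws.mean()
        m4 = np.mean(centered ** 4)
        var = draws.var(ddof=1)
        se_sd = math.sqrt(max(m4 - var ** 2, 0.0) / len(draws)) / (2.0 * math.sqrt(var))
        assert abs(draws.std(ddof=1) - m.sd) < 3.0 * se_sd


class TestParameterValidation:
    def test_scale_must_be_positive(self):
        with pytest.raises(ParameterError):
            FamilyParams(Family.NORMAL, {"loc": 0.0, "scale": -1.0})

    def test_mirror_requires_finite_upper_bound(self):
        with pytest.raises(ParameterError):
            FamilyParams(Family.MIRROR_GAMMA, {"shape": 1.0, "rate": 1.0})

    def test_beta_requires_ordered_bounds(self):
        with pytest.raises(ParameterError):
            FamilyParams(Family.SHIFTED_SCALED_BETA, {"alpha": 1.0, "beta": 1.0},
                         support_lower=2.0, support_upper=1.0)

    def test_unknown_parameter_names_rejected(self):
        with pytest.raises(ParameterError):
            FamilyParams(Family.NORMAL, {"loc": 0.0, "scale": 1.0, "df": 3.0})


class TestSerialization:
    @pytest.mark.parametrize("family", list(Family))
    def test_json_round_trip(self, family):
        params = FAMILY_EXAMPLES[family]
        assert params_from_json(params_to_json(params)) == params

    @pytest.mark.parametrize("family", list(Family))
    def test_string_round_trip_preserves_quantiles(self, family):
        params = FAMILY_EXAMPLES[family]
        parsed = parse_params(format_params(params, decimals=6))
        assert np.asarray(quantile(parsed, GRID)) == pytest.approx(
            np.asarray(quantile(params, GRID)), rel=1e-4)

    def test_published_style_strings_parse(self):
        beta = parse_params("Beta (7.62, 5.76)")
        assert beta.family is Family.SHIFTED_SCALED_BETA
        assert beta.theta == {"alpha": 7.62, "beta": 5.76}
        t = parse_params("T (130.29, 207.84, df = 7)")
        assert t.family is Family.STUDENT_T
        assert t.theta == {"loc": 130.29, "scale": 207.84, "df": 7.0}
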