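"""Design-matrix construction, the OLS/L-M pair, and fit statistics."""
import numpy as np
import pytest

from beeheat import (
    CollinearityError,
    SyntheticConfig,
    ValidationError,
    build_design_matrix,
    compare_variants,
    fit_iterative,
    fit_linear,
    fit_statistics,
    generate_visits,
    load_preset,
)


@pytest.fixture(scope="module")
def noise_free_visits():
    cfg = SyntheticConfig(n_visits=200, seed=11, residual_noise_sd_mW=0.0)
    visits, _ = generate_visits(cfg)
    return visits


class TestDesignMatrix:
    @pytest.mark.parametrize(
        "variant,k",
        [
            ("simple", 4),
            ("per_part", 9),
            ("per_part_reduced", 8),
            ("three_compartment", 9),
            ("three_compartment_reduced", 8),
        ],
    )
    def test_dimensions_and_df(self, small_visits, variant, k):
        design = build_design_matrix(small_visits, variant)
        assert design.X.shape == (len(small_visits), k)
        assert design.df == len(small_visits) - k
        assert len(design.columns) == k

    def test_missing_m_rows_are_excluded(self, small_visits):
        visits = small_visits.copy()
        visits.loc[visits.index[:10], "M_mW"] = np.nan
        design = build_design_matrix(visits, "per_part")
        assert design.n == len(visits) - 10
        assert design.n_excluded == 10

    def test_no_usable_rows_is_an_error(self, small_visits):
        visits = small_visits.copy()
        visits["M_mW"] = np.nan
        with pytest.raises(ValidationError):
            build_design_matrix(visits, "per_part")

    def test_constant_ambient_temperature_is_rank_deficient(self, small_visits):
        visits = small_visits.copy()
        visits["T_a_C"] = 25.0
        design = build_design_matrix(visits, "per_part")
        with pytest.raises(CollinearityError) as err:
            fit_linear(design)
        # intercept/slope pairs become proportional; the error names them
        assert any("hth" in c or "hhd" in c or "hab" in c for c in err.value.columns)


class TestRecovery:
    def test_noise_free_recovery_is_exact(self, noise_free_visits):
        generating = load_preset("table2a")
        result = fit_linear(build_design_matrix(noise_free_visits, "per_part"))
        np.testing.assert_allclose(
            result.coefficients.as_array(), generating.as_array(), rtol=1e-6
        )
        assert result.sd_res_mW == pytest.approx(0.0, abs=1e-6)

    def test_iterative_equals_linear(self, small_visits):
        design = build_design_matrix(small_visits, "per_part_reduced")
        ols = fit_linear(design)
        lm = fit_iterative(design)
        assert lm.converged
        np.testing.assert_allclose(
            lm.coefficients.as_array(), ols.coefficients.as_array(), rtol=1e-6
        )

    def test_initialization_independence(self, small_visits):
        design = build_design_matrix(small_visits, "per_part")
        from_zeros = fit_iterative(design, init=np.zeros(design.k))
        from_ones = fit_iterative(design, init=np.ones(design.k))
        np.testing.assert_allclose(
            from_zeros.coefficients.as_array(),
            from_ones.coefficients.as_array(),
            rtol=1e-6,
        )

    def test_convergence_reporting(self, small_visits):
        design = build_design_matrix(small_visits, "per_part")
        strict = fit_iterative(design, tol=1e-9)
        assert strict.converged and strict.n_iterations >= 1
        capped = fit_iterative(design, tol=1e-30, max_iterations=2)
        assert not capped.converged and capped.n_iterations == 2


class TestStatistics:
    def test_sem_identity(self):
        residuals = np.random.default_rng(0).normal(size=500)
        st = fit_statistics(residuals, 4, residuals + 10.0)
        assert st.sem_res == pytest.approx(st.sd_res / np.sqrt(500), rel=1e-12)

    def test_zero_residuals(self):
        y = np.linspace(1.0, 2.0, 50)
        st = fit_statistics(np.zeros(50), 3, y)
        assert st.sd_res == 0.0 and st.adj_r2 == pytest.approx(1.0)

    def test_null_model_adjusted_r2_near_zero(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=2000)
        st = fit_statistics(y - y.mean(), 1, y)
        assert st.adj_r2 == pytest.approx(0.0, abs=0.01)

    def test_df_bookkeeping_per_coefficient(self):
        residuals = np.ones(100)
        assert fit_statistics(residuals, 5, residuals).df == 95
        assert fit_statistics(residuals, 6, residuals).df == 94

    def test_degenerate_df_rejected(self):
        with pytest.raises(ValidationError):
            fit_statistics(np.ones(3), 3, np.ones(3))

    def test_per_coefficient_se_t_p(self, small_visits):
        result = fit_linear(build_design_matrix(small_visits, "per_part"))
        for name in result.coefficients.names:
            assert result.t_value[name] == pytest.approx(
                result.coefficients[name] / result.se[name], rel=1e-12
            )
            assert 0.0 <= result.p_gt_t[name] <= 1.0


class TestCompareVariants:
    def test_span_equivalent_pairs_share_residuals(self, small_visits):
        for pair in (
            ("per_part", "three_compartment"),
            ("per_part_reduced", "three_compartment_reduced"),
        ):
            fits = [
                fit_linear(build_design_matrix(small_visits, variant)) for variant in pair
            ]
            scale = np.std(fits[0].residuals)
            np.testing.assert_allclose(
                fits[0].residuals / scale, fits[1].residuals / scale, atol=1e-8
            )

    def test_nested_model_cannot_fit_worse(self, small_visits):
        # residual sum of squares is monotone under nesting; SD_res uses
        # the df denominator, so it is only compared across the large
        # simple-vs-per-part gap
        rss = {
            variant: float(
                fit_linear(build_design_matrix(small_visits, variant)).residuals @
                fit_linear(build_design_matrix(small_visits, variant)).residuals
            )
            for variant in ("simple", "per_part_reduced", "per_part")
        }
        assert rss["per_part"] <= rss["per_part_reduced"] <= rss["simple"]
        table = compare_variants(small_visits, ["simple", "per_part"])
        assert table.loc["per_part", "sd_res_mW"] <= table.loc["simple", "sd_res_mW"]
        assert set(table.columns) >= {"sd_res_mW", "adj_r2", "df", "n"}

    def test_needs_two_variants(self, small_visits):
        with pytest.raises(ValidationError):
            compare_variants(small_visits, ["per_part"])
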