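import dataclasses
import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from polityscale.spatial import (
    ModelSpec,
    build_covariance,
    cross_validate,
    fit_mixed_model,
    fixed_design,
    great_circle_km,
    level_intercepts_slopes,
    matern_correlation,
    matern_covariance,
    trend_across_levels,
)
from polityscale.synth import generate_societies, reference_config
from polityscale import reference


def _random_coords(rng, n):
    return np.column_stack(
        [rng.uniform(-180, 180, n), rng.uniform(-85, 85, n)]
    )


def test_great_circle_known_values():
    # quarter circumference along the equator
    d = great_circle_km([0.0, 90.0], [0.0, 0.0])
    assert d[0, 1] == pytest.approx(math.pi / 2 * 6371.0, rel=1e-12)
    assert d[0, 0] == 0.0
    # antipodal points: half circumference
    d2 = great_circle_km([0.0, 180.0], [0.0, 0.0])
    assert d2[0, 1] == pytest.approx(math.pi * 6371.0, rel=1e-12)


def test_matern_diagonal_and_exponential_special_case():
    rng = np.random.default_rng(0)
    coords = _random_coords(rng, 20)
    cov = matern_covariance(coords, nu=0.5, rho=2000.0, sigma2=1.7)
    assert np.allclose(np.diag(cov), 1.7, atol=0, rtol=0)
    d = great_circle_km(coords[:, 0], coords[:, 1])
    assert np.allclose(cov, 1.7 * np.exp(-d / 2000.0), atol=1e-12)


def test_matern_antipodal_limit_and_validation():
    cov = matern_covariance(
        np.array([[0.0, 0.0], [180.0, 0.0]]), nu=1.5, rho=50.0, sigma2=1.0
    )
    assert cov[0, 1] < 1e-12
    with pytest.raises(ValueError):
        matern_correlation(np.zeros((2, 2)), nu=-1.0, rho=10.0)
    with pytest.raises(ValueError):
        matern_covariance(np.zeros((2, 2)), nu=1.5, rho=100.0, sigma2=-1.0)


@pytest.mark.parametrize("nu", [0.5, 1.5, 2.5, 0.8])
def test_matern_positive_semidefinite(nu):
    rng = np.random.default_rng(int(nu * 10))
    coords = _random_coords(rng, 40)
    cov = matern_covariance(coords, nu=nu, rho=3000.0, sigma2=1.0)
    assert np.min(np.linalg.eigvalsh(cov)) >= -1e-8


def test_matern_general_nu_matches_closed_form():
    # Bessel-function branch agrees with the nu = 1.5 closed form
    d = np.linspace(0, 5000, 50)
    a = matern_correlation(d, 1.5, 800.0)
    b = matern_correlation(d, 1.5000001, 800.0)
    assert np.allclose(a, b, atol=1e-5)


def test_degenerate_model_equals_ols(small_config):
    """With no random or spatial part, the ML fit is exactly interacted OLS."""
    cfg = dataclasses.replace(
        small_config,
        sigma_continent=0.0, sigma_family=0.0, sigma_language=0.0,
        matern_variance=0.0, sd_resid=0.8, seed=17,
    )
    table = generate_societies(cfg)
    spec = ModelSpec(include_spatial=False, include_random_effects=False)
    fit = fit_mixed_model(table, spec)
    x, names, y, _ = fixed_design(table.df)
    ols = sm.OLS(y, x).fit()
    assert np.allclose(fit.fe, ols.params, atol=1e-8)
    assert fit.converged and fit.levels == [1, 2, 3, 4, 5]


def test_full_model_on_independent_data_near_ols(small_config):
    """Fitted to data with no group/spatial structure, the full model's
    variance ratios collapse and the fixed effects approach OLS."""
    cfg = dataclasses.replace(
        small_config,
        sigma_continent=0.0, sigma_family=0.0, sigma_language=0.0,
        matern_variance=0.0, sd_resid=0.8, seed=23,
    )
    table = generate_societies(cfg)
    fit = fit_mixed_model(table, ModelSpec())
    x, _, y, _ = fixed_design(table.df)
    ols = sm.OLS(y, x).fit()
    # ML may leave small positive variance components on finite null data,
    # so equality with OLS is statistical, not exact
    assert np.all(np.abs(fit.fe - ols.params) <= 2.0 * fit.fe_se)
    structure = sum(
        v for k, v in fit.varcomp.items()
        if k not in ("sigma2_residual", "sigma2_nugget")
    )
    assert structure < 0.2 * fit.varcomp["sigma2_residual"]
    assert fit.singular  # zero variances are flagged, not hidden


def test_marginal_likelihood_matches_dense_mvn_oracle(small_config):
    """At the optimum the profiled marginal log-likelihood equals a direct
    multivariate-normal density evaluation with the implied mean and
    covariance."""
    cfg = dataclasses.replace(
        small_config, n_per_level=(10, 8, 6, 4, 2), seed=31
    )
    table = generate_societies(cfg)
    fit = fit_mixed_model(table, ModelSpec(maxiter=60))
    x, _, y, _ = fixed_design(table.df)
    v = build_covariance(fit, table)
    oracle = stats.multivariate_normal.logpdf(y, mean=x @ fit.fe, cov=v)
    assert fit.loglik == pytest.approx(oracle, abs=1e-8)


def test_fixed_effect_recovery_coverage(small_config):
    """95% Wald intervals on the fixed effects cover the generating values
    in >= 90% of seeded replicates (pooled over all 10 coefficients)."""
    truth = np.array(
        [reference.FIXED_EFFECTS["intercept"], reference.FIXED_EFFECTS["slope"]]
        + [reference.FIXED_EFFECTS[f"intercept_offset_{w}"] for w in (2, 3, 4, 5)]
        + [reference.FIXED_EFFECTS[f"slope_offset_{w}"] for w in (2, 3, 4, 5)]
    )
    covered = total = 0
    for rep in range(20):
        cfg = dataclasses.replace(small_config, seed=100 + rep)
        table = generate_societies(cfg)
        fit = fit_mixed_model(table, ModelSpec(maxiter=80))
        order = (
            ["intercept", "ln_n"]
            + [f"level_{w}" for w in (2, 3, 4, 5)]
            + [f"ln_n:level_{w}" for w in (2, 3, 4, 5)]
        )
        est = np.array([fit.coef(nm) for nm in order])
        se = np.array([fit.fe_se[fit.fe_names.index(nm)] for nm in order])
        covered += int(np.sum(np.abs(est - truth) <= 1.96 * se))
        total += len(order)
    assert covered / total >= 0.90


def test_level_parameter_assembly():
    # published-coefficient arithmetic
    assert reference.assembled_slopes()[3] == pytest.approx(0.73649, abs=1e-9)
    assert reference.assembled_intercepts()[1] == pytest.approx(2.76438, abs=1e-9)


def test_level_intercepts_slopes_from_fit(small_table):
    fit = fit_mixed_model(small_table, ModelSpec(maxiter=60))
    per_level = level_intercepts_slopes(fit)
    assert [w for w, _, _ in per_level] == [1, 2, 3, 4, 5]
    base_int, base_slope = fit.coef("intercept"), fit.coef("ln_n")
    w, a0, b = per_level[2]
    assert a0 == pytest.approx(base_int + fit.coef("level_3"), abs=1e-12)
    assert b == pytest.approx(base_slope + fit.coef("ln_n:level_3"), abs=1e-12)


def test_trend_across_levels():
    flat = trend_across_levels([(1, 2.0), (2, 2.0), (3, 2.0), (4, 2.0)])
    assert flat.slope == pytest.approx(0.0, abs=1e-12)
    assert flat.factor == pytest.approx(1.0, abs=1e-12)
    ints = list(zip(reference.LEVELS, reference.assembled_intercepts()))
    slps = list(zip(reference.LEVELS, reference.assembled_slopes()))
    t_int = trend_across_levels(ints)
    t_slp = trend_across_levels(slps)
    assert t_int.slope == pytest.approx(-0.8758, abs=1e-3)
    assert t_int.factor == pytest.approx(0.4165, abs=1e-3)
    assert t_slp.factor == pytest.approx(1.0678, abs=1e-3)
    with pytest.raises(ValueError):
        trend_across_levels([(1, 0.0), (2, 1.0)])


def test_cross_validation_noise_free_is_perfect(small_config):
    cfg = dataclasses.replace(
        small_config.noise_free(),
        n_per_level=(40, 30, 20, 15, 10),
        sd_log_n=(2.0,) * 5,  # keep variation in the regressor
        seed=41,
    )
    table = generate_societies(cfg)
    cv = cross_validate(table, ModelSpec(maxiter=40), seed=1)
    assert cv.train_r2 == pytest.approx(1.0, abs=1e-6)
    assert cv.test_r2 == pytest.approx(1.0, abs=1e-6)


def test_cross_validation_overfits_in_the_right_direction(small_config):
    """In-sample fit (with predicted random effects) beats out-of-sample
    prediction in every seeded replicate."""
    worse = 0
    for seed in range(5):
        table = generate_societies(dataclasses.replace(small_config, seed=60 + seed))
        cv = cross_validate(table, ModelSpec(maxiter=60), seed=seed)
        worse += int(cv.test_r2 < cv.train_r2)
    assert worse == 5


def test_cross_validation_split_sizes(reference_table):
    cv_sizes = []
    for _, grp in reference_table.df.groupby("level"):
        cv_sizes.append(int(round(0.7 * len(grp))))
    # stratified 70/30 on n = 1120: 784/336 up to per-level rounding
    assert abs(sum(cv_sizes) - 784) <= 3


def test_cross_validation_degenerate_split_errors(small_config):
    cfg = dataclasses.replace(
        small_config, n_per_level=(30, 2, 0, 0, 0), seed=71
    )
    table = generate_societies(cfg)
    with pytest.raises(ValueError):
        cross_validate(table, ModelSpec(), train_fraction=0.9, seed=0)
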