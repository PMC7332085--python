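import dataclasses
import math

import numpy as np
import pytest
from scipy import optimize, stats

from polityscale.branching import (
    branching_ratios_adjacent,
    density_fit,
    fit_horton_law,
    level_summaries,
    lognormality_check,
    predict_beta,
    quantile_horton_fit,
)
from polityscale.synth import GeneratorConfig, generate_societies
from tests.conftest import make_table


def _ols_slope_closed_form(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    return float(np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2))


def test_level_summary_closed_form():
    """Two records e^2, e^4 at one level: mean log 3, geomean e^3, sd sqrt(2)."""
    table = make_table(
        [math.e**2, math.e**4], [10.0, 10.0], [1, 1],
    )
    (s,) = level_summaries(table, "N")
    assert s.mean_log == pytest.approx(3.0, abs=1e-12)
    assert s.geomean == pytest.approx(math.e**3, rel=1e-12)
    assert s.sd_log == pytest.approx(math.sqrt(2.0), rel=1e-12)
    assert s.cl_lower < s.geomean < s.cl_upper


def test_level_summary_confidence_limit_formula():
    rng = np.random.default_rng(0)
    vals = np.exp(rng.normal(8.55, 3.03, size=412))
    table = make_table(vals, np.ones(412), [1] * 412)
    (s,) = level_summaries(table, "N")
    half = 1.959963984540054 * s.sd_log / math.sqrt(412)
    assert s.cl_lower == pytest.approx(math.exp(s.mean_log - half), rel=1e-12)
    assert s.cl_upper == pytest.approx(math.exp(s.mean_log + half), rel=1e-12)


def test_single_record_level_degenerate():
    table = make_table([100.0, 200.0, 300.0, 400.0], [1, 1, 1, 1], [1, 1, 2, 3])
    summ = level_summaries(table, "N")
    by_level = {s.level: s for s in summ}
    assert by_level[2].degenerate and by_level[3].degenerate
    assert by_level[2].cl_lower == by_level[2].geomean == by_level[2].cl_upper
    assert not by_level[1].degenerate


def test_adjacent_ratios():
    table = make_table(
        [math.exp(1.5 * w) for w in (1, 2, 3, 5)] * 2,
        [1.0] * 8,
        [1, 2, 3, 5] * 2,
    )
    summ = level_summaries(table, "N")
    ratios = branching_ratios_adjacent(summ)
    assert ratios[0][:2] == (1, 2) and ratios[0][2] == pytest.approx(math.exp(1.5))
    assert ratios[1][2] == pytest.approx(math.exp(1.5))
    # gap between 3 and 5 reported, never interpolated
    assert ratios[2] == (3, 5, None)
    with pytest.raises(ValueError):
        branching_ratios_adjacent(summ[:1])


def test_identical_geomeans_give_unit_ratios():
    table = make_table([50.0] * 6, [1.0] * 6, [1, 1, 2, 2, 3, 3])
    for _, _, r in branching_ratios_adjacent(level_summaries(table, "N")):
        assert r == pytest.approx(1.0, rel=1e-12)


def test_horton_fit_exact_line_and_ols_oracle():
    # exact line: slope recovered with R^2 = 1 and ratio = exp(slope)
    table = make_table(
        [math.exp(2.0 + 0.7 * w) for w in range(1, 6)],
        [1.0] * 5,
        list(range(1, 6)),
    )
    fit = fit_horton_law(level_summaries(table, "N"))
    assert fit.slope == pytest.approx(0.7, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
    assert fit.branching_ratio == math.exp(fit.slope)  # exact identity
    assert fit.self_similar

    # OLS slope equals the closed-form hand computation on a noisy instance
    means = [8.1, 10.3, 11.9, 13.8, 14.1]
    noisy = make_table(
        [math.exp(m) for m in means], [1.0] * 5, list(range(1, 6))
    )
    fit2 = fit_horton_law(level_summaries(noisy, "N"))
    assert fit2.slope == pytest.approx(
        _ols_slope_closed_form(range(1, 6), means), abs=1e-12
    )
    # CI bounds are exp(slope +/- t * se) with 3 degrees of freedom
    tq = stats.t.ppf(0.975, 3)
    assert fit2.ratio_ci_lower == pytest.approx(
        math.exp(fit2.slope - tq * fit2.slope_se), rel=1e-12
    )
    assert fit2.ratio_ci_upper == pytest.approx(
        math.exp(fit2.slope + tq * fit2.slope_se), rel=1e-12
    )


def test_horton_fit_requires_three_levels():
    table = make_table([10.0, 20.0, 30.0, 60.0], [1.0] * 4, [1, 1, 2, 2])
    with pytest.raises(ValueError):
        fit_horton_law(level_summaries(table, "N"))


def test_adjacent_ratio_consistency_property():
    """Geometric mean of adjacent ratios equals exp((m_last - m_first)/(L-1))
    for a full run of levels."""
    rng = np.random.default_rng(7)
    vals = np.exp(rng.normal(9, 2, size=100))
    table = make_table(vals, np.ones(100), list(np.arange(100) % 5 + 1))
    summ = level_summaries(table, "N")
    ratios = [r for _, _, r in branching_ratios_adjacent(summ)]
    geo = math.exp(np.mean(np.log(ratios)))
    expected = math.exp((summ[-1].mean_log - summ[0].mean_log) / 4)
    assert geo == pytest.approx(expected, rel=1e-12)


def test_density_fit_identity_and_mismatch():
    cfg = GeneratorConfig.from_rates(
        8.0, 1.5, n_per_level=(30, 30, 30, 30, 30), seed=9,
        sd_log_n=(1.0,) * 5,
    )
    table = generate_societies(cfg)
    fit_n = fit_horton_law(level_summaries(table, "N"))
    fit_a = fit_horton_law(level_summaries(table, "A"))
    fit_d = density_fit(fit_n, fit_a, level_summaries(table, "D"))
    # theta = lam - gamma is an exact identity for per-record density
    assert fit_d.slope == pytest.approx(fit_n.slope - fit_a.slope, abs=1e-9)

    partial = make_table([1.0, 2.0, 4.0], [1.0] * 3, [1, 2, 3])
    fit3 = fit_horton_law(level_summaries(partial, "N"))
    with pytest.raises(ValueError, match="different level sets"):
        density_fit(fit_n, fit3, level_summaries(table, "D"))


def test_noise_free_density_rate_exact():
    cfg = GeneratorConfig.from_rates(
        8.0, 1.5, gamma=0.7, base_log_a=7.0,
        n_per_level=(5,) * 5, seed=0,
    ).noise_free()
    table = generate_societies(cfg)
    fit_n = fit_horton_law(level_summaries(table, "N"))
    fit_a = fit_horton_law(level_summaries(table, "A"))
    fit_d = density_fit(fit_n, fit_a, level_summaries(table, "D"))
    assert fit_d.slope == pytest.approx(0.8, abs=1e-9)
    assert fit_d.branching_ratio == pytest.approx(math.exp(0.8), rel=1e-9)


def test_predict_beta():
    table = make_table(
        [math.exp(8 + 1.5 * w) for w in range(5)],
        [math.exp(7 + 0.7 * w) for w in range(5)],
        list(range(1, 6)),
    )
    fit_n = fit_horton_law(level_summaries(table, "N"))
    fit_a = fit_horton_law(level_summaries(table, "A"))
    beta = predict_beta(fit_n, fit_a)
    assert beta.beta == pytest.approx(0.7 / 1.5, abs=1e-9)
    assert f"{beta.beta:.2f}" == "0.47"
    # gamma = lam => beta = 1 (area proportional to N)
    beta1 = predict_beta(fit_n, fit_n)
    assert beta1.beta == pytest.approx(1.0, abs=1e-12)

    flat = make_table([5.0] * 5, [1.0] * 5, list(range(1, 6)))
    fit_flat = fit_horton_law(level_summaries(flat, "N"))
    with pytest.raises(ValueError):
        predict_beta(fit_flat, fit_a)


def test_quantile_slopes_noise_free_all_equal():
    cfg = GeneratorConfig.from_rates(
        8.0, 1.5, gamma=0.7, base_log_a=7.0, n_per_level=(10,) * 5, seed=0
    ).noise_free()
    table = generate_societies(cfg)
    out = quantile_horton_fit(table, "N", [0.1, 0.5, 0.9])
    assert np.allclose(out["slope"], 1.5, atol=1e-8)


def test_median_regression_recovers_rate():
    cfg = GeneratorConfig.from_rates(
        8.0, 1.5, gamma=0.7, base_log_a=7.0,
        n_per_level=(400,) * 5,
        sd_log_n=(1.0,) * 5, sd_log_a=(1.0,) * 5,
        seed=21,
    )
    table = generate_societies(cfg)
    out = quantile_horton_fit(table, "N", [0.5])
    # median slope within Monte-Carlo error of the configured rate
    assert out.loc[0, "slope"] == pytest.approx(1.5, abs=0.1)


def test_median_regression_matches_lad_oracle():
    """q=0.5 slope agrees with brute-force minimization of absolute
    deviations on a 10-point instance."""
    rng = np.random.default_rng(3)
    levels = np.array([1, 1, 2, 2, 3, 3, 4, 4, 5, 5])
    y = 2.0 + 1.1 * levels + rng.normal(0, 0.4, 10)
    table = make_table(np.exp(y), np.ones(10), list(levels))
    out = quantile_horton_fit(table, "N", [0.5])

    def lad(params):
        a, b = params
        return np.sum(np.abs(y - a - b * levels))

    best = min(
        (
            optimize.minimize(lad, x0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
            for x0 in ([2.0, 1.0], [0.0, 0.5], [5.0, 2.0])
        ),
        key=lambda r: r.fun,
    )
    assert lad([out.loc[0, "intercept"], out.loc[0, "slope"]]) <= best.fun + 1e-6


def test_quantile_fit_input_validation(small_table):
    with pytest.raises(ValueError):
        quantile_horton_fit(small_table, "N", [])
    with pytest.raises(ValueError):
        quantile_horton_fit(small_table, "N", [0.0, 0.5])


def test_lognormality_check():
    rng = np.random.default_rng(12)
    lognormal = np.exp(rng.normal(5, 1, 400))
    table = make_table(lognormal, np.ones(400), [1] * 400)
    diag = lognormality_check(table, "N", 1)
    assert diag.sufficient_n
    assert abs(diag.log_skewness) < 0.3
    assert diag.normality_pvalue > 0.01

    # exponential-of-uniform has uniform logs: flagged non-normal
    uniform_logs = np.exp(rng.uniform(0, 1, 400))
    table2 = make_table(uniform_logs, np.ones(400), [1] * 400)
    diag2 = lognormality_check(table2, "N", 1)
    assert diag2.normality_pvalue < 0.01

    small = make_table([1.0, 2.0, 3.0, 4.0, 5.0], np.ones(5), [1] * 5)
    diag3 = lognormality_check(small, "N", 1)
    assert not diag3.sufficient_n
    with pytest.raises(ValueError):
        lognormality_check(small, "N", 4)
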