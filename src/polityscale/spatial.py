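"""Spatial mixed-effects scaling model of geographic range on population size.

The model is the log-log allometry ``ln A = ln A0_w + beta_w ln N`` with the
hierarchy level ``w`` entering as an unordered factor (level 1 is the
reference category), plus random intercepts for continent, language family
within continent and language within family, a Gaussian spatial field with
Matern covariance over great-circle distance, and iid Gaussian residuals:

    ln A = X b + u_C + u_F + u_L + m(lon, lat) + eps

All variance components are estimated jointly with the fixed effects by
maximum likelihood on the Gaussian marginal likelihood (random effects and
the spatial field integrated out). The residual scale is profiled out
analytically, so the optimizer only searches over variance *ratios* and the
Matern range.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special

from .io import SocietyTable

__all__ = [
    "EARTH_RADIUS_KM",
    "ModelSpec",
    "MixedFitResult",
    "CrossValidation",
    "TrendResult",
    "great_circle_km",
    "matern_correlation",
    "matern_covariance",
    "fit_mixed_model",
    "build_covariance",
    "fixed_design",
    "level_intercepts_slopes",
    "trend_across_levels",
    "cross_validate",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


def great_circle_km(
    lon: np.ndarray,
    lat: np.ndarray,
    lon2: np.ndarray | None = None,
    lat2: np.ndarray | None = None,
) -> np.ndarray:
    """Pairwise haversine distances in km between point sets.

    With one point set given, returns the symmetric n x n matrix; with two,
    the n x m cross-distance matrix.
    """
    lon1r = np.radians(np.asarray(lon, dtype=float))[:, None]
    lat1r = np.radians(np.asarray(lat, dtype=float))[:, None]
    if lon2 is None:
        lon2r, lat2r = lon1r.T, lat1r.T
    else:
        lon2r = np.radians(np.asarray(lon2, dtype=float))[None, :]
        lat2r = np.radians(np.asarray(lat2, dtype=float))[None, :]
    dlon = lon2r - lon1r
    dlat = lat2r - lat1r
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1r) * np.cos(lat2r) * np.sin(
        dlon / 2.0
    ) ** 2
    h = np.clip(h, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def matern_correlation(d: np.ndarray, nu: float, rho: float) -> np.ndarray:
    """Matern correlation at distance ``d`` with smoothness nu and range rho.

    Uses the scaled argument x = sqrt(2 nu) d / rho, so nu = 0.5 is exactly
    exp(-d/rho) and correlation is 1 at d = 0 for every nu. Closed forms are
    used for nu in {0.5, 1.5, 2.5}; other nu go through the Bessel-K formula.
    """
    if rho <= 0 or nu <= 0:
        raise ValueError("matern requires rho > 0 and nu > 0")
    d = np.asarray(d, dtype=float)
    x = np.sqrt(2.0 * nu) * d / rho
    if nu == 0.5:
        return np.exp(-x)
    if nu == 1.5:
        return (1.0 + x) * np.exp(-x)
    if nu == 2.5:
        return (1.0 + x + x * x / 3.0) * np.exp(-x)
    with np.errstate(invalid="ignore", over="ignore"):
        out = (2.0 ** (1.0 - nu) / special.gamma(nu)) * x**nu * special.kv(nu, x)
    out = np.where(d == 0.0, 1.0, out)
    return np.nan_to_num(out, nan=0.0)


def matern_covariance(
    coords: np.ndarray, nu: float, rho: float, sigma2: float
) -> np.ndarray:
    """Matern covariance matrix over great-circle distances.

    ``coords`` is an (n, 2) array of (longitude, latitude) in degrees. The
    diagonal equals sigma2 exactly.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    coords = np.asarray(coords, dtype=float)
    d = great_circle_km(coords[:, 0], coords[:, 1])
    return sigma2 * matern_correlation(d, nu, rho)


@dataclass
class ModelSpec:
    """Configuration of the spatial mixed scaling model.

    ``nu`` is the Matern smoothness; with ``profile_nu`` the model is
    refitted for each value in ``nu_grid`` and the best marginal likelihood
    wins. ``nugget`` is carried for covariance construction but is not a
    free parameter in fitting: a spatial nugget and the iid residual are
    indistinguishable without repeated coordinates, so the fitted residual
    variance absorbs any nugget. ``family_random_slope`` adds a random
    ln N slope by language family.
    """

    nu: float = 1.5
    profile_nu: bool = False
    nu_grid: tuple[float, ...] = (0.5, 1.5, 2.5)
    nugget: float = 0.0
    include_spatial: bool = True
    include_random_effects: bool = True
    family_random_slope: bool = False
    rho_init_km: float = 1000.0
    rho_bounds_km: tuple[float, float] = (10.0, 20000.0)
    maxiter: int = 200

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if self.nugget < 0:
            raise ValueError("nugget must be non-negative")


@dataclass
class MixedFitResult:
    """Maximum-likelihood fit of the spatial mixed scaling model."""

    fe_names: list[str]
    fe: np.ndarray
    fe_se: np.ndarray
    t_values: np.ndarray
    varcomp: dict[str, float]
    nu: float
    rho_km: float
    loglik: float
    converged: bool
    singular: bool
    n: int
    levels: list[int]
    reference_level: int
    spec: ModelSpec

    def coef(self, name: str) -> float:
        return float(self.fe[self.fe_names.index(name)])

    def to_frame(self) -> pd.DataFrame:
        """Fixed-effect table: estimate, conditional SE, t-value.

        t-values are reported without p-values; the ML fit has no exact
        reference distribution for them.
        """
        return pd.DataFrame(
            {
                "fixed_effect": self.fe_names,
                "estimate": self.fe,
                "cond_se": self.fe_se,
                "t_value": self.t_values,
            }
        )


@dataclass
class CrossValidation:
    """Out-of-sample validation of the mixed model on a stratified split."""

    train_fraction: float
    seed: int
    train_r2: float
    test_r2: float
    train_r2_sse: float
    test_r2_sse: float
    n_train: int
    n_test: int


@dataclass
class TrendResult:
    """OLS trend of a per-level parameter against hierarchy level."""

    slope: float
    slope_se: float
    intercept: float
    factor: float  # exp(slope): multiplicative change per level


def fixed_design(
    df: pd.DataFrame, levels: Sequence[int] | None = None
) -> tuple[np.ndarray, list[str], np.ndarray, int]:
    """Design matrix for ln A ~ ln N x factor(level), reference = min level.

    Returns (X, column names, y = ln A, reference level). ``levels`` fixes
    the factor coding (needed so a test split uses the training coding).
    """
    if levels is None:
        levels = sorted(df["level"].unique())
    levels = sorted(levels)
    ref = levels[0]
    ln_n = np.log(df["pop_size"].to_numpy(dtype=float))
    y = np.log(df["range_area_km2"].to_numpy(dtype=float))
    cols = [np.ones(len(df)), ln_n]
    names = ["intercept", "ln_n"]
    lev = df["level"].to_numpy()
    for w in levels[1:]:
        ind = (lev == w).astype(float)
        cols.append(ind)
        names.append(f"level_{w}")
    for w in levels[1:]:
        ind = (lev == w).astype(float)
        cols.append(ind * ln_n)
        names.append(f"ln_n:level_{w}")
    return np.column_stack(cols), names, y, ref


def _group_kernels(df: pd.DataFrame, spec: ModelSpec) -> dict[str, np.ndarray]:
    """Equal-group indicator kernels Z Z' for the nested random intercepts."""
    kernels: dict[str, np.ndarray] = {}
    if not spec.include_random_effects:
        return kernels
    for name, col in (
        ("continent", "continent"),
        ("family", "family"),
        ("language", "language"),
    ):
        codes = pd.factorize(df[col])[0]
        kernels[name] = (codes[:, None] == codes[None, :]).astype(float)
    if spec.family_random_slope:
        ln_n = np.log(df["pop_size"].to_numpy(dtype=float))
        kernels["family_slope"] = kernels["family"] * np.outer(ln_n, ln_n)
    return kernels


def _chol_with_jitter(w: np.ndarray) -> tuple[np.ndarray, float]:
    """Cholesky factor of W, adding diagonal jitter if needed (logged)."""
    jitter = 0.0
    for _ in range(6):
        try:
            c = linalg.cholesky(
                w + jitter * np.eye(len(w)), lower=True, check_finite=False
            )
            if jitter > 0:
                logger.warning("added jitter %.1e to covariance diagonal", jitter)
            return c, jitter
        except linalg.LinAlgError:
            jitter = 1e-10 if jitter == 0.0 else jitter * 100.0
    raise linalg.LinAlgError("covariance not positive definite even with jitter")


def _profiled_neg2ll(
    w: np.ndarray, x: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray, float, np.ndarray]:
    """Profile beta and the residual scale out of the Gaussian -2 loglik.

    V = sigma2 * W; given W, the ML estimates are beta = GLS(W) and
    sigma2 = r' W^-1 r / n. Returns (-2 loglik, beta, sigma2, xtwx_inv).
    """
    n = len(y)
    c, _ = _chol_with_jitter(w)
    logdet_w = 2.0 * np.sum(np.log(np.diag(c)))
    cx = linalg.solve_triangular(c, x, lower=True, check_finite=False)
    cy = linalg.solve_triangular(c, y, lower=True, check_finite=False)
    xtwx = cx.T @ cx
    xtwy = cx.T @ cy
    xtwx_inv = linalg.inv(xtwx)
    beta = xtwx_inv @ xtwy
    resid = cy - cx @ beta
    sigma2 = max(float(resid @ resid) / n, 1e-300)
    neg2ll = n * math.log(2.0 * math.pi * sigma2) + logdet_w + n
    return neg2ll, beta, sigma2, xtwx_inv


def _fit_at_nu(
    df: pd.DataFrame, spec: ModelSpec, nu: float
) -> tuple[MixedFitResult, np.ndarray]:
    x, names, y, ref = fixed_design(df)
    n = len(y)
    kernels = _group_kernels(df, spec)
    kernel_names = list(kernels)
    dist = None
    if spec.include_spatial:
        dist = great_circle_km(
            df["longitude"].to_numpy(), df["latitude"].to_numpy()
        )

    eye = np.eye(n)
    log_rho_bounds = (
        math.log(spec.rho_bounds_km[0]),
        math.log(spec.rho_bounds_km[1]),
    )

    def build_w(theta: np.ndarray) -> np.ndarray:
        w = eye.copy()
        for i, kname in enumerate(kernel_names):
            w += math.exp(theta[i]) * kernels[kname]
        if spec.include_spatial:
            g_m = math.exp(theta[len(kernel_names)])
            rho = math.exp(theta[len(kernel_names) + 1])
            w += g_m * matern_correlation(dist, nu, rho)
        return w

    def objective(theta: np.ndarray) -> float:
        try:
            return _profiled_neg2ll(build_w(theta), x, y)[0]
        except linalg.LinAlgError:
            return 1e12

    x0 = [math.log(0.1)] * len(kernel_names)
    bounds: list[tuple[float, float]] = [(-18.0, 6.0)] * len(kernel_names)
    if spec.include_spatial:
        x0 += [math.log(0.1), math.log(spec.rho_init_km)]
        bounds += [(-18.0, 6.0), log_rho_bounds]

    if x0:
        res = optimize.minimize(
            objective,
            np.array(x0),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": spec.maxiter, "ftol": 1e-10},
        )
        theta, success, message = res.x, bool(res.success), str(res.message)
    else:
        # no free covariance parameters: the model is plain OLS
        theta, success, message = np.array([]), True, "no covariance parameters"
    w = build_w(theta)
    neg2ll, beta, sigma2, xtwx_inv = _profiled_neg2ll(w, x, y)
    fe_cov = sigma2 * xtwx_inv
    fe_se = np.sqrt(np.diag(fe_cov))

    ratios = {kname: math.exp(theta[i]) for i, kname in enumerate(kernel_names)}
    rho_km = float("nan")
    if spec.include_spatial:
        ratios["spatial"] = math.exp(theta[len(kernel_names)])
        rho_km = math.exp(theta[len(kernel_names) + 1])
    varcomp = {f"sigma2_{k}": sigma2 * g for k, g in ratios.items()}
    varcomp["sigma2_nugget"] = spec.nugget
    varcomp["sigma2_residual"] = sigma2
    singular = any(g < 1e-5 for g in ratios.values())
    if not success:
        logger.warning("mixed-model optimizer did not converge: %s", message)

    fit = MixedFitResult(
        fe_names=names,
        fe=beta,
        fe_se=fe_se,
        t_values=beta / np.where(fe_se > 0, fe_se, np.nan),
        varcomp=varcomp,
        nu=nu,
        rho_km=rho_km,
        loglik=-0.5 * neg2ll,
        converged=success,
        singular=singular,
        n=n,
        levels=sorted(df["level"].unique()),
        reference_level=ref,
        spec=spec,
    )
    return fit, w


def fit_mixed_model(table: SocietyTable, spec: ModelSpec | None = None) -> MixedFitResult:
    """Fit the spatial mixed scaling model by maximum likelihood.

    Requires at least two levels present and complete coordinates and
    nesting labels (guaranteed by the SocietyTable invariants). Returns a
    flagged (never silently wrong) result: ``converged`` reports optimizer
    status and ``singular`` marks variance ratios pinned near zero.
    """
    spec = spec or ModelSpec()
    df = table.df
    if df["level"].nunique() < 2:
        raise ValueError("mixed model requires at least two levels present")
    if spec.profile_nu:
        best: MixedFitResult | None = None
        for nu in spec.nu_grid:
            fit, _ = _fit_at_nu(df, spec, nu)
            if best is None or fit.loglik > best.loglik:
                best = fit
        assert best is not None
        return best
    fit, _ = _fit_at_nu(df, spec, spec.nu)
    return fit


def _w_matrix(fit: MixedFitResult, df: pd.DataFrame) -> np.ndarray:
    """Rebuild the fitted correlation-scale matrix W with V = sigma2 W."""
    sigma2 = fit.varcomp["sigma2_residual"]
    w = np.eye(len(df))
    kernels = _group_kernels(df, fit.spec)
    for kname, k in kernels.items():
        w += (fit.varcomp[f"sigma2_{kname}"] / sigma2) * k
    if fit.spec.include_spatial:
        dist = great_circle_km(
            df["longitude"].to_numpy(), df["latitude"].to_numpy()
        )
        w += (fit.varcomp["sigma2_spatial"] / sigma2) * matern_correlation(
            dist, fit.nu, fit.rho_km
        )
    return w


def build_covariance(fit: MixedFitResult, table: SocietyTable) -> np.ndarray:
    """Fitted marginal covariance V of ln A for the given records."""
    return fit.varcomp["sigma2_residual"] * _w_matrix(fit, table.df)


def level_intercepts_slopes(fit: MixedFitResult) -> list[tuple[int, float, float]]:
    """Per-level (level, intercept ln A0_w, slope beta_w) from base + offsets."""
    if not fit.converged:
        logger.warning("assembling level parameters from a non-converged fit")
    out = []
    base_int = fit.coef("intercept")
    base_slope = fit.coef("ln_n")
    for w in fit.levels:
        if w == fit.reference_level:
            out.append((w, base_int, base_slope))
        else:
            out.append(
                (
                    w,
                    base_int + fit.coef(f"level_{w}"),
                    base_slope + fit.coef(f"ln_n:level_{w}"),
                )
            )
    return out


def trend_across_levels(per_level_values: Sequence[tuple[int, float]]) -> TrendResult:
    """Unweighted OLS of a per-level parameter on level, with exp(slope).

    The returned ``factor`` is the multiplicative change of the parameter
    per additional level of hierarchy.
    """
    if len(per_level_values) < 3:
        raise ValueError("trend requires at least 3 levels")
    w = np.array([p[0] for p in per_level_values], dtype=float)
    v = np.array([p[1] for p in per_level_values], dtype=float)
    slope, intercept = np.polyfit(w, v, 1)
    resid = v - (slope * w + intercept)
    dof = len(w) - 2
    se = (
        math.sqrt(float(resid @ resid) / dof / float(np.sum((w - w.mean()) ** 2)))
        if dof > 0
        else float("nan")
    )
    return TrendResult(
        slope=float(slope),
        slope_se=se,
        intercept=float(intercept),
        factor=float(np.exp(slope)),
    )


def _cross_w(
    fit: MixedFitResult, df_a: pd.DataFrame, df_b: pd.DataFrame
) -> np.ndarray:
    """Cross-covariance (in W units) between two record sets under the fit."""
    sigma2 = fit.varcomp["sigma2_residual"]
    n_a, n_b = len(df_a), len(df_b)
    w = np.zeros((n_a, n_b))
    for kname, col in (
        ("continent", "continent"),
        ("family", "family"),
        ("language", "language"),
    ):
        match = (
            df_a[col].to_numpy()[:, None] == df_b[col].to_numpy()[None, :]
        ).astype(float)
        w += (fit.varcomp[f"sigma2_{kname}"] / sigma2) * match
    if fit.spec.family_random_slope:
        match = (
            df_a["family"].to_numpy()[:, None]
            == df_b["family"].to_numpy()[None, :]
        ).astype(float)
        ln_a = np.log(df_a["pop_size"].to_numpy(dtype=float))
        ln_b = np.log(df_b["pop_size"].to_numpy(dtype=float))
        w += (
            fit.varcomp["sigma2_family_slope"] / sigma2
        ) * match * np.outer(ln_a, ln_b)
    if fit.spec.include_spatial:
        dist = great_circle_km(
            df_a["longitude"].to_numpy(),
            df_a["latitude"].to_numpy(),
            df_b["longitude"].to_numpy(),
            df_b["latitude"].to_numpy(),
        )
        w += (fit.varcomp["sigma2_spatial"] / sigma2) * matern_correlation(
            dist, fit.nu, fit.rho_km
        )
    return w


def _r2_pair(obs: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    """(squared Pearson correlation, 1 - SSE/SST)."""
    if np.std(pred) == 0 or np.std(obs) == 0:
        corr2 = 1.0 if np.allclose(obs, pred) else 0.0
    else:
        corr2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    sse = float(np.sum((obs - pred) ** 2))
    r2_sse = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else 0.0)
    return corr2, r2_sse


def cross_validate(
    table: SocietyTable,
    spec: ModelSpec | None = None,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> CrossValidation:
    """Train/test split validation of the mixed model.

    The split is stratified by level (seed-deterministic). Test predictions
    use the fixed effects plus the best linear predictor of the random and
    spatial parts given the training residuals; groups or regions unseen in
    training contribute nothing beyond the fixed effects (population-level
    prediction). R^2 is the squared Pearson correlation of observed vs
    predicted ln A; a 1 - SSE/SST variant is reported alongside.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    spec = spec or ModelSpec()
    df = table.df
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for _, grp in df.groupby("level"):
        perm = rng.permutation(grp.index.to_numpy())
        n_train = int(round(train_fraction * len(perm)))
        n_train = min(max(n_train, 1), len(perm))
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    train_df = df.loc[sorted(train_idx)].reset_index(drop=True)
    test_df = df.loc[sorted(test_idx)].reset_index(drop=True)
    if train_df["level"].nunique() < 2 or test_df["level"].nunique() < 2:
        raise ValueError("degenerate split: fewer than 2 levels in a partition")
    if not set(test_df["level"]).issubset(set(train_df["level"])):
        raise ValueError("test split contains a level absent from training")

    train_table = SocietyTable(train_df, provenance="cv-train")
    fit = fit_mixed_model(train_table, spec)

    x_train, _, y_train, _ = fixed_design(train_df, levels=fit.levels)
    x_test, _, y_test, _ = fixed_design(test_df, levels=fit.levels)
    w_train = _w_matrix(fit, train_df)
    c, _ = _chol_with_jitter(w_train)
    resid = y_train - x_train @ fit.fe
    alpha = linalg.cho_solve((c, True), resid, check_finite=False)

    # BLUP of the structured (non-iid) part at the training points; at the
    # test points the cross-covariance with training drives the prediction.
    fitted_train = x_train @ fit.fe + (w_train - np.eye(len(y_train))) @ alpha
    pred_test = x_test @ fit.fe + _cross_w(fit, test_df, train_df) @ alpha

    train_r2, train_r2_sse = _r2_pair(y_train, fitted_train)
    test_r2, test_r2_sse = _r2_pair(y_test, pred_test)
    return CrossValidation(
        train_fraction=train_fraction,
        seed=seed,
        train_r2=train_r2,
        test_r2=test_r2,
        train_r2_sse=train_r2_sse,
        test_r2_sse=test_r2_sse,
        n_train=len(train_df),
        n_test=len(test_df),
    )
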