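"""Synthetic society tables with the statistical structure of the study data.

The generator draws, per hierarchy level ``w``, lognormal population sizes
(configurable per-level log-moments, or log-means linear in ``w`` at rate
``lam``), then produces geographic ranges either

* ``allometric`` mode — through the within-level power law
  ``ln A = ln A0_w + beta_w ln N`` plus nested continent/family/language
  random intercepts, a Matern Gaussian field over great-circle distance and
  iid residual noise (the structure the spatial mixed model assumes), or
* ``direct`` mode — as per-level lognormals with log-means linear in ``w``
  at rate ``gamma``, for exercising the branching analysis in isolation.

Locations are scattered around fixed, dispersed continent centers; the
nesting continent(family(language)) is strict by construction. A fixed seed
fully determines the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import reference
from .io import COLUMNS, SocietyTable
from .spatial import great_circle_km, matern_correlation

__all__ = [
    "CONTINENT_CENTERS",
    "GeneratorConfig",
    "reference_config",
    "generate_societies",
]

#: Fixed, dispersed continent centers (longitude, latitude) used to scatter
#: synthetic locations. Chosen to span the continents' rough centroids.
CONTINENT_CENTERS: tuple[tuple[float, float], ...] = (
    (-100.0, 45.0),  # North America
    (-60.0, -15.0),  # South America
    (20.0, 5.0),     # Africa
    (45.0, 50.0),    # western Eurasia
    (100.0, 35.0),   # eastern Asia
    (140.0, -25.0),  # Oceania
)


@dataclass(frozen=True)
class GeneratorConfig:
    """All parameters of the synthetic society generator.

    Per-level tuples are indexed by level 1..5 (length 5); a level with
    ``n_per_level[w-1] == 0`` is simply absent from the output.
    """

    n_per_level: tuple[int, ...] = reference.SAMPLE_SIZES
    mean_log_n: tuple[float, ...] = reference.MEAN_LOG_POP
    sd_log_n: tuple[float, ...] = reference.SD_LOG_POP

    area_mode: str = "allometric"  # or "direct"
    # allometric mode: ln A = ln_a0[w] + beta[w] * ln N + random parts
    ln_a0: tuple[float, ...] = field(default_factory=reference.assembled_intercepts)
    beta: tuple[float, ...] = field(default_factory=reference.assembled_slopes)
    sd_resid: float = 0.8
    # direct mode: ln A ~ Normal(mean_log_a[w], sd_log_a[w]) (no random parts)
    mean_log_a: tuple[float, ...] = reference.MEAN_LOG_AREA
    sd_log_a: tuple[float, ...] = reference.SD_LOG_AREA

    # nested random-intercept standard deviations
    sigma_continent: float = 0.4
    sigma_family: float = 0.5
    sigma_language: float = 0.5

    # Matern spatial field (variance, range in km, smoothness)
    matern_variance: float = 0.25
    matern_range_km: float = 1500.0
    matern_nu: float = 1.5

    # grouping structure and geography
    n_continents: int = 6
    families_per_continent: int = 25
    languages_per_family: int = 6
    scatter_deg: float = 12.0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sd_resid",
            "sigma_continent",
            "sigma_family",
            "sigma_language",
            "matern_variance",
            "scatter_deg",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for tup in (self.sd_log_n, self.sd_log_a):
            if any(s < 0 for s in tup):
                raise ValueError("per-level sds must be non-negative")
        if any(n < 0 for n in self.n_per_level):
            raise ValueError("n_per_level must be non-negative")
        if sum(self.n_per_level) == 0:
            raise ValueError("at least one level must have records")
        if self.area_mode not in ("allometric", "direct"):
            raise ValueError("area_mode must be 'allometric' or 'direct'")
        if not all(map(math.isfinite, self.beta)):
            raise ValueError("allometric exponents must be finite")
        if self.matern_nu <= 0 or self.matern_range_km <= 0:
            raise ValueError("Matern parameters must be positive")
        if not 1 <= self.n_continents <= len(CONTINENT_CENTERS):
            raise ValueError(
                f"n_continents must be in 1..{len(CONTINENT_CENTERS)}"
            )

    @classmethod
    def from_rates(
        cls,
        base_log_n: float,
        lam: float,
        gamma: float | None = None,
        base_log_a: float | None = None,
        **kwargs,
    ) -> "GeneratorConfig":
        """Config with log-means exactly linear in level.

        ``ln N`` means follow ``base_log_n + lam * (w - 1)``; if ``gamma``
        and ``base_log_a`` are given the config switches to direct area mode
        with ``ln A`` means ``base_log_a + gamma * (w - 1)``.
        """
        kwargs["mean_log_n"] = tuple(base_log_n + lam * k for k in range(5))
        if gamma is not None:
            if base_log_a is None:
                raise ValueError("base_log_a required with gamma")
            kwargs.setdefault("area_mode", "direct")
            kwargs["mean_log_a"] = tuple(
                base_log_a + gamma * k for k in range(5)
            )
        return cls(**kwargs)

    def noise_free(self) -> "GeneratorConfig":
        """Copy with every noise source zeroed (deterministic limit)."""
        return replace(
            self,
            sd_log_n=(0.0,) * 5,
            sd_log_a=(0.0,) * 5,
            sd_resid=0.0,
            sigma_continent=0.0,
            sigma_family=0.0,
            sigma_language=0.0,
            matern_variance=0.0,
        )


def reference_config(seed: int) -> GeneratorConfig:
    """Generator configuration matching the study sample's conditions.

    Per-level sample sizes and log-moments of N come from the published
    descriptive statistics; the level-specific allometric intercepts and
    elasticities come from the published fixed-effect estimates. The
    random-effect, spatial, and residual variances are set so the implied
    per-level spread of ln A matches the published level-1 value
    (sqrt(beta_1^2 sd_lnN_1^2 + total variance) ~ 2.0).
    """
    return GeneratorConfig(seed=seed)


def _assign_groups(
    rng: np.random.Generator, n: int, config: GeneratorConfig
) -> pd.DataFrame:
    """Draw a language per record; nesting fixes family and continent."""
    n_fam = config.n_continents * config.families_per_continent
    n_lang = n_fam * config.languages_per_family
    lang_ids = rng.integers(0, n_lang, size=n)
    fam_ids = lang_ids // config.languages_per_family
    cont_ids = fam_ids // config.families_per_continent
    return pd.DataFrame(
        {
            "language": [f"L{i:04d}" for i in lang_ids],
            "family": [f"F{i:03d}" for i in fam_ids],
            "continent": [f"C{i}" for i in cont_ids],
            "_lang_id": lang_ids,
            "_fam_id": fam_ids,
            "_cont_id": cont_ids,
        }
    )


def _scatter_locations(
    rng: np.random.Generator, cont_ids: np.ndarray, config: GeneratorConfig
) -> tuple[np.ndarray, np.ndarray]:
    centers = np.array(CONTINENT_CENTERS[: config.n_continents])
    lon = centers[cont_ids, 0] + rng.normal(0.0, config.scatter_deg, len(cont_ids))
    lat = centers[cont_ids, 1] + rng.normal(0.0, config.scatter_deg, len(cont_ids))
    lon = (lon + 180.0) % 360.0 - 180.0
    lat = np.clip(lat, -89.0, 89.0)
    return lon, lat


def _group_effects(
    rng: np.random.Generator, ids: np.ndarray, sigma: float
) -> np.ndarray:
    """One iid Normal(0, sigma) effect per distinct group, broadcast to rows."""
    n_groups = int(ids.max()) + 1 if len(ids) else 0
    draws = rng.normal(0.0, sigma, size=n_groups)
    return draws[ids]


def _spatial_field(
    rng: np.random.Generator,
    lon: np.ndarray,
    lat: np.ndarray,
    config: GeneratorConfig,
) -> np.ndarray:
    """Zero-mean Gaussian field with Matern covariance over great circles."""
    if config.matern_variance == 0.0:
        return np.zeros(len(lon))
    d = great_circle_km(lon, lat)
    cov = config.matern_variance * matern_correlation(
        d, config.matern_nu, config.matern_range_km
    )
    cov[np.diag_indices_from(cov)] += 1e-10  # draw-time jitter
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(len(lon))


def generate_societies(config: GeneratorConfig) -> SocietyTable:
    """Generate a synthetic society table under ``config``.

    Output is byte-identical for identical configs (the seed drives a single
    ``numpy`` Generator through a fixed draw order).
    """
    rng = np.random.default_rng(config.seed)
    levels = np.concatenate(
        [
            np.full(n, w, dtype=int)
            for w, n in zip(range(1, 6), config.n_per_level)
        ]
    )
    n = len(levels)

    groups = _assign_groups(rng, n, config)
    lon, lat = _scatter_locations(rng, groups["_cont_id"].to_numpy(), config)

    mean_n = np.array(config.mean_log_n)[levels - 1]
    sd_n = np.array(config.sd_log_n)[levels - 1]
    ln_n = mean_n + sd_n * rng.standard_normal(n)

    if config.area_mode == "direct":
        mean_a = np.array(config.mean_log_a)[levels - 1]
        sd_a = np.array(config.sd_log_a)[levels - 1]
        ln_a = mean_a + sd_a * rng.standard_normal(n)
    else:
        a0 = np.array(config.ln_a0)[levels - 1]
        beta = np.array(config.beta)[levels - 1]
        u_c = _group_effects(
            rng, groups["_cont_id"].to_numpy(), config.sigma_continent
        )
        u_f = _group_effects(rng, groups["_fam_id"].to_numpy(), config.sigma_family)
        u_l = _group_effects(
            rng, groups["_lang_id"].to_numpy(), config.sigma_language
        )
        m = _spatial_field(rng, lon, lat, config)
        eps = config.sd_resid * rng.standard_normal(n)
        ln_a = a0 + beta * ln_n + u_c + u_f + u_l + m + eps

    df = pd.DataFrame(
        {
            "society_id": [f"S{i:05d}" for i in range(n)],
            "language": groups["language"],
            "family": groups["family"],
            "continent": groups["continent"],
            "longitude": lon,
            "latitude": lat,
            "pop_size": np.exp(ln_n),
            "range_area_km2": np.exp(ln_a),
            "level": levels,
        },
        columns=list(COLUMNS),
    )
    return SocietyTable(df, provenance=f"synthetic seed={config.seed}")
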