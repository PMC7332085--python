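"""Reference statistics for the global cross-cultural sample.

These are the published per-level descriptive statistics (sample sizes and
log-moments of population size N and geographic range A, with geometric
means and 95% confidence limits) and the fixed-effect coefficients of the
spatial scaling model fitted to that sample. They serve two purposes:

1. They parameterize :func:`polityscale.synth.reference_config`, so the
   synthetic generator reproduces the statistical conditions of the study
   sample (per-level composition, lognormal moments, level-specific
   allometry).
2. They are the inputs for purely arithmetic re-derivations: branching
   ratios from the level means, per-level intercepts/slopes assembled from
   the coefficient table, and cross-level trends of those parameters.

Levels ``1..5`` are the jurisdictional-hierarchy orders (acephalous
societies up to large states).
"""

from __future__ import annotations

LEVELS: tuple[int, ...] = (1, 2, 3, 4, 5)

#: Number of ethnolinguistic populations observed at each level.
SAMPLE_SIZES: tuple[int, ...] = (412, 351, 187, 140, 30)

#: Per-level mean of ln N (population size).
MEAN_LOG_POP: tuple[float, ...] = (8.55, 10.15, 12.08, 13.48, 14.29)

#: Per-level standard deviation of ln N.
SD_LOG_POP: tuple[float, ...] = (3.03, 2.93, 2.59, 2.73, 3.81)

#: Per-level mean of ln A (geographic range, km^2).
MEAN_LOG_AREA: tuple[float, ...] = (7.40, 7.47, 8.70, 9.48, 9.58)

#: Per-level standard deviation of ln A.
SD_LOG_AREA: tuple[float, ...] = (2.03, 2.18, 2.38, 2.54, 3.71)

#: Printed geometric means of N per level.
GEOMEAN_POP: tuple[float, ...] = (5176, 25628, 177106, 713318, 1599611)

#: Printed 95% confidence limits (lower, upper) for the geometric mean of N.
POP_CL: tuple[tuple[float, float], ...] = (
    (3863, 6935),
    (18866, 34813),
    (122230, 256620),
    (453540, 1121893),
    (408630, 6261798),
)

#: Printed geometric means of A per level (km^2).
GEOMEAN_AREA: tuple[float, ...] = (1643, 1754, 6004, 13094, 14432)

#: Printed 95% confidence limits (lower, upper) for the geometric mean of A.
AREA_CL: tuple[tuple[float, float], ...] = (
    (1351, 1997),
    (1396, 2204),
    (4270, 8441),
    (8591, 19959),
    (3829, 54394),
)

#: Fixed effects of the spatial mixed model ln A ~ ln N x level-factor,
#: with level 1 as the reference category. ``intercept`` is ln A0 at level 1
#: and ``slope`` is the level-1 elasticity beta_1 = dlnA/dlnN. The offsets
#: for levels 2-5 are additive on the reference values.
FIXED_EFFECTS: dict[str, float] = {
    "intercept": 3.52938,
    "slope": 0.51185,
    "intercept_offset_2": -0.765,
    "intercept_offset_3": -1.56394,
    "intercept_offset_4": -2.70212,
    "intercept_offset_5": -3.41055,
    "slope_offset_2": 0.06178,
    "slope_offset_3": 0.1409,
    "slope_offset_4": 0.22464,
    "slope_offset_5": 0.24661,
}


def assembled_intercepts() -> tuple[float, ...]:
    """Per-level allometric intercepts ln A0_w = base + offset_w."""
    base = FIXED_EFFECTS["intercept"]
    return (base,) + tuple(
        base + FIXED_EFFECTS[f"intercept_offset_{w}"] for w in LEVELS[1:]
    )


def assembled_slopes() -> tuple[float, ...]:
    """Per-level elasticities beta_w = base + offset_w."""
    base = FIXED_EFFECTS["slope"]
    return (base,) + tuple(
        base + FIXED_EFFECTS[f"slope_offset_{w}"] for w in LEVELS[1:]
    )
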