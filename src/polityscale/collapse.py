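"""Generalized Horton laws: CCDFs, mean-rescaling, and data collapse.

Self-similarity of the *entire* distribution (not just the mean) across
hierarchy levels means that after each level's values are divided by that
level's mean, the per-level distributions superpose onto one curve. The
collapse is quantified by the maximum over level pairs of the two-sample
Kolmogorov-Smirnov distance between the log-rescaled samples, with a
permutation null obtained by shuffling level labels and re-rescaling within
each permuted grouping. KS is invariant under monotone transforms, so the
log transform changes nothing about the statistic; it only symmetrizes the
heavy tails for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .io import SocietyTable

__all__ = [
    "EmpiricalCCDF",
    "CollapseResult",
    "ccdf",
    "rescale_by_mean",
    "collapse_test",
]


@dataclass
class EmpiricalCCDF:
    """Empirical complementary CDF, P(X > x) with strict inequality."""

    support: np.ndarray  # sorted distinct values
    tail_prob: np.ndarray  # P(X > support[i])
    n: int

    def __call__(self, x: float | np.ndarray) -> np.ndarray:
        """Evaluate P(X > x); 1 below the minimum, 0 at/above the maximum."""
        probs = np.concatenate([[1.0], self.tail_prob])
        idx = np.searchsorted(self.support, np.asarray(x, dtype=float), "right")
        return probs[idx]


def ccdf(values: np.ndarray) -> EmpiricalCCDF:
    """Empirical tail function of a positive sample; ties share one step."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if (values <= 0).any():
        raise ValueError("values must be positive")
    support, counts = np.unique(values, return_counts=True)
    n = values.size
    exceed = n - np.cumsum(counts)
    return EmpiricalCCDF(support=support, tail_prob=exceed / n, n=n)


def rescale_by_mean(values: np.ndarray, mode: str = "geometric") -> np.ndarray:
    """Divide a sample by its geometric (default) or arithmetic mean.

    In geometric mode the rescaled sample has geometric mean exactly 1
    (product of outputs = 1).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if mode == "geometric":
        if (values <= 0).any():
            raise ValueError("geometric rescaling requires positive values")
        return values / np.exp(np.mean(np.log(values)))
    if mode == "arithmetic":
        return values / np.mean(values)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class CollapseResult:
    """Quantified data collapse across hierarchy levels.

    ``statistic`` is the max pairwise two-sample KS distance between the
    log-rescaled per-level samples (0 iff all rescaled empirical
    distributions coincide); ``p_value`` comes from the label-permutation
    null. Large statistic / small p rejects the generalized Horton law.
    """

    levels: tuple[int, ...]
    rescaled: dict[int, np.ndarray]
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    mode: str


def _max_pairwise_ks(groups: list[np.ndarray]) -> float:
    best = 0.0
    for a, b in combinations(groups, 2):
        d = stats.ks_2samp(a, b, method="asymp").statistic
        best = max(best, float(d))
    return best


def _center_logs(logs: np.ndarray, mode: str) -> np.ndarray:
    """Log-scale mean-rescaling: subtract the log of the chosen mean.

    The result is rounded to 12 decimals so that samples identical up to
    floating-point noise (e.g. one level being an exact multiple of
    another) compare as exactly equal in the KS statistic.
    """
    if mode == "geometric":
        centered = logs - logs.mean()
    elif mode == "arithmetic":
        shift = logs.max()  # stable log-mean-exp
        centered = logs - (shift + np.log(np.mean(np.exp(logs - shift))))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return np.round(centered, 12)


def collapse_test(
    table: SocietyTable,
    metric: str,
    mode: str = "geometric",
    n_permutations: int = 999,
    seed: int = 0,
    min_level_n: int = 5,
) -> CollapseResult:
    """Test whether per-level distributions collapse after mean-rescaling.

    Levels with fewer than ``min_level_n`` records are excluded; at least
    two eligible levels are required. The statistic is scale-invariant per
    level: multiplying one level's values by any positive constant is
    absorbed by the rescaling.
    """
    values = table.metric_values(metric).to_numpy(dtype=float)
    lev = table.df["level"].to_numpy()
    eligible = [
        int(w) for w in sorted(np.unique(lev)) if (lev == w).sum() >= min_level_n
    ]
    if len(eligible) < 2:
        raise ValueError("collapse test requires >= 2 levels with enough records")

    if (values <= 0).any():
        raise ValueError("collapse test requires positive values")
    raw = [values[lev == w] for w in eligible]
    logs = [_center_logs(np.log(v), mode) for v in raw]
    observed = _max_pairwise_ks(logs)

    # Null: after mean-rescaling, all levels share one distribution. Pool the
    # centered samples (scale factors already removed, so the procedure is
    # invariant to per-level rescaling of the input), permute level labels,
    # and re-center within each permuted grouping.
    sizes = [len(v) for v in raw]
    pooled = np.concatenate(logs)
    rng = np.random.default_rng(seed)
    n_extreme = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        groups, start = [], 0
        for size in sizes:
            groups.append(_center_logs(perm[start : start + size], mode))
            start += size
        if _max_pairwise_ks(groups) >= observed:
            n_extreme += 1
    p_value = (1 + n_extreme) / (1 + n_permutations)

    return CollapseResult(
        levels=tuple(eligible),
        rescaled={w: np.exp(lg) for w, lg in zip(eligible, logs)},
        statistic=observed,
        p_value=p_value,
        n_permutations=n_permutations,
        seed=seed,
        mode=mode,
    )
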