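"""Resampling-based inference: paired sign-flip permutation test, resampled
chance levels for atlas overlap, Bonferroni correction, Friedman's test.

All Monte-Carlo p-values use add-one smoothing, (1 + #extreme) / (1 + n), so
a reported p is never exactly 0; all procedures are bit-reproducible given
(inputs, seed, iteration count).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as _sps

from .surface import RoiLabel

__all__ = [
    "PermutationResult",
    "ChanceNull",
    "paired_permutation_test",
    "chance_overlap_null",
    "chance_exceedance_p",
    "bonferroni",
    "friedman_test",
]

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a paired permutation test on per-fold differences."""

    observed: float
    null: np.ndarray
    p_value: float
    n_permutations: int
    seed: int | None
    exact: bool = False


@dataclass(frozen=True)
class ChanceNull:
    """Resampled chance distribution of overlap for one region.

    ``values`` are the n_iter single-draw overlaps; the chance level is their
    mean, with a 95% CI from the 2.5/97.5 percentiles of the draws.
    """

    region_id: str
    hemisphere: str
    values: np.ndarray
    n_iter: int
    seed: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.min() < 0 or v.max() > 1:
            raise ValueError("overlap values outside [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def ci(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.values, [2.5, 97.5])
        return float(lo), float(hi)


def paired_permutation_test(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 10_000,
    seed: int | None = None,
    *,
    exact: bool = False,
) -> PermutationResult:
    """Two-sided paired permutation test of mean(a - b) by sign flipping.

    The folds are the exchangeable units: each permutation independently
    flips each pair's sign with probability 1/2 (resampling the sign
    assignments with replacement) and records the mean of the signed
    differences.  ``exact=True`` enumerates all 2^n sign patterns instead
    (n <= 20), in which case the p-value is the exact proportion without
    add-one smoothing.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("a and b must have the same length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    obs = float(d.mean())
    if exact:
        if n > 20:
            raise ValueError("exact enumeration limited to n <= 20 pairs")
        signs = np.array(
            [[1 if (m >> k) & 1 else -1 for k in range(n)] for m in range(2**n)]
        )
        null = (signs * d).mean(axis=1)
        p = float(np.mean(np.abs(null) >= abs(obs) - _TIE_EPS))
        return PermutationResult(obs, null, p, len(null), seed, exact=True)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    null = (signs * d).mean(axis=1)
    p = float((1 + np.sum(np.abs(null) >= abs(obs) - _TIE_EPS)) / (1 + n_perm))
    return PermutationResult(obs, null, p, n_perm, seed)


def chance_overlap_null(
    region: RoiLabel,
    pool: Sequence[RoiLabel],
    overlap_fn: Callable[[RoiLabel, RoiLabel], float],
    n_iter: int = 1000,
    seed: int = 0,
) -> ChanceNull:
    """Chance level of overlap with a region by resampling the (brain, ROI) pool.

    Each of ``n_iter`` iterations draws one label uniformly *with replacement*
    from ``pool`` and records ``overlap_fn(region, label)``.
    """
    if not pool:
        raise ValueError("empty chance pool")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(pool), size=n_iter)
    values = np.array([overlap_fn(region, pool[i]) for i in draws])
    return ChanceNull(
        region_id=region.roi_id,
        hemisphere=region.hemisphere.value,
        values=values,
        n_iter=n_iter,
        seed=seed,
    )


def chance_exceedance_p(observed: float, null: ChanceNull) -> float:
    """One-sided Monte-Carlo p that the observed overlap exceeds chance."""
    return float(
        (1 + np.sum(null.values >= observed - _TIE_EPS)) / (1 + null.n_iter)
    )


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, p * m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


def friedman_test(data: np.ndarray) -> tuple[float, int, float]:
    """Friedman's rank test over a blocks x treatments matrix, with tie
    correction (midranks within blocks).

    chi2 = [12 / (n k (k+1))] * sum_j R_j^2 - 3 n (k+1), divided by the
    standard tie-correction factor 1 - sum(t^3 - t) / (n k (k^2 - 1));
    df = k - 1; p from the chi-square distribution.  Unlike the scipy
    implementation this accepts k = 2 treatments (e.g. a hemisphere
    contrast).  A matrix constant within every block yields chi2 = 0, p = 1.
    """
    x = np.asarray(data, float)
    if x.ndim != 2:
        raise ValueError("data must be a 2-D blocks x treatments matrix")
    if np.isnan(x).any():
        raise ValueError("missing cells are not allowed")
    n, k = x.shape
    if k < 2:
        raise ValueError("need >= 2 treatments")
    if n < 2:
        raise ValueError("need >= 2 blocks")
    ranks = np.apply_along_axis(_sps.rankdata, 1, x)  # midranks for ties
    rj = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in x:
        _, cnt = np.unique(row, return_counts=True)
        ties += float(np.sum(cnt**3 - cnt))
    c = 1.0 - ties / (n * k * (k * k - 1))
    if c <= 0:
        return 0.0, k - 1, 1.0  # every block fully tied
    stat = float(stat / c)
    df = k - 1
    p = float(_sps.chi2.sf(stat, df))
    return stat, df, p
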