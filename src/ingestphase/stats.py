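"""Permutation inference and intra-class correlation.

Two-sided (or one-sided) permutation tests on a difference-in-means
statistic, enumerated exactly when the number of distinct relabellings is
small enough (<= 2^20) and otherwise approximated by Monte Carlo with the
add-one (Phipson–Smyth) convention, so p is always in (0, 1].

The intra-class correlation across mice is the one-way random-effects
variance decomposition (ANOVA method-of-moments): between-mouse variance
divided by total variance, guarding group effects against single-animal
outliers.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import substream

EXACT_CAP = 2**20


@dataclass
class PermutationResult:
    statistic_observed: float
    p_value: float
    exact: bool
    n_iterations: int
    sides: int
    seed: Optional[int] = None


def _pvalue(null: np.ndarray, obs: float, sides: int, exact: bool, n_total: int) -> float:
    tol = 1e-12 * max(1.0, abs(obs))
    if sides == 2:
        hits = int(np.sum(np.abs(null) >= abs(obs) - tol))
    else:
        hits = int(np.sum(null >= obs - tol))
    if exact:
        return hits / n_total
    return (hits + 1) / (n_total + 1)


def permutation_test(
    x: Sequence[float],
    y: Sequence[float],
    paired: bool = False,
    sides: int = 2,
    n_iter: int = 10000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of x vs y on the difference in means.

    Paired: statistic = mean(x - y), null = sign flips of the differences
    (2^n relabellings).  Unpaired: statistic = mean(x) - mean(y), null =
    reassignments of the pooled values to the two groups.  Exact enumeration
    when the relabelling count is <= 2^20, else ``n_iter`` Monte Carlo draws
    with the observed statistic included in the null set (add-one rule).
    ``sides=1`` tests the alternative mean(x) > mean(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if sides not in (1, 2):
        raise ValueError("sides must be 1 or 2")
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if paired and x.size != y.size:
        raise ValueError("paired samples must have equal length")

    if paired:
        d = x - y
        obs = float(d.mean())
        if np.all(d == 0):
            warnings.warn("all paired differences are zero; p = 1", RuntimeWarning)
            return PermutationResult(obs, 1.0, True, 2 ** d.size, sides, seed)
        n_total = 2 ** d.size
        if n_total <= EXACT_CAP:
            signs = np.array(list(itertools.product((1.0, -1.0), repeat=d.size)))
            null = signs @ d / d.size
            p = _pvalue(null, obs, sides, exact=True, n_total=n_total)
            return PermutationResult(obs, p, True, n_total, sides, seed)
        rng = substream(seed, "permtest", "paired")
        signs = rng.choice((1.0, -1.0), size=(n_iter, d.size))
        null = signs @ d / d.size
        p = _pvalue(null, obs, sides, exact=False, n_total=n_iter)
        return PermutationResult(obs, p, False, n_iter, sides, seed)

    pooled = np.concatenate([x, y])
    obs = float(x.mean() - y.mean())
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; p = 1", RuntimeWarning)
        return PermutationResult(obs, 1.0, True, 1, sides, seed)
    nx, n = x.size, pooled.size
    n_total = math.comb(n, nx)
    if n_total <= EXACT_CAP:
        idx_all = np.fromiter(
            (i for combo in itertools.combinations(range(n), nx) for i in combo),
            dtype=int,
            count=n_total * nx,
        ).reshape(n_total, nx)
        sums_x = pooled[idx_all].sum(axis=1)
        total = pooled.sum()
        null = sums_x / nx - (total - sums_x) / (n - nx)
        p = _pvalue(null, obs, sides, exact=True, n_total=n_total)
        return PermutationResult(obs, p, True, n_total, sides, seed)
    rng = substream(seed, "permtest", "unpaired")
    perms = rng.permuted(np.broadcast_to(pooled, (n_iter, n)).copy(), axis=1)
    sums_x = perms[:, :nx].sum(axis=1)
    total = pooled.sum()
    null = sums_x / nx - (total - sums_x) / (n - nx)
    p = _pvalue(null, obs, sides, exact=False, n_total=n_iter)
    return PermutationResult(obs, p, False, n_iter, sides, seed)


@dataclass
class ICCResult:
    icc: float
    variance_between: float
    variance_within: float
    variance_between_raw: float  # method-of-moments estimate before clipping at 0
    n_groups: int


def icc_between_mice(values: Sequence[float], mouse_ids: Sequence) -> ICCResult:
    """Intra-class correlation: between-mouse variance over total variance.

    One-way random-effects ANOVA method-of-moments: MSB and MSW from the
    group decomposition, between-variance = (MSB - MSW)/n0 with n0 the
    effective group size, clipped at zero when the estimate is negative.
    """
    values = np.asarray(values, dtype=float)
    mouse_ids = np.asarray(mouse_ids)
    if values.shape != mouse_ids.shape:
        raise ValueError("values and mouse_ids must align")
    groups = [values[mouse_ids == m] for m in np.unique(mouse_ids)]
    k = len(groups)
    if k < 2:
        raise ValueError("ICC undefined with fewer than 2 mice")
    n_i = np.array([g.size for g in groups], dtype=float)
    N = n_i.sum()
    grand = values.mean()
    ss_between = float(np.sum(n_i * (np.array([g.mean() for g in groups]) - grand) ** 2))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    msb = ss_between / (k - 1)
    dof_within = N - k
    msw = ss_within / dof_within if dof_within > 0 else 0.0
    n0 = (N - float(np.sum(n_i**2)) / N) / (k - 1)
    vb_raw = (msb - msw) / n0
    vb = max(0.0, vb_raw)
    vw = msw
    denom = vb + vw
    icc = vb / denom if denom > 0 else 0.0
    return ICCResult(icc=icc, variance_between=vb, variance_within=vw,
                     variance_between_raw=vb_raw, n_groups=k)
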