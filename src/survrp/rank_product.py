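"""Rank product consensus statistics for per-model outlyingness scores.

Given an n x k matrix of outlyingness scores (one column per sub-model), each
column is converted to ranks with rank 1 assigned to the most outlying
observation, and the per-observation rank product

    RP_i = prod_{j=1}^{k} R_ij

is referred to the null hypothesis of k independent uniform rankings.  Small
rank products indicate observations that are consistently flagged across
sub-models.  Four p-value strategies are provided:

``exact``
    Exact tail probability by integer counting of rank configurations.
``bounds_gm``
    Geometric mean of strict recursive lower/upper bounds on the exact
    p-value (fast for moderate to large k).
``gamma``
    Continuous approximation: -ln(RP/n^k) ~ Gamma(k, 1) under the null.
``permutation``
    Monte Carlo estimate from simulated uniform rankings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from scipy import special, stats

from ._bounds import rank_count_bounds

__all__ = [
    "OutlyingnessMatrix",
    "RankMatrix",
    "RPResult",
    "rank_observations",
    "rank_product",
    "rp_pvalue_exact",
    "rp_pvalue_bounds",
    "rp_pvalue_gamma",
    "rp_pvalue_permutation",
    "rp_pvalues",
]

Direction = Literal["ascending", "descending", "absolute"]
TieMethod = Literal["midrank", "ordinal"]
Method = Literal["auto", "exact", "bounds_gm", "gamma", "permutation"]

#: method dispatch thresholds used by ``method="auto"``
EXACT_MAX_K = 4
BOUNDS_MAX_K = 30


@dataclass
class OutlyingnessMatrix:
    """n x k matrix of deviance/outlyingness scores across k sub-models."""

    Z: np.ndarray
    sample_ids: list[str]
    model_labels: list[str]

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2:
            raise ValueError("Z must be a 2-d array (observations x models)")
        n, k = self.Z.shape
        if k < 1:
            raise ValueError("need at least one model column")
        if len(self.sample_ids) != n or len(self.model_labels) != k:
            raise ValueError("sample_ids/model_labels do not match Z shape")
        if not np.all(np.isfinite(self.Z)):
            raise ValueError("Z contains missing or non-finite entries")


@dataclass
class RankMatrix:
    """Per-column ranks of an outlyingness matrix (1 = most outlying)."""

    R: np.ndarray
    sample_ids: list[str]
    model_labels: list[str]

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        n, k = self.R.shape
        if np.any(self.R < 1.0) or np.any(self.R > n):
            raise ValueError("ranks must lie in [1, n]")
        colsums = self.R.sum(axis=0)
        if not np.allclose(colsums, n * (n + 1) / 2.0, rtol=1e-9):
            raise ValueError("each rank column must sum to n(n+1)/2")

    @property
    def n(self) -> int:
        return self.R.shape[0]

    @property
    def k(self) -> int:
        return self.R.shape[1]


@dataclass
class RPResult:
    """Rank-product statistic and p-value for one observation."""

    sample_id: str
    rp: float
    log_rp: float
    p_value: float
    method: str
    bounds: tuple[float, float] | None = None


def rank_observations(
    Z: OutlyingnessMatrix,
    direction: Direction = "ascending",
    tie_method: TieMethod = "midrank",
) -> RankMatrix:
    """Rank each column of ``Z`` so that rank 1 is the most outlying score.

    ``ascending`` ranks the smallest score first (martingale residuals: the
    most negative residual, a long-term survivor, gets rank 1);
    ``descending`` ranks the largest first; ``absolute`` ranks the largest
    |score| first (two-sided use).  Midranks are assigned to ties unless
    ``tie_method="ordinal"``, which breaks ties by sample order.
    """
    scores = Z.Z
    if direction == "descending":
        scores = -scores
    elif direction == "absolute":
        scores = -np.abs(scores)
    elif direction != "ascending":
        raise ValueError(f"unknown direction: {direction!r}")
    method = {"midrank": "average", "ordinal": "ordinal"}.get(tie_method)
    if method is None:
        raise ValueError(f"unknown tie method: {tie_method!r}")
    R = np.column_stack(
        [stats.rankdata(scores[:, j], method=method) for j in range(scores.shape[1])]
    )
    return RankMatrix(R, Z.sample_ids, Z.model_labels)


def rank_product(R: RankMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-observation rank products and their logs (overflow safe)."""
    log_rp = np.log(R.R).sum(axis=1)
    # direct product is exact for integer ranks up to 2**53; may overflow to
    # inf for very large k, in which case log_rp is the usable statistic
    with np.errstate(over="ignore"):
        rp = np.prod(R.R, axis=1)
    return rp, log_rp


# ---------------------------------------------------------------------------
# p-value strategies
# ---------------------------------------------------------------------------


_PAIR_TABLE_MAX_N = 1500  # sieve memory cap: n^2 int64 entries


@lru_cache(maxsize=8)
def _pair_count_table(n: int) -> np.ndarray:
    """Cumulative counts T[m] = #{(a,b) in {1..n}^2 : a*b <= m}, via a sieve."""
    N = n * n
    cnt = np.zeros(N + 1, dtype=np.int64)
    for b in range(1, n + 1):
        hi = min(n, N // b)
        cnt[b : b * hi + 1 : b] += 1
    return np.cumsum(cnt)


def _count_pairs(n: int, m: int) -> int:
    if m >= n * n:
        return n * n
    if n <= _PAIR_TABLE_MAX_N:
        return int(_pair_count_table(n)[m])
    b = np.arange(1, min(n, m) + 1, dtype=np.int64)
    return int(np.minimum(m // b, n).sum())


@lru_cache(maxsize=200_000)
def _count_le(n: int, k: int, m: int) -> int:
    """#{(r_1..r_k) in {1..n}^k : prod r_j <= m}, by recursion over k.

    k = 2 uses a sieved lookup table; k = 3 reduces to one vectorized gather
    over that table; deeper k groups consecutive divisors with equal
    quotient so the work per call is O(sqrt(m)) distinct sub-problems.
    """
    if m < 1:
        return 0
    if k == 0:
        return 1
    if m >= n**k:
        return n**k
    if k == 1:
        return min(n, m)
    if k == 2:
        return _count_pairs(n, m)
    if k == 3 and n <= _PAIR_TABLE_MAX_N:
        a = np.arange(1, min(n, m) + 1, dtype=np.int64)
        q = np.minimum(m // a, n * n)
        return int(_pair_count_table(n)[q].sum())
    total = 0
    a = 1
    lim = min(n, m)
    while a <= lim:
        q = m // a
        a_hi = min(lim, m // q)
        total += (a_hi - a + 1) * _count_le(n, k - 1, q)
        a = a_hi + 1
    return total


def rp_pvalue_exact(rho: float, n: int, k: int) -> float:
    """Exact null p-value P(RP <= rho) by integer counting.

    Non-integer rank products (midranks) are handled conservatively through
    the floor, since the discrete null only charges integer products.
    """
    if n < 1 or k < 1:
        raise ValueError("n and k must be positive")
    if rho < 1:
        raise ValueError("rank product must be >= 1")
    if k > 10:
        raise ValueError(
            f"exact counting is not feasible for k={k}; "
            "use rp_pvalue_bounds or rp_pvalue_gamma"
        )
    m = min(int(math.floor(rho)), n**k)
    count = _count_le(n, k, m)
    # exact rational -> float at the very end
    return float(count / n**k)


def rp_pvalue_bounds(rho: float, n: int, k: int) -> tuple[float, float, float]:
    """Strict (lower, upper, geometric_mean) for the null p-value.

    The bounds come from a recursive sandwich of the tail count between
    piecewise log-polynomial functions; ``geometric_mean`` is the reported
    approximate p-value.
    """
    if n < 1 or k < 1:
        raise ValueError("n and k must be positive")
    rho = min(max(float(rho), 1.0), float(n) ** k)
    lower_f, upper_f = rank_count_bounds(n, k)
    denom = float(n) ** k
    lo = min(max(lower_f(rho) / denom, 0.0), 1.0)
    hi = min(max(upper_f(rho) / denom, lo), 1.0)
    if rho >= denom:
        lo = hi = 1.0
    gm = math.sqrt(lo * hi)
    return lo, hi, gm


def rp_pvalue_gamma(log_rho: float, n: int, k: int) -> float:
    """Gamma(k, 1) approximation operating entirely in the log domain.

    Under the continuous null, -ln(RP / n^k) is a sum of k independent
    Exp(1) variables, so P(RP <= rho) = P(Gamma(k,1) >= k ln n - ln rho).
    The approximation overshoots the exact discrete p-value deep in the
    tail (small rank products), where discreteness matters most.
    """
    if n < 1 or k < 1:
        raise ValueError("n and k must be positive")
    top = k * math.log(n)
    if log_rho < 0.0 or log_rho > top:
        import warnings

        warnings.warn(
            f"log rank product {log_rho:.3g} outside [0, k ln n]; clamping",
            stacklevel=2,
        )
        log_rho = min(max(log_rho, 0.0), top)
    L = top - log_rho
    # upper regularized incomplete gamma Q(k, L) = exp(-L) * sum_{j<k} L^j/j!
    return float(special.gammaincc(k, L))


def rp_pvalue_permutation(
    rank_source: RankMatrix | np.ndarray,
    B: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Monte Carlo p-values with an add-one estimator.

    Each of the ``B`` null draws permutes every rank column independently and
    records one observation's rank product, which under the null is the
    product of k independent uniforms on {1..n}.  Estimates are bounded below
    by 1/(B+1) and are reproducible given ``seed``.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if isinstance(rank_source, RankMatrix):
        R = rank_source.R
    else:
        R = np.asarray(rank_source, dtype=float)
    n, k = R.shape
    rng = np.random.default_rng(seed)
    null_log = np.log(rng.integers(1, n + 1, size=(B, k))).sum(axis=1)
    null_log.sort()
    obs_log = np.log(R).sum(axis=1)
    # count null draws with RP* <= RP_i  (tolerance for float log products)
    counts = np.searchsorted(null_log, obs_log * (1 + 1e-12) + 1e-12, side="right")
    return (1.0 + counts) / (B + 1.0)


def rp_pvalues(
    R: RankMatrix,
    method: Method = "auto",
    B: int = 10_000,
    seed: int = 0,
) -> list[RPResult]:
    """Rank products plus null p-values for every observation.

    ``auto`` dispatches on k: exact counting for k <= 4, geometric-mean
    bounds for k <= 30, and the log-domain gamma approximation beyond that.
    """
    rp, log_rp = rank_product(R)
    n, k = R.n, R.k
    if method == "auto":
        if k <= EXACT_MAX_K:
            method = "exact"
        elif k <= BOUNDS_MAX_K:
            method = "bounds_gm"
        else:
            method = "gamma"
    results: list[RPResult] = []
    if method == "permutation":
        p = rp_pvalue_permutation(R, B=B, seed=seed)
        for i, sid in enumerate(R.sample_ids):
            results.append(RPResult(sid, float(rp[i]), float(log_rp[i]), float(p[i]), method))
        return results
    for i, sid in enumerate(R.sample_ids):
        bounds = None
        if method == "exact":
            p = rp_pvalue_exact(rp[i], n, k)
        elif method == "bounds_gm":
            lo, hi, p = rp_pvalue_bounds(rp[i], n, k)
            bounds = (lo, hi)
        elif method == "gamma":
            p = rp_pvalue_gamma(float(log_rp[i]), n, k)
        else:
            raise ValueError(f"unknown method: {method!r}")
        results.append(
            RPResult(sid, float(rp[i]), float(log_rp[i]), float(p), method, bounds)
        )
    return results
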