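"""FDR control for per-observation rank-product p-values.

One test is performed per observation, so the family size m equals the
number of observations n.  q-values are Benjamini-Hochberg step-up adjusted
p-values (optionally scaled by an externally supplied pi0 estimate); an
observation is declared an outlier when q <= alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TestTable", "bh_qvalues", "bonferroni", "declare_outliers"]


@dataclass
class TestTable:
    sample_ids: list[str]
    p_values: np.ndarray
    q_values: np.ndarray
    m: int


def bh_qvalues(p, m: int | None = None, pi0: float = 1.0) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``m`` may exceed ``len(p)`` to adjust a printed subset of the smallest
    p-values under the assumption that the remaining, unreported p-values are
    larger; percentile ranks then still refer to the full family.
    q_(i) = min_{j >= i} (pi0 * m * p_(j) / j), clipped at 1, mapped back to
    the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p must be a non-empty 1-d vector")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("family size m cannot be smaller than len(p)")
    if not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must be in (0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, len(p) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def bonferroni(p, m: int | None = None) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return np.minimum((m or len(p)) * p, 1.0)


def declare_outliers(table: TestTable, alpha: float = 0.05) -> list[str]:
    """Sample IDs with q <= alpha, most significant first."""
    hits = np.flatnonzero(table.q_values <= alpha)
    hits = hits[np.argsort(table.q_values[hits], kind="stable")]
    return [table.sample_ids[i] for i in hits]
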