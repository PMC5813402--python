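"""Recursive piecewise bounds on the null distribution of a product of uniform ranks.

Under the null, the k ranks of one observation are independent uniforms on
{1, ..., n} and the tail count

    C_k(rho) = #{(r_1, ..., r_k) in {1..n}^k : prod_j r_j <= rho}

obeys C_k(rho) = sum_{i=1}^{n} C_{k-1}(rho / i),  C_0(rho) = 1 for rho >= 1.

Because C_{k-1}(rho / x) is non-increasing in x, the sum is sandwiched by
integrals once the i = 1 term is kept exact on both sides:

    C_{k-1}(rho) + int_2^{n+1} C_{k-1}(rho/x) dx
        <= C_k(rho) <=
    C_{k-1}(rho) + int_1^{n} C_{k-1}(rho/x) dx

Iterating from C_0 keeps every iterate inside the closed function class

    f(rho) = c_m + rho * P_m(ln rho - ln b_m)   on pieces [b_m, b_{m+1})

(constants plus rho times a polynomial in log rho), for which the integral
transform int_a^b f(rho/x) dx has a closed form.  The geometric mean of the
two resulting bounds is an accurate approximation to the exact tail
probability; the bounds themselves are strict.

Polynomials are stored in the local coordinate s = ln(rho / b_m) of their own
piece so that high-degree terms stay numerically tame (|s| <= ln n per piece).
"""

from __future__ import annotations

import bisect
import math
from functools import lru_cache

import numpy as np

__all__ = ["rank_count_bounds", "tail_count_bounds"]

_REL_TOL = 1e-12


def _poly_shift(p: np.ndarray, s: float) -> np.ndarray:
    """Coefficients of P(t + s) given coefficients ``p`` of P(t)."""
    out = np.zeros_like(p)
    for j, c in enumerate(p):
        if c == 0.0:
            continue
        for i in range(j + 1):
            out[i] += c * math.comb(j, i) * s ** (j - i)
    return out


def _poly_antideriv(p: np.ndarray) -> np.ndarray:
    """Q with Q' = P and Q(0) = 0."""
    return np.concatenate(([0.0], p / np.arange(1.0, len(p) + 1.0)))


def _poly_eval(p: np.ndarray, t: float) -> float:
    acc = 0.0
    for c in p[::-1]:
        acc = acc * t + c
    return acc


class _PiecewiseLogPoly:
    """f(rho) = c_m + rho * P_m(ln rho - ln b_m) on [b_m, b_{m+1}); 0 below b_0."""

    def __init__(self, breaks, consts, polys):
        self.breaks = [float(b) for b in breaks]
        self.logb = [math.log(b) for b in self.breaks]
        self.consts = [float(c) for c in consts]
        self.polys = [np.asarray(p, dtype=float) for p in polys]

    def _index(self, rho: float) -> int:
        # last piece whose start is <= rho (with a relative slack for floats)
        return bisect.bisect_right(self.breaks, rho * (1.0 + _REL_TOL)) - 1

    def __call__(self, rho):
        arr = np.asarray(rho, dtype=float)
        out = np.zeros(arr.shape)
        for idx, r in np.ndenumerate(arr.reshape(-1)):
            i = np.unravel_index(idx[0], arr.shape) if arr.shape else ()
            if r < self.breaks[0] * (1.0 - _REL_TOL):
                continue
            m = self._index(r)
            s = math.log(r) - self.logb[m]
            out[i] = self.consts[m] + r * _poly_eval(self.polys[m], s)
        return out if arr.shape else float(out)

    # -- algebra -----------------------------------------------------------

    def add(self, other: "_PiecewiseLogPoly") -> "_PiecewiseLogPoly":
        breaks = _merge_breaks(self.breaks, other.breaks)
        consts, polys = [], []
        deg = max(max(len(p) for p in self.polys), max(len(p) for p in other.polys))
        for b in breaks:
            c = 0.0
            P = np.zeros(deg)
            for f in (self, other):
                if b < f.breaks[0] * (1.0 - _REL_TOL):
                    continue
                m = f._index(b)
                c += f.consts[m]
                sh = _poly_shift(_pad(f.polys[m], deg), math.log(b) - f.logb[m])
                P += sh
            consts.append(c)
            polys.append(P)
        return _PiecewiseLogPoly(breaks, consts, polys)

    def shift_arg(self, s: float) -> "_PiecewiseLogPoly":
        """g(rho) = f(rho / s) for s > 0."""
        breaks = [b * s for b in self.breaks]
        consts = list(self.consts)
        polys = [p / s for p in self.polys]  # rho/s * P(...) = rho * P(...)/s
        return _PiecewiseLogPoly(breaks, consts, polys)

    def transform(self, a: float, b: float) -> "_PiecewiseLogPoly":
        """T(rho) = int_a^b f(rho / x) dx  for 0 < a < b."""
        # Antiderivative H(u) = int_{b_0}^{u} f(v) / v^2 dv, kept continuous:
        # on piece m, H(u) = -c_m/u + Q_m(ln u - ln b_m) + K_m.
        H = []
        running = 0.0
        for m, start in enumerate(self.breaks):
            c = self.consts[m]
            Q = _poly_antideriv(self.polys[m])
            K = running + c / start  # so H(start) = running
            H.append((c, Q, K))
            if m + 1 < len(self.breaks):
                nxt = self.breaks[m + 1]
                running = -c / nxt + _poly_eval(Q, math.log(nxt) - self.logb[m]) + K
        cand = sorted({x * a for x in self.breaks} | {x * b for x in self.breaks})
        cand = [x for x in cand if x >= a * self.breaks[0] * (1.0 - _REL_TOL)]
        cand = _merge_breaks(cand, [])
        deg = max(len(p) for p in self.polys) + 1
        breaks_out, consts_out, polys_out = [], [], []
        la, lb = math.log(a), math.log(b)
        for x in cand:
            probe = x * (1.0 + 10.0 * _REL_TOL)
            u_hi = probe / a
            if u_hi < self.breaks[0]:
                continue
            m1 = self._index(u_hi)
            c1, Q1, K1 = H[m1]
            # G(rho) = rho * (H(rho/a) - H(max(rho/b, b_0)))
            cc = -c1 * a
            P = np.zeros(deg)
            sh = _poly_shift(_pad(Q1, deg), math.log(x) - la - self.logb[m1])
            P += sh
            P[0] += K1
            u_lo = probe / b
            if u_lo > self.breaks[0]:
                m0 = self._index(u_lo)
                c0, Q0, K0 = H[m0]
                cc += c0 * b
                sh = _poly_shift(_pad(Q0, deg), math.log(x) - lb - self.logb[m0])
                P -= sh
                P[0] -= K0
            breaks_out.append(x)
            consts_out.append(cc)
            polys_out.append(P)
        if not breaks_out:
            return _PiecewiseLogPoly([1.0], [0.0], [np.zeros(1)])
        return _PiecewiseLogPoly(breaks_out, consts_out, polys_out)


def _pad(p: np.ndarray, deg: int) -> np.ndarray:
    if len(p) >= deg:
        return p
    return np.concatenate([p, np.zeros(deg - len(p))])


def _merge_breaks(a, b):
    merged = sorted(set(a) | set(b))
    out = []
    for x in merged:
        if out and x <= out[-1] * (1.0 + 10.0 * _REL_TOL):
            continue
        out.append(x)
    return out


def _indicator() -> _PiecewiseLogPoly:
    # C_0(rho) = 1 for rho >= 1
    return _PiecewiseLogPoly([1.0], [1.0], [np.zeros(1)])


@lru_cache(maxsize=64)
def rank_count_bounds(n: int, k: int):
    """Return (lower, upper) callables bounding the tail count C_k(rho).

    Both are strict bounds: lower(rho) <= C_k(rho) <= upper(rho) for every
    rho >= 1, with equality C_k(n^k) = n^k at saturation.
    """
    if n < 1 or k < 1:
        raise ValueError("n and k must be positive integers")
    nf = float(n)
    upper = _indicator()
    lower = _indicator()
    for _ in range(k):
        upper = upper.add(upper.transform(1.0, nf))
        lower = lower.add(lower.transform(2.0, nf + 1.0))
    return lower, upper


def tail_count_bounds(rho: float, n: int, k: int):
    """Strict (lower, upper) bounds on C_k(rho) for a single rho."""
    lower, upper = rank_count_bounds(n, k)
    lo = max(0.0, lower(rho))
    hi = min(float(n) ** k, upper(rho))
    return lo, hi
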