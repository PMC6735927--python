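"""Shared simulation helpers and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: the grid
search scans the (a, b) box exhaustively instead of using the optimizer, and
the enumeration oracles compute hypergeometric/Fisher probabilities with
exact integer arithmetic.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def sim_curve_points(
    n: int, a: float, b: float, noise_sd: float, rng: np.random.Generator,
    x_low: float = 0.05, x_high: float = 5.0,
):
    """Points on y = a*x/(b+x) with Gaussian noise, x uniform on the Ks window."""
    x = rng.uniform(x_low, x_high, n)
    y = a * x / (b + x) + rng.normal(0.0, noise_sd, n)
    return x, y


def grid_search_fit(
    x: np.ndarray, y: np.ndarray,
    a_range=(0.0, 1.0), b_range=(1e-3, 2.0), step: float = 1e-3,
) -> tuple[float, float, float]:
    """Exhaustive grid minimum of SSE(a, b) for y = a*x/(b+x).

    Returns (a, b, sse) at the grid minimum.  For each b the inner sums
    S_gg = sum g^2 and S_gy = sum g*y with g = x/(b+x) are precomputed, so
    SSE(a, b) = a^2 S_gg - 2 a S_gy + S_yy is evaluated on the full grid
    exactly as a dense scan would, in vectorized form.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    a_grid = np.arange(a_range[0], a_range[1] + step / 2, step)
    b_grid = np.arange(b_range[0], b_range[1] + step / 2, step)
    s_yy = float(y @ y)
    g = x[None, :] / (b_grid[:, None] + x[None, :])  # nb x n
    s_gg = (g * g).sum(axis=1)
    s_gy = g @ y
    sse = (
        a_grid[None, :] ** 2 * s_gg[:, None]
        - 2.0 * a_grid[None, :] * s_gy[:, None]
        + s_yy
    )
    bi, ai = np.unravel_index(np.argmin(sse), sse.shape)
    return float(a_grid[ai]), float(b_grid[bi]), float(sse[bi, ai])


def hypergeom_tail_exact(k: int, N: int, K: int, n: int, upper: bool) -> Fraction:
    """Exact hypergeometric tail P(X >= k) (upper) or P(X <= k) (lower)."""
    denom = comb(N, n)
    lo = max(0, n - (N - K))
    hi = min(K, n)
    if upper:
        support = range(max(k, lo), hi + 1)
    else:
        support = range(lo, min(k, hi) + 1)
    return Fraction(sum(comb(K, j) * comb(N - K, n - j) for j in support), denom)


def fisher_two_sided_exact(table) -> float:
    """Two-sided Fisher exact p by enumeration of the conditional support.

    Sums the probabilities of all tables (with the observed margins) that are
    no more likely than the observed one; ties are admitted with a relative
    1e-7 guard, the standard numerically-safe convention.
    """
    (a, b), (c, d) = table
    N, K, n = a + b + c + d, a + b, a + c
    lo = max(0, n - (N - K))
    hi = min(K, n)
    denom = comb(N, n)
    pmf = {j: Fraction(comb(K, j) * comb(N - K, n - j), denom) for j in range(lo, hi + 1)}
    p_obs = pmf[a]
    cutoff = p_obs + p_obs * Fraction(1, 10**7)
    return float(sum(p for p in pmf.values() if p <= cutoff))
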