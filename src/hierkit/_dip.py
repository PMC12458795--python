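"""Hartigan's dip statistic for unimodality.

The dip of an empirical distribution function F_n is the smallest sup-norm
distance between F_n and any unimodal distribution function (convex up to the
mode, concave after it; an atom is permitted at the mode).

The computation scans candidate mode positions over the sample's support
points.  For a mode at support ``x_s`` the fit error decomposes into a
convex-fit problem on the prefix and a concave-fit problem on the suffix,
coupled only through the junction (the left piece must end no higher than the
right piece starts; the mode atom may absorb the ecdf jump there).  Ignoring
the coupling gives a cheap lower bound per split via convex-hull feasibility:
a convex nondecreasing G tracks the ecdf prefix within ``e`` iff the greatest
convex minorant of the pre-jump ecdf values stays within ``2e`` below the
post-jump values.  The exact per-split error (with coupling) is the solution
of a small linear program.  The dip is found by evaluating the LP only on
splits whose lower bound beats the best exact value so far, which prunes all
but a few splits in practice.

Anchors: an equally spaced sample gives ``1/(2n)``; two equal point masses
give ``1/4`` in the limit; a constant sample is exactly unimodal (dip 0).
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_test"]


def _collapse_ties(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique support points with the ecdf value just left of (``a``) and at
    (``b``) each support; a continuous G within error e must satisfy
    ``b_j - e <= G(x_j) <= a_j + e`` away from the mode."""
    n = len(x)
    xs = np.sort(np.asarray(x, dtype=float))
    uniq, first = np.unique(xs, return_index=True)
    counts = np.diff(np.append(first, n))
    a = first / n
    b = (first + counts) / n
    return uniq, a, b


def _prefix_bounds(xs: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Uncoupled convex-fit error bound for every prefix.

    ``err[s] = max_{k < s} (b_k - GCM_{0..s}(a)(x_k)) / 2``: the smallest e
    admitting a convex nondecreasing G with ``b_k - e <= G(x_k) <= a_k + e``
    for k < s and ``|G(x_s^-) - a_s| <= e`` at the mode candidate.  The lower
    convex hull of (x, a) is maintained incrementally.
    """
    m = len(xs)
    errs = np.empty(m)
    hull: list[int] = []
    for s in range(m):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            if (a[k] - a[j]) * (xs[s] - xs[j]) >= (a[s] - a[j]) * (xs[k] - xs[j]):
                hull.pop()
            else:
                break
        hull.append(s)
        if s == 0:
            errs[s] = 0.0
        else:
            gcm = np.interp(xs[:s], xs[hull], a[hull])
            errs[s] = float(np.max(b[:s] - gcm)) / 2.0
    return errs


def _exact_split_error(xs: np.ndarray, a: np.ndarray, b: np.ndarray, s: int) -> float:
    """Exact minimal sup-norm error for a unimodal fit with mode at support s.

    Linear program in the G values at the supports: gL_0..gL_s is the convex
    left piece (gL_s = G(x_s^-)), gR_s..gR_{m-1} the concave right piece
    (gR_s = G(x_s)); the mode atom is the jump gR_s - gL_s >= 0.  Tube
    constraints compare each value with the ecdf step it faces; the junction
    values face only their one-sided ecdf limits.
    """
    from scipy.optimize import linprog

    m = len(xs)
    nL = s + 1
    nv = nL + (m - s) + 1
    ie = nv - 1

    def idxL(k):
        return k

    def idxR(k):
        return nL + (k - s)

    rows, ub = [], []

    def add(coefs, rhs):
        row = np.zeros(nv)
        for v, c in coefs:
            row[v] += c
        rows.append(row)
        ub.append(rhs)

    for k in range(s + 1):
        hi = a[k] if k < s else a[s]
        lo = b[k] if k < s else a[s]
        add([(idxL(k), 1), (ie, -1)], hi)
        add([(idxL(k), -1), (ie, -1)], -lo)
    for k in range(s, m):
        hi = a[k] if k > s else b[s]
        add([(idxR(k), 1), (ie, -1)], hi)
        add([(idxR(k), -1), (ie, -1)], -b[k])
    for k in range(s):
        add([(idxL(k), 1), (idxL(k + 1), -1)], 0)
    add([(idxL(s), 1), (idxR(s), -1)], 0)
    for k in range(s, m - 1):
        add([(idxR(k), 1), (idxR(k + 1), -1)], 0)
    for k in range(1, s):  # convexity: g_k <= chord(g_{k-1}, g_{k+1})
        d1, d2 = xs[k] - xs[k - 1], xs[k + 1] - xs[k]
        add([(idxL(k - 1), -d2), (idxL(k), d1 + d2), (idxL(k + 1), -d1)], 0)
    for k in range(s + 1, m - 1):  # concavity: g_k >= chord
        d1, d2 = xs[k] - xs[k - 1], xs[k + 1] - xs[k]
        add([(idxR(k - 1), d2), (idxR(k), -(d1 + d2)), (idxR(k + 1), d1)], 0)

    c = np.zeros(nv)
    c[ie] = 1.0
    res = linprog(c, A_ub=np.array(rows), b_ub=np.array(ub), bounds=[(0, 1)] * nv, method="highs")
    if not res.success:  # numerically infeasible split; never optimal
        return np.inf
    return float(res.fun)


def dip_statistic(x: np.ndarray) -> float:
    """Hartigan's dip statistic of a sample (sup-norm distance to unimodality)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("dip statistic requires at least 4 observations")
    xs, a, b = _collapse_ties(x)
    if len(xs) == 1:
        return 0.0
    e_conv = _prefix_bounds(xs, a, b)
    # concave side by reflection: -x reverses order and swaps the step roles
    e_conc = _prefix_bounds(-xs[::-1], (1.0 - b)[::-1], (1.0 - a)[::-1])[::-1]
    lower = np.maximum(e_conv, e_conc)
    order = np.argsort(lower)
    best = np.inf
    for s in order:
        if lower[s] >= best:
            break
        best = min(best, _exact_split_error(xs, a, b, int(s)))
    return float(best)


def dip_test(x: np.ndarray, n_boot: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Dip statistic and bootstrap p-value against a uniform reference null.

    The null distribution of the dip is simulated from ``n_boot`` uniform
    samples of the same size (the dip is invariant to monotone rescaling, so
    any continuous unimodal null gives the same reference up to Monte-Carlo
    error; the uniform is the conventional choice).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError("dip test requires at least 4 observations")
    d = dip_statistic(x)
    rng = np.random.default_rng(seed)
    null = np.array([dip_statistic(rng.uniform(size=len(x))) for _ in range(n_boot)])
    p = (1.0 + np.sum(null >= d)) / (1.0 + n_boot)
    return d, float(p)
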