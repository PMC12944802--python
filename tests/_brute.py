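"""Independent brute-force oracles for the test suite.

Everything here is a literal, slow transcription of the defining formulas
(pure-Python double loops, exhaustive permutation enumeration, winding-
number point-in-polygon), deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math


def dense_weights(W):
    """WeightsMatrix -> dense nested-list matrix w[i][j]."""
    n = W.n
    w = [[0.0] * n for _ in range(n)]
    for i, (nb, wts) in enumerate(zip(W.neighbors, W.weights)):
        for j, wij in zip(nb.tolist(), wts.tolist()):
            w[i][j] = wij
    return w


def brute_global_lee(w, x, y):
    """Double-loop transcription of global Lee's L on a dense matrix."""
    n = len(x)
    xbar = sum(x) / n
    ybar = sum(y) / n
    S = 0.0
    num = 0.0
    for i in range(n):
        rs = 0.0
        lx = 0.0
        ly = 0.0
        for j in range(n):
            rs += w[i][j]
            lx += w[i][j] * (x[j] - xbar)
            ly += w[i][j] * (y[j] - ybar)
        S += rs * rs
        num += lx * ly
    denx = math.sqrt(sum((xi - xbar) ** 2 for xi in x))
    deny = math.sqrt(sum((yi - ybar) ** 2 for yi in y))
    return (n / S) * num / (denx * deny)


def brute_local_lee(w, x, y):
    """Double-loop transcription of the local coefficients L_i."""
    n = len(x)
    xbar = sum(x) / n
    ybar = sum(y) / n
    S = sum(sum(row) ** 2 for row in w)
    denx = math.sqrt(sum((xi - xbar) ** 2 for xi in x))
    deny = math.sqrt(sum((yi - ybar) ** 2 for yi in y))
    out = []
    for i in range(n):
        lx = sum(w[i][j] * (x[j] - xbar) for j in range(n))
        ly = sum(w[i][j] * (y[j] - ybar) for j in range(n))
        out.append((n**2 / S) * lx * ly / (denx * deny))
    return out


def exhaustive_global_p(w, x, y, alternative="two-sided"):
    """Exact permutation p for global L: enumerate all n! joint
    rearrangements of the (x, y) pairs."""
    n = len(x)
    l_obs = brute_global_lee(w, x, y)
    extreme = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        xs = [x[p] for p in perm]
        ys = [y[p] for p in perm]
        ls = brute_global_lee(w, xs, ys)
        if _is_extreme(ls, l_obs, alternative):
            extreme += 1
        total += 1
    return extreme / total


def exhaustive_local_p(w, x, y, alternative="two-sided"):
    """Exact conditional permutation p per area: hold (x_i, y_i), enumerate
    all (n-1)! arrangements of the other pairs over the other slots."""
    n = len(x)
    l_obs = brute_local_lee(w, x, y)
    out = []
    for i in range(n):
        others = [j for j in range(n) if j != i]
        extreme = 0
        total = 0
        for perm in itertools.permutations(others):
            xs = list(x)
            ys = list(y)
            for slot, src in zip(others, perm):
                xs[slot] = x[src]
                ys[slot] = y[src]
            li = brute_local_lee(w, xs, ys)[i]
            if _is_extreme(li, l_obs[i], alternative):
                extreme += 1
            total += 1
        out.append(extreme / total)
    return out


def _is_extreme(stat, obs, alternative):
    # rearranged sums can perturb the statistic by an ulp; structural ties
    # must still count as "at least as extreme"
    eps = 1e-9 * (1.0 + abs(obs))
    if alternative == "two-sided":
        return abs(stat) >= abs(obs) - eps
    if alternative == "greater":
        return stat >= obs - eps
    return stat <= obs + eps


def winding_number_contains(ring, point):
    """Winding-number point-in-polygon test (nonzero rule).

    ``ring`` is a closed list of (x, y) vertices. Points exactly on the
    boundary are not guaranteed a stable answer; callers use interior
    points.
    """
    px, py = point
    wn = 0
    for k in range(len(ring) - 1):
        x1, y1 = ring[k]
        x2, y2 = ring[k + 1]
        if y1 <= py:
            if y2 > py and _is_left(x1, y1, x2, y2, px, py) > 0:
                wn += 1
        elif y2 <= py and _is_left(x1, y1, x2, y2, px, py) < 0:
            wn -= 1
    return wn != 0


def _is_left(x1, y1, x2, y2, px, py):
    return (x2 - x1) * (py - y1) - (px - x1) * (y2 - y1)
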