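"""Lee's L bivariate spatial correlation with Monte Carlo inference.

Lee's L combines the Pearson-type association between two area-level
variables with the spatial autocorrelation of each, by correlating their
spatially lagged (neighbourhood-averaged) values. With centred variables
x~_i = x_i - xbar, lagged values lx~_i = sum_j w_ij x~_j and
S = sum_i (sum_j w_ij)^2:

    L = (n / S) * sum_i lx~_i * ly~_i / ( sqrt(sum x~^2) * sqrt(sum y~^2) )

The local decomposition L_i = (n^2 / S) * lx~_i * ly~_i / (same norms)
averages back to the global L under row-standardised weights. Two
companion diagnostics separate genuine bivariate association from
autocorrelation: the spatial smoothing scalar SSS_x = L(x, x) (how much
neighbourhood averaging preserves a variable's variance) and the Pearson
correlation of the two lag vectors.

Significance is assessed by Monte Carlo permutation: (x_i, y_i) pairs are
permuted jointly across areas, which destroys the spatial arrangement
while preserving the within-area pairing. Local statistics use conditional
permutation (the focal area's pair held fixed, all others permuted). All
pseudo-p-values use the plus-one estimator (1 + #extreme) / (R + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .weights import DegenerateInputError, WeightsMatrix, spatial_lag

logger = logging.getLogger(__name__)

ALTERNATIVES = ("two-sided", "greater", "less")

#: Default number of Monte Carlo permutations.
DEFAULT_PERMUTATIONS = 10_000

_PERM_CHUNK = 2_000  # permutation batch size, caps peak memory


@dataclass
class LeeResult:
    """Global Lee statistics for one (x, y) pair on one weights matrix."""

    L: float
    sss_x: float
    sss_y: float
    lag_pearson: float
    pseudo_p: float
    n_permutations: int
    alternative: str
    seed: int
    n: int  # non-island areas analysed


@dataclass
class LocalLeeResult:
    """Per-area local Lee coefficients with conditional-permutation p-values.

    Arrays are aligned to ``area_ids``; island entries are NaN and carry no
    p-value. ``lag_x_centred`` / ``lag_y_centred`` are the lagged centred
    variables whose signs drive the high/low classification.
    """

    area_ids: list[str]
    local_l: np.ndarray
    pseudo_p: np.ndarray
    lag_x_centred: np.ndarray
    lag_y_centred: np.ndarray
    n_permutations: int
    alternative: str
    seed: int
    islands: list[str]


# ---------------------------------------------------------------------------
# Internal plumbing
# ---------------------------------------------------------------------------


def _prepare(W: WeightsMatrix, x, y):
    """Validate, drop islands, centre, and pre-compute shared quantities."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != (W.n,) or y.shape != (W.n,):
        raise ValueError(f"x and y must have length {W.n}")
    mask = ~W.island_mask
    n = int(mask.sum())
    if n < 2:
        raise DegenerateInputError("need at least 2 non-island areas")
    if W.islands:
        logger.warning("excluding %d island(s) from Lee statistics", len(W.islands))
    # Islands are nobody's neighbour (symmetry), so the subgraph restriction
    # is exact: re-index the non-island rows.
    remap = -np.ones(W.n, dtype=int)
    remap[mask] = np.arange(n)
    rows, cols, vals = [], [], []
    for i in np.flatnonzero(mask):
        nb, w = W.neighbors[i], W.weights[i]
        rows.extend([remap[i]] * len(nb))
        cols.extend(remap[nb].tolist())
        vals.extend(w.tolist())
    Ws = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n), dtype=float)
    xs, ys = x[mask], y[mask]
    xt = xs - xs.mean()
    yt = ys - ys.mean()
    denx = float(np.sqrt(np.sum(xt**2)))
    deny = float(np.sqrt(np.sum(yt**2)))
    if denx == 0 or deny == 0:
        raise DegenerateInputError("zero-variance input")
    row_sums = np.asarray(Ws.sum(axis=1)).ravel()
    S = float(np.sum(row_sums**2))
    return Ws, mask, n, xt, yt, denx, deny, S


def _global_from_parts(Ws, n, xt, yt, denx, deny, S) -> float:
    lx = Ws @ xt
    ly = Ws @ yt
    return (n / S) * float(lx @ ly) / (denx * deny)


def _extreme_count(stat_obs: float, stats: np.ndarray, alternative: str) -> int:
    # permuted statistics are computed through a different summation order
    # than the observed one, so structural ties (permutations that leave the
    # statistic unchanged) must be counted with a tolerance
    eps = 1e-9 * (1.0 + abs(stat_obs))
    if alternative == "two-sided":
        return int(np.sum(np.abs(stats) >= abs(stat_obs) - eps))
    if alternative == "greater":
        return int(np.sum(stats >= stat_obs - eps))
    if alternative == "less":
        return int(np.sum(stats <= stat_obs + eps))
    raise ValueError(f"alternative must be one of {ALTERNATIVES}")


# ---------------------------------------------------------------------------
# Point statistics
# ---------------------------------------------------------------------------


def global_lee_l(W: WeightsMatrix, x, y) -> float:
    """Global Lee's L of x and y on weights W (non-island areas).

    With row-standardised weights S = n, so the prefactor n/S is 1 and L
    lies in [-1, 1].
    """
    Ws, _, n, xt, yt, denx, deny, S = _prepare(W, x, y)
    return _global_from_parts(Ws, n, xt, yt, denx, deny, S)


def spatial_smoothing_scalar(W: WeightsMatrix, x) -> float:
    """SSS(x) = L(x, x): nonnegative; near 1 means strong positive spatial
    autocorrelation (neighbourhood averaging preserves the variance), near
    0 means averaging destroys it."""
    return global_lee_l(W, x, x)


def lag_pearson(W: WeightsMatrix, x, y) -> float:
    """Pearson correlation of the two neighbourhood weighted averages."""
    Ws, _, n, xt, yt, denx, deny, _ = _prepare(W, x, y)
    lx = Ws @ xt
    ly = Ws @ yt
    if np.std(lx) == 0 or np.std(ly) == 0:
        raise DegenerateInputError("zero-variance spatial lag")
    return float(np.corrcoef(lx, ly)[0, 1])


def local_lee_l(W: WeightsMatrix, x, y) -> np.ndarray:
    """Per-area local Lee coefficients, NaN at islands.

    Under row-standardised weights the mean over non-island areas equals
    the global L.
    """
    Ws, mask, n, xt, yt, denx, deny, S = _prepare(W, x, y)
    li = (n**2 / S) * (Ws @ xt) * (Ws @ yt) / (denx * deny)
    out = np.full(W.n, np.nan)
    out[mask] = li
    return out


# ---------------------------------------------------------------------------
# Monte Carlo inference
# ---------------------------------------------------------------------------


def permutation_test_global(
    W: WeightsMatrix,
    x,
    y,
    R: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    alternative: str = "two-sided",
) -> float:
    """Pseudo-p-value for global Lee's L by joint pair permutation.

    Each permutation reassigns the observed (x_i, y_i) pairs to areas at
    random; the norms and means are permutation-invariant, so only the two
    lag products are recomputed. Two-sided extremeness compares |L*| with
    |L_obs|.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    Ws, _, n, xt, yt, denx, deny, S = _prepare(W, x, y)
    l_obs = _global_from_parts(Ws, n, xt, yt, denx, deny, S)
    rng = np.random.default_rng(seed)
    scale = (n / S) / (denx * deny)
    extreme = 0
    done = 0
    while done < R:
        m = min(_PERM_CHUNK, R - done)
        perms = rng.permuted(np.tile(np.arange(n), (m, 1)), axis=1)
        Xp = xt[perms]  # (m, n): same permutation applied to both variables
        Yp = yt[perms]
        lstar = scale * np.einsum("in,in->i", (Ws @ Xp.T).T, (Ws @ Yp.T).T)
        extreme += _extreme_count(l_obs, lstar, alternative)
        done += m
    return (1 + extreme) / (R + 1)


def permutation_test_local(
    W: WeightsMatrix,
    x,
    y,
    R: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    alternative: str = "two-sided",
) -> np.ndarray:
    """Conditional-permutation pseudo-p-values for local Lee coefficients.

    For each area i the observed pair (x_i, y_i) is held in place and the
    remaining n-1 pairs are permuted across the remaining areas; only i's
    neighbourhood matters for L_i, so each permutation amounts to drawing
    |N(i)| pairs without replacement from the others. A single bank of R
    permutations of the n-1 "other" slots is shared across areas.

    Returns an array aligned to ``W.area_ids``; islands get NaN.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    Ws, mask, n, xt, yt, denx, deny, S = _prepare(W, x, y)
    li_obs = (n**2 / S) * (Ws @ xt) * (Ws @ yt) / (denx * deny)
    scale = (n**2 / S) / (denx * deny)

    sub_idx = np.flatnonzero(mask)
    nb_sub = []  # neighbour lists re-indexed to the non-island subspace
    remap = -np.ones(W.n, dtype=int)
    remap[mask] = np.arange(n)
    for i in sub_idx:
        nb_sub.append(remap[W.neighbors[i]])

    rng = np.random.default_rng(seed)
    perm_bank = rng.permuted(np.tile(np.arange(n - 1), (R, 1)), axis=1)

    p_sub = np.empty(n)
    for i in range(n):
        nb = nb_sub[i]
        k = len(nb)
        w = W.weights[sub_idx[i]]
        pos = perm_bank[:, :k]  # (R, k) sample without replacement from others
        idx = pos + (pos >= i)  # skip the focal area's own slot
        lx_star = xt[idx] @ w
        ly_star = yt[idx] @ w
        li_star = scale * lx_star * ly_star
        p_sub[i] = (1 + _extreme_count(float(li_obs[i]), li_star, alternative)) / (R + 1)

    out = np.full(W.n, np.nan)
    out[mask] = p_sub
    return out


# ---------------------------------------------------------------------------
# Bundled analyses
# ---------------------------------------------------------------------------


def global_lee_analysis(
    W: WeightsMatrix,
    x,
    y,
    R: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    alternative: str = "two-sided",
) -> LeeResult:
    """Global L, both smoothing scalars, lag-Pearson and the pseudo-p."""
    return LeeResult(
        L=global_lee_l(W, x, y),
        sss_x=spatial_smoothing_scalar(W, x),
        sss_y=spatial_smoothing_scalar(W, y),
        lag_pearson=lag_pearson(W, x, y),
        pseudo_p=permutation_test_global(W, x, y, R=R, seed=seed, alternative=alternative),
        n_permutations=R,
        alternative=alternative,
        seed=seed,
        n=W.n - len(W.islands),
    )


def local_lee_analysis(
    W: WeightsMatrix,
    x,
    y,
    R: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    alternative: str = "two-sided",
    bh_adjust: bool = False,
) -> LocalLeeResult:
    """Local coefficients, their conditional-permutation p-values and the
    lagged centred variables used by the five-category classification.

    ``bh_adjust`` optionally applies Benjamini-Hochberg FDR adjustment to
    the local p-values (off by default: the classification follows the
    unadjusted per-area test, with the usual caveat about repeated local
    tests).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~W.island_mask
    xbar = x[mask].mean()
    ybar = y[mask].mean()
    lag_x = spatial_lag(W, np.where(mask, x - xbar, np.nan))
    lag_y = spatial_lag(W, np.where(mask, y - ybar, np.nan))
    pvals = permutation_test_local(W, x, y, R=R, seed=seed, alternative=alternative)
    if bh_adjust:
        from scipy.stats import false_discovery_control

        sub = ~np.isnan(pvals)
        pvals = pvals.copy()
        pvals[sub] = false_discovery_control(pvals[sub], method="bh")
    return LocalLeeResult(
        area_ids=list(W.area_ids),
        local_l=local_lee_l(W, x, y),
        pseudo_p=pvals,
        lag_x_centred=lag_x,
        lag_y_centred=lag_y,
        n_permutations=R,
        alternative=alternative,
        seed=seed,
        islands=list(W.islands),
    )
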