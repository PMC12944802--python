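"""Contiguity-based spatial weights.

Builds the neighbourhood graph from polygon boundaries (queen or rook
contiguity), row-standardises it to equal weights 1/|N(i)|, and computes
neighbourhood weighted averages (spatial lags). Areas with no contiguous
neighbour ("islands") keep empty rows: their lag is undefined and they are
excluded from lag-based statistics downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import sparse

from .synthetic import AreaSet

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Raised when an input admits no meaningful statistic (e.g. zero variance)."""


@dataclass
class WeightsMatrix:
    """Row-standardised contiguity weights.

    ``neighbors[i]`` holds the indices of areas contiguous with area i
    (self excluded), ``weights[i]`` the matching weights. After row
    standardisation every non-island row sums to one.
    """

    area_ids: list[str]
    neighbors: list[np.ndarray]
    weights: list[np.ndarray]
    islands: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.area_ids)

    @property
    def island_mask(self) -> np.ndarray:
        mask = np.zeros(self.n, dtype=bool)
        isl = set(self.islands)
        for i, a in enumerate(self.area_ids):
            if a in isl:
                mask[i] = True
        return mask

    def to_sparse(self) -> sparse.csr_matrix:
        rows, cols, vals = [], [], []
        for i, (nb, w) in enumerate(zip(self.neighbors, self.weights)):
            rows.extend([i] * len(nb))
            cols.extend(nb.tolist())
            vals.extend(w.tolist())
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(self.n, self.n), dtype=float
        )

    def validate(self) -> None:
        """Check graph symmetry, no self-loops, positive weights, row sums."""
        nb_sets = [set(nb.tolist()) for nb in self.neighbors]
        for i, nb in enumerate(nb_sets):
            if i in nb:
                raise ValueError(f"area {self.area_ids[i]} is its own neighbour")
            for j in nb:
                if i not in nb_sets[j]:
                    raise ValueError("adjacency is not symmetric")
        for i, w in enumerate(self.weights):
            if len(w) and (np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-12):
                raise ValueError(f"row {self.area_ids[i]} not standardised")


def _lattice_neighbors(areas: AreaSet, rule: str) -> list[set[int]]:
    nx, ny = areas.lattice_shape  # type: ignore[misc]
    offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if rule == "queen":
        offs += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    adj: list[set[int]] = [set() for _ in range(nx * ny)]
    for iy in range(ny):
        for ix in range(nx):
            i = iy * nx + ix
            for dx, dy in offs:
                jx, jy = ix + dx, iy + dy
                if areas.torus:
                    jx, jy = jx % nx, jy % ny
                elif not (0 <= jx < nx and 0 <= jy < ny):
                    continue
                j = jy * nx + jx
                if j != i:
                    adj[i].add(j)
    return adj


def _geometric_neighbors(areas: AreaSet, rule: str) -> list[set[int]]:
    polys = np.asarray(areas.polygons, dtype=object)
    tree = shapely.STRtree(polys)
    adj: list[set[int]] = [set() for _ in range(len(areas))]
    for i, poly in enumerate(areas.polygons):
        for j in tree.query(poly, predicate="intersects"):
            j = int(j)
            if j == i:
                continue
            inter = poly.intersection(areas.polygons[j])
            if inter.is_empty:
                continue
            if rule == "rook":
                if inter.length > 0:  # shared boundary of positive length
                    adj[i].add(j)
            else:  # queen: any shared boundary point
                adj[i].add(j)
    return adj


def contiguity_neighbors(areas: AreaSet, rule: str = "queen") -> list[set[int]]:
    """Adjacency lists under queen (shared point) or rook (shared segment)
    contiguity. Torus lattices wrap around their edges."""
    if rule not in ("queen", "rook"):
        raise ValueError("rule must be 'queen' or 'rook'")
    if areas.torus and areas.lattice_shape is not None:
        return _lattice_neighbors(areas, rule)
    return _geometric_neighbors(areas, rule)


def row_standardize(adjacency: list[set[int]], area_ids: list[str]) -> WeightsMatrix:
    """Equal weights 1/|N(i)| across each neighbourhood.

    Islands (empty neighbourhoods) keep empty rows and are reported on the
    ``islands`` list with a logged warning.
    """
    neighbors, weights, islands = [], [], []
    for i, nb in enumerate(adjacency):
        idx = np.array(sorted(nb), dtype=int)
        neighbors.append(idx)
        if len(idx):
            weights.append(np.full(len(idx), 1.0 / len(idx)))
        else:
            weights.append(np.empty(0))
            islands.append(area_ids[i])
    if islands:
        logger.warning("%d island area(s) with no neighbours: %s", len(islands), islands)
    return WeightsMatrix(list(area_ids), neighbors, weights, islands)


def build_weights(areas: AreaSet, rule: str = "queen") -> WeightsMatrix:
    """Contiguity adjacency + row standardisation in one step."""
    return row_standardize(contiguity_neighbors(areas, rule), areas.area_ids)


def identity_weights(area_ids: list[str]) -> WeightsMatrix:
    """Include-self identity weights: N(i) = {i}, w_ii = 1.

    A degenerate fixture under which the spatial lag is the identity map,
    so Lee's L collapses to the Pearson correlation. Not a valid contiguity
    scheme (violates the self-exclusion invariant); for testing only.
    """
    n = len(area_ids)
    return WeightsMatrix(
        list(area_ids),
        [np.array([i]) for i in range(n)],
        [np.array([1.0]) for _ in range(n)],
        [],
    )


def spatial_lag(W: WeightsMatrix, values: np.ndarray) -> np.ndarray:
    """Neighbourhood weighted average lag_i = sum_j w_ij v_j.

    Islands get NaN (their lag is undefined).
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (W.n,):
        raise ValueError(f"values must have length {W.n}, got {values.shape}")
    out = np.full(W.n, np.nan)
    for i, (nb, w) in enumerate(zip(W.neighbors, W.weights)):
        if len(nb):
            out[i] = float(w @ values[nb])
    return out
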