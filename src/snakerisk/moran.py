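"""Local spatial autocorrelation of municipality counts (Anselin's Local Moran's I).

The cluster stage asks, for every municipality, whether its snakebite count
together with the counts of its queen-contiguous neighbours (any shared
boundary point — edge or single vertex) departs from what an exchangeable
arrangement of the remaining municipalities would produce.  Significant units
are labelled by the quadrant of (own deviation, neighbourhood deviation):
High-High and Low-Low mark clusters, High-Low and Low-High mark outliers.

The statistic for unit *i* is

    I_i = (z_i / m2) * sum_j w_ij z_j,      z_i = x_i - mean(x),
    m2  = sum_i z_i^2 / n,

with row-standardised weights ``w``.  Under this scaling the average of the
I_i equals the global Moran's I.  Inference is by conditional permutation:
unit *i*'s value is held fixed while the remaining n-1 values are randomly
reassigned to its neighbour slots; the pseudo p-value is two-sided on |I_i|.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import sparse as sp

__all__ = [
    "SpatialWeights",
    "local_moran_i",
    "permutation_pvalues",
    "classify_clusters",
    "local_moran",
]

QUADRANTS = ("HH", "LL", "HL", "LH", "NS")


@dataclass
class SpatialWeights:
    """Sparse symmetric neighbour structure over spatial units.

    ``neighbors`` maps each unit id to the sorted list of its neighbour ids.
    The binary relation is symmetric and irreflexive (no self-neighbours).
    Row standardisation is applied when the weights matrix is materialised.
    """

    ids: list
    neighbors: dict = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate unit identifiers in weights")
        idset = set(self.ids)
        for i, nbrs in self.neighbors.items():
            if i not in idset:
                raise ValueError(f"neighbor list for unknown unit {i!r}")
            if i in nbrs:
                raise ValueError(f"unit {i!r} listed as its own neighbor")
            for j in nbrs:
                if i not in self.neighbors.get(j, ()):
                    raise ValueError(f"asymmetric adjacency: {i!r} -> {j!r}")

    # ------------------------------------------------------------------ #
    # constructors
    # ------------------------------------------------------------------ #
    @classmethod
    def from_grid(cls, rows: int, cols: int, ids: Sequence | None = None) -> "SpatialWeights":
        """Queen contiguity on a ``rows x cols`` lattice, row-major unit order."""
        if rows < 1 or cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if ids is None:
            ids = [r * cols + c for r in range(rows) for c in range(cols)]
        if len(ids) != rows * cols:
            raise ValueError("ids length must equal rows*cols")
        neighbors = {}
        for r in range(rows):
            for c in range(cols):
                nbrs = []
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < rows and 0 <= cc < cols:
                            nbrs.append(ids[rr * cols + cc])
                neighbors[ids[r * cols + c]] = nbrs  # row-major scan order
        return cls(list(ids), neighbors)

    @classmethod
    def from_polygons(cls, polygons: Mapping) -> "SpatialWeights":
        """Queen contiguity from a mapping ``id -> shapely geometry``.

        Two polygons are neighbours iff their geometries share at least one
        point.  Polygons are assumed valid and non-overlapping (touching
        boundaries only), as produced by a municipal tessellation.
        """
        ids = list(polygons.keys())
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate polygon identifiers")
        geoms = []
        for i in ids:
            g = polygons[i]
            if g is None or g.is_empty:
                raise ValueError(f"empty geometry for unit {i!r}")
            geoms.append(g)
        tree = shapely.STRtree(geoms)
        neighbors = {i: [] for i in ids}
        left, right = tree.query(np.array(geoms, dtype=object), predicate="intersects")
        for a, b in zip(left, right):
            if a != b:
                neighbors[ids[a]].append(ids[b])
        neighbors = {i: sorted(set(v)) for i, v in neighbors.items()}
        return cls(ids, neighbors)

    @classmethod
    def from_adjacency(cls, pairs: Iterable[tuple], ids: Sequence | None = None) -> "SpatialWeights":
        """Build from an edge list; symmetry is enforced, self-pairs rejected."""
        pairs = list(pairs)
        if ids is None:
            ids = sorted({u for p in pairs for u in p})
        neighbors = {i: set() for i in ids}
        for a, b in pairs:
            if a == b:
                raise ValueError(f"self-neighbor pair for unit {a!r}")
            neighbors[a].add(b)
            neighbors[b].add(a)
        return cls(list(ids), {i: sorted(v) for i, v in neighbors.items()})

    # ------------------------------------------------------------------ #
    @property
    def n_units(self) -> int:
        return len(self.ids)

    @property
    def cardinalities(self) -> np.ndarray:
        return np.array([len(self.neighbors[i]) for i in self.ids])

    @property
    def islands(self) -> list:
        """Units with no neighbours (allowed, reported, excluded from inference)."""
        return [i for i in self.ids if not self.neighbors[i]]

    def sparse(self, row_standardized: bool = True) -> sp.csr_matrix:
        pos = {i: k for k, i in enumerate(self.ids)}
        rows_, cols_, data = [], [], []
        for i in self.ids:
            nbrs = self.neighbors[i]
            w = 1.0 / len(nbrs) if (row_standardized and nbrs) else 1.0
            for j in nbrs:
                rows_.append(pos[i])
                cols_.append(pos[j])
                data.append(w)
        return sp.csr_matrix((data, (rows_, cols_)), shape=(self.n_units, self.n_units))

    def neighbor_index_lists(self) -> list[np.ndarray]:
        pos = {i: k for k, i in enumerate(self.ids)}
        return [np.array([pos[j] for j in self.neighbors[i]], dtype=np.intp) for i in self.ids]


def queen_contiguity(polygons: Mapping) -> SpatialWeights:
    """Convenience alias: queen-contiguity weights from polygon geometries."""
    return SpatialWeights.from_polygons(polygons)


# ---------------------------------------------------------------------- #
# statistic
# ---------------------------------------------------------------------- #
def _deviations(values: np.ndarray) -> tuple[np.ndarray, float]:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if np.ptp(x) == 0:
        raise ValueError("Local Moran's I is undefined for constant input")
    z = x - x.mean()
    m2 = float(np.mean(z**2))  # population moment, denominator n
    return z, m2


def local_moran_i(values, weights: SpatialWeights) -> np.ndarray:
    """Local Moran statistic I_i with row-standardised weights.

    Returns an array aligned to ``weights.ids``.  Isolated units get I_i = 0
    (their spatial lag is empty).
    """
    z, m2 = _deviations(values)
    if len(z) != weights.n_units:
        raise ValueError("values not aligned to weights units")
    lag = weights.sparse(row_standardized=True) @ z
    return z / m2 * lag


def spatial_lag(values, weights: SpatialWeights) -> np.ndarray:
    z = np.asarray(values, dtype=float)
    return weights.sparse(row_standardized=True) @ z


def permutation_pvalues(
    values,
    weights: SpatialWeights,
    n_perm: int = 9999,
    seed: int | None = None,
    method: str = "sample",
) -> np.ndarray:
    """Conditional-permutation pseudo p-values for the local Moran statistics.

    For each unit the observed value is held fixed and the remaining n-1
    values are reassigned at random to its neighbour slots.  The p-value is
    two-sided: the fraction of permuted statistics with |I| at least the
    observed |I|, with the +1 pseudo-count floor 1/(n_perm+1).

    ``method="exhaustive"`` enumerates every neighbour-value subset instead of
    sampling; the p-value is then the exact fraction of arrangements at least
    as extreme (the observed arrangement is one of them, so p > 0).  Feasible
    only for very small maps.

    Isolated units receive NaN.
    """
    if method not in ("sample", "exhaustive"):
        raise ValueError(f"unknown method {method!r}")
    if method == "sample" and n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    z, m2 = _deviations(values)
    n = weights.n_units
    if len(z) != n:
        raise ValueError("values not aligned to weights units")
    I_obs = local_moran_i(values, weights)
    nbr_idx = weights.neighbor_index_lists()
    p = np.full(n, np.nan)

    if method == "exhaustive":
        for i in range(n):
            k = len(nbr_idx[i])
            if k == 0:
                continue
            others = np.delete(z, i)
            total = comb(n - 1, k)
            count = 0
            # tolerance so the observed arrangement itself always counts,
            # regardless of floating-point summation order
            cut = abs(I_obs[i]) - 1e-9 * (1.0 + abs(I_obs[i]))
            for subset in itertools.combinations(others, k):
                I_perm = z[i] / m2 * (sum(subset) / k)
                if abs(I_perm) >= cut:
                    count += 1
            p[i] = count / total
        return p

    rng = np.random.default_rng(seed)
    kmax = int(weights.cardinalities.max(initial=0))
    if kmax == 0:
        return p
    # one shared pool of permutations of the n-1 "other" slots, as in the
    # standard conditional-randomisation implementation
    perms = np.empty((n_perm, kmax), dtype=np.intp)
    for t in range(n_perm):
        perms[t] = rng.permutation(n - 1)[:kmax]
    for i in range(n):
        k = len(nbr_idx[i])
        if k == 0:
            continue
        others = np.delete(z, i)
        lag_perm = others[perms[:, :k]].mean(axis=1)
        I_perm = z[i] / m2 * lag_perm
        count = int(np.count_nonzero(np.abs(I_perm) >= abs(I_obs[i])))
        p[i] = (count + 1) / (n_perm + 1)
    return p


def classify_clusters(z: np.ndarray, lag: np.ndarray, p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Quadrant labels HH/LL/HL/LH for significant units, NS otherwise.

    ``z`` are deviations from the mean, ``lag`` their row-standardised spatial
    lag, ``p`` the pseudo p-values (NaN = isolated unit, labelled NS).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    z = np.asarray(z, float)
    lag = np.asarray(lag, float)
    p = np.asarray(p, float)
    labels = np.full(z.shape, "NS", dtype=object)
    sig = ~np.isnan(p) & (p <= alpha)
    hh = sig & (z > 0) & (lag > 0)
    ll = sig & (z < 0) & (lag < 0)
    hl = sig & (z > 0) & (lag <= 0)
    lh = sig & (z <= 0) & (lag > 0)
    labels[hh], labels[ll], labels[hl], labels[lh] = "HH", "LL", "HL", "LH"
    return labels.astype(str)


def local_moran(
    values,
    weights: SpatialWeights,
    n_perm: int = 9999,
    seed: int | None = None,
    alpha: float = 0.05,
    method: str = "sample",
) -> pd.DataFrame:
    """Full cluster analysis: statistic, pseudo p-values and quadrant labels.

    Returns a DataFrame with one row per unit: ``muni_id, I, p, z, lag,
    quadrant, n_perm``.  ``z`` here is the standardised deviate of the
    analysed value (deviation divided by its population SD).
    """
    x = np.asarray(values, dtype=float)
    zdev, m2 = _deviations(x)
    I = local_moran_i(x, weights)
    lag = spatial_lag(zdev, weights)
    p = permutation_pvalues(x, weights, n_perm=n_perm, seed=seed, method=method)
    quad = classify_clusters(zdev, lag, p, alpha=alpha)
    return pd.DataFrame(
        {
            "muni_id": weights.ids,
            "I": I,
            "p": p,
            "z": zdev / np.sqrt(m2),
            "lag": lag,
            "quadrant": quad,
            "n_perm": n_perm,
        }
    )
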