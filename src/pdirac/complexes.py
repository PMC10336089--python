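"""Simplicial complexes, filtrations, and signed boundary matrices.

A simplex is represented as a strictly increasing tuple of integer vertex
labels; the increasing-label order is the positive orientation.  Complexes
store simplices grouped by dimension in lexicographic order, and all
matrices in the package index rows and columns by that canonical order.

Two filtration constructions are provided: the Vietoris--Rips filtration
(simplex enters at the diameter of its vertex set) and the Alpha filtration
(subcomplex of the Delaunay triangulation, filtered by circumradius with
the usual Gabriel-face correction).  Both report filtration values in
Angstrom.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.spatial import QhullError, Delaunay
from scipy.spatial.distance import pdist, squareform

Simplex = Tuple[int, ...]

__all__ = [
    "Simplex",
    "SimplicialComplex",
    "Filtration",
    "BoundaryMatrix",
    "rips_filtration",
    "alpha_filtration",
    "complete_complex",
    "boundary_matrix",
    "betti_numbers",
]


def _as_simplex(s: Sequence[int]) -> Simplex:
    t = tuple(int(v) for v in s)
    if any(t[i] >= t[i + 1] for i in range(len(t) - 1)):
        raise ValueError(f"simplex vertices must be strictly increasing, got {t}")
    return t


class SimplicialComplex:
    """A finite simplicial complex, closed under taking faces.

    Parameters
    ----------
    simplices
        Iterable of vertex tuples (strictly increasing labels).  Faces of
        every given simplex are added automatically, so it is enough to
        pass the maximal simplices.
    """

    def __init__(self, simplices: Iterable[Sequence[int]]):
        seen: set = set()
        for s in simplices:
            t = _as_simplex(s)
            if t in seen:
                continue
            # close under faces
            for k in range(1, len(t) + 1):
                for face in itertools.combinations(t, k):
                    seen.add(face)
        by_dim: Dict[int, List[Simplex]] = {}
        for s in seen:
            by_dim.setdefault(len(s) - 1, []).append(s)
        self._simplices: Dict[int, List[Simplex]] = {
            d: sorted(v) for d, v in sorted(by_dim.items())
        }
        self._index: Dict[int, Dict[Simplex, int]] = {
            d: {s: i for i, s in enumerate(v)} for d, v in self._simplices.items()
        }

    # -- basic queries ----------------------------------------------------
    @property
    def max_dim(self) -> int:
        """Largest dimension with at least one simplex (-1 if empty)."""
        return max(self._simplices, default=-1)

    def n(self, p: int) -> int:
        """Number of p-simplices."""
        return len(self._simplices.get(p, ()))

    @property
    def counts(self) -> Tuple[int, ...]:
        """(n_0, n_1, ..., n_maxdim)."""
        return tuple(self.n(p) for p in range(self.max_dim + 1))

    def simplices(self, p: int) -> List[Simplex]:
        """The p-simplices in canonical (lexicographic) order."""
        return list(self._simplices.get(p, ()))

    def index(self, p: int) -> Dict[Simplex, int]:
        """Map p-simplex -> column position in the canonical order."""
        return dict(self._index.get(p, {}))

    def __contains__(self, s: Sequence[int]) -> bool:
        t = tuple(int(v) for v in s)
        return t in self._index.get(len(t) - 1, {})

    def __len__(self) -> int:
        return sum(len(v) for v in self._simplices.values())

    def all_simplices(self) -> List[Simplex]:
        return [s for d in sorted(self._simplices) for s in self._simplices[d]]

    def skeleton(self, k: int) -> "SimplicialComplex":
        """The k-skeleton (all simplices of dimension <= k)."""
        out = SimplicialComplex.__new__(SimplicialComplex)
        out._simplices = {d: list(v) for d, v in self._simplices.items() if d <= k}
        out._index = {d: dict(self._index[d]) for d in out._simplices}
        return out

    def is_subcomplex_of(self, other: "SimplicialComplex") -> bool:
        return all(s in other for s in self.all_simplices())

    def __repr__(self) -> str:  # pragma: no cover
        return f"SimplicialComplex(counts={self.counts})"


class Filtration:
    """A simplicial complex together with monotone filtration values (Angstrom).

    ``values[s]`` is the scale at which simplex ``s`` enters; every face
    enters no later than its cofaces, so each sublevel set is itself a
    valid simplicial complex.
    """

    def __init__(self, complex: SimplicialComplex, values: Mapping[Simplex, float]):
        for s in complex.all_simplices():
            if s not in values:
                raise ValueError(f"no filtration value for simplex {s}")
            v = values[s]
            if not np.isfinite(v) and v != np.inf:
                raise ValueError(f"non-finite filtration value for {s}")
            if len(s) > 1:
                for face in itertools.combinations(s, len(s) - 1):
                    if values[face] > v + 1e-12:
                        raise ValueError(
                            f"filtration not monotone: face {face} enters at "
                            f"{values[face]} after coface {s} at {v}"
                        )
        self.complex = complex
        self.values: Dict[Simplex, float] = {
            s: float(values[s]) for s in complex.all_simplices()
        }

    @property
    def max_value(self) -> float:
        return max(self.values.values(), default=0.0)

    def sublevel(self, a: float) -> SimplicialComplex:
        """The subcomplex of simplices with filtration value <= ``a``."""
        members = [s for s, v in self.values.items() if v <= a]
        out = SimplicialComplex.__new__(SimplicialComplex)
        by_dim: Dict[int, List[Simplex]] = {}
        for s in members:
            by_dim.setdefault(len(s) - 1, []).append(s)
        out._simplices = {d: sorted(v) for d, v in sorted(by_dim.items())}
        out._index = {
            d: {s: i for i, s in enumerate(v)} for d, v in out._simplices.items()
        }
        return out

    def sorted_simplices(self) -> List[Tuple[float, Simplex]]:
        """Simplices sorted by (value, dimension, lexicographic order)."""
        return sorted(self.values.items(), key=lambda kv: (kv[1], len(kv[0]), kv[0]))

    def sorted_pairs(self) -> List[Tuple[float, Simplex]]:
        return [(v, s) for s, v in self.sorted_simplices()]


@dataclass
class BoundaryMatrix:
    """Signed incidence matrix of the boundary operator from dimension p.

    ``entries`` is the sparse n_{p-1} x n_p matrix with values in
    {-a_p, 0, +a_p}; the unweighted operator is the a_p = 1 case.
    """

    entries: sp.csr_matrix
    row_simplices: List[Simplex]
    col_simplices: List[Simplex]
    p: int
    a_p: float = 1.0

    @property
    def shape(self) -> Tuple[int, int]:
        return self.entries.shape

    def toarray(self) -> np.ndarray:
        return self.entries.toarray()


def _validate_points(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("points must be a non-empty N x d array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite coordinates")
    return pts


def rips_filtration(points: np.ndarray, max_dim: int, max_radius: float) -> Filtration:
    """Vietoris--Rips filtration of a point cloud.

    A simplex enters at the maximum pairwise distance among its vertices
    (diameter convention), so an edge appears exactly at its Euclidean
    length.  Only simplices of dimension <= ``max_dim`` with value
    <= ``max_radius`` are included.
    """
    pts = _validate_points(points)
    if max_dim < 0:
        raise ValueError("max_dim must be >= 0")
    if max_radius <= 0:
        raise ValueError("max_radius must be positive")
    n = pts.shape[0]
    dist = squareform(pdist(pts)) if n > 1 else np.zeros((1, 1))

    values: Dict[Simplex, float] = {(i,): 0.0 for i in range(n)}
    # neighbor sets of the threshold graph (neighbors with larger label,
    # for label-increasing clique expansion)
    nbrs: List[set] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= max_radius:
                nbrs[i].add(j)

    frontier: List[Tuple[Simplex, set, float]] = []
    if max_dim >= 1:
        for i in range(n):
            for j in sorted(nbrs[i]):
                s = (i, j)
                values[s] = dist[i, j]
                frontier.append((s, nbrs[i] & nbrs[j], dist[i, j]))
    dim = 1
    while dim < max_dim and frontier:
        nxt: List[Tuple[Simplex, set, float]] = []
        for s, cands, val in frontier:
            for v in sorted(cands):
                t = s + (v,)
                tval = max(val, max(dist[u, v] for u in s))
                values[t] = tval
                nxt.append((t, cands & nbrs[v], tval))
        frontier = nxt
        dim += 1

    K = SimplicialComplex.__new__(SimplicialComplex)
    by_dim: Dict[int, List[Simplex]] = {}
    for s in values:
        by_dim.setdefault(len(s) - 1, []).append(s)
    K._simplices = {d: sorted(v) for d, v in sorted(by_dim.items())}
    K._index = {d: {s: i for i, s in enumerate(v)} for d, v in K._simplices.items()}
    return Filtration(K, values)


def _circumsphere(pts: np.ndarray) -> Tuple[np.ndarray, float]:
    """Circumcenter and circumradius of the simplex spanned by ``pts``.

    The center is constrained to the affine hull of the vertices, which
    for a segment gives the midpoint (radius = half the length) and for a
    triangle the classical circumcenter.
    """
    x0 = pts[0]
    if len(pts) == 1:
        return x0.copy(), 0.0
    M = pts[1:] - x0
    b = 0.5 * np.einsum("ij,ij->i", M, M)
    gram = M @ M.T
    try:
        gamma = np.linalg.solve(gram, b)
    except np.linalg.LinAlgError:
        gamma = np.linalg.lstsq(gram, b, rcond=None)[0]
    offset = M.T @ gamma
    return x0 + offset, float(np.linalg.norm(offset))


def _delaunay_cells(pts: np.ndarray, rng: np.random.Generator, jitter: float):
    """Top-dimensional Delaunay cells of a (possibly degenerate) point set.

    The cloud is projected onto its affine hull first, so collinear and
    coplanar inputs triangulate in their intrinsic dimension.  Remaining
    qhull degeneracies are resolved by a tiny seeded jitter.
    """
    n = pts.shape[0]
    if n == 1:
        return [(0,)]
    centered = pts - pts.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scale = s[0] if s.size and s[0] > 0 else 1.0
    rank = int(np.sum(s > 1e-9 * scale))
    if rank == 0:
        # all points coincide: a single vertex cluster, no higher cells
        return [tuple(sorted(range(n)))] if n <= 1 else [(i,) for i in range(n)]
    proj = centered @ vt[:rank].T
    if rank == 1:
        order = np.argsort(proj[:, 0])
        return [tuple(sorted((int(order[i]), int(order[i + 1])))) for i in range(n - 1)]
    if n < rank + 2:
        return [tuple(range(n))]
    try:
        tri = Delaunay(proj)
    except QhullError:
        tri = Delaunay(proj + rng.normal(scale=jitter, size=proj.shape))
    return [tuple(sorted(int(v) for v in cell)) for cell in tri.simplices]


def alpha_filtration(
    points: np.ndarray,
    max_dim: int,
    jitter: float = 1e-9,
    seed: int = 0,
) -> Filtration:
    """Alpha filtration of a point cloud, parametrised by circumradius (A).

    Simplices are restricted to the Delaunay triangulation.  A simplex
    whose circumsphere is empty (Gabriel) enters at its circumradius; a
    non-Gabriel face inherits the smallest entry value among its cofaces,
    which keeps the filtration monotone.  Degenerate point sets are
    projected to their affine hull; residual qhull failures fall back to a
    seeded jitter of ``jitter`` Angstrom.
    """
    pts = _validate_points(points)
    if max_dim < 0:
        raise ValueError("max_dim must be >= 0")
    rng = np.random.default_rng(seed)
    cells = _delaunay_cells(pts, rng, jitter)

    by_dim: Dict[int, set] = {}
    for cell in cells:
        for k in range(1, len(cell) + 1):
            for face in itertools.combinations(cell, k):
                by_dim.setdefault(k - 1, set()).add(face)
    top = max(by_dim)

    alpha: Dict[Simplex, float] = {}
    for d in range(top, 0, -1):
        for s in by_dim.get(d, ()):
            if s not in alpha:
                _, r = _circumsphere(pts[list(s)])
                alpha[s] = r
            if d == 1:
                continue
            for face in itertools.combinations(s, d):
                if face in alpha:
                    alpha[face] = min(alpha[face], alpha[s])
                else:
                    center, r = _circumsphere(pts[list(face)])
                    (extra,) = set(s) - set(face)
                    if np.linalg.norm(pts[extra] - center) < r:
                        # non-Gabriel face: enters with its coface
                        alpha[face] = alpha[s]
    for i in range(pts.shape[0]):
        alpha[(i,)] = 0.0

    keep = [s for s in alpha if len(s) - 1 <= max_dim]
    K = SimplicialComplex.__new__(SimplicialComplex)
    grouped: Dict[int, List[Simplex]] = {}
    for s in keep:
        grouped.setdefault(len(s) - 1, []).append(s)
    K._simplices = {d: sorted(v) for d, v in sorted(grouped.items())}
    K._index = {d: {s: i for i, s in enumerate(v)} for d, v in K._simplices.items()}
    return Filtration(K, {s: alpha[s] for s in keep})


def complete_complex(n: int, max_dim: int) -> SimplicialComplex:
    """The complete complex on ``n`` vertices up to dimension ``max_dim``:
    every set of p+1 vertices forms a p-simplex."""
    if n < 1 or max_dim < 0:
        raise ValueError("need n >= 1 and max_dim >= 0")
    K = SimplicialComplex.__new__(SimplicialComplex)
    K._simplices = {
        d: [tuple(c) for c in itertools.combinations(range(n), d + 1)]
        for d in range(min(max_dim, n - 1) + 1)
    }
    K._index = {d: {s: i for i, s in enumerate(v)} for d, v in K._simplices.items()}
    return K


def boundary_matrix(K: SimplicialComplex, p: int, a_p: float = 1.0) -> BoundaryMatrix:
    """The signed n_{p-1} x n_p boundary matrix B_p (scaled by ``a_p``).

    Column j holds the alternating face signs (-1)^i of the j-th
    p-simplex; rows and columns follow the canonical lexicographic order.
    """
    if p < 1 or p > K.max_dim:
        raise ValueError(f"p={p} out of range for complex of dimension {K.max_dim}")
    if a_p <= 0:
        raise ValueError("a_p must be positive")
    rows = K.simplices(p - 1)
    cols = K.simplices(p)
    ridx = K.index(p - 1)
    data, ri, ci = [], [], []
    for j, s in enumerate(cols):
        for i in range(p + 1):  # face omitting vertex i carries sign (-1)^i
            face = s[:i] + s[i + 1 :]
            ri.append(ridx[face])
            ci.append(j)
            data.append(a_p * (-1.0) ** i)
    mat = sp.csr_matrix(
        (data, (ri, ci)), shape=(len(rows), len(cols)), dtype=float
    )
    return BoundaryMatrix(mat, rows, cols, p, a_p)


def _rank(mat: sp.spmatrix) -> int:
    if min(mat.shape) == 0:
        return 0
    return int(np.linalg.matrix_rank(mat.toarray()))


def betti_numbers(K: SimplicialComplex, p_max: int | None = None) -> List[int]:
    """Betti numbers beta_0..beta_{p_max} via boundary-matrix ranks.

    beta_p = n_p - rank(B_p) - rank(B_{p+1}), with B_0 and B_{max_dim+1}
    the zero maps.
    """
    if K.max_dim < 0:
        return []
    if p_max is None:
        p_max = K.max_dim
    if p_max > K.max_dim:
        raise ValueError("p_max exceeds complex dimension")
    ranks = {0: 0}
    for p in range(1, p_max + 2):
        ranks[p] = _rank(boundary_matrix(K, p).entries) if p <= K.max_dim else 0
    return [K.n(p) - ranks[p] - ranks[p + 1] for p in range(p_max + 1)]
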