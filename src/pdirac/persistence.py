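"""Persistent boundary/Dirac operators and filtration snapshot spectra.

For a nested pair of complexes K_a inside K_b, the persistent p-chains
are those chains of K_b whose boundary lies in K_a; the persistent
boundary operator is the restriction of the boundary of K_b to that
subspace, mapped into the (p-1)-chains of K_a.  The kernel of the
persistent Dirac operator decomposes into the kernels of the persistent
Hodge Laplacians, whose dimensions are the persistent Betti numbers plus
a persistent coboundary rank term -- the quantity tracked along a
filtration.

Featurization consumes snapshot spectra (a = b at each grid value); the
general two-parameter operators are exposed for analysis and testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .complexes import Filtration, Simplex, SimplicialComplex, boundary_matrix
from .dirac_core import (
    Spectrum,
    assemble_dirac,
    assemble_weighted_dirac,
    dirac_spectrum,
    metric_matrices,
)

__all__ = [
    "NestedPair",
    "PersistentOperator",
    "PersistentNullity",
    "SnapshotSeries",
    "persistent_boundary",
    "persistent_dirac_nullity",
    "snapshot_series",
]


@dataclass
class NestedPair:
    """A nested pair of complexes K_a within K_b at scales a <= b."""

    K_a: SimplicialComplex
    K_b: SimplicialComplex
    a: float = 0.0
    b: float = 0.0

    def __post_init__(self):
        if self.a > self.b:
            raise ValueError("need a <= b")
        if not self.K_a.is_subcomplex_of(self.K_b):
            raise ValueError("K_a is not a subcomplex of K_b")

    @classmethod
    def from_filtration(cls, F: Filtration, a: float, b: float) -> "NestedPair":
        return cls(F.sublevel(a), F.sublevel(b), a, b)


@dataclass
class PersistentOperator:
    """Matrix of the persistent boundary operator B_p^{a,b}.

    ``domain_basis`` (n_p^b x m, orthonormal columns) spans the chains of
    K_b whose boundary stays inside K_a; ``matrix`` (n_{p-1}^a x m) is
    the boundary of K_b composed with that basis, with rows on the
    (p-1)-simplices of K_a in canonical order.
    """

    matrix: np.ndarray
    domain_basis: np.ndarray
    codomain_simplices: List[Simplex]
    p: int
    tol: float

    @property
    def domain_dim(self) -> int:
        """n_p^{a,b} = dim C_p^{a,b}."""
        return self.domain_basis.shape[1]


def persistent_boundary(
    pair: NestedPair, p: int, tol: float = 1e-10
) -> PersistentOperator:
    """The persistent boundary operator for a nested pair.

    The domain basis is the null space (SVD, rank tolerance ``tol``
    relative to the largest singular value) of the rows of B_p^b indexed
    by (p-1)-simplices outside K_a; composing B_p^b with it and keeping
    the K_a rows yields the operator matrix.  Its nonzero singular values
    do not depend on the orthonormal basis chosen.
    """
    if p < 1:
        raise ValueError("persistent boundary needs p >= 1")
    rows_a = pair.K_a.simplices(p - 1)
    n_p_b = pair.K_b.n(p)
    if n_p_b == 0 or p > pair.K_b.max_dim:
        return PersistentOperator(
            np.zeros((len(rows_a), 0)), np.zeros((n_p_b, 0)), rows_a, p, tol
        )
    B = boundary_matrix(pair.K_b, p).toarray()
    rows_b = pair.K_b.simplices(p - 1)
    inside = np.array([s in pair.K_a for s in rows_b], dtype=bool)
    outside_rows = B[~inside]
    if outside_rows.shape[0] == 0:
        basis = np.eye(n_p_b)
    else:
        basis = null_space(outside_rows, rcond=tol)
    # K_a's (p-1)-simplices appear in the same lexicographic order within K_b
    matrix = B[inside] @ basis
    return PersistentOperator(matrix, basis, rows_a, p, tol)


@dataclass
class PersistentNullity:
    """Nullity of the persistent Dirac operator with its decomposition.

    ``laplacian_kernels[k]`` (k = 0..p) is the kernel dimension of the
    k-th persistent Hodge Laplacian (the k-th persistent Betti number);
    ``down_kernel`` is the kernel dimension of the persistent lower
    Laplacian in dimension p+1.
    """

    laplacian_kernels: List[int]
    down_kernel: int

    @property
    def total(self) -> int:
        return sum(self.laplacian_kernels) + self.down_kernel


def _kernel_dim(M: np.ndarray, tol: float) -> int:
    n = M.shape[0]
    if n == 0:
        return 0
    return n - int(np.linalg.matrix_rank(M, tol=tol * max(1.0, np.abs(M).max())))


def persistent_dirac_nullity(
    pair: NestedPair, p: int, tol: float = 1e-8
) -> PersistentNullity:
    """Kernel dimension of the persistent Dirac operator D_p^{a,b}.

    Computed blockwise from persistent Hodge Laplacians: for k <= p the
    Laplacian on C_k^a combines the persistent up term
    B_{k+1}^{a,b} (B_{k+1}^{a,b})^T with the down term of K_a itself
    (boundaries of K_a chains always stay in K_a, so the restriction is
    the snapshot operator); its kernel dimension is the k-th persistent
    Betti number.  The final term is the kernel of the persistent lower
    Laplacian on C_{p+1}^{a,b}.  At a = b this reduces to the snapshot
    Dirac nullity.
    """
    kernels: List[int] = []
    for k in range(p + 1):
        n_k_a = pair.K_a.n(k)
        if n_k_a == 0:
            kernels.append(0)
            continue
        L = np.zeros((n_k_a, n_k_a))
        up = persistent_boundary(pair, k + 1, tol=min(tol, 1e-10))
        if up.matrix.shape[1]:
            L += up.matrix @ up.matrix.T
        if k >= 1 and k <= pair.K_a.max_dim:
            Bk = boundary_matrix(pair.K_a, k).toarray()
            L += Bk.T @ Bk
        kernels.append(_kernel_dim(L, tol))
    down_op = persistent_boundary(pair, p + 1, tol=min(tol, 1e-10))
    m = down_op.domain_dim
    if m == 0:
        down = 0
    else:
        down = _kernel_dim(down_op.matrix.T @ down_op.matrix, tol)
    return PersistentNullity(kernels, down)


@dataclass
class SnapshotSeries:
    """Dirac spectra along a filtration grid.

    ``spectra[i][p]`` is the Spectrum of D_p (or of the weighted Dirac)
    for the sublevel complex at ``grid[i]``; ``sides[i][p]`` the matrix
    side at that snapshot.
    """

    grid: np.ndarray
    p_list: Tuple[int, ...]
    spectra: List[Dict[int, Spectrum]]
    sides: List[Dict[int, int]]

    def to_frame(self) -> pd.DataFrame:
        """One row per (grid value, Dirac index) with eigenvalue summaries."""
        rows = []
        for g, by_p, side_by_p in zip(self.grid, self.spectra, self.sides):
            for p in self.p_list:
                s = by_p[p]
                rows.append(
                    {
                        "filtration": g,
                        "dirac_index": p,
                        "side": side_by_p[p],
                        "nullity": s.nullity,
                        "n_positive": int(s.positive.size),
                    }
                )
        return pd.DataFrame(rows)


def snapshot_series(
    F: Filtration,
    grid: Sequence[float],
    p_list: Sequence[int],
    weighting: Optional[Mapping[Simplex, float]] = None,
    zero_tol: float = 1e-8,
) -> SnapshotSeries:
    """Assemble and eigendecompose the Dirac matrices at each grid value.

    ``weighting`` maps every simplex of the filtration's final complex to
    a positive weight; metric matrices are rebuilt per sublevel complex
    (the coface recursion depends on which cofaces are present).  Each
    snapshot is recomputed from scratch -- complexes in this package's
    scope are small enough that correctness beats incremental updates.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size and np.any(np.diff(grid) <= 0):
        raise ValueError("grid values must be strictly increasing")
    p_list = tuple(int(p) for p in p_list)
    spectra: List[Dict[int, Spectrum]] = []
    sides: List[Dict[int, int]] = []
    for g in grid:
        K = F.sublevel(g)
        metrics = None
        if weighting is not None and len(K):
            metrics = metric_matrices(
                K, {s: weighting[s] for s in K.all_simplices()}
            )
        by_p: Dict[int, Spectrum] = {}
        side_by_p: Dict[int, int] = {}
        for p in p_list:
            if len(K) == 0:
                by_p[p] = Spectrum(np.zeros(0), zero_tol)
                side_by_p[p] = 0
                continue
            if metrics is None:
                D = assemble_dirac(K, p)
            else:
                D = assemble_weighted_dirac(K, p, metrics)
            by_p[p] = dirac_spectrum(D, zero_tol)
            side_by_p[p] = D.side
        spectra.append(by_p)
        sides.append(side_by_p)
    return SnapshotSeries(grid, p_list, spectra, sides)
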