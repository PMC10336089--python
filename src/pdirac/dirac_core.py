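"""Discrete and weighted Dirac matrices and their spectra.

The Dirac matrix D_p of a simplicial complex is the block-tridiagonal
symmetric matrix holding the boundary matrices B_1..B_{p+1} on the
super-diagonal and their transposes below; its square is block diagonal
with the Hodge Laplacians L_0..L_p and the lower Laplacian
L_{p+1}^down.  The weighted variant replaces each boundary block by its
adjoint with respect to a diagonal metric G_k built recursively from
positive simplex weights (a simplex's metric is its own weight plus the
metrics of its cofaces), with per-dimension scales a_k = (k+1)^{-1/2}.
The weighted matrix is self-adjoint in the metric inner product, hence
similar to a symmetric matrix and with a real spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.io import mmwrite

from .complexes import (
    Simplex,
    SimplicialComplex,
    betti_numbers,
    boundary_matrix,
    _rank,
)

__all__ = [
    "MetricWeights",
    "DiracMatrix",
    "Spectrum",
    "KernelDecomposition",
    "assemble_dirac",
    "metric_matrices",
    "assemble_weighted_dirac",
    "dirac_spectrum",
    "hodge_blocks",
    "supersymmetry_matrix",
    "supersymmetry_check",
    "kernel_decomposition",
    "homology_eigenvectors",
    "non_homology_eigenvectors",
    "default_scales",
]

#: Side length below which dense eigensolvers are used.
DENSE_LIMIT = 3000


def default_scales(top: int) -> Dict[int, float]:
    """The weighted-convention boundary scales a_p = (p+1)^{-1/2}."""
    return {p: (p + 1) ** -0.5 for p in range(1, top + 1)}


@dataclass
class MetricWeights:
    """Per-simplex weights and the diagonal metric matrices G_p.

    ``G[p]`` holds the diagonal of the n_p x n_p metric matrix in the
    complex's canonical simplex order.  The coface recursion
    G_p(s) = w_s + sum of G_{p+1} over cofaces of s (top dimension:
    G_d = w) ties each simplex's metric to the structure above it.
    """

    w: Dict[Simplex, float]
    G: Dict[int, np.ndarray]

    def diag(self, p: int, n: int) -> np.ndarray:
        if p in self.G:
            return self.G[p]
        return np.ones(n)


@dataclass
class DiracMatrix:
    """A Dirac matrix together with its block bookkeeping.

    ``dims[k]`` is n_k for each structural dimension present (0..p+1,
    truncated where the complex has no simplices), ``block_offsets`` the
    cumulative row/column offsets, and ``g_diag`` the concatenated metric
    diagonal for the weighted variant (None for the discrete case).
    """

    matrix: sp.csr_matrix
    p: int
    dims: List[int]
    block_offsets: List[int]
    symmetric: bool
    g_diag: Optional[np.ndarray] = None

    @property
    def side(self) -> int:
        return self.matrix.shape[0]

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()

    def block_slice(self, k: int) -> slice:
        return slice(self.block_offsets[k], self.block_offsets[k + 1])

    def split_vector(self, v: np.ndarray) -> List[np.ndarray]:
        """Split a vector on the full complex into per-dimension blocks w_k."""
        return [np.asarray(v)[self.block_slice(k)] for k in range(len(self.dims))]

    def symmetrized(self) -> np.ndarray:
        """The symmetric matrix similar to this one (S D S^-1, S = G^{1/2});
        equal to the matrix itself for the discrete case."""
        A = self.matrix.toarray()
        if self.symmetric or self.g_diag is None:
            return A
        s = np.sqrt(self.g_diag)
        return (A * s[:, None]) / s[None, :]

    def to_matrix_market(self, path) -> None:
        """Export the sparse matrix for external inspection."""
        mmwrite(path, sp.coo_matrix(self.matrix))


@dataclass
class Spectrum:
    """Sorted real eigenvalues of a Dirac matrix with a zero threshold."""

    eigenvalues: np.ndarray
    tol: float
    eigenvectors: Optional[np.ndarray] = None

    @property
    def side(self) -> int:
        return self.eigenvalues.size

    @property
    def nullity(self) -> int:
        return int(np.sum(np.abs(self.eigenvalues) <= self.tol))

    @property
    def positive(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues > self.tol]


def _structural_dims(K: SimplicialComplex, p: int) -> List[int]:
    """Block sizes n_0..n_{p+1}, dropping trailing absent dimensions."""
    top = min(p + 1, K.max_dim)
    return [K.n(k) for k in range(max(top, 0) + 1)]


def assemble_dirac(K: SimplicialComplex, p: int) -> DiracMatrix:
    """The discrete Dirac matrix D_p: boundary blocks B_1..B_{p+1} above
    the diagonal, transposes below; side = sum of n_0..n_{p+1}."""
    if p < 0:
        raise ValueError("p must be >= 0")
    dims = _structural_dims(K, p)
    nb = len(dims)
    blocks = [[None] * nb for _ in range(nb)]
    for k in range(1, nb):
        B = boundary_matrix(K, k).entries
        blocks[k - 1][k] = B
        blocks[k][k - 1] = B.T
    if nb == 1:
        mat = sp.csr_matrix((dims[0], dims[0]), dtype=float)
    else:
        mat = sp.bmat(blocks, format="csr").astype(float)
    offsets = np.concatenate([[0], np.cumsum(dims)]).tolist()
    return DiracMatrix(mat, p, dims, offsets, symmetric=True)


def metric_matrices(K: SimplicialComplex, w: Mapping[Simplex, float]) -> MetricWeights:
    """Diagonal metric matrices from positive simplex weights.

    Top dimension: G_d = w.  Below: G_p(s) = w_s plus the sum of
    G_{p+1} over the cofaces of s, computed by descending recursion.
    """
    for s in K.all_simplices():
        if s not in w:
            raise ValueError(f"missing weight for simplex {s}")
        if w[s] <= 0:
            raise ValueError(f"non-positive weight {w[s]} for simplex {s}")
    d = K.max_dim
    G: Dict[int, np.ndarray] = {}
    for p in range(d, -1, -1):
        simps = K.simplices(p)
        diag = np.array([w[s] for s in simps], dtype=float)
        if p < d:
            idx = K.index(p)
            upper = K.simplices(p + 1)
            for j, cof in enumerate(upper):
                for i in range(p + 2):
                    face = cof[:i] + cof[i + 1 :]
                    diag[idx[face]] += G[p + 1][j]
        G[p] = diag
    return MetricWeights({s: float(w[s]) for s in K.all_simplices()}, G)


def assemble_weighted_dirac(
    K: SimplicialComplex,
    p: int,
    metrics: MetricWeights,
    a: Mapping[int, float] | None = None,
) -> DiracMatrix:
    """The weighted Dirac matrix.

    Super-diagonal block k: a_k G_{k-1}^{-1} B_k G_k (the transposed
    adjoint); sub-diagonal block: a_k B_k^T (the adjoint in the metric
    inner product).  Defaults to a_k = (k+1)^{-1/2}; with identity
    metrics and a_k = 1 the result coincides entrywise with the discrete
    Dirac matrix.  The matrix is generally non-symmetric but similar to a
    symmetric one via the block square-root metric.
    """
    if p < 0:
        raise ValueError("p must be >= 0")
    dims = _structural_dims(K, p)
    nb = len(dims)
    for k in range(nb):
        g = metrics.G.get(k)
        if g is not None and g.size != dims[k]:
            raise ValueError(
                f"metric size {g.size} does not match n_{k} = {dims[k]}"
            )
    if a is None:
        a = default_scales(nb - 1)
    blocks = [[None] * nb for _ in range(nb)]
    for k in range(1, nb):
        a_k = float(a.get(k, 1.0)) if hasattr(a, "get") else float(a[k])
        B = boundary_matrix(K, k).entries
        g_lo = metrics.diag(k - 1, dims[k - 1])
        g_hi = metrics.diag(k, dims[k])
        blocks[k - 1][k] = sp.csr_matrix(
            sp.diags(a_k / g_lo) @ B @ sp.diags(g_hi)
        )
        blocks[k][k - 1] = (a_k * B).T
    if nb == 1:
        mat = sp.csr_matrix((dims[0], dims[0]), dtype=float)
    else:
        mat = sp.bmat(blocks, format="csr").astype(float)
    g_diag = np.concatenate(
        [metrics.diag(k, dims[k]) for k in range(nb)]
    ) if sum(dims) else np.zeros(0)
    offsets = np.concatenate([[0], np.cumsum(dims)]).tolist()
    asym = mat - mat.T
    symmetric = asym.nnz == 0 or float(np.max(np.abs(asym.data))) == 0.0
    return DiracMatrix(mat, p, dims, offsets, symmetric=symmetric, g_diag=g_diag)


def dirac_spectrum(
    D: DiracMatrix, tol: float = 1e-8, with_vectors: bool = False
) -> Spectrum:
    """Real sorted eigenvalues of a Dirac matrix.

    Non-symmetric weighted matrices are conjugated by the block
    square-root metric first, so the solver always sees a real symmetric
    matrix.  The zero threshold is ``tol`` relative to the spectral
    radius (at least ``tol`` in absolute terms).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    n = D.side
    if n == 0:
        return Spectrum(np.zeros(0), tol, np.zeros((0, 0)) if with_vectors else None)
    H = D.symmetrized()
    if with_vectors:
        evals, evecs = np.linalg.eigh(H)
        if not D.symmetric and D.g_diag is not None:
            evecs = evecs / np.sqrt(D.g_diag)[:, None]
    else:
        evals = np.linalg.eigvalsh(H)
        evecs = None
    thresh = tol * max(1.0, float(np.max(np.abs(evals))) if evals.size else 1.0)
    return Spectrum(evals, thresh, evecs)


def hodge_blocks(
    K: SimplicialComplex, p: int, metrics: MetricWeights | None = None
) -> List[np.ndarray]:
    """The diagonal blocks of D_p^2: [L_0, ..., L_p, L_{p+1}^down].

    Unweighted: L_k = B_k^T B_k + B_{k+1} B_{k+1}^T.  With metrics, the
    metric Hodge Laplacians
    L_[k] = B_k^T G_{k-1}^{-1} B_k G_k / (k+1)
          + G_k^{-1} B_{k+1} G_{k+1} B_{k+1}^T / (k+2)
    (the scales matching a_k = (k+1)^{-1/2}).
    """
    dims = _structural_dims(K, p)
    nb = len(dims)
    Bs: Dict[int, np.ndarray] = {
        k: boundary_matrix(K, k).toarray() for k in range(1, nb)
    }
    out: List[np.ndarray] = []
    for k in range(nb):
        L = np.zeros((dims[k], dims[k]))
        if metrics is None:
            if k >= 1:
                L += Bs[k].T @ Bs[k]
            if k + 1 < nb and k <= p:
                L += Bs[k + 1] @ Bs[k + 1].T
        else:
            g_k = metrics.diag(k, dims[k])
            if k >= 1:
                g_lo = metrics.diag(k - 1, dims[k - 1])
                L += (Bs[k].T / g_lo[None, :]) @ (Bs[k] * g_k[None, :]) / (k + 1)
            if k + 1 < nb and k <= p:
                g_hi = metrics.diag(k + 1, dims[k + 1])
                L += ((Bs[k + 1] * g_hi[None, :]) @ Bs[k + 1].T) / g_k[:, None] / (
                    k + 2
                )
        out.append(L)
    return out


def supersymmetry_matrix(D: DiracMatrix) -> np.ndarray:
    """Diagonal of Q_p: sign (-1)^k on the dimension-k block."""
    return np.concatenate(
        [((-1.0) ** k) * np.ones(nk) for k, nk in enumerate(D.dims)]
    ) if D.side else np.zeros(0)


def supersymmetry_check(D: DiracMatrix) -> Tuple[bool, float]:
    """Residual of the anticommutation D Q + Q D = 0 (max-norm)."""
    if D.side == 0:
        return True, 0.0
    q = supersymmetry_matrix(D)
    A = D.matrix
    resid = sp.csr_matrix(A.multiply(q[None, :]) + A.multiply(q[:, None]))
    r = float(np.max(np.abs(resid.toarray()))) if resid.nnz else 0.0
    return r <= 1e-12, r


@dataclass
class KernelDecomposition:
    """Both sides of the Dirac nullity identity
    dim ker D_p = rank B_{p+2}^T + sum of beta_0..beta_{p+1}."""

    betti: List[int]
    rank_next: int
    nullity: int  # from the eigenspectrum (or rank-nullity when spectral=False)

    @property
    def identity_nullity(self) -> int:
        return self.rank_next + sum(self.betti)


def kernel_decomposition(
    K: SimplicialComplex, p: int, tol: float = 1e-8, spectral: bool = True
) -> KernelDecomposition:
    """Decompose the kernel of D_p into homology and coboundary parts.

    ``betti`` holds beta_0..beta_{p+1} (boundary-rank computation),
    ``rank_next`` the rank of B_{p+2}^T, and ``nullity`` the kernel
    dimension of D_p measured from its eigenspectrum when ``spectral``
    (otherwise by rank-nullity on the assembled matrix, exact for large
    complexes where a dense eigendecomposition is wasteful).
    """
    top = min(p + 1, K.max_dim)
    betti = betti_numbers(K, top) if K.max_dim >= 0 else []
    betti += [0] * (p + 2 - len(betti))
    rank_next = (
        _rank(boundary_matrix(K, p + 2).entries) if p + 2 <= K.max_dim else 0
    )
    D = assemble_dirac(K, p)
    if spectral and D.side <= DENSE_LIMIT:
        nullity = dirac_spectrum(D, tol).nullity
    else:
        rank = _rank(D.matrix)
        nullity = D.side - rank
    return KernelDecomposition(betti, rank_next, nullity)


def homology_eigenvectors(
    D: DiracMatrix, tol: float = 1e-8
) -> List[List[np.ndarray]]:
    """Kernel eigenvectors (homology generators) split into blocks w_k.

    Returns one list of per-dimension blocks for each zero eigenvalue.
    """
    spec = dirac_spectrum(D, tol, with_vectors=True)
    out = []
    for i, lam in enumerate(spec.eigenvalues):
        if abs(lam) <= spec.tol:
            out.append(D.split_vector(spec.eigenvectors[:, i]))
    return out


def non_homology_eigenvectors(
    D: DiracMatrix, count: int, tol: float = 1e-8
) -> List[Tuple[float, List[np.ndarray]]]:
    """Eigenvectors of the ``count`` smallest positive eigenvalues, each
    split into per-dimension blocks; truncated with a warning if fewer
    positive eigenpairs exist."""
    import warnings

    spec = dirac_spectrum(D, tol, with_vectors=True)
    pos = [
        (lam, i) for i, lam in enumerate(spec.eigenvalues) if lam > spec.tol
    ]
    pos.sort()
    if count > len(pos):
        warnings.warn(
            f"requested {count} non-homology generators, only {len(pos)} available"
        )
        count = len(pos)
    return [
        (float(lam), D.split_vector(spec.eigenvectors[:, i]))
        for lam, i in pos[:count]
    ]
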