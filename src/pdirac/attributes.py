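"""Persistent attributes: spectral statistics of a Dirac matrix.

All statistics are taken over the positive eigenvalues only -- the
nonzero spectrum of a Dirac matrix is symmetric about zero, so the
negative half carries no extra information.  The twelve attributes, in
their fixed output order, are

  i    Fiedler value (smallest positive eigenvalue)
  ii   largest eigenvalue
  iii  mean of the positive eigenvalues
  iv   standard deviation of the positive eigenvalues (population form)
  v    Laplacian graph energy, zeta(-1)
  vi   signless Euler--Poincare number, the count of nonzero pairs
  vii  generalised mean graph energy, sum |lambda_i - mean| / n
  viii spectral second moment, zeta(-2)
  ix   zeta(2) = 2 sum lambda_j^{-2}
  x    quasi-Wiener index, (n + 1) zeta(1)
  xi   spanning-tree number t = (1/2) log c_1 - log(ell + 1)
  xii  persistent multiplicity (nullity, the zero-eigenvalue count)

with n the number of positive eigenvalues and natural logarithms
throughout.  An empty positive spectrum (early filtration snapshots,
where the Dirac matrix is all-zero) yields zeros for (i)-(xi) and the
matrix side for (xii).
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np

from .dirac_core import Spectrum

__all__ = [
    "ATTRIBUTE_NAMES",
    "dirac_zeta",
    "euler_poincare",
    "dirac_complexity",
    "spanning_tree_number",
    "attribute_vector",
]

#: Stable column headers for the twelve attributes, in output order.
ATTRIBUTE_NAMES: Tuple[str, ...] = (
    "fiedler",
    "max",
    "mean",
    "std",
    "energy",
    "euler_poincare",
    "gen_mean_energy",
    "moment2",
    "zeta2",
    "quasi_wiener",
    "spanning_tree",
    "multiplicity",
)


def _positive(eigenvalues: Sequence[float]) -> np.ndarray:
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size and np.any(lam <= 0):
        raise ValueError("zeta/complexity inputs must be strictly positive")
    return lam


def dirac_zeta(positive_eigenvalues: Sequence[float], s: float) -> float:
    """Dirac zeta function zeta(s) = sum lambda_j^{-s} over the positive
    spectrum; zeta(-m) is the m-th spectral moment and zeta(-1) the graph
    energy.  Empty input gives 0."""
    lam = _positive(positive_eigenvalues)
    if lam.size == 0:
        return 0.0
    return float(np.sum(lam ** (-s)))


def euler_poincare(matrix_side: int, nullity: int) -> int:
    """Signless Euler--Poincare number: ell = (side - nullity) / 2, the
    count of nonzero eigenvalue pairs."""
    if nullity > matrix_side:
        raise ValueError("nullity exceeds matrix side")
    diff = matrix_side - nullity
    if diff % 2:
        raise ValueError(
            "odd count of nonzero eigenvalues: the pairing is broken, "
            "check the zero tolerance upstream"
        )
    return diff // 2


def dirac_complexity(positive_eigenvalues: Sequence[float], q: float) -> float:
    """log of the q-Dirac complexity c_q, the product of lambda^q over all
    nonzero eigenvalues.

    Because nonzero eigenvalues come in +/- pairs, the product is taken
    in magnitude as prod (lambda_j^2)^{q/2} over the positive half, and
    the result is returned in the log domain to avoid overflow.  Empty
    input gives log c_q = 0 (c_q = 1).
    """
    lam = _positive(positive_eigenvalues)
    if lam.size == 0:
        return 0.0
    return float(q * np.sum(np.log(lam)))


def spanning_tree_number(positive_eigenvalues: Sequence[float], ell: int) -> float:
    """Spanning-tree number t = (1/2) log c_1 - log(ell + 1), natural log,
    with c_1 in the paired-magnitude convention (so (1/2) log c_1 is the
    sum of log positive eigenvalues)."""
    log_c1 = dirac_complexity(positive_eigenvalues, 2.0)
    return float(0.5 * log_c1 - np.log(ell + 1))


def attribute_vector(spectrum: Spectrum, matrix_side: int | None = None) -> np.ndarray:
    """The ordered 12-attribute vector of a Dirac spectrum.

    ``matrix_side`` defaults to the spectrum's own side; passing it
    explicitly supports all-zero matrices represented by empty spectra.
    """
    if matrix_side is None:
        matrix_side = spectrum.side
    lam = spectrum.positive
    nullity = (
        spectrum.nullity if spectrum.side else int(matrix_side)
    )
    n = lam.size
    ell = euler_poincare(int(matrix_side), nullity)
    if n == 0:
        vals = [0.0] * 11 + [float(nullity)]
        return np.array(vals)
    if n != ell:
        raise ValueError(
            f"positive-eigenvalue count {n} disagrees with pair count {ell}"
        )
    mean = float(np.mean(lam))
    out = np.array(
        [
            float(np.min(lam)),
            float(np.max(lam)),
            mean,
            float(np.std(lam)),
            dirac_zeta(lam, -1.0),
            float(ell),
            float(np.sum(np.abs(lam - mean)) / n),
            dirac_zeta(lam, -2.0),
            2.0 * dirac_zeta(lam, 2.0),
            (n + 1) * dirac_zeta(lam, 1.0),
            spanning_tree_number(lam, ell),
            float(nullity),
        ]
    )
    return out
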