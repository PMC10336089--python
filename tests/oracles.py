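"""Independent test oracles.

Everything here is deliberately separate from the library's linear
algebra: persistent homology by classic boundary-matrix column reduction
over Z/2, Hodge Laplacians built entrywise from adjacency/orientation
rules, and connected components by union-find.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Sequence, Tuple

import numpy as np

Simplex = Tuple[int, ...]


# -- persistent homology by column reduction over Z/2 ---------------------

def reduce_barcode(
    sorted_simplices: Sequence[Tuple[float, Simplex]]
) -> Dict[int, List[Tuple[float, float]]]:
    """Barcode of a filtration via the standard reduction algorithm.

    ``sorted_simplices`` is the filtration order (faces before cofaces).
    Returns per-dimension lists of (birth, death) intervals, death =
    inf for essential classes.
    """
    index = {s: i for i, (_, s) in enumerate(sorted_simplices)}
    # Z/2 boundary columns as python sets of filtration indices
    columns: List[set] = []
    for _, s in sorted_simplices:
        if len(s) == 1:
            columns.append(set())
        else:
            columns.append(
                {index[f] for f in itertools.combinations(s, len(s) - 1)}
            )
    low_to_col: Dict[int, int] = {}
    pairs: List[Tuple[int, int]] = []
    for j, col in enumerate(columns):
        while col:
            low = max(col)
            if low not in low_to_col:
                break
            col ^= columns[low_to_col[low]]
        if col:
            low_to_col[max(col)] = j
            pairs.append((max(col), j))
        columns[j] = col
    paired = {i for pair in pairs for i in pair}
    bars: Dict[int, List[Tuple[float, float]]] = {}
    for birth_i, death_i in pairs:
        dim = len(sorted_simplices[birth_i][1]) - 1
        bars.setdefault(dim, []).append(
            (sorted_simplices[birth_i][0], sorted_simplices[death_i][0])
        )
    for i, (val, s) in enumerate(sorted_simplices):
        if i not in paired:
            bars.setdefault(len(s) - 1, []).append((val, math.inf))
    return bars


def persistent_betti(
    bars: Dict[int, List[Tuple[float, float]]], k: int, a: float, b: float
) -> int:
    """Number of k-dimensional classes alive on [a, b]: born at or before
    a, dead strictly after b."""
    return sum(1 for birth, death in bars.get(k, ()) if birth <= a and death > b)


# -- entrywise Hodge Laplacian from the adjacency/orientation rules -------

def _face_sign(face: Simplex, simplex: Simplex) -> int:
    """Sign of ``face`` in the alternating boundary of ``simplex``."""
    (missing,) = set(simplex) - set(face)
    return (-1) ** simplex.index(missing)


def hodge_entrywise(K, p: int) -> np.ndarray:
    """Hodge Laplacian L_p built entry by entry.

    Diagonal: upper degree d(sigma) plus p+1 (plus nothing for p = 0);
    off-diagonal for p > 0: +/-1 when the two simplices are lower- but
    not upper-adjacent, signed by whether their shared face carries the
    same boundary sign in both; 0 when upper-adjacent.  For p = 0 the
    familiar graph Laplacian rules apply.
    """
    simps = K.simplices(p)
    n = len(simps)
    cofaces = K.simplices(p + 1) if p + 1 <= K.max_dim else []
    L = np.zeros((n, n))
    upper_sets = [set(c) for c in cofaces]
    for i, si in enumerate(simps):
        deg = sum(1 for c in upper_sets if set(si) <= c)
        L[i, i] = deg + (p + 1 if p > 0 else 0)
    for i, si in enumerate(simps):
        for j in range(i + 1, n):
            sj = simps[j]
            union = set(si) | set(sj)
            upper = len(union) == p + 2 and tuple(sorted(union)) in K
            if p == 0:
                L[i, j] = L[j, i] = -1.0 if upper else 0.0
                continue
            shared = set(si) & set(sj)
            lower = len(shared) == p and tuple(sorted(shared)) in K
            if upper or not lower:
                continue
            face = tuple(sorted(shared))
            val = 1.0 if _face_sign(face, si) == _face_sign(face, sj) else -1.0
            L[i, j] = L[j, i] = val
    return L


# -- connected components by union-find -----------------------------------

def component_count(n_vertices: int, edges: Sequence[Simplex]) -> int:
    parent = list(range(n_vertices))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    return len({find(i) for i in range(n_vertices)})
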