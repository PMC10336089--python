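"""Molecule I/O, atom subsets, weighting schemes, and feature assembly.

Turns a 3D molecular structure into a fixed-length feature vector: for
each requested atom subset a filtration (Rips or Alpha) is built from
the atomic coordinates, Dirac spectra are computed on a grid of
filtration values, and the twelve spectral attributes are concatenated
in the fixed order subset -> grid value -> Dirac index -> attribute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .attributes import ATTRIBUTE_NAMES, attribute_vector
from .complexes import (
    Filtration,
    Simplex,
    SimplicialComplex,
    alpha_filtration,
    rips_filtration,
)
from .persistence import snapshot_series

__all__ = [
    "Molecule",
    "FeaturizeConfig",
    "read_structure",
    "subset_atoms",
    "physchem_weights",
    "featurize",
    "featurize_table",
    "generate_fixture",
    "oihp_config",
    "freesolv_config",
    "charges_from_csv",
]

_HYDROGEN = {"H", "D", "T"}


@dataclass
class Molecule:
    """A molecular structure as a labelled 3D point cloud.

    coords in Angstrom, one element symbol per atom, optional per-atom
    partial charges in elementary-charge units.
    """

    coords: np.ndarray
    elements: List[str]
    charges: Optional[np.ndarray] = None
    name: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an N x 3 array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if len(self.elements) != self.coords.shape[0]:
            raise ValueError("one element symbol required per atom")
        self.elements = [str(e).strip().capitalize() for e in self.elements]
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
            if self.charges.shape != (self.coords.shape[0],):
                raise ValueError("charges must have one value per atom")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


def _read_xyz(path: Path) -> Molecule:
    # XYZ: atom count, comment line, then "element x y z" records
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}:1: expected an atom count") from exc
    elements, coords = [], []
    for ln, line in enumerate(lines[2 : 2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}:{ln}: malformed XYZ record {line!r}")
        elements.append(parts[0])
        try:
            coords.append([float(x) for x in parts[1:4]])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: bad coordinate in {line!r}") from exc
    if len(coords) != n:
        raise ValueError(f"{path}: header says {n} atoms, found {len(coords)}")
    return Molecule(np.array(coords), elements, name=path.stem)


def _read_pdb(path: Path) -> Molecule:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    elements = [str(e) for e in atoms.element]
    if any(not e for e in elements):
        raise ValueError(f"{path}: missing element column in ATOM/HETATM records")
    return Molecule(np.asarray(atoms.coord, dtype=float), elements, name=path.stem)


def _read_sdf(path: Path) -> Molecule:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    mol = next((m for m in supplier if m is not None), None)
    if mol is None:
        raise ValueError(f"{path}: no parsable molecule in SDF/MOL file")
    conf = mol.GetConformer()
    coords = np.array(
        [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
    )
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    charges = np.array([float(a.GetFormalCharge()) for a in mol.GetAtoms()])
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else path.stem
    return Molecule(coords, elements, charges=charges, name=name or path.stem)


def read_structure(path: Union[str, Path], fmt: Optional[str] = None) -> Molecule:
    """Read a molecular structure from XYZ, PDB or SDF/MOL.

    ``fmt`` defaults to the file suffix.  Coordinates are returned in
    Angstrom; SDF charge blocks populate ``charges``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    readers = {"xyz": _read_xyz, "pdb": _read_pdb, "sdf": _read_sdf, "mol": _read_sdf}
    if fmt not in readers:
        raise ValueError(f"unsupported structure format {fmt!r}")
    return readers[fmt](path)


def charges_from_csv(path: Union[str, Path]) -> np.ndarray:
    """Per-atom partial charges from a one-column (or 'charge'-column) CSV."""
    df = pd.read_csv(path)
    col = "charge" if "charge" in df.columns else df.columns[-1]
    return df[col].to_numpy(dtype=float)


def subset_atoms(mol: Molecule, scheme: str) -> Molecule:
    """Atom subset schemes: A = all atoms, B = drop hydrogens, C = drop
    hydrogens and carbons.  An empty result is an error."""
    scheme = scheme.upper()
    if scheme == "A":
        keep = np.ones(mol.n_atoms, dtype=bool)
    elif scheme == "B":
        keep = np.array([e not in _HYDROGEN for e in mol.elements])
    elif scheme == "C":
        keep = np.array(
            [e not in _HYDROGEN and e != "C" for e in mol.elements]
        )
    else:
        raise ValueError(f"unknown atom subset scheme {scheme!r}")
    if not np.any(keep):
        raise ValueError(
            f"molecule {mol.name!r} has no atoms left under subset {scheme}"
        )
    return Molecule(
        mol.coords[keep],
        [e for e, k in zip(mol.elements, keep) if k],
        charges=None if mol.charges is None else mol.charges[keep],
        name=mol.name,
    )


def _heron_area(a: float, b: float, c: float) -> float:
    s = 0.5 * (a + b + c)
    val = s * (s - a) * (s - b) * (s - c)
    return math.sqrt(max(val, 0.0))


def physchem_weights(
    mol: Molecule, K: SimplicialComplex, floor: float = 1e-6
) -> Dict[Simplex, float]:
    """Physicochemical simplex weights for the weighted Dirac scheme.

    Vertices weigh the magnitude of the atomic partial charge, edges
    their Euclidean length (A), triangles their Heron area (A^2); higher
    simplices weigh 1.  Zero charges and degenerate areas are clamped to
    ``floor`` so the metric matrices stay positive.
    """
    if mol.charges is None:
        raise ValueError(
            "vertex weights need partial charges: supply a charge column "
            "(SDF charge block or sidecar CSV) or use weighting='none'"
        )
    pts = mol.coords
    w: Dict[Simplex, float] = {}
    for s in K.all_simplices():
        d = len(s) - 1
        if d == 0:
            w[s] = max(abs(float(mol.charges[s[0]])), floor)
        elif d == 1:
            w[s] = max(float(np.linalg.norm(pts[s[0]] - pts[s[1]])), floor)
        elif d == 2:
            ab = float(np.linalg.norm(pts[s[0]] - pts[s[1]]))
            ac = float(np.linalg.norm(pts[s[0]] - pts[s[2]]))
            bc = float(np.linalg.norm(pts[s[1]] - pts[s[2]]))
            w[s] = max(_heron_area(ab, ac, bc), floor)
        else:
            w[s] = 1.0
    return w


def _grid_from_spec(grid) -> np.ndarray:
    if isinstance(grid, tuple) and len(grid) == 3:
        start, stop, step = grid
        n = int(round((stop - start) / step)) + 1
        return np.round(start + step * np.arange(n), 10)
    return np.asarray(grid, dtype=float)


@dataclass
class FeaturizeConfig:
    """Featurization configuration.

    ``complex_type`` is either a single name ('rips' or 'alpha') or a
    per-subset mapping; ``grid`` an explicit increasing list of
    filtration values in Angstrom or a (start, stop, step) triple.
    """

    complex_type: Union[str, Mapping[str, str]] = "alpha"
    grid: Union[Tuple[float, float, float], Sequence[float]] = (1.0, 6.5, 0.25)
    dirac_indices: Tuple[int, ...] = (0, 1)
    atom_subsets: Tuple[str, ...] = ("A",)
    weighting: str = "none"
    zero_tol: float = 1e-8
    rips_max_radius: Optional[float] = None

    def __post_init__(self):
        g = _grid_from_spec(self.grid)
        if g.size == 0 or np.any(g <= 0) or np.any(np.diff(g) <= 0):
            raise ValueError("grid must be positive and strictly increasing")
        self.grid = g
        if not self.atom_subsets:
            raise ValueError("need at least one atom subset")
        if self.weighting not in ("none", "physchem"):
            raise ValueError("weighting must be 'none' or 'physchem'")

    def complex_for(self, subset: str) -> str:
        if isinstance(self.complex_type, str):
            return self.complex_type
        return self.complex_type[subset]

    @property
    def feature_length(self) -> int:
        return (
            len(self.atom_subsets)
            * len(self.grid)
            * len(self.dirac_indices)
            * len(ATTRIBUTE_NAMES)
        )


def oihp_config(with_hydrogen_split: bool = False) -> FeaturizeConfig:
    """The perovskite-trajectory configuration: Alpha complex, grid 1.0
    to 6.5 A in 0.25 A steps (23 snapshots), Dirac indices 0 and 1.
    ``with_hydrogen_split`` adds the hydrogen-free subset, doubling the
    feature length (552 -> 1104)."""
    return FeaturizeConfig(
        complex_type="alpha",
        grid=(1.0, 6.5, 0.25),
        dirac_indices=(0, 1),
        atom_subsets=("A", "B") if with_hydrogen_split else ("A",),
        weighting="none",
    )


def freesolv_config(weighting: str = "none") -> FeaturizeConfig:
    """The solvation-energy configuration: subsets A (Alpha complex) and
    B, C (Rips complex), 120 grid values 0.1..12.0 A, Dirac indices 0
    and 1 -- feature length 8640."""
    return FeaturizeConfig(
        complex_type={"A": "alpha", "B": "rips", "C": "rips"},
        grid=(0.1, 12.0, 0.1),
        dirac_indices=(0, 1),
        atom_subsets=("A", "B", "C"),
        weighting=weighting,
    )


def _build_filtration(sub: Molecule, cfg: FeaturizeConfig, subset: str) -> Filtration:
    max_dim = max(cfg.dirac_indices) + 1
    kind = cfg.complex_for(subset)
    if kind == "alpha":
        return alpha_filtration(sub.coords, max_dim)
    if kind == "rips":
        radius = cfg.rips_max_radius or float(cfg.grid[-1])
        return rips_filtration(sub.coords, max_dim, radius)
    raise ValueError(f"unknown complex type {kind!r}")


def featurize(
    mol: Molecule, cfg: FeaturizeConfig
) -> Tuple[np.ndarray, List[str]]:
    """Feature vector and column labels for one molecule.

    Order: subset -> grid value -> Dirac index -> the 12 attributes.
    Length = |subsets| * |grid| * |indices| * 12.
    """
    values: List[float] = []
    labels: List[str] = []
    for subset in cfg.atom_subsets:
        try:
            sub = subset_atoms(mol, subset)
            F = _build_filtration(sub, cfg, subset)
            weighting = None
            if cfg.weighting == "physchem":
                weighting = physchem_weights(sub, F.complex)
            series = snapshot_series(
                F, cfg.grid, cfg.dirac_indices, weighting, cfg.zero_tol
            )
        except Exception as exc:
            raise RuntimeError(
                f"featurization failed for molecule {mol.name!r}, "
                f"subset {subset}: {exc}"
            ) from exc
        for gi, g in enumerate(cfg.grid):
            for p in cfg.dirac_indices:
                spec = series.spectra[gi][p]
                side = series.sides[gi][p]
                values.extend(attribute_vector(spec, side))
                labels.extend(
                    f"{subset}|f{g:g}|D{p}|{name}" for name in ATTRIBUTE_NAMES
                )
    return np.array(values), labels


def featurize_table(
    molecules: Sequence[Molecule], cfg: FeaturizeConfig
) -> pd.DataFrame:
    """Feature table for a batch of molecules: 'name' column first, then
    one labelled column per feature."""
    rows, labels = [], None
    for mol in molecules:
        vec, labels = featurize(mol, cfg)
        rows.append([mol.name, *vec])
    return pd.DataFrame(rows, columns=["name", *(labels or [])])


# -- fixture generation ---------------------------------------------------

_TOY_ELEMENTS = ["C", "C", "N", "O", "H", "H", "H", "H", "S"]


def generate_fixture(kind: str, n: int = 16, seed: int = 0) -> Molecule:
    """Deterministic synthetic structures for tests and demonstrations.

    isolated      points mutually farther apart than any filtration grid
    cycle         regular n-gon with unit edge length
    guanine_like  16 points with nearest-neighbour spacing ~1.2-1.5 A
                  and diameter below 4.7 A (a fused-ring-sized cloud)
    random_cloud  uniform points in a box scaled to the point count
    toy_molecule  a 9-atom structure with element labels and synthetic
                  partial charges
    """
    rng = np.random.default_rng(seed)
    if kind == "isolated":
        coords = np.zeros((n, 3))
        coords[:, 0] = 100.0 * np.arange(n)
        return Molecule(coords, ["C"] * n, name=f"isolated{n}")
    if kind == "cycle":
        radius = 1.0 / (2.0 * math.sin(math.pi / n))
        theta = 2.0 * math.pi * np.arange(n) / n
        coords = np.stack(
            [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n)], axis=1
        )
        return Molecule(coords, ["C"] * n, name=f"cycle{n}")
    if kind == "guanine_like":
        # 3 x 3 x 2 grid at 1.35 A spacing (diameter ~4.1 A), 16 of the
        # 18 sites kept, with a small seeded jitter
        base = [
            (i, j, k) for k in range(2) for j in range(3) for i in range(3)
        ][:16]
        coords = 1.35 * np.array(base, dtype=float)
        coords += rng.normal(scale=0.05, size=coords.shape)
        elements = ["C"] * 8 + ["N"] * 5 + ["O"] * 2 + ["H"]
        return Molecule(coords, elements, name="guanine_like")
    if kind == "random_cloud":
        side = 2.0 * n ** (1.0 / 3.0)
        coords = rng.uniform(0.0, side, size=(n, 3))
        return Molecule(coords, ["C"] * n, name=f"cloud{n}")
    if kind == "toy_molecule":
        coords = np.array(
            [
                [0.000, 0.000, 0.000],
                [1.520, 0.000, 0.000],
                [2.180, 1.210, 0.150],
                [2.150, -1.090, -0.120],
                [-0.520, 0.930, 0.250],
                [-0.420, -0.880, 0.460],
                [-0.330, -0.230, -1.010],
                [3.190, 1.190, 0.090],
                [1.560, 2.620, 0.420],
            ]
        )
        charges = np.round(rng.normal(scale=0.3, size=9), 3)
        charges[np.abs(charges) < 0.05] = 0.05
        return Molecule(coords, list(_TOY_ELEMENTS), charges=charges, name="toy")
    raise ValueError(f"unknown fixture kind {kind!r}")
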