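"""Atomistic and voxelized particle models consumed by the imaging stages.

Two kinds of objects are produced here.  "Toy proteins" are compact
self-avoiding-walk atom clouds with average protein stoichiometry
({C:5, N:1, O:1, H:8} per residue plus one S per 30 residues); they stand
in for real PDB structures in the Coulomb-explosion stage.  Voxelized
particles (solid icosahedra or spheres filled with the electron density of
a material composition) stand in for large virus-like particles in the
diffraction stage.  Real structures can be ingested from PDB files.

Internal coordinates are Cartesian nanometres; angstroms appear only at
the PDB boundary.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

from ._elements import ATOMIC_MASS, ATOMIC_NUMBER, SUPPORTED_ELEMENTS
from .xray_optics import Composition

__all__ = [
    "AtomRecord",
    "MolecularStructure",
    "VoxelDensity",
    "make_toy_protein",
    "make_icosahedral_particle",
    "read_pdb",
    "structure_to_density",
    "write_xyz",
    "write_density_h5",
    "read_density_h5",
    "MIN_INTERATOMIC_NM",
]

logger = logging.getLogger(__name__)

#: Hard lower bound on interatomic distances (prevents force singularities).
MIN_INTERATOMIC_NM = 0.05

#: Per-residue atom multiset of the toy protein.
RESIDUE_ATOMS = ("C",) * 5 + ("N", "O") + ("H",) * 8

BACKBONE_STEP_NM = 0.38


@dataclass(frozen=True)
class AtomRecord:
    """One atom: element symbol, position (nm), mass (u)."""

    element: str
    position: np.ndarray
    mass: float

    def __post_init__(self) -> None:
        if self.element not in SUPPORTED_ELEMENTS:
            raise ValueError(f"unsupported element {self.element!r}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        ref = ATOMIC_MASS[self.element]
        if not self.mass > 0 or abs(self.mass - ref) > 0.01 * ref:
            raise ValueError(
                f"mass {self.mass} inconsistent with {self.element} ({ref} u)"
            )


@dataclass
class MolecularStructure:
    """Ordered atom collection stored as arrays for vectorized physics.

    ``elements`` is an array of symbols, ``positions`` an (n, 3) array in
    nm, ``masses`` in u.  Invariants: at least one atom, all coordinates
    finite, and no two atoms closer than ``MIN_INTERATOMIC_NM``.
    """

    elements: np.ndarray
    positions: np.ndarray
    masses: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype="U2")
        self.positions = np.asarray(self.positions, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n = len(self.elements)
        if n < 1:
            raise ValueError("structure needs at least one atom")
        if self.positions.shape != (n, 3) or self.masses.shape != (n,):
            raise ValueError("inconsistent array shapes")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        unknown = set(self.elements) - set(SUPPORTED_ELEMENTS)
        if unknown:
            raise ValueError(f"unsupported elements {sorted(unknown)}")
        for el in set(self.elements.tolist()):
            ref = ATOMIC_MASS[el]
            m = self.masses[self.elements == el]
            if np.any(m <= 0) or np.any(np.abs(m - ref) > 0.01 * ref):
                raise ValueError(f"masses inconsistent with element {el}")
        if n > 1:
            d, _ = cKDTree(self.positions).query(self.positions, k=2)
            if d[:, 1].min() < MIN_INTERATOMIC_NM * (1 - 1e-9):
                raise ValueError(
                    f"atoms closer than {MIN_INTERATOMIC_NM} nm "
                    f"(min {d[:, 1].min():.4f} nm)"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBER[el] for el in self.elements])

    @property
    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(el, pos, m)
            for el, pos, m in zip(self.elements, self.positions, self.masses)
        ]

    @property
    def bounding_box(self) -> np.ndarray:
        """(2, 3) array: [min_corner, max_corner] in nm."""
        return np.vstack([self.positions.min(axis=0), self.positions.max(axis=0)])

    def radius_of_gyration(self) -> float:
        """Mass-weighted radius of gyration, nm."""
        com = np.average(self.positions, axis=0, weights=self.masses)
        r2 = np.sum((self.positions - com) ** 2, axis=1)
        return float(np.sqrt(np.average(r2, weights=self.masses)))


@dataclass
class VoxelDensity:
    """Electron counts on a regular 3D grid.

    ``grid[i, j, k]`` is the number of electrons in the voxel whose
    low corner sits at ``origin + voxel_size * (i, j, k)``.
    """

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise ValueError("grid must be 3D with >= 2 voxels per axis")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if np.any(self.grid < 0) or not np.all(np.isfinite(self.grid)):
            raise ValueError("grid values must be finite and >= 0")

    @property
    def total_electrons(self) -> float:
        return float(self.grid.sum())


# ---------------------------------------------------------------------------
# generators

def make_toy_protein(n_residues: int, seed: int) -> MolecularStructure:
    """Generate a toy protein on a self-avoiding random-walk backbone.

    Each residue contributes {C:5, N:1, O:1, H:8} placed within 0.2 nm of a
    backbone node (0.38 nm step); every 30th residue carries one extra S.
    Deterministic for a fixed seed.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)

    backbone = _self_avoiding_walk(n_residues, rng)

    positions: list[np.ndarray] = []
    elements: list[str] = []
    placed = np.empty((0, 3))
    for i, center in enumerate(backbone):
        atoms = list(RESIDUE_ATOMS)
        if (i + 1) % 30 == 0:
            atoms.append("S")
        for el in atoms:
            positions.append(_place_atom(center, placed, rng))
            placed = np.vstack([placed, positions[-1]])
            elements.append(el)
    masses = [ATOMIC_MASS[el] for el in elements]
    return MolecularStructure(
        np.array(elements), np.array(positions), np.array(masses),
        label=f"toy_protein(n={n_residues},seed={seed})",
    )


def _self_avoiding_walk(n: int, rng: np.random.Generator) -> np.ndarray:
    """Backbone nodes: fixed step, non-adjacent nodes kept >= 0.3 nm apart."""
    for _ in range(200):  # restart budget
        nodes = [np.zeros(3)]
        ok = True
        for _ in range(n - 1):
            for _ in range(200):
                step = rng.normal(size=3)
                step *= BACKBONE_STEP_NM / np.linalg.norm(step)
                cand = nodes[-1] + step
                if len(nodes) < 2 or np.min(
                    np.linalg.norm(np.array(nodes[:-1]) - cand, axis=1)
                ) >= 0.3:
                    nodes.append(cand)
                    break
            else:
                ok = False
                break
        if ok:
            return np.array(nodes)
    raise RuntimeError("self-avoiding walk failed to converge")


def _place_atom(center: np.ndarray, placed: np.ndarray, rng: np.random.Generator,
                radius: float = 0.2, min_dist: float = 0.08) -> np.ndarray:
    """Rejection-sample a point near ``center`` at >= min_dist from others."""
    tree = cKDTree(placed) if len(placed) else None
    for attempt in range(4000):
        # uniform in a ball, radius grows slowly if crowded
        r = radius * (1.0 + attempt / 2000.0)
        offset = rng.normal(size=3)
        offset *= r * rng.uniform() ** (1 / 3) / np.linalg.norm(offset)
        cand = center + offset
        if tree is None or tree.query(cand)[0] >= min_dist:
            return cand
    raise RuntimeError("atom placement failed (residue too crowded)")


def make_icosahedral_particle(
    diameter: float,
    composition: Composition,
    voxel_size: float,
    shape: str = "icosahedron",
) -> VoxelDensity:
    """Voxelize a solid particle filled with a composition's electron density.

    ``diameter`` is the circumscribed diameter (nm).  The interior is
    uniform at the electron density implied by the composition's mass
    density; surface voxels are weighted by the fraction of the voxel
    inside the solid (3x3x3 subsampling).  ``shape='sphere'`` gives the
    degenerate spherical limit used by the form-factor oracle.
    """
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    if voxel_size > diameter / 10.0:
        raise ValueError(
            f"voxel_size {voxel_size} too coarse; must be <= diameter/10 = {diameter / 10:.3g}"
        )
    if shape not in ("icosahedron", "sphere"):
        raise ValueError(f"unknown shape {shape!r}")

    radius = diameter / 2.0
    n = int(math.ceil(diameter / voxel_size)) + 2
    # voxel centers, particle centered in the grid
    axis = (np.arange(n) - (n - 1) / 2.0) * voxel_size
    sub = (np.arange(3) - 1.0) / 3.0 * voxel_size  # subsample offsets

    if shape == "sphere":
        def inside(pts):
            return np.einsum("...i,...i", pts, pts) <= radius**2
    else:
        hull = ConvexHull(_icosahedron_vertices() * radius)
        A, b = hull.equations[:, :3], hull.equations[:, 3]

        def inside(pts):
            return np.all(pts @ A.T + b <= 1e-12, axis=-1)

    frac = np.zeros((n, n, n))
    X, Y = np.meshgrid(axis, axis, indexing="ij")
    for dz in sub:
        for dy in sub:
            for dx in sub:
                for k, z in enumerate(axis):
                    pts = np.stack(
                        [X + dx, Y + dy, np.full_like(X, z + dz)], axis=-1
                    )
                    frac[:, :, k] += inside(pts)
    frac /= len(sub) ** 3

    electrons = composition.electron_density_nm3() * voxel_size**3 * frac
    origin = np.full(3, axis[0] - voxel_size / 2.0)
    return VoxelDensity(electrons, voxel_size, origin)


def _icosahedron_vertices() -> np.ndarray:
    """Unit-circumradius regular icosahedron vertices."""
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    v = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            v += [(0, a, b), (a, b, 0), (b, 0, a)]
    v = np.array(v)
    return v / np.linalg.norm(v[0])


# ---------------------------------------------------------------------------
# PDB ingestion (biotite-backed)

def read_pdb(path, keep_waters: bool = False, keep_hydrogens: bool = True) -> MolecularStructure:
    """Read ATOM/HETATM records from a PDB file into a MolecularStructure.

    Fixed-width columns per the PDB standard; the element symbol comes from
    columns 77-78 with fallback to the atom-name field.  For alternate
    locations the highest-occupancy conformer is kept.  Waters are dropped
    unless ``keep_waters``.  Atoms with elements outside the supported set
    are skipped with a logged warning.  Coordinates are converted A -> nm.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    try:
        array = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # no parsable atoms
        raise ValueError(f"no parsable ATOM/HETATM records in {path}: {exc}") from exc
    if array.array_length() == 0:
        raise ValueError(f"no parsable ATOM/HETATM records in {path}")

    if not keep_waters:
        array = array[~struc.filter_solvent(array)]
    if not keep_hydrogens:
        array = array[array.element != "H"]

    elements, positions, masses = [], [], []
    skipped: dict[str, int] = {}
    for el, coord in zip(array.element, array.coord):
        symbol = el.capitalize()
        if symbol not in SUPPORTED_ELEMENTS:
            skipped[symbol] = skipped.get(symbol, 0) + 1
            continue
        elements.append(symbol)
        positions.append(coord * 0.1)
        masses.append(ATOMIC_MASS[symbol])
    for symbol, count in skipped.items():
        msg = f"skipped {count} atom(s) with unsupported element {symbol!r}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    if not elements:
        raise ValueError(f"no atoms with supported elements in {path}")
    return MolecularStructure(
        np.array(elements), np.array(positions), np.array(masses), label=str(path)
    )


# ---------------------------------------------------------------------------
# conversions and I/O

def structure_to_density(structure: MolecularStructure, voxel_size: float) -> VoxelDensity:
    """Deposit each atom's electron count (atomic number) into its voxel.

    Total electrons are conserved exactly (integer sum of atomic numbers).
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be > 0")
    lo = structure.positions.min(axis=0) - 0.5 * voxel_size
    idx = np.floor((structure.positions - lo) / voxel_size).astype(int)
    shape = np.maximum(idx.max(axis=0) + 2, 2)
    grid = np.zeros(shape)
    np.add.at(grid, tuple(idx.T), structure.atomic_numbers.astype(float))
    return VoxelDensity(grid, voxel_size, lo)


def write_xyz(structure: MolecularStructure, path) -> None:
    """Write an XYZ file (coordinates in angstrom, per convention)."""
    with open(path, "w") as fh:
        fh.write(f"{structure.n_atoms}\n{structure.label}\n")
        for el, pos in zip(structure.elements, structure.positions):
            x, y, z = pos * 10.0
            fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def write_density_h5(density: VoxelDensity, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("density", data=density.grid)
        ds.attrs["voxel_size_nm"] = density.voxel_size
        ds.attrs["origin_nm"] = density.origin


def read_density_h5(path) -> VoxelDensity:
    import h5py

    with h5py.File(path, "r") as fh:
        ds = fh["density"]
        return VoxelDensity(ds[...], float(ds.attrs["voxel_size_nm"]), ds.attrs["origin_nm"][...])
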