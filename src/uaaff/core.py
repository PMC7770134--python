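"""Domain types and geometry primitives for dipeptide parametrization.

Molecules are plain ordered atom lists; conformers annotate the backbone
torsion state (alpha-helical, beta-strand, or other).  All Cartesian
coordinates are in Angstrom; electrostatic-potential work converts to
atomic units at the boundary (see :mod:`uaaff.resp`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "ANGSTROM_PER_BOHR",
    "VDW_RADII",
    "AtomRecord",
    "Conformer",
    "ForceFieldParameters",
    "ChargeSet",
    "DegenerateGeometryError",
    "measure_dihedral",
    "dihedral_from_coords",
    "superpose",
    "rmsd_after_superposition",
    "vdw_radius",
]

#: fixed Angstrom <-> Bohr conversion used everywhere in the package
ANGSTROM_PER_BOHR = 0.52917721

KNOWN_ELEMENTS = {
    "H", "C", "N", "O", "F", "Cl", "Br", "I", "S", "P",
    "Na", "K", "Mg", "Ca", "Zn", "Fe",
}

#: Bondi van der Waals radii (Angstrom), except iodine which uses the
#: Pauling radius 2.15 A — the standard choice when the Bondi table is
#: paired with heavy-halogen amino-acid analogs.  Configurable per call.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 2.15,
    "S": 1.80,
    "P": 1.80,
    "Na": 2.27,
    "K": 2.75,
}


class DegenerateGeometryError(ValueError):
    """Raised when a torsion or angle is undefined (collinear atoms)."""


def vdw_radius(element: str, table: dict[str, float] | None = None) -> float:
    """Van der Waals radius in Angstrom for *element*.

    Uses :data:`VDW_RADII` (Bondi, with the Pauling value for iodine)
    unless an explicit *table* overrides it.
    """
    tab = VDW_RADII if table is None else table
    try:
        return tab[element]
    except KeyError:
        raise KeyError(f"no van der Waals radius for element {element!r}")


@dataclass(frozen=True)
class AtomRecord:
    """One atom: ordinal index, naming metadata and Cartesian coordinates."""

    index: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    coords: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.element not in KNOWN_ELEMENTS:
            raise ValueError(f"unrecognized element {self.element!r}")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Conformer:
    """An ordered molecule with a backbone-state label.

    ``label`` is ``"alpha"`` for the helical backbone near
    (phi, psi) = (-60, -40) degrees, ``"beta"`` for the extended strand
    near (+-180, +-180), and ``"other"`` otherwise.
    """

    atoms: list[AtomRecord]
    label: str = "other"
    phi: float | None = None
    psi: float | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a conformer needs at least one atom")
        if self.label not in ("alpha", "beta", "other"):
            raise ValueError(f"unknown backbone label {self.label!r}")
        indices = [a.index for a in self.atoms]
        if len(set(indices)) != len(indices):
            raise ValueError("atom indices must be unique")
        for ang in (self.phi, self.psi):
            if ang is not None and not (-180.0 < ang <= 180.0 + 1e-9):
                raise ValueError(f"torsion {ang} outside (-180, 180]")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) float array of Cartesian coordinates, Angstrom."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def with_coordinates(self, coords: np.ndarray) -> "Conformer":
        """Copy of this conformer with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coords=tuple(c)) for a, c in zip(self.atoms, coords)]
        return Conformer(atoms=atoms, label=self.label, phi=self.phi, psi=self.psi)


@dataclass
class ForceFieldParameters:
    """Amber-form bonded and Lennard-Jones parameters plus exclusions.

    bonds:     (i, j, K_r, r_eq)            kcal/(mol A^2), A
    angles:    (i, j, k, K_theta, theta_eq) kcal/(mol rad^2), degrees
    dihedrals: (i, j, k, l, V_n, n, gamma)  kcal/mol, periodicity, degrees
    lj:        per-atom (r_min/2, epsilon)  A, kcal/mol
    exclusions: 1-2 and 1-3 pairs (frozenset of frozenset pairs)
    pairs14:   1-4 pairs, computed with scaled interactions
    """

    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    angles: list[tuple[int, int, int, float, float]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int, float, int, float]] = field(
        default_factory=list
    )
    lj: list[tuple[float, float]] = field(default_factory=list)
    exclusions: set[tuple[int, int]] = field(default_factory=set)
    pairs14: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for i, j, kr, _req in self.bonds:
            if kr < 0:
                raise ValueError("bond force constants must be >= 0")
        for *_ijk, kth, _th in self.angles:
            if kth < 0:
                raise ValueError("angle force constants must be >= 0")
        for *_ijkl, _v, n, _g in self.dihedrals:
            if n < 1:
                raise ValueError("dihedral periodicity must be >= 1")
        for _rm, eps in self.lj:
            if eps < 0:
                raise ValueError("LJ epsilon must be >= 0")
        self.exclusions = {_canon(p) for p in self.exclusions}
        self.pairs14 = {_canon(p) for p in self.pairs14}
        if self.exclusions & self.pairs14:
            raise ValueError("exclusion and 1-4 lists must be disjoint")


def _canon(pair) -> tuple[int, int]:
    i, j = pair
    if i == j:
        raise ValueError("self-pair in exclusion/1-4 list")
    return (i, j) if i < j else (j, i)


CHARGE_GROUPS = ("ACE", "NME", "BACKBONE", "SIDECHAIN")


@dataclass
class ChargeSet:
    """Per-atom partial charges (e) with net charge and group tags."""

    charges: np.ndarray
    net_charge: int
    group_of_atom: list[str] | None = None

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)
        if self.charges.ndim != 1:
            raise ValueError("charges must be a flat array")
        if abs(self.charges.sum() - self.net_charge) > 1e-6:
            raise ValueError(
                f"charges sum to {self.charges.sum():.8f}, "
                f"declared net charge is {self.net_charge}"
            )
        if self.group_of_atom is not None:
            if len(self.group_of_atom) != len(self.charges):
                raise ValueError("group tags must match charge count")
            bad = set(self.group_of_atom) - set(CHARGE_GROUPS)
            if bad:
                raise ValueError(f"unknown charge groups: {bad}")

    def __len__(self) -> int:
        return len(self.charges)

    def atoms_in_group(self, group: str) -> np.ndarray:
        if self.group_of_atom is None:
            return np.array([], dtype=int)
        return np.array(
            [i for i, g in enumerate(self.group_of_atom) if g == group], dtype=int
        )


# ---------------------------------------------------------------------------
# geometry


def dihedral_from_coords(p0, p1, p2, p3) -> float:
    """Signed torsion angle (degrees, in (-180, 180]) of four points.

    IUPAC convention: looking down the p1->p2 axis, a clockwise rotation
    of the far bond relative to the near bond is positive.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1n = np.linalg.norm(n1)
    n2n = np.linalg.norm(n2)
    b2n = np.linalg.norm(b2)
    if n1n < 1e-10 * max(1.0, b2n) or n2n < 1e-10 * max(1.0, b2n) or b2n < 1e-10:
        raise DegenerateGeometryError("collinear atoms: torsion undefined")
    # atan2 form is numerically stable near 0 and 180
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / b2n)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def measure_dihedral(conformer: Conformer, i: int, j: int, k: int, l: int) -> float:
    """Torsion angle i-j-k-l of *conformer* in degrees, range (-180, 180]."""
    idx = (i, j, k, l)
    if len(set(idx)) != 4:
        raise ValueError("the four atom indices must be distinct")
    n = conformer.n_atoms
    if any(not (0 <= t < n) for t in idx):
        raise IndexError("atom index out of range")
    coords = conformer.coordinates()
    return dihedral_from_coords(*(coords[t] for t in idx))


def _selection_mask(conformer: Conformer, selection: str) -> np.ndarray:
    if selection == "all":
        return np.ones(conformer.n_atoms, dtype=bool)
    if selection == "heavy":
        return conformer.heavy_mask()
    raise ValueError(f"selection must be 'heavy' or 'all', got {selection!r}")


def superpose(
    mobile: Conformer,
    reference: Conformer,
    selection: str = "heavy",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of *mobile* onto *reference* (Kabsch).

    Atoms are paired by position in the atom list over the chosen
    ``selection`` (``"heavy"`` or ``"all"``); the RMSD is measured on the
    same selection used for the fit.

    Returns
    -------
    rotation : (3, 3) proper rotation matrix (det = +1)
    translation : (3,) vector; ``x @ R.T + t`` maps mobile onto reference
    rmsd : float, Angstrom
    """
    mask_m = _selection_mask(mobile, selection)
    mask_r = _selection_mask(reference, selection)
    xm = mobile.coordinates()[mask_m]
    xr = reference.coordinates()[mask_r]
    if xm.shape != xr.shape:
        raise ValueError("selections have mismatched atom counts")
    if xm.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    cm = xm.mean(axis=0)
    cr = xr.mean(axis=0)
    rot, _ = Rotation.align_vectors(xr - cr, xm - cm)
    rmat = rot.as_matrix()
    trans = cr - cm @ rmat.T
    # recompute the residual directly: scipy's rssd loses precision near 0
    diff = xm @ rmat.T + trans - xr
    rmsd = float(np.sqrt((diff * diff).sum() / xm.shape[0]))
    return rmat, trans, rmsd


def rmsd_after_superposition(
    mobile: Conformer, reference: Conformer, selection: str = "heavy"
) -> float:
    """Least-squares RMSD (Angstrom) after optimal rigid superposition."""
    return superpose(mobile, reference, selection)[2]
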