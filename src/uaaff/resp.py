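"""Electrostatic-potential grids and restrained charge fitting.

Implements the classic two-stage restrained ESP (RESP) protocol: atomic
point charges are fitted to reproduce a molecular electrostatic potential
sampled on shells outside the van der Waals surface, under a hyperbolic
restraint that shrinks statistically ill-determined charges, with exact
net-charge, equivalence and frozen-charge constraints.

All quantities in this module are in atomic units (Bohr, hartree/e);
conversion from Angstrom happens at the call boundary via
:data:`uaaff.core.ANGSTROM_PER_BOHR`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ANGSTROM_PER_BOHR, ChargeSet, Conformer, vdw_radius

__all__ = [
    "EspGrid",
    "RespOptions",
    "RespFitResult",
    "esp_from_point_charges",
    "build_mk_grid",
    "fit_charges",
    "fit_charges_two_stage",
]


@dataclass
class EspGrid:
    """Off-surface sample points (Bohr) with target potentials (hartree/e)."""

    points: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.points) != len(self.values):
            raise ValueError("points and values must have equal length")

    @property
    def n_points(self) -> int:
        return len(self.values)


@dataclass
class RespOptions:
    """Hyperparameters and constraints for a restrained ESP fit.

    The restraint strengths are the canonical two-stage values:
    ``a = 0.0005`` hartree in stage 1 (all charges free), ``a = 0.001``
    in stage 2 (only declared refit sets free), hyperbolic width
    ``b = 0.1`` e, hydrogens unrestrained.
    """

    restraint_a_stage1: float = 0.0005
    restraint_a_stage2: float = 0.001
    restraint_b: float = 0.1
    restrain_hydrogens: bool = False
    equivalence_classes: list[list[int]] = field(default_factory=list)
    frozen_atoms: dict[int, float] = field(default_factory=dict)
    net_charge: int = 0
    max_iter: int = 200
    tolerance: float = 1e-10

    def __post_init__(self) -> None:
        if self.restraint_a_stage1 < 0 or self.restraint_a_stage2 < 0:
            raise ValueError("restraint strength a must be >= 0")
        if self.restraint_b <= 0:
            raise ValueError("restraint width b must be > 0")
        seen: set[int] = set()
        for cls in self.equivalence_classes:
            s = set(cls)
            if s & seen:
                raise ValueError("equivalence classes must be disjoint")
            seen |= s
        if seen & set(self.frozen_atoms):
            raise ValueError("frozen atoms may not appear in equivalence classes")


@dataclass
class RespFitResult:
    charge_set: ChargeSet
    rrms: float
    n_iterations: int
    converged: bool


def esp_from_point_charges(
    charges: np.ndarray, atom_coords: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Coulomb potential of point charges, atomic units.

    ``V(r_k) = sum_j q_j / |r_k - r_j|`` with coordinates in Bohr; the
    result is in hartree per unit charge and is exactly linear in the
    charges.
    """
    charges = np.asarray(charges, dtype=float).ravel()
    atom_coords = np.asarray(atom_coords, dtype=float).reshape(-1, 3)
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    d = np.linalg.norm(points[:, None, :] - atom_coords[None, :, :], axis=2)
    if d.size and d.min() < 1e-6:
        raise ValueError("grid point coincides with an atom position")
    return (charges[None, :] / d).sum(axis=1)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def build_mk_grid(
    molecule: Conformer,
    shells: tuple[float, ...] = (1.4, 1.6, 1.8, 2.0),
    density: float = 1.0,
    seed: int = 0,
    radii_table: dict[str, float] | None = None,
) -> EspGrid:
    """Merz–Kollman-style shell grid around a molecule.

    Candidate points are placed on spheres of radius ``scale * r_vdw``
    around every atom for each scale factor in *shells* (about *density*
    points per square Angstrom, randomly rotated per atom/shell with the
    given *seed*), then culled if they fall inside any atom's scaled
    sphere.  Returned points are in Bohr with zero-filled values.
    """
    if molecule.n_atoms < 1:
        raise ValueError("empty molecule")
    rng = np.random.default_rng(seed)
    coords = molecule.coordinates()
    radii = np.array([vdw_radius(e, radii_table) for e in molecule.elements()])
    kept: list[np.ndarray] = []
    for scale in shells:
        scaled = radii * scale
        for a in range(molecule.n_atoms):
            r = scaled[a]
            n_pts = max(8, int(round(density * 4.0 * np.pi * r * r)))
            pts = _fibonacci_sphere(n_pts)
            # random proper rotation decorrelates the deterministic spiral
            # between atoms and shells
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            rot = np.array(
                [
                    [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                    [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                    [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
                ]
            )
            cand = coords[a] + r * (pts @ rot.T)
            d = np.linalg.norm(cand[:, None, :] - coords[None, :, :], axis=2)
            outside = (d >= scaled[None, :] - 1e-9).all(axis=1)
            if outside.any():
                kept.append(cand[outside])
    if not kept:
        raise ValueError("no grid points survived culling")
    points_bohr = np.vstack(kept) / ANGSTROM_PER_BOHR
    return EspGrid(points=points_bohr, values=np.zeros(len(points_bohr)))


def _reduction(
    n_atoms: int, options: RespOptions
) -> tuple[np.ndarray, np.ndarray]:
    """Map free parameters to charges: q = M p + f.

    Equivalence classes share one parameter; frozen atoms contribute only
    to the offset f.
    """
    class_of = {}
    for c, cls in enumerate(options.equivalence_classes):
        for a in cls:
            class_of[a] = c
    col_of_class: dict[int, int] = {}
    cols: list[int | None] = []
    n_free = 0
    for a in range(n_atoms):
        if a in options.frozen_atoms:
            cols.append(None)
        elif a in class_of:
            c = class_of[a]
            if c not in col_of_class:
                col_of_class[c] = n_free
                n_free += 1
            cols.append(col_of_class[c])
        else:
            cols.append(n_free)
            n_free += 1
    M = np.zeros((n_atoms, n_free))
    f = np.zeros(n_atoms)
    for a, col in enumerate(cols):
        if col is None:
            f[a] = options.frozen_atoms[a]
        else:
            M[a, col] = 1.0
    return M, f


def fit_charges(
    grid: EspGrid,
    atom_coords: np.ndarray,
    options: RespOptions,
    elements: list[str] | None = None,
    restraint_a: float | None = None,
) -> RespFitResult:
    """Restrained least-squares charge fit to an ESP grid.

    Minimizes ``sum_k (V_k - sum_j q_j/|r_k - r_j|)^2
    + a * sum_restrained (sqrt(q_j^2 + b^2) - b)`` subject to the exact
    net-charge constraint, equality within equivalence classes and frozen
    values, by iteratively reweighted linear solves (the hyperbolic
    restraint is linearized around the current charges).  With ``a = 0``
    this is the exact constrained ordinary-least-squares solution.

    Parameters
    ----------
    grid : EspGrid, target potentials (atomic units)
    atom_coords : (n_atoms, 3) in Bohr
    options : RespOptions
    elements : needed only when ``restrain_hydrogens`` is False, to know
        which atoms are hydrogens
    restraint_a : override for the restraint strength (defaults to
        ``options.restraint_a_stage1``)
    """
    atom_coords = np.asarray(atom_coords, dtype=float).reshape(-1, 3)
    n_atoms = len(atom_coords)
    a_str = options.restraint_a_stage1 if restraint_a is None else restraint_a
    M, f = _reduction(n_atoms, options)
    n_free = M.shape[1]
    if n_free == 0:
        q = f.copy()
        model = esp_from_point_charges(q, atom_coords, grid.points)
        rrms = _rrms(model, grid.values)
        return RespFitResult(
            ChargeSet(q, options.net_charge), rrms, 0, True
        )
    if grid.n_points < n_free:
        raise ValueError(
            f"{grid.n_points} grid points cannot determine {n_free} free charges"
        )
    d = np.linalg.norm(
        grid.points[:, None, :] - atom_coords[None, :, :], axis=2
    )
    if d.min() < 1e-6:
        raise ValueError("grid point coincides with an atom position")
    A = 1.0 / d  # (n_points, n_atoms)

    restrained = np.ones(n_atoms, dtype=bool)
    if not options.restrain_hydrogens:
        if elements is None:
            raise ValueError(
                "elements required to exempt hydrogens from the restraint"
            )
        restrained = np.array([e != "H" for e in elements], dtype=bool)
    restrained &= np.array(
        [a not in options.frozen_atoms for a in range(n_atoms)], dtype=bool
    )

    AtA = A.T @ A
    AtV = A.T @ grid.values
    ones = np.ones(n_atoms)
    cM = ones @ M  # net-charge constraint row in p-space
    target = options.net_charge - f.sum()

    b2 = options.restraint_b**2
    q = M @ np.full(n_free, target / max(cM.sum(), 1.0)) + f
    n_it = 0
    converged = a_str == 0.0
    for n_it in range(1, options.max_iter + 1):
        D = np.zeros(n_atoms)
        if a_str > 0:
            D[restrained] = a_str / np.sqrt(q[restrained] ** 2 + b2)
        H = M.T @ (AtA + np.diag(D)) @ M
        rhs = M.T @ (AtV - (AtA + np.diag(D)) @ f)
        kkt = np.zeros((n_free + 1, n_free + 1))
        kkt[:n_free, :n_free] = H
        kkt[:n_free, n_free] = cM
        kkt[n_free, :n_free] = cM
        vec = np.concatenate([rhs, [target]])
        try:
            sol = np.linalg.solve(kkt, vec)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular constrained RESP system"
            ) from exc
        q_new = M @ sol[:n_free] + f
        delta = np.abs(q_new - q).max()
        q = q_new
        if a_str == 0.0 or delta < options.tolerance:
            converged = True
            break
    model = A @ q
    rrms = _rrms(model, grid.values)
    return RespFitResult(
        ChargeSet(q, options.net_charge), rrms, n_it, converged
    )


def _rrms(model: np.ndarray, target: np.ndarray) -> float:
    denom = float(np.sum(target**2))
    if denom == 0.0:
        return float(np.sqrt(np.mean(model**2)))
    return float(np.sqrt(np.sum((model - target) ** 2) / denom))


def fit_charges_two_stage(
    grid: EspGrid,
    atom_coords: np.ndarray,
    options: RespOptions,
    elements: list[str],
    stage2_refit_atoms: list[int],
    stage2_equivalences: list[list[int]] | None = None,
) -> RespFitResult:
    """Canonical two-stage RESP.

    Stage 1 fits all non-frozen charges with the weak restraint and the
    stage-1 equivalence classes (no methyl/methylene equivalencing).
    Stage 2 freezes everything except *stage2_refit_atoms*, applies
    *stage2_equivalences* (typically the methyl hydrogens) and refits
    under the stronger restraint.
    """
    stage1 = fit_charges(
        grid, atom_coords, options, elements,
        restraint_a=options.restraint_a_stage1,
    )
    q1 = stage1.charge_set.charges
    refit = set(stage2_refit_atoms)
    frozen = {
        a: (options.frozen_atoms.get(a, float(q1[a])))
        for a in range(len(q1))
        if a not in refit
    }
    opts2 = RespOptions(
        restraint_a_stage1=options.restraint_a_stage2,
        restraint_a_stage2=options.restraint_a_stage2,
        restraint_b=options.restraint_b,
        restrain_hydrogens=options.restrain_hydrogens,
        equivalence_classes=stage2_equivalences or [],
        frozen_atoms=frozen,
        net_charge=options.net_charge,
        max_iter=options.max_iter,
        tolerance=options.tolerance,
    )
    return fit_charges(
        grid, atom_coords, opts2, elements,
        restraint_a=options.restraint_a_stage2,
    )
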