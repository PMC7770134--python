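"""Amber-functional-form potential energy and restrained minimization.

The total energy is the classic five-term sum

    E_total = E_bond + E_angle + E_dihedral + E_es + E_vdW

with harmonic bonds/angles ``K (x - x_eq)^2``, cosine dihedrals
``(V_n/2)(1 + cos(n phi - gamma))``, Coulomb electrostatics with the
Amber constant ``k_e = 332.0637`` kcal A / (mol e^2) and Lennard-Jones
``eps [(r_min/r)^12 - 2 (r_min/r)^6]`` with Lorentz–Berthelot combining.
1-2 and 1-3 pairs are excluded; 1-4 pairs are scaled by 1/1.2
(electrostatics) and 1/2.0 (van der Waals), the ff14SB convention.
Gas phase, no cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .core import ChargeSet, Conformer, ForceFieldParameters, dihedral_from_coords

__all__ = [
    "COULOMB_CONSTANT",
    "SCEE",
    "SCNB",
    "EnergyBreakdown",
    "ConformerPair",
    "TorsionRestraint",
    "energy",
    "energy_and_gradient",
    "minimize",
    "relative_energy",
]

#: Amber electrostatic constant, kcal A / (mol e^2)
COULOMB_CONSTANT = 332.0637
#: 1-4 electrostatic scale divisor (ff14SB)
SCEE = 1.2
#: 1-4 van der Waals scale divisor (ff14SB)
SCNB = 2.0


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term energies, kcal/mol; ``e_total`` is their exact sum."""

    e_bond: float
    e_angle: float
    e_dihedral: float
    e_es: float
    e_vdw: float

    @property
    def e_total(self) -> float:
        return self.e_bond + self.e_angle + self.e_dihedral + self.e_es + self.e_vdw


@dataclass
class TorsionRestraint:
    """Harmonic torsion restraint ``k * wrap(phi - target)^2``.

    ``atoms`` are the four torsion indices, ``target`` in degrees,
    ``k`` in kcal/(mol rad^2).  The deviation is wrapped into
    (-180, 180] before squaring, so the restraint is periodic.
    """

    atoms: tuple[int, int, int, int]
    target: float
    k: float = 100.0


@dataclass
class ConformerPair:
    """An alpha/beta conformer pair with its QM benchmark relative energy."""

    system_id: int
    alpha: Conformer
    beta: Conformer
    re_qm: float | None = None
    re_model: float | None = None

    def __post_init__(self) -> None:
        if self.alpha.n_atoms != self.beta.n_atoms:
            raise ValueError("alpha and beta conformers must share atom ordering")


def _pair_lists(n_atoms: int, params: ForceFieldParameters):
    """Nonbonded pair index arrays: (full pairs, 1-4 pairs)."""
    excl = params.exclusions | params.pairs14
    full = [
        (i, j)
        for i in range(n_atoms)
        for j in range(i + 1, n_atoms)
        if (i, j) not in excl
    ]
    p14 = sorted(params.pairs14)
    return full, p14


def _nonbonded(coords, charges, params, pairs, scale_ee, scale_nb, grad):
    e_es = 0.0
    e_vdw = 0.0
    g = np.zeros_like(coords) if grad else None
    for i, j in pairs:
        rij = coords[i] - coords[j]
        r = float(np.linalg.norm(rij))
        if r < 1e-6:
            raise ValueError(f"overlapping atoms {i} and {j} (r = {r:.2e} A)")
        qq = COULOMB_CONSTANT * charges[i] * charges[j] / scale_ee
        e_es += qq / r
        rmin_i, eps_i = params.lj[i]
        rmin_j, eps_j = params.lj[j]
        eps = math.sqrt(eps_i * eps_j) / scale_nb
        rmin = rmin_i + rmin_j  # r_min/2 values sum to pair r_min
        if eps > 0.0:
            s6 = (rmin / r) ** 6
            e_vdw += eps * (s6 * s6 - 2.0 * s6)
            if grad:
                de_dr = eps * (-12.0 * s6 * s6 + 12.0 * s6) / r
                gv = (de_dr - qq / (r * r)) / r * rij
                g[i] += gv
                g[j] -= gv
        elif grad:
            gv = -qq / (r * r) / r * rij
            g[i] += gv
            g[j] -= gv
    return e_es, e_vdw, g


def _bonded_terms(coords, params, grad):
    g = np.zeros_like(coords) if grad else None
    e_bond = 0.0
    for i, j, kr, req in params.bonds:
        rij = coords[i] - coords[j]
        r = float(np.linalg.norm(rij))
        d = r - req
        e_bond += kr * d * d
        if grad and r > 1e-12:
            gv = 2.0 * kr * d / r * rij
            g[i] += gv
            g[j] -= gv
    e_angle = 0.0
    for i, j, k, kth, theq in params.angles:
        u = coords[i] - coords[j]
        v = coords[k] - coords[j]
        nu = float(np.linalg.norm(u))
        nv = float(np.linalg.norm(v))
        c = float(np.dot(u, v) / (nu * nv))
        c = max(-1.0, min(1.0, c))
        th = math.acos(c)
        d = th - math.radians(theq)
        e_angle += kth * d * d
        if grad:
            s = math.sqrt(max(1e-14, 1.0 - c * c))
            dth_di = -(v / (nu * nv) - c * u / (nu * nu)) / s
            dth_dk = -(u / (nu * nv) - c * v / (nv * nv)) / s
            coef = 2.0 * kth * d
            g[i] += coef * dth_di
            g[k] += coef * dth_dk
            g[j] -= coef * (dth_di + dth_dk)
    e_dih = 0.0
    for i, j, k, l, vn, n, gamma in params.dihedrals:
        phi = math.radians(dihedral_from_coords(coords[i], coords[j], coords[k], coords[l]))
        arg = n * phi - math.radians(gamma)
        e_dih += 0.5 * vn * (1.0 + math.cos(arg))
        if grad:
            dE_dphi = -0.5 * vn * n * math.sin(arg)
            _add_torsion_grad(g, coords, (i, j, k, l), dE_dphi)
    return e_bond, e_angle, e_dih, g


def _add_torsion_grad(g, coords, idx, dE_dphi):
    """Accumulate dE/dx = dE/dphi * dphi/dx for a torsion (radians)."""
    i, j, k, l = idx
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = float(np.dot(n1, n1))
    n2sq = float(np.dot(n2, n2))
    b2n = float(np.linalg.norm(b2))
    if n1sq < 1e-14 or n2sq < 1e-14 or b2n < 1e-14:
        raise ValueError("degenerate torsion geometry in gradient")
    dphi_di = -b2n / n1sq * n1
    dphi_dl = b2n / n2sq * n2
    f1 = float(np.dot(b1, b2)) / (b2n * b2n)
    f2 = float(np.dot(b3, b2)) / (b2n * b2n)
    dphi_dj = -(1.0 + f1) * dphi_di + f2 * dphi_dl
    dphi_dk = f1 * dphi_di - (1.0 + f2) * dphi_dl
    g[i] += dE_dphi * dphi_di
    g[j] += dE_dphi * dphi_dj
    g[k] += dE_dphi * dphi_dk
    g[l] += dE_dphi * dphi_dl


def energy_and_gradient(
    coords: np.ndarray,
    params: ForceFieldParameters,
    charges: ChargeSet,
    compute_gradient: bool = True,
) -> tuple[EnergyBreakdown, np.ndarray | None]:
    """Energy breakdown and (optionally) its analytic Cartesian gradient."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    if len(charges) != n:
        raise ValueError("charge set length does not match atom count")
    e_bond, e_angle, e_dih, g_bonded = _bonded_terms(coords, params, compute_gradient)
    full, p14 = _pair_lists(n, params)
    q = charges.charges
    e_es_f, e_vdw_f, g_f = _nonbonded(coords, q, params, full, 1.0, 1.0, compute_gradient)
    e_es_4, e_vdw_4, g_4 = _nonbonded(coords, q, params, p14, SCEE, SCNB, compute_gradient)
    breakdown = EnergyBreakdown(
        e_bond=e_bond,
        e_angle=e_angle,
        e_dihedral=e_dih,
        e_es=e_es_f + e_es_4,
        e_vdw=e_vdw_f + e_vdw_4,
    )
    grad = None
    if compute_gradient:
        grad = g_bonded + g_f + g_4
    return breakdown, grad


def energy(
    conformer: Conformer | np.ndarray,
    params: ForceFieldParameters,
    charges: ChargeSet,
) -> EnergyBreakdown:
    """Amber-form potential energy of a conformer, kcal/mol."""
    coords = (
        conformer.coordinates() if isinstance(conformer, Conformer) else conformer
    )
    breakdown, _ = energy_and_gradient(coords, params, charges, compute_gradient=False)
    return breakdown


def _wrap_deg(x: float) -> float:
    """Wrap an angle difference into (-180, 180]."""
    x = math.fmod(x, 360.0)
    if x <= -180.0:
        x += 360.0
    elif x > 180.0:
        x -= 360.0
    return x


def _restraint_energy_grad(coords, restraints, grad):
    e = 0.0
    g = np.zeros_like(coords) if grad else None
    for rest in restraints:
        i, j, k, l = rest.atoms
        phi = dihedral_from_coords(coords[i], coords[j], coords[k], coords[l])
        d = math.radians(_wrap_deg(phi - rest.target))
        e += rest.k * d * d
        if grad:
            _add_torsion_grad(g, coords, rest.atoms, 2.0 * rest.k * d)
    return e, g


def minimize(
    conformer: Conformer,
    params: ForceFieldParameters,
    charges: ChargeSet,
    restraints: list[TorsionRestraint] | None = None,
    max_steps: int = 5000,
    gtol: float = 1e-6,
) -> tuple[Conformer, EnergyBreakdown, list[float]]:
    """Quasi-Newton (L-BFGS) minimization with optional torsion restraints.

    Restraints enter the minimized objective only; the returned
    :class:`EnergyBreakdown` is the unrestrained force-field energy at
    the final geometry.  Returns the relaxed conformer, its energy and
    the trace of objective values along accepted steps.
    """
    restraints = restraints or []
    x0 = conformer.coordinates().ravel()
    trace: list[float] = []

    def objective(x):
        coords = x.reshape(-1, 3)
        breakdown, g = energy_and_gradient(coords, params, charges)
        e_r, g_r = _restraint_energy_grad(coords, restraints, True)
        e = breakdown.e_total + e_r
        if not math.isfinite(e):
            raise FloatingPointError("non-finite energy during minimization")
        return e, (g + g_r).ravel()

    def callback(xk):
        trace.append(objective(xk)[0])

    res = _scipy_minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_steps, "gtol": gtol, "ftol": 1e-12},
        callback=callback,
    )
    final = conformer.with_coordinates(res.x.reshape(-1, 3))
    breakdown, _ = energy_and_gradient(res.x.reshape(-1, 3), params, charges, False)
    return final, breakdown, trace


#: default backbone targets for restrained relaxation, degrees
ALPHA_TARGET = (-60.0, -40.0)
BETA_TARGET = (180.0, 180.0)


def relative_energy(
    pair: ConformerPair,
    params: ForceFieldParameters,
    charges: ChargeSet,
    mode: str = "minimized",
    phi_atoms: tuple[int, int, int, int] | None = None,
    psi_atoms: tuple[int, int, int, int] | None = None,
    restraint_k: float = 100.0,
) -> float:
    """Relative conformer energy RE = E(alpha) - E(beta), kcal/mol.

    Both conformers are evaluated under the *same* charge set (one
    blended set per residue).  ``mode="single_point"`` uses the input
    geometries; ``mode="minimized"`` relaxes each conformer first with
    harmonic phi/psi restraints at (-60, -40) and (180, 180) so the
    backbone states survive the relaxation.
    """
    if mode not in ("single_point", "minimized"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "single_point":
        ea = energy(pair.alpha, params, charges).e_total
        eb = energy(pair.beta, params, charges).e_total
        return ea - eb
    if phi_atoms is None or psi_atoms is None:
        raise ValueError("minimized mode needs phi_atoms and psi_atoms")
    rest_a = [
        TorsionRestraint(phi_atoms, ALPHA_TARGET[0], restraint_k),
        TorsionRestraint(psi_atoms, ALPHA_TARGET[1], restraint_k),
    ]
    rest_b = [
        TorsionRestraint(phi_atoms, BETA_TARGET[0], restraint_k),
        TorsionRestraint(psi_atoms, BETA_TARGET[1], restraint_k),
    ]
    _, ba, _ = minimize(pair.alpha, params, charges, rest_a)
    _, bb, _ = minimize(pair.beta, params, charges, rest_b)
    return ba.e_total - bb.e_total
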