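"""Synthetic test systems and the embedded relative-energy benchmark.

Everything here is generated programmatically and bit-reproducible from
a seed: a toy capped dipeptide with alpha/beta backbone copies, an
ESP generate-and-recover problem, a desk-scale receptor-ligand complex
for MM/PBSA, and the 18-system alpha/beta relative-energy benchmark
(MP2 reference, a DFT comparison column, the four optimization cycles
and the literature-parameter values available for systems 7, 9, 11, 13).
The toy systems are geometric/electrostatic stand-ins, not attempts at
realistic side-chain chemistry.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blend import BenchmarkTable
from .core import AtomRecord, ChargeSet, Conformer, ForceFieldParameters
from .energy import ConformerPair
from .resp import EspGrid, build_mk_grid, esp_from_point_charges

__all__ = [
    "table2",
    "ToyDipeptide",
    "make_toy_dipeptide",
    "make_esp_recovery_problem",
    "BindingComplex",
    "make_binding_complex",
]

# 18-system benchmark: relative energies E(alpha) - E(beta), kcal/mol.
# "reference" holds literature-parameter values, present only for
# systems 7, 9, 11 and 13.
_TABLE2_TSV = """\
system	MP2	M06-2X	cycle1	cycle2	cycle3	cycle4	reference
1	6.50	7.39	11.07	2.61	6.72	6.72
2	6.93	7.72	10.78	3.34	7.12	7.12
3	6.35	7.13	11.14	1.96	6.70	6.70
4	6.05	7.30	6.63	0.01	3.52	6.63
5	6.45	7.28	10.11	2.01	6.31	6.31
6	6.53	7.38	10.56	2.44	6.55	6.55
7	6.76	7.58	10.36	2.77	6.76	6.76	5.74
8	6.77	7.54	10.06	3.18	7.06	7.06
9	6.86	7.62	12.78	5.56	9.57	7.00	8.52
10	6.89	9.74	12.40	5.54	9.06	6.77
11	6.79	7.54	12.32	4.33	8.22	7.10	8.05
12	8.02	8.90	15.12	6.34	11.08	7.93
13	8.26	8.99	13.78	4.05	8.94	8.94	4.40
14	7.12	8.08	14.38	2.44	7.70	7.70
15	7.44	8.37	12.76	1.80	7.58	7.58
16	7.53	8.42	12.88	2.69	7.86	7.86
17	5.07	5.54	6.70	-6.75	0.47	4.96
18	4.80	5.34	4.45	-7.52	-1.53	4.45
"""

#: per-system blend fractions (w_beta) adopted in the final cycle:
#: pure beta for 4 and 18, beta/6 + alpha*5/6 for 9 and 12,
#: beta/5 + alpha*4/5 for 10, beta/3 + alpha*2/3 for 11,
#: beta*7/8 + alpha/8 for 17, and the half/half average elsewhere.
FINAL_CYCLE_WBETA: dict[int, tuple[int, int]] = {
    **{s: (1, 2) for s in range(1, 19)},
    4: (1, 1),
    18: (1, 1),
    9: (1, 6),
    12: (1, 6),
    10: (1, 5),
    11: (1, 3),
    17: (7, 8),
}


def table2() -> BenchmarkTable:
    """The embedded 18-system relative-energy benchmark."""
    frame = pd.read_csv(_io.StringIO(_TABLE2_TSV), sep="\t")
    return BenchmarkTable(frame)


# ---------------------------------------------------------------------------
# toy dipeptide


def _nerf(a, b, c, r, theta_deg, phi_deg):
    """Place atom D bonded to C with |CD| = r, angle(B,C,D) = theta and
    torsion(A,B,C,D) = phi (natural-extension reference frame)."""
    theta = math.radians(theta_deg)
    phi = math.radians(phi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms in internal-coordinate build")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -r * math.cos(theta),
            r * math.sin(theta) * math.cos(phi),
            r * math.sin(theta) * math.sin(phi),
        ]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


# (name, element, residue_name, residue_index) for the 13-atom chain:
# an acetyl cap, one residue with a two-carbon side chain carrying two
# hydrogens, and an N-methyl cap.
_TOY_ATOMS = [
    ("CAY", "C", "ACE", 1),
    ("CY", "C", "ACE", 1),
    ("OY", "O", "ACE", 1),
    ("N", "N", "UAA", 2),
    ("CA", "C", "UAA", 2),
    ("CB", "C", "UAA", 2),
    ("CG", "C", "UAA", 2),
    ("C", "C", "UAA", 2),
    ("O", "O", "UAA", 2),
    ("NT", "N", "NME", 3),
    ("CAT", "C", "NME", 3),
    ("HB", "H", "UAA", 2),
    ("HG", "H", "UAA", 2),
]

_TOY_BONDS = [
    (0, 1), (1, 2), (1, 3), (3, 4), (4, 5), (4, 7), (5, 6),
    (7, 8), (7, 9), (9, 10), (5, 11), (6, 12),
]

#: backbone torsion atom indices: phi = CY-N-CA-C, psi = N-CA-C-NT
PHI_ATOMS = (1, 3, 4, 7)
PSI_ATOMS = (3, 4, 7, 9)

_GROUPS = [
    "ACE", "ACE", "ACE",
    "BACKBONE", "BACKBONE", "SIDECHAIN", "SIDECHAIN",
    "BACKBONE", "BACKBONE", "NME", "NME", "SIDECHAIN", "SIDECHAIN",
]


def _build_toy_coords(phi: float, psi: float, chi1: float, chi2: float) -> np.ndarray:
    x = np.zeros((13, 3))
    x[0] = [0.0, 0.0, 0.0]
    x[1] = [1.50, 0.0, 0.0]
    # N in the xy-plane at a 120 degree Ace angle
    x[3] = x[1] + 1.34 * np.array(
        [math.cos(math.radians(60.0)), math.sin(math.radians(60.0)), 0.0]
    )
    x[2] = _nerf(x[3], x[0], x[1], 1.23, 121.0, 180.0)
    x[4] = _nerf(x[0], x[1], x[3], 1.45, 121.0, 180.0)
    x[7] = _nerf(x[1], x[3], x[4], 1.52, 110.0, phi)
    x[5] = _nerf(x[1], x[3], x[4], 1.53, 109.0, phi + 122.0)
    x[8] = _nerf(x[3], x[4], x[7], 1.23, 121.0, psi + 180.0)
    x[9] = _nerf(x[3], x[4], x[7], 1.34, 115.0, psi)
    x[10] = _nerf(x[4], x[7], x[9], 1.45, 120.0, 180.0)
    x[6] = _nerf(x[3], x[4], x[5], 1.50, 111.0, chi1)
    x[11] = _nerf(x[4], x[5], x[6], 1.09, 108.0, chi2 + 120.0)
    x[12] = _nerf(x[4], x[5], x[6], 1.09, 109.0, chi2)
    return x


def _angle_deg(a, b, c) -> float:
    u = a - b
    v = c - b
    cosv = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


def _connectivity(bonds, n):
    adj = {i: set() for i in range(n)}
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    return adj


def _toy_parameters(coords: np.ndarray) -> ForceFieldParameters:
    """Bonded/LJ parameters with equilibrium values measured from the
    built geometry, so both conformers start finite and near-relaxed."""
    n = len(coords)
    adj = _connectivity(_TOY_BONDS, n)
    bonds = [
        (i, j, 300.0, float(np.linalg.norm(coords[i] - coords[j])))
        for i, j in _TOY_BONDS
    ]
    angles = []
    for j in range(n):
        nb = sorted(adj[j])
        for ai in range(len(nb)):
            for ak in range(ai + 1, len(nb)):
                i, k = nb[ai], nb[ak]
                angles.append((i, j, k, 50.0, _angle_deg(coords[i], coords[j], coords[k])))
    dihedrals = []
    for j, k in _TOY_BONDS:
        for i in sorted(adj[j] - {k}):
            for l in sorted(adj[k] - {j}):
                if i != l:
                    dihedrals.append((i, j, k, l, 0.4, 3, 0.0))
    # 1-2/1-3 exclusions and 1-4 pairs from connectivity
    excl = set()
    for i, j in _TOY_BONDS:
        excl.add((min(i, j), max(i, j)))
    for i, j, k, _kth, _th in angles:
        excl.add((min(i, k), max(i, k)))
    pairs14 = set()
    for i, j, k, l, *_ in dihedrals:
        p = (min(i, l), max(i, l))
        if p not in excl:
            pairs14.add(p)
    lj = [
        (1.80 if el != "H" else 1.38, 0.10 if el != "H" else 0.015)
        for _, el, _, _ in _TOY_ATOMS
    ]
    return ForceFieldParameters(
        bonds=bonds, angles=angles, dihedrals=dihedrals,
        lj=lj, exclusions=excl, pairs14=pairs14,
    )


@dataclass
class ToyDipeptide:
    pair: ConformerPair
    params: ForceFieldParameters
    q_alpha: ChargeSet
    q_beta: ChargeSet
    phi_atoms: tuple[int, int, int, int] = PHI_ATOMS
    psi_atoms: tuple[int, int, int, int] = PSI_ATOMS


def _conformer_from_coords(coords, label, phi, psi) -> Conformer:
    atoms = [
        AtomRecord(i, name, el, res, rid, tuple(coords[i]))
        for i, (name, el, res, rid) in enumerate(_TOY_ATOMS)
    ]
    return Conformer(atoms=atoms, label=label, phi=phi, psi=psi)


def make_toy_dipeptide(seed: int = 0) -> ToyDipeptide:
    """A capped toy dipeptide in alpha and beta backbone states.

    Both copies share atom ordering and parameters; the helical copy is
    built at (phi, psi) = (-60, -40), the strand copy at (180, 180).
    The seed varies the side-chain rotamer and the charge values but not
    the backbone targets.
    """
    rng = np.random.default_rng(seed)
    chi1 = float(rng.uniform(-180.0, 180.0))
    chi2 = float(rng.uniform(-180.0, 180.0))
    xa = _build_toy_coords(-60.0, -40.0, chi1, chi2)
    xb = _build_toy_coords(180.0, 180.0, chi1, chi2)
    params = _toy_parameters(xb)
    qa = rng.uniform(-0.35, 0.35, size=13)
    qa -= qa.mean()
    qb = qa.copy()
    free = [i for i, g in enumerate(_GROUPS) if g in ("BACKBONE", "SIDECHAIN")]
    dq = rng.uniform(-0.05, 0.05, size=len(free))
    dq -= dq.mean()
    qb[free] += dq
    alpha = _conformer_from_coords(xa, "alpha", -60.0, -40.0)
    beta = _conformer_from_coords(xb, "beta", 180.0, 180.0)
    return ToyDipeptide(
        pair=ConformerPair(system_id=1, alpha=alpha, beta=beta),
        params=params,
        q_alpha=ChargeSet(qa, 0, list(_GROUPS)),
        q_beta=ChargeSet(qb, 0, list(_GROUPS)),
    )


# ---------------------------------------------------------------------------
# ESP recovery


def make_esp_recovery_problem(
    seed: int = 0, n_atoms: int = 4
) -> tuple[np.ndarray, ChargeSet, EspGrid]:
    """Ground-truth generator for the restrained charge fit.

    Random well-separated atoms with zero-sum hidden charges; the grid
    is a seeded shell construction around them and the target values are
    the exact Coulomb potential of the hidden charges.  Coordinates in
    the returned tuple are in Bohr (fitting units).
    """
    if n_atoms < 1:
        raise ValueError("need at least one atom")
    rng = np.random.default_rng(seed)
    coords_ang = np.zeros((n_atoms, 3))
    placed = 1
    while placed < n_atoms:
        cand = rng.uniform(-3.0, 3.0, size=3)
        if np.linalg.norm(coords_ang[:placed] - cand, axis=1).min() > 1.8:
            coords_ang[placed] = cand
            placed += 1
    hidden = rng.uniform(-0.8, 0.8, size=n_atoms)
    hidden -= hidden.mean()
    atoms = [
        AtomRecord(i, f"C{i + 1}", "C", "LIG", 1, tuple(coords_ang[i]))
        for i in range(n_atoms)
    ]
    mol = Conformer(atoms=atoms)
    grid = build_mk_grid(mol, density=1.2, seed=seed)
    from .core import ANGSTROM_PER_BOHR

    coords_bohr = coords_ang / ANGSTROM_PER_BOHR
    values = esp_from_point_charges(hidden, coords_bohr, grid.points)
    return coords_bohr, ChargeSet(hidden, 0), EspGrid(grid.points, values)


# ---------------------------------------------------------------------------
# binding complex


@dataclass
class BindingComplex:
    snapshots: list[Conformer]
    ligand_atoms: list[int]
    params: ForceFieldParameters
    charges: ChargeSet
    radii: np.ndarray


def make_binding_complex(
    seed: int = 0,
    n_res: int = 3,
    n_snapshots: int = 5,
    jitter: float = 0.05,
    charged_ligand: bool = True,
) -> BindingComplex:
    """Desk-scale receptor-ligand complex for MM/PBSA exercises.

    *n_res* three-atom pseudo-residues arranged on an arc form the
    receptor; a single three-atom residue sitting in front of the arc is
    the ligand.  Snapshots jitter all coordinates with a seeded normal
    of scale *jitter* (Angstrom).  With ``charged_ligand=False`` the
    ligand carries zero charges and zero LJ epsilon, making the complex
    non-interacting.
    """
    if n_res < 2:
        raise ValueError("need at least two receptor residues")
    rng = np.random.default_rng(seed)
    base = []
    meta = []
    for r in range(n_res):
        ang = math.pi * (0.25 + 0.5 * r / max(1, n_res - 1))
        center = 4.5 * np.array([math.cos(ang), math.sin(ang), 0.0])
        local = np.array(
            [[0.0, 0.0, 0.0], [1.4, 0.0, 0.6], [0.5, 1.3, -0.5]]
        )
        for a, off in enumerate(local):
            base.append(center + off)
            meta.append((f"R{a + 1}", ["C", "N", "O"][a], "RES", r + 1))
    lig_center = np.array([0.0, 0.0, 0.0])
    lig_local = np.array([[0.0, 0.0, 0.0], [1.3, 0.3, 0.4], [-0.4, 1.2, -0.4]])
    lig_idx = []
    for a, off in enumerate(lig_local):
        lig_idx.append(len(base))
        base.append(lig_center + off)
        meta.append((f"L{a + 1}", ["C", "O", "N"][a], "LIG", n_res + 1))
    base = np.array(base)
    n_atoms = len(base)

    q = rng.uniform(-0.3, 0.3, size=n_atoms)
    if charged_ligand:
        q -= q.mean()
    else:
        q[lig_idx] = 0.0
        rec = [i for i in range(n_atoms) if i not in lig_idx]
        q[rec] -= q[rec].mean()
    lj = [(1.8, 0.1)] * n_atoms
    if not charged_ligand:
        for i in lig_idx:
            lj[i] = (1.8, 0.0)
    params = ForceFieldParameters(lj=lj)
    radii = np.array([{"C": 1.7, "N": 1.55, "O": 1.52}[m[1]] for m in meta])

    snapshots = []
    for _ in range(n_snapshots):
        coords = base + rng.normal(scale=jitter, size=base.shape)
        atoms = [
            AtomRecord(i, meta[i][0], meta[i][1], meta[i][2], meta[i][3], tuple(coords[i]))
            for i in range(n_atoms)
        ]
        snapshots.append(Conformer(atoms=atoms))
    return BindingComplex(
        snapshots=snapshots,
        ligand_atoms=lig_idx,
        params=params,
        charges=ChargeSet(q, 0),
        radii=radii,
    )
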