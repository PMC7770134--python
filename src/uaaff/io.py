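"""File formats: PDB structures, ESP grids, parameter sets, benchmarks.

PDB reading and writing goes through biotite's fixed-column PDB support;
multi-model files become snapshot lists with identical atom ordering.
The ESP grid dialect mirrors the classic RESP input layout (header,
atom coordinates in Bohr, then ``V x y z`` lines in atomic units) and
tolerates Fortran ``D`` exponents.  Force-field parameters travel as a
versioned YAML/JSON document with an explicit units declaration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile

from .core import AtomRecord, ChargeSet, Conformer, ForceFieldParameters
from .resp import EspGrid

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_esp_grid",
    "write_esp_grid",
    "read_parameters",
    "write_parameters",
    "read_mol2_charges",
]

_NAME_TO_ELEMENT = {
    "CL": "Cl", "BR": "Br", "NA": "Na", "MG": "Mg", "CA": "Ca", "ZN": "Zn",
    "FE": "Fe",
}


def _element_from_name(name: str) -> str:
    stripped = name.strip()
    two = stripped[:2].upper()
    if two in _NAME_TO_ELEMENT:
        return _NAME_TO_ELEMENT[two]
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot derive an element from atom name {name!r}")


def _array_to_conformer(arr: AtomArray) -> Conformer:
    atoms = []
    for i in range(arr.array_length()):
        elem = str(arr.element[i]).strip()
        if not elem:
            elem = _element_from_name(str(arr.atom_name[i]))
        elif len(elem) == 2:
            elem = elem[0].upper() + elem[1].lower()
        atoms.append(
            AtomRecord(
                index=i,
                name=str(arr.atom_name[i]),
                element=elem,
                residue_name=str(arr.res_name[i]),
                residue_index=int(arr.res_id[i]),
                coords=tuple(float(x) for x in arr.coord[i]),
            )
        )
    return Conformer(atoms=atoms)


def read_pdb(path) -> list[Conformer]:
    """Read a (possibly multi-model) PDB file into a snapshot list.

    The element column is honoured when present, with a fallback to
    name-derived elements; nonstandard residue names (noncanonical
    amino-acid codes such as NIY) are preserved verbatim.
    """
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure()
    except Exception as exc:
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    if isinstance(stack, AtomArray):
        stack = [stack]
    return [_array_to_conformer(model) for model in stack]


def write_pdb(conformers: Conformer | list[Conformer], path) -> None:
    """Write one or more conformers as a fixed-column (multi-model) PDB."""
    if isinstance(conformers, Conformer):
        conformers = [conformers]
    if not conformers:
        raise ValueError("nothing to write")
    n = conformers[0].n_atoms
    if any(c.n_atoms != n for c in conformers):
        raise ValueError("all models must share the atom count")
    template = conformers[0]
    stack = AtomArrayStack(len(conformers), n)
    stack.coord = np.stack([c.coordinates() for c in conformers])
    stack.atom_name = np.array([a.name for a in template.atoms])
    stack.element = np.array([a.element.upper() for a in template.atoms])
    stack.res_name = np.array([a.residue_name for a in template.atoms])
    stack.res_id = np.array([a.residue_index for a in template.atoms])
    stack.chain_id = np.array(["A"] * n)
    stack.hetero = np.array([False] * n)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# ESP grid dialect


def _parse_float(tok: str) -> float:
    return float(tok.replace("D", "E").replace("d", "e"))


def read_esp_grid(path) -> tuple[np.ndarray, EspGrid, int]:
    """Read the plain-text ESP grid dialect.

    Layout: header line ``n_atoms n_points net_charge``; *n_atoms* lines
    of atom coordinates (Bohr); *n_points* lines ``V x y z`` with the
    potential in hartree/e and coordinates in Bohr.  Fortran D-exponents
    are accepted.  Returns (atom_coords, grid, net_charge).
    """
    lines = [
        ln for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    try:
        n_atoms, n_points, net_charge = (
            int(tok) for tok in lines[0].split()[:3]
        )
    except (ValueError, IndexError) as exc:
        raise ValueError(f"bad ESP header line: {lines[0]!r}") from exc
    if len(lines) < 1 + n_atoms + n_points:
        raise ValueError("truncated ESP grid file")
    atoms = np.array(
        [[_parse_float(t) for t in lines[1 + i].split()[:3]] for i in range(n_atoms)]
    )
    vals = np.empty(n_points)
    pts = np.empty((n_points, 3))
    for k in range(n_points):
        toks = lines[1 + n_atoms + k].split()
        vals[k] = _parse_float(toks[0])
        pts[k] = [_parse_float(t) for t in toks[1:4]]
    return atoms, EspGrid(points=pts, values=vals), net_charge


def write_esp_grid(atom_coords: np.ndarray, grid: EspGrid, net_charge: int, path) -> None:
    atom_coords = np.asarray(atom_coords, dtype=float).reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write(f"{len(atom_coords)} {grid.n_points} {net_charge}\n")
        for c in atom_coords:
            fh.write(f"  {c[0]: .10E} {c[1]: .10E} {c[2]: .10E}\n")
        for v, p in zip(grid.values, grid.points):
            fh.write(f"  {v: .10E} {p[0]: .10E} {p[1]: .10E} {p[2]: .10E}\n")


# ---------------------------------------------------------------------------
# parameter schema

SCHEMA_VERSION = 1
_UNITS = {
    "energy": "kcal/mol",
    "length": "angstrom",
    "charge": "e",
    "angle": "degrees",
}


def write_parameters(
    params: ForceFieldParameters,
    charges: ChargeSet | None,
    path,
    atom_names: list[str] | None = None,
    elements: list[str] | None = None,
) -> None:
    """Serialize a parameter set (+ optional charges) as YAML or JSON.

    The format is chosen by the file suffix (``.json`` vs anything
    else → YAML).  Indices are written 1-based, matching PDB convention.
    """
    n = len(params.lj)
    doc = {
        "version": SCHEMA_VERSION,
        "units": dict(_UNITS),
        "atoms": [
            {
                "name": atom_names[i] if atom_names else f"X{i + 1}",
                "element": elements[i] if elements else "C",
                "rmin_half": params.lj[i][0],
                "epsilon": params.lj[i][1],
                "charge": float(charges.charges[i]) if charges is not None else 0.0,
                "group": (
                    charges.group_of_atom[i]
                    if charges is not None and charges.group_of_atom
                    else "SIDECHAIN"
                ),
            }
            for i in range(n)
        ],
        "net_charge": charges.net_charge if charges is not None else 0,
        "bonds": [
            {"atoms": [i + 1, j + 1], "k": k, "r_eq": r}
            for i, j, k, r in params.bonds
        ],
        "angles": [
            {"atoms": [i + 1, j + 1, k + 1], "k": kth, "theta_eq": th}
            for i, j, k, kth, th in params.angles
        ],
        "dihedrals": [
            {
                "atoms": [i + 1, j + 1, k + 1, l + 1],
                "v": v,
                "periodicity": n_,
                "phase": g,
            }
            for i, j, k, l, v, n_, g in params.dihedrals
        ],
        "exclusions": [[i + 1, j + 1] for i, j in sorted(params.exclusions)],
        "pairs14": [[i + 1, j + 1] for i, j in sorted(params.pairs14)],
    }
    text = (
        json.dumps(doc, indent=2)
        if str(path).endswith(".json")
        else yaml.safe_dump(doc, sort_keys=False)
    )
    Path(path).write_text(text)


def read_parameters(path) -> tuple[ForceFieldParameters, ChargeSet, dict]:
    """Read the parameter schema; returns (params, charges, metadata)."""
    text = Path(path).read_text()
    doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if "units" not in doc:
        raise ValueError("parameter file must declare units")
    if doc["units"] != _UNITS:
        raise ValueError(f"unsupported units declaration: {doc['units']}")
    n = len(doc["atoms"])
    lj = [(a["rmin_half"], a["epsilon"]) for a in doc["atoms"]]
    bonds = [
        (b["atoms"][0] - 1, b["atoms"][1] - 1, b["k"], b["r_eq"])
        for b in doc.get("bonds", [])
    ]
    angles = [
        (a["atoms"][0] - 1, a["atoms"][1] - 1, a["atoms"][2] - 1, a["k"], a["theta_eq"])
        for a in doc.get("angles", [])
    ]
    dihedrals = [
        (
            d["atoms"][0] - 1,
            d["atoms"][1] - 1,
            d["atoms"][2] - 1,
            d["atoms"][3] - 1,
            d["v"],
            d["periodicity"],
            d["phase"],
        )
        for d in doc.get("dihedrals", [])
    ]
    for lst in (bonds, angles, dihedrals):
        for entry in lst:
            for idx in entry[: len(entry) - 2]:
                if isinstance(idx, int) and not (0 <= idx < n):
                    raise ValueError("parameter atom index out of range")
    params = ForceFieldParameters(
        bonds=bonds,
        angles=angles,
        dihedrals=dihedrals,
        lj=lj,
        exclusions={(p[0] - 1, p[1] - 1) for p in doc.get("exclusions", [])},
        pairs14={(p[0] - 1, p[1] - 1) for p in doc.get("pairs14", [])},
    )
    charges = ChargeSet(
        np.array([a["charge"] for a in doc["atoms"]], dtype=float),
        int(doc.get("net_charge", 0)),
        [a.get("group", "SIDECHAIN") for a in doc["atoms"]],
    )
    meta = {
        "version": doc.get("version"),
        "atom_names": [a["name"] for a in doc["atoms"]],
        "elements": [a["element"] for a in doc["atoms"]],
    }
    return params, charges, meta


def read_mol2_charges(path) -> np.ndarray:
    """Partial charges from the last column of a mol2 ATOM block."""
    charges = []
    in_atoms = False
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s.startswith("@<TRIPOS>"):
            in_atoms = s == "@<TRIPOS>ATOM"
            continue
        if in_atoms and s:
            toks = s.split()
            if len(toks) < 9:
                raise ValueError(f"mol2 ATOM record lacks a charge column: {s!r}")
            charges.append(float(toks[8]))
    if not charges:
        raise ValueError("no ATOM block found in mol2 file")
    return np.array(charges)
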