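"""Molecule and activity-table I/O.

Defines the internal molecular representation consumed by the field engine,
the descriptor encoders and the QSAR models: a light container of atoms with
3D coordinates (Å), partial charges (e) and probe-interaction atom types.
RDKit does the heavy lifting for the structure-data formats (SDF V2000/V3000,
MOL2) and for Gasteiger charges; everything downstream sees only the
containers defined here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

log = logging.getLogger(__name__)

__all__ = [
    "AtomType",
    "Atom",
    "ActivityRecord",
    "Molecule",
    "read_sdf",
    "write_sdf",
    "read_mol2",
    "read_activity_table",
    "assign_atom_types",
    "molecule_from_rdkit",
    "molecule_to_rdkit",
]


class AtomType(Enum):
    """Probe-interaction role of an atom.

    DONOR_H marks a heavy atom carrying at least one polar hydrogen (it may
    simultaneously be an acceptor; see :attr:`Atom.acceptor_flag`). ACCEPTOR
    marks N/O with an available lone pair and no attached polar H. HYDROPHOBE
    is carbon/sulfur in an apolar context; POLAR covers the remaining
    heteroatom cases and hydrogens on heteroatoms; OTHER is the fallback for
    elements without an assigned role.
    """

    DONOR_H = "DONOR_H"
    ACCEPTOR = "ACCEPTOR"
    HYDROPHOBE = "HYDROPHOBE"
    POLAR = "POLAR"
    OTHER = "OTHER"


@dataclass(frozen=True)
class Atom:
    element: str
    coords: np.ndarray  # shape (3,), Å
    partial_charge: float = 0.0
    atom_type: AtomType = AtomType.OTHER
    acceptor_flag: bool = False  # dual donor/acceptor role (e.g. hydroxyl O)

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom coords must be a finite 3-vector, got {self.coords!r}")
        object.__setattr__(self, "coords", c)
        if not -2.0 <= self.partial_charge <= 2.0:
            raise ValueError(
                f"partial charge {self.partial_charge} outside [-2, 2] e for {self.element}"
            )


@dataclass(frozen=True)
class ActivityRecord:
    """IC50 in μM and its log(1/IC50) transform; optional calculated logP."""

    ic50_um: float
    log_inv_ic50: float
    clogp: float | None = None

    def __post_init__(self):
        if self.ic50_um <= 0:
            raise ValueError(f"IC50 must be positive, got {self.ic50_um}")
        expected = -math.log10(self.ic50_um)
        if abs(self.log_inv_ic50 - expected) > 1e-9:
            raise ValueError(
                f"log_inv_ic50={self.log_inv_ic50} inconsistent with IC50 {self.ic50_um} μM"
            )

    @classmethod
    def from_ic50(cls, ic50_um: float, clogp: float | None = None) -> "ActivityRecord":
        if ic50_um <= 0:
            raise ValueError(f"IC50 must be positive, got {ic50_um}")
        return cls(ic50_um=ic50_um, log_inv_ic50=-math.log10(ic50_um), clogp=clogp)


@dataclass
class Molecule:
    id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)  # (i, j, order)
    activity: ActivityRecord | None = None
    charge_provenance: str = "input"  # "input" | "gasteiger" | "synthetic"

    def __post_init__(self):
        if not self.atoms:
            raise ValueError(f"empty molecule: {self.id!r}")
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms in {self.id!r}")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])

    def atoms_of_type(self, t: AtomType) -> list[int]:
        idx = [i for i, a in enumerate(self.atoms) if a.atom_type is t]
        if t is AtomType.ACCEPTOR:
            idx += [i for i, a in enumerate(self.atoms)
                    if a.acceptor_flag and a.atom_type is not AtomType.ACCEPTOR]
        return sorted(idx)

    def is_3d(self) -> bool:
        z = self.coords[:, 2]
        return bool(np.ptp(z) > 1e-6) or len(self.atoms) == 1


# ---------------------------------------------------------------------------
# RDKit bridge


def molecule_from_rdkit(mol: Chem.Mol, mol_id: str, *, conf_id: int = 0) -> Molecule:
    if mol.GetNumAtoms() == 0:
        raise ValueError("empty molecule")
    if mol.GetNumConformers() == 0:
        raise ValueError(f"molecule {mol_id!r} has no 3D coordinates")
    conf = mol.GetConformer(conf_id)
    have_charges = all(a.HasProp("_GasteigerCharge") for a in mol.GetAtoms()) or all(
        a.HasProp("_TriposPartialCharge") for a in mol.GetAtoms()
    )
    provenance = "input"
    if not have_charges:
        AllChem.ComputeGasteigerCharges(mol)
        provenance = "gasteiger"
    atoms = []
    for a in mol.GetAtoms():
        pos = conf.GetAtomPosition(a.GetIdx())
        if a.HasProp("_TriposPartialCharge"):
            q = a.GetDoubleProp("_TriposPartialCharge")
        else:
            q = a.GetDoubleProp("_GasteigerCharge")
        if not math.isfinite(q):
            q = 0.0
        atoms.append(Atom(a.GetSymbol(), np.array([pos.x, pos.y, pos.z]), float(q)))
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(b.GetBondTypeAsDouble()) or 1)
        for b in mol.GetBonds()
    ]
    m = Molecule(id=mol_id, atoms=atoms, bonds=bonds, charge_provenance=provenance)
    return assign_atom_types(m, rdkit_mol=mol)


def molecule_to_rdkit(m: Molecule) -> Chem.Mol:
    rw = Chem.RWMol()
    for a in m.atoms:
        rw.AddAtom(Chem.Atom(a.element))
    for i, j, order in m.bonds:
        rw.AddBond(i, j, Chem.BondType.values.get(float(order), Chem.BondType.SINGLE))
    conf = Chem.Conformer(len(m.atoms))
    for i, a in enumerate(m.atoms):
        conf.SetAtomPosition(i, a.coords.tolist())
    mol = rw.GetMol()
    mol.AddConformer(conf)
    mol.SetProp("_Name", m.id)
    try:
        Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
    except Exception:  # synthetic pseudo-molecules need not be valence-legal
        pass
    return mol


# ---------------------------------------------------------------------------
# Readers / writers


def read_sdf(path: str | Path, *, strict: bool = False) -> list[Molecule]:
    """Read a V2000/V3000 SDF into Molecules, one per record.

    Malformed records are reported with their index and skipped unless
    ``strict``. Records without 3D coordinates raise (flagged per record).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    out: list[Molecule] = []
    for i, mol in enumerate(supplier):
        try:
            if mol is None:
                raise ValueError("unparseable record")
            if mol.GetNumAtoms() == 0:
                raise ValueError("empty molecule")
            Chem.FastFindRings(mol)
            mol.UpdatePropertyCache(strict=False)
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol_{i}"
            m = molecule_from_rdkit(mol, mol_id)
            if not m.is_3d():
                log.warning("record %d (%s): coordinates are planar/2D", i, mol_id)
            out.append(m)
        except Exception as exc:
            msg = f"SDF record {i}: {exc}"
            if strict:
                raise ValueError(msg) from exc
            log.error(msg)
    if not out:
        log.warning("no molecules read from %s", path)
    return out


def write_sdf(molecules: Iterable[Molecule], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for m in molecules:
        mol = molecule_to_rdkit(m)
        if m.activity is not None:
            mol.SetProp("IC50_uM", repr(m.activity.ic50_um))
        writer.write(mol)
    writer.close()


def read_mol2(path: str | Path) -> list[Molecule]:
    """Read a (single- or multi-record) Tripos MOL2 file, keeping its charges."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    blocks = ["@<TRIPOS>MOLECULE" + b for b in text.split("@<TRIPOS>MOLECULE")[1:]]
    out = []
    for i, block in enumerate(blocks):
        mol = Chem.MolFromMol2Block(block, removeHs=False, sanitize=False)
        if mol is None:
            log.error("MOL2 record %d: unparseable", i)
            continue
        mol.UpdatePropertyCache(strict=False)
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol2_{i}"
        out.append(molecule_from_rdkit(mol, name))
    return out


def read_activity_table(path: str | Path) -> dict[str, ActivityRecord]:
    """Read a delimited table with columns id, ic50_um[, clogp].

    log(1/IC50) is computed as −log10(IC50[μM]); the μM unit convention is
    fixed package-wide.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    if "id" not in cols or "ic50_um" not in cols:
        raise ValueError(f"activity table needs columns id, ic50_um; found {list(df.columns)}")
    records: dict[str, ActivityRecord] = {}
    for row_no, row in df.iterrows():
        cid = str(row[cols["id"]])
        ic50 = float(row[cols["ic50_um"]])
        if not ic50 > 0:
            raise ValueError(f"row {row_no} (id={cid}): non-positive IC50 {ic50}")
        if cid in records:
            raise ValueError(f"duplicate compound id {cid!r} at row {row_no}")
        clogp = None
        if "clogp" in cols and pd.notna(row[cols["clogp"]]):
            clogp = float(row[cols["clogp"]])
        records[cid] = ActivityRecord.from_ic50(ic50, clogp)
    return records


# ---------------------------------------------------------------------------
# Atom typing

_HYDROPHOBIC_ELEMENTS = {"C", "S"}
_POLAR_ELEMENTS = {"N", "O"}
_KNOWN = {"H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I"}


def assign_atom_types(m: Molecule, *, rdkit_mol: Chem.Mol | None = None) -> Molecule:
    """Assign probe-interaction types from element + bonding pattern.

    N/O with an attached hydrogen → DONOR_H (an O/N that also keeps a lone
    pair gets the dual-role acceptor flag); N/O without polar H and without
    formal positive charge → ACCEPTOR; C/S bonded only to C/S/H/halogen →
    HYDROPHOBE; anything else polar or unknown → POLAR/OTHER. Deterministic
    and independent of atom ordering.
    """
    n = len(m.atoms)
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for i, j, _ in m.bonds:
        neighbors[i].append(j)
        neighbors[j].append(i)

    formal_charges = [0] * n
    if rdkit_mol is not None and rdkit_mol.GetNumAtoms() == n:
        formal_charges = [a.GetFormalCharge() for a in rdkit_mol.GetAtoms()]

    typed: list[Atom] = []
    for i, a in enumerate(m.atoms):
        el = a.element
        t = AtomType.OTHER
        acc = False
        if el in _POLAR_ELEMENTS:
            has_h = any(m.atoms[j].element == "H" for j in neighbors[i])
            if has_h:
                t = AtomType.DONOR_H
                # hydroxyl/amine heavy atoms keep a lone pair: dual role
                acc = formal_charges[i] <= 0
            elif formal_charges[i] <= 0:
                t = AtomType.ACCEPTOR
            else:
                t = AtomType.POLAR
        elif el in _HYDROPHOBIC_ELEMENTS:
            apolar = all(
                m.atoms[j].element in ("C", "S", "H", "F", "Cl", "Br", "I") for j in neighbors[i]
            )
            t = AtomType.HYDROPHOBE if apolar else AtomType.POLAR
        elif el == "H":
            heavy_polar = any(m.atoms[j].element in _POLAR_ELEMENTS for j in neighbors[i])
            t = AtomType.POLAR if heavy_polar else AtomType.OTHER
        elif el in _KNOWN:
            t = AtomType.POLAR if el == "P" else AtomType.OTHER
        else:
            log.warning("unknown element %s in %s: typed OTHER", el, m.id)
        typed.append(replace(a, atom_type=t, acceptor_flag=acc))
    return Molecule(m.id, typed, m.bonds, m.activity, m.charge_provenance)
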