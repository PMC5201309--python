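"""Molecular interaction fields on a regular 3D lattice.

Four classical probes are supported: DRY (hydrophobic), O (a carbonyl-type
H-bond acceptor probe, hence it maps the molecule's *donor* groups), N1 (an
amide-NH donor probe mapping the molecule's *acceptor* groups) and TIP (a
small steric probe tracing the shape envelope). The probe–molecule energy at
a lattice node is the classical three-term sum

    E(x) = Σ E_lj + Σ E_hb + Σ E_el

with a 12-6 Lennard-Jones term per atom, a distance-Gaussian hydrogen-bond
well on type-matched partner atoms, and a Coulomb term with the 332.0
kcal·Å/(mol·e²) constant and a distance-dependent dielectric ε(r) = 4r.
Functional forms and all parameters live in :data:`DEFAULT_PROBES` and are
overridable from YAML; they are generic GRID-like values, not a claim about
any proprietary parameterization. Angular H-bond dependence is deliberately
omitted: downstream correlogram encoding consumes node positions and
energies only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .chem_io import AtomType, Molecule

log = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "ProbeParams",
    "MIFField",
    "DEFAULT_PROBES",
    "load_probe_params",
    "build_grid",
    "probe_energy",
    "compute_mif",
]

COULOMB_CONSTANT = 332.0  # kcal·Å/(mol·e²)
DISTANCE_CUTOFF = 8.0     # Å: atoms beyond this contribute nothing
R_CLAMP = 0.5             # Å: lower clamp preventing singularities
HB_GAUSS_DENOM = 0.25     # Å²: width of exp(−(r−r0)²/0.25)

PROBE_NAMES = ("DRY", "O", "N1", "TIP")


@dataclass(frozen=True)
class GridSpec:
    """Regular lattice: spacing (Å), margin beyond the molecular bounding box."""

    spacing: float = 0.5
    margin: float = 4.0

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        if self.margin < 0:
            raise ValueError(f"grid margin must be non-negative, got {self.margin}")


# Lennard-Jones A/B coefficients (kcal·Å¹²/mol, kcal·Å⁶/mol) per target
# element, derived from generic well depths ε and contact radii σ via
# A = 4εσ¹², B = 4εσ⁶. "X" is the fallback for unknown/pseudo atoms.
def _lj(epsilon: float, sigma: float) -> tuple[float, float]:
    return 4 * epsilon * sigma**12, 4 * epsilon * sigma**6


_LJ_BY_ELEMENT = {
    "C": _lj(0.10, 3.40),
    "N": _lj(0.12, 3.25),
    "O": _lj(0.15, 3.05),
    "S": _lj(0.20, 3.55),
    "H": _lj(0.02, 2.40),
    "P": _lj(0.20, 3.70),
    "F": _lj(0.08, 2.95),
    "Cl": _lj(0.24, 3.45),
    "Br": _lj(0.30, 3.60),
    "I": _lj(0.35, 3.80),
    "X": _lj(0.05, 3.20),
}

def _tip_lj_table() -> dict[str, tuple[float, float]]:
    # TIP is a pure shape probe: uniform modest well depth at a smaller
    # contact radius, so only regions of high atom density (pronounced
    # steric pockets and molecular cores) accumulate retained nodes.
    table = {}
    for el, (A, B) in _LJ_BY_ELEMENT.items():
        sigma = (A / B) ** (1 / 6)
        table[el] = _lj(0.10, max(sigma - 0.5, 2.0))
    return table


@dataclass(frozen=True)
class ProbeParams:
    """One probe's interaction parameters.

    ``hb_partner`` names the atom-type the probe hydrogen-bonds with (None
    disables the HB term). ``energy_cutoff`` is the node-retention threshold
    used later by AMANDA-style extraction.
    """

    probe: str
    lj_table: dict = field(default_factory=lambda: dict(_LJ_BY_ELEMENT))
    hb_partner: AtomType | None = None
    hb_emin: float = -4.0   # kcal/mol, ≤ 0
    hb_r0: float = 1.9      # Å
    charge: float = 0.0     # e
    energy_cutoff: float = -0.5  # kcal/mol; nodes above are discarded
    hydrophobe_only_lj: bool = False  # DRY: attractive LJ on HYDROPHOBE atoms only
    polar_penalty: bool = False       # DRY: +|hb_emin|·f(r) near polar atoms

    def __post_init__(self):
        if self.hb_emin > 0:
            raise ValueError("hb_emin must be ≤ 0 (an attractive well)")
        if self.energy_cutoff > 0:
            raise ValueError("energy_cutoff must be ≤ 0 for attractive probes")

    def lj_coeffs(self, element: str) -> tuple[float, float]:
        return self.lj_table.get(element, self.lj_table.get("X", _LJ_BY_ELEMENT["X"]))


def _dry_lj_table() -> dict[str, tuple[float, float]]:
    # DRY carries an enhanced dispersive term on hydrophobic contacts,
    # standing in for the entropic water-displacement reward of classical
    # hydrophobic probes.
    table = dict(_LJ_BY_ELEMENT)
    table["C"] = _lj(0.30, 3.40)
    table["S"] = _lj(0.45, 3.55)
    return table


DEFAULT_PROBES: dict[str, ProbeParams] = {
    "DRY": ProbeParams(
        probe="DRY", lj_table=_dry_lj_table(), hydrophobe_only_lj=True,
        polar_penalty=True, hb_partner=None, energy_cutoff=-0.5,
    ),
    # O probe: sp2 carbonyl oxygen — accepts H-bonds from the molecule's donors
    "O": ProbeParams(
        probe="O", hb_partner=AtomType.DONOR_H, charge=-0.2, energy_cutoff=-2.5,
    ),
    # N1 probe: amide NH — donates an H-bond to the molecule's acceptors
    "N1": ProbeParams(
        probe="N1", hb_partner=AtomType.ACCEPTOR, charge=+0.2, energy_cutoff=-2.5,
    ),
    "TIP": ProbeParams(
        probe="TIP", lj_table=_tip_lj_table(), hb_partner=None, energy_cutoff=-0.75,
    ),
}


def load_probe_params(path: str | Path) -> dict[str, ProbeParams]:
    """Load probe-parameter overrides from a YAML mapping probe → fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    probes = dict(DEFAULT_PROBES)
    for name, over in raw.items():
        if name not in probes:
            raise ValueError(f"unknown probe {name!r}; expected one of {PROBE_NAMES}")
        base = probes[name]
        if "hb_partner" in over and over["hb_partner"] is not None:
            over = dict(over)
            over["hb_partner"] = AtomType[over["hb_partner"]]
        probes[name] = replace(base, **over)
    return probes


@dataclass
class MIFField:
    probe: str
    grid: GridSpec
    origin: np.ndarray          # (3,) Å
    shape: tuple[int, int, int]
    energies: np.ndarray        # flat, kcal/mol, C-order over the lattice
    cutoff: float

    def node_coords(self) -> np.ndarray:
        """All node coordinates, (N, 3), same flat ordering as energies."""
        axes = [self.origin[k] + self.grid.spacing * np.arange(self.shape[k]) for k in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)


# ---------------------------------------------------------------------------


def build_grid(m: Molecule, spec: GridSpec) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Lattice origin and per-axis node counts covering the molecule + margin.

    Node count per axis is ceil((extent + 2·margin)/spacing) + 1.
    """
    coords = m.coords
    lo = coords.min(axis=0) - spec.margin
    hi = coords.max(axis=0) + spec.margin
    # tiny epsilon so exactly-commensurate extents don't gain a node from FP noise
    counts = tuple(int(np.ceil((hi[k] - lo[k]) / spec.spacing - 1e-9)) + 1 for k in range(3))
    return lo, counts


def _pairwise_energy(
    probe: ProbeParams,
    points: np.ndarray,   # (N, 3)
    m: Molecule,
    *,
    apply_cutoff: bool = True,
) -> np.ndarray:
    """Vectorized probe energies at arbitrary points: the reference path."""
    coords = m.coords
    charges = m.charges
    elements = [a.element for a in m.atoms]
    types = [a.atom_type for a in m.atoms]
    acc_flags = [a.acceptor_flag for a in m.atoms]

    d = np.linalg.norm(points[:, None, :] - coords[None, :, :], axis=2)
    np.clip(d, R_CLAMP, None, out=d)
    within = d <= DISTANCE_CUTOFF if apply_cutoff else np.ones_like(d, dtype=bool)

    def _is_partner(j: int) -> bool:
        if probe.hb_partner is None:
            return False
        return types[j] is probe.hb_partner or (
            probe.hb_partner is AtomType.ACCEPTOR and acc_flags[j]
        )

    E = np.zeros(len(points))
    inv6 = np.where(within, d**-6, 0.0)
    for j, el in enumerate(elements):
        if _is_partner(j):
            # the H-bond well replaces the LJ term for partner atoms: the
            # 1.9 Å optimum sits inside the generic steric wall
            g = np.exp(-((d[:, j] - probe.hb_r0) ** 2) / HB_GAUSS_DENOM)
            E += probe.hb_emin * np.where(within[:, j], g, 0.0)
            continue
        A, B = probe.lj_coeffs(el)
        if probe.hydrophobe_only_lj and types[j] is not AtomType.HYDROPHOBE:
            # DRY: repulsive wall only (no dispersive attraction) off-hydrophobes
            E += A * inv6[:, j] ** 2
        else:
            E += A * inv6[:, j] ** 2 - B * inv6[:, j]

    if probe.polar_penalty:
        for j in range(len(elements)):
            if types[j] in (AtomType.DONOR_H, AtomType.ACCEPTOR, AtomType.POLAR):
                g = np.exp(-((d[:, j] - probe.hb_r0) ** 2) / HB_GAUSS_DENOM)
                E += abs(probe.hb_emin) * np.where(within[:, j], g, 0.0)

    if probe.charge != 0.0:
        nz = charges != 0.0
        if nz.any():
            eel = COULOMB_CONSTANT * probe.charge * charges[None, nz] / (4.0 * d[:, nz] ** 2)
            E += np.where(within[:, nz], eel, 0.0).sum(axis=1)
    return E


def probe_energy(probe: ProbeParams, point: np.ndarray, m: Molecule) -> float:
    """Interaction energy (kcal/mol) of the probe at one point."""
    point = np.asarray(point, dtype=float)
    if point.shape != (3,) or not np.all(np.isfinite(point)):
        raise ValueError(f"point must be a finite 3-vector, got {point!r}")
    return float(_pairwise_energy(probe, point[None, :], m)[0])


def compute_mif(m: Molecule, probe: ProbeParams, spec: GridSpec) -> MIFField:
    """Probe energy at every lattice node.

    Implemented atom-centrically: each atom scatters its LJ/HB/Coulomb
    contribution onto the nodes inside its 8 Å neighbourhood, which keeps the
    cost linear in atoms × local nodes instead of atoms × all nodes.
    """
    if all(a.atom_type is AtomType.OTHER for a in m.atoms):
        raise ValueError(f"molecule {m.id!r} is untyped: run assign_atom_types first")
    origin, shape = build_grid(m, spec)
    s = spec.spacing
    nx, ny, nz = shape
    E = np.zeros(shape)

    axes = [origin[k] + s * np.arange(shape[k]) for k in range(3)]

    for j, atom in enumerate(m.atoms):
        c = atom.coords
        lo_idx = [max(0, int(np.floor((c[k] - DISTANCE_CUTOFF - origin[k]) / s))) for k in range(3)]
        hi_idx = [
            min(shape[k] - 1, int(np.ceil((c[k] + DISTANCE_CUTOFF - origin[k]) / s)))
            for k in range(3)
        ]
        if any(lo_idx[k] > hi_idx[k] for k in range(3)):
            continue
        ax = axes[0][lo_idx[0]:hi_idx[0] + 1] - c[0]
        ay = axes[1][lo_idx[1]:hi_idx[1] + 1] - c[1]
        az = axes[2][lo_idx[2]:hi_idx[2] + 1] - c[2]
        d2 = ax[:, None, None] ** 2 + ay[None, :, None] ** 2 + az[None, None, :] ** 2
        d = np.sqrt(d2)
        np.clip(d, R_CLAMP, None, out=d)
        within = d <= DISTANCE_CUTOFF

        contrib = np.zeros_like(d)
        is_partner = probe.hb_partner is not None and (
            atom.atom_type is probe.hb_partner
            or (probe.hb_partner is AtomType.ACCEPTOR and atom.acceptor_flag)
        )
        A, B = probe.lj_coeffs(atom.element)
        inv6 = d**-6
        if is_partner:
            # H-bond well replaces the LJ term for partner atoms
            contrib += probe.hb_emin * np.exp(-((d - probe.hb_r0) ** 2) / HB_GAUSS_DENOM)
        elif probe.hydrophobe_only_lj and atom.atom_type is not AtomType.HYDROPHOBE:
            contrib += A * inv6**2
        else:
            contrib += A * inv6**2 - B * inv6

        if probe.polar_penalty and atom.atom_type in (
            AtomType.DONOR_H, AtomType.ACCEPTOR, AtomType.POLAR
        ):
            contrib += abs(probe.hb_emin) * np.exp(-((d - probe.hb_r0) ** 2) / HB_GAUSS_DENOM)
        if probe.charge != 0.0 and atom.partial_charge != 0.0:
            contrib += COULOMB_CONSTANT * probe.charge * atom.partial_charge / (4.0 * d**2)

        contrib[~within] = 0.0
        E[lo_idx[0]:hi_idx[0] + 1, lo_idx[1]:hi_idx[1] + 1, lo_idx[2]:hi_idx[2] + 1] += contrib

    return MIFField(
        probe=probe.probe,
        grid=spec,
        origin=origin,
        shape=shape,
        energies=E.ravel(),
        cutoff=probe.energy_cutoff,
    )


def export_field_dx(field: MIFField, path: str | Path) -> None:
    """Write the field as OpenDX-style regular-grid text (readable by most
    molecular viewers)."""
    nx, ny, nz = field.shape
    s = field.grid.spacing
    ox, oy, oz = field.origin
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.4f} {oy:.4f} {oz:.4f}\n")
        fh.write(f"delta {s:.4f} 0 0\ndelta 0 {s:.4f} 0\ndelta 0 0 {s:.4f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {field.energies.size} data follows\n"
        )
        for i in range(0, field.energies.size, 3):
            fh.write(" ".join(f"{e:.6e}" for e in field.energies[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')


def export_field_tsv(field: MIFField, path: str | Path, *, only_retained: bool = False) -> None:
    """Write the field as flat TSV (x, y, z, E)."""
    coords = field.node_coords()
    E = field.energies
    if only_retained:
        keep = E <= field.cutoff
        coords, E = coords[keep], E[keep]
    with open(path, "w") as fh:
        fh.write("x\ty\tz\tenergy\n")
        for (x, y, z), e in zip(coords, E):
            fh.write(f"{x:.3f}\t{y:.3f}\t{z:.3f}\t{e:.6f}\n")
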