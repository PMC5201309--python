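"""Grid-independent descriptors from molecular interaction fields.

Two steps: (1) AMANDA-style node extraction keeps, per probe, an
energetically relevant and spatially spread subset of sub-cutoff lattice
nodes; (2) maximum auto-/cross-correlogram encoding (MACC2-style) turns each
probe pair's node set into a distance-binned vector whose bin value is the
largest product |E_i|·|E_j| over node pairs falling in that bin. The
correlogram depends on inter-node distances only, so the descriptor is
invariant to rigid motion of the molecule — the "grid-independent" property.

The default bin width is 0.4 Å and the default window is 75 bins (0–30 Å).
An optional consistency post-filter (a CLACC-style approximation) drops
variables whose nonzero support covers less than a set fraction of the
training molecules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chem_io import Molecule
from .mif_engine import DEFAULT_PROBES, GridSpec, MIFField, ProbeParams, compute_mif

log = logging.getLogger(__name__)

__all__ = [
    "MIFNode",
    "CorrelogramBlock",
    "BLOCK_ORDER",
    "extract_nodes",
    "encode",
    "build_descriptor_matrix",
    "consistency_filter",
]

# Fixed block ordering: 4 auto blocks then 6 cross blocks.
BLOCK_ORDER: tuple[tuple[str, str], ...] = (
    ("DRY", "DRY"), ("O", "O"), ("N1", "N1"), ("TIP", "TIP"),
    ("DRY", "O"), ("DRY", "N1"), ("DRY", "TIP"),
    ("O", "N1"), ("O", "TIP"), ("N1", "TIP"),
)

DEFAULT_BIN_WIDTH = 0.4  # Å; matches the 0.4 Å-wide pharmacophore distance ranges
DEFAULT_N_BINS = 75      # covers 0–30 Å
DEFAULT_MAX_NODES = 100


@dataclass(frozen=True)
class MIFNode:
    probe: str
    coords: np.ndarray  # (3,) Å
    energy: float       # kcal/mol, below the probe's retention cutoff


@dataclass
class CorrelogramBlock:
    probe_pair: tuple[str, str]
    bin_width: float
    values: np.ndarray                       # (n_bins,), ≥ 0
    witnesses: list[tuple[int, int] | None]  # node-index pair per bin, None if empty

    def bin_range(self, k: int) -> tuple[float, float]:
        return k * self.bin_width, (k + 1) * self.bin_width

    def label(self, k: int) -> str:
        lo, hi = self.bin_range(k)
        return f"{self.probe_pair[0]}-{self.probe_pair[1]} {lo:.1f}–{hi:.1f} Å"


def extract_nodes(mif: MIFField, max_nodes: int = DEFAULT_MAX_NODES) -> list[MIFNode]:
    """AMANDA-style extraction: energetically relevant, spatially spread nodes.

    Nodes with energy above the probe cutoff are discarded; the survivors are
    selected greedily, each step maximizing |E_i| · (1 + w·d_min(i, selected))
    with spread weight w = 0.5 Å⁻¹, starting from the deepest node. Ties break
    on the lower flat node index, so the result is deterministic.
    """
    keep = mif.energies <= mif.cutoff
    if not keep.any():
        log.warning("probe %s: no nodes below cutoff %.2f", mif.probe, mif.cutoff)
        return []
    coords = mif.node_coords()[keep]
    energies = mif.energies[keep]
    n = len(energies)
    absE = np.abs(energies)

    selected: list[int] = [int(np.argmax(absE))]
    if n > 1:
        dmin = np.linalg.norm(coords - coords[selected[0]], axis=1)
        chosen = np.zeros(n, dtype=bool)
        chosen[selected[0]] = True
        w = 0.5
        while len(selected) < min(max_nodes, n):
            score = np.where(chosen, -np.inf, absE * (1.0 + w * dmin))
            nxt = int(np.argmax(score))
            selected.append(nxt)
            chosen[nxt] = True
            np.minimum(dmin, np.linalg.norm(coords - coords[nxt], axis=1), out=dmin)
    return [MIFNode(mif.probe, coords[i], float(energies[i])) for i in selected]


def encode(
    nodes_by_probe: dict[str, list[MIFNode]],
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_bins: int = DEFAULT_N_BINS,
    *,
    truncate_beyond: bool = False,
) -> list[CorrelogramBlock]:
    """Maximum auto-/cross-correlograms over all 10 probe pairs.

    For every node pair of a probe pair, the inter-node distance d selects
    bin floor(d / bin_width) and competes with the product |E_i|·|E_j|; the
    bin keeps the maximum and a witness index pair. Auto-blocks enumerate
    unordered pairs i < j. A distance at or beyond the window raises unless
    ``truncate_beyond`` (then the pair is ignored and counted).
    """
    blocks: list[CorrelogramBlock] = []
    for p, q in BLOCK_ORDER:
        values = np.zeros(n_bins)
        witnesses: list[tuple[int, int] | None] = [None] * n_bins
        a = nodes_by_probe.get(p, [])
        b = nodes_by_probe.get(q, [])
        truncated = 0
        if a and b:
            ca = np.array([nd.coords for nd in a])
            cb = np.array([nd.coords for nd in b])
            ea = np.abs([nd.energy for nd in a])
            eb = np.abs([nd.energy for nd in b])
            d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
            prod = ea[:, None] * eb[None, :]
            if p == q:
                ii, jj = np.triu_indices(len(a), k=1)
            else:
                ii, jj = np.meshgrid(np.arange(len(a)), np.arange(len(b)), indexing="ij")
                ii, jj = ii.ravel(), jj.ravel()
            bins = np.floor(d[ii, jj] / bin_width).astype(int)
            over = bins >= n_bins
            if over.any():
                if not truncate_beyond:
                    raise ValueError(
                        f"{p}-{q}: distances up to {d[ii, jj].max():.2f} Å need "
                        f"{int(bins.max()) + 1} bins but only {n_bins} configured"
                    )
                truncated = int(over.sum())
                ii, jj, bins = ii[~over], jj[~over], bins[~over]
            for i, j, k in zip(ii, jj, bins):
                v = prod[i, j]
                if v > values[k]:
                    values[k] = v
                    witnesses[k] = (int(i), int(j))
        if truncated:
            log.debug("%s-%s: %d node pairs beyond the %d-bin window ignored",
                      p, q, truncated, n_bins)
        blocks.append(CorrelogramBlock((p, q), bin_width, values, witnesses))
    return blocks


@dataclass
class EncodingConfig:
    grid: GridSpec = field(default_factory=GridSpec)
    probes: dict[str, ProbeParams] = field(default_factory=lambda: dict(DEFAULT_PROBES))
    bin_width: float = DEFAULT_BIN_WIDTH
    n_bins: int = DEFAULT_N_BINS
    max_nodes: int = DEFAULT_MAX_NODES


def molecule_blocks(m: Molecule, config: EncodingConfig) -> list[CorrelogramBlock]:
    """MIF → nodes → correlogram blocks for one molecule."""
    nodes = {
        name: extract_nodes(compute_mif(m, probe, config.grid), config.max_nodes)
        for name, probe in config.probes.items()
    }
    return encode(nodes, config.bin_width, config.n_bins, truncate_beyond=True)


def build_descriptor_matrix(
    molecules: list[Molecule],
    config: EncodingConfig | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Stack per-molecule correlograms into X (molecules × concatenated bins).

    Returns (X, column labels, row ids). Columns follow the fixed block
    ordering (4 auto + 6 cross), n_bins each; a molecule whose field
    computation fails is dropped with a logged error.
    """
    config = config or EncodingConfig()
    rows, ids = [], []
    for m in molecules:
        try:
            blocks = molecule_blocks(m, config)
        except Exception as exc:
            log.error("molecule %s dropped from descriptor matrix: %s", m.id, exc)
            continue
        rows.append(np.concatenate([b.values for b in blocks]))
        ids.append(m.id)
    if not rows:
        raise ValueError("no molecule yielded a descriptor row")
    labels = []
    for p, q in BLOCK_ORDER:
        for k in range(config.n_bins):
            lo, hi = k * config.bin_width, (k + 1) * config.bin_width
            labels.append(f"{p}-{q} {lo:.1f}–{hi:.1f} Å")
    return np.vstack(rows), labels, ids


_PROBE_PDB_ELEMENT = {"DRY": "C", "O": "O", "N1": "N", "TIP": "S"}


def export_nodes_pdb(nodes_by_probe: dict[str, list[MIFNode]], path) -> None:
    """Write hotspot nodes as pseudo-atoms in PDB format for molecular
    viewers; the B-factor column carries |energy|."""
    with open(path, "w") as fh:
        serial = 1
        for probe in sorted(nodes_by_probe):
            el = _PROBE_PDB_ELEMENT.get(probe, "X")
            for nd in nodes_by_probe[probe]:
                x, y, z = nd.coords
                fh.write(
                    f"HETATM{serial:5d} {el:<4s}{probe[:3]:<4s}A{serial % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{abs(nd.energy):6.2f}"
                    f"          {el:>2s}\n"
                )
                serial += 1
        fh.write("END\n")


def consistency_filter(X: np.ndarray, min_support: float = 0.3) -> np.ndarray:
    """CLACC-style approximation: keep variables whose nonzero support spans
    at least ``min_support`` of the molecules. Returns kept column indices."""
    support = (X > 0).mean(axis=0)
    return np.flatnonzero(support >= min_support)
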