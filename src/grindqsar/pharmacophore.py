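"""Translate a fitted correlogram PLS model into pharmacophoric features.

Each retained correlogram variable is a probe pair plus a distance bin; the
variables with the largest |PLS coefficient| are the model's pharmacophore:
e.g. a positive O-O variable at 15.2–15.6 Å reads "two H-bond donor hotspots
15.2–15.6 Å apart raise activity". Positive and negative contributors are
reported in separate sections, since negative variables typically mark
boundary/penalty features rather than desirable interactions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .modeling import PLSModel

log = logging.getLogger(__name__)

__all__ = ["FeaturePair", "top_features", "render_table", "render_markdown"]

_LABEL_RE = re.compile(r"^(\w+)-(\w+)\s+([\d.]+)–([\d.]+)\s*Å$")


@dataclass
class FeaturePair:
    probe_pair: tuple[str, str]
    distance_range: tuple[float, float]  # [lo, hi) Å
    sign: str                            # "positive" | "negative"
    coefficient: float
    witnesses: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        expected = "positive" if self.coefficient >= 0 else "negative"
        if self.sign != expected:
            raise ValueError(f"sign {self.sign!r} contradicts coefficient {self.coefficient}")


def _parse_label(label: str) -> tuple[tuple[str, str], tuple[float, float]]:
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"unparseable descriptor label {label!r}")
    return (m.group(1), m.group(2)), (float(m.group(3)), float(m.group(4)))


def top_features(model: PLSModel, labels: list[str] | None = None, k: int = 10,
                 *, sign: str | None = None) -> list[FeaturePair]:
    """The k variables of largest |coefficient|, resolved to probe pair and
    distance bin. ``sign`` restricts to "positive" or "negative"
    contributors. Ordering is by |coefficient|, ties by label."""
    labels = labels if labels is not None else model.labels
    if labels is None:
        raise ValueError("model has no descriptor labels")
    coef = model.coefficients
    if len(labels) != len(coef):
        raise ValueError("label/coefficient length mismatch")
    idx = np.flatnonzero(np.abs(coef) > 1e-15)
    if sign == "positive":
        idx = idx[coef[idx] > 0]
    elif sign == "negative":
        idx = idx[coef[idx] < 0]
    if k > len(idx):
        log.warning("requested %d features but only %d nonzero; truncating", k, len(idx))
    ranked = sorted(idx, key=lambda j: (-abs(coef[j]), labels[j]))[:k]
    out = []
    for j in ranked:
        pair, rng = _parse_label(labels[j])
        out.append(FeaturePair(
            probe_pair=pair,
            distance_range=rng,
            sign="positive" if coef[j] >= 0 else "negative",
            coefficient=float(coef[j]),
        ))
    return out


def attach_witnesses(
    features: list[FeaturePair],
    blocks_by_molecule: dict[str, list],
    nodes_by_molecule: dict[str, dict[str, list]],
) -> list[FeaturePair]:
    """Resolve each feature's witnessing node pair per molecule.

    ``blocks_by_molecule`` maps molecule id → its CorrelogramBlock list;
    ``nodes_by_molecule`` maps molecule id → probe → MIFNode list. The
    stored witness coordinates reproduce the bin's descriptor value by
    construction (max |E_i|·|E_j| of that node pair)."""
    for f in features:
        bin_k = None
        for mol_id, blocks in blocks_by_molecule.items():
            blk = next(b for b in blocks if b.probe_pair == f.probe_pair)
            if bin_k is None:
                bin_k = int(round(f.distance_range[0] / blk.bin_width))
            w = blk.witnesses[bin_k]
            if w is None:
                continue
            i, j = w
            nodes = nodes_by_molecule[mol_id]
            a = nodes[f.probe_pair[0]][i]
            b = nodes[f.probe_pair[1]][j]
            f.witnesses[mol_id] = (a.coords, b.coords)
    return features


def render_table(features: list[FeaturePair], sep: str = "\t") -> str:
    """Deterministic delimited report: one row per feature, distances
    rounded to 0.1 Å."""
    lines = [sep.join(["probe_pair", "distance_range_A", "sign", "coefficient"])]
    for f in features:
        lo, hi = f.distance_range
        lines.append(sep.join([
            f"{f.probe_pair[0]}-{f.probe_pair[1]}",
            f"{lo:.1f}–{hi:.1f}",
            f.sign,
            f"{f.coefficient:.6g}",
        ]))
    return "\n".join(lines) + "\n"


def render_markdown(model: PLSModel, labels: list[str] | None = None, k: int = 10) -> str:
    """Markdown report with positive and negative contributors in separate
    sections, mirroring how pharmacophore distance tables are usually read."""
    pos = top_features(model, labels, k, sign="positive")
    neg = top_features(model, labels, k, sign="negative")
    parts = ["# Pharmacophoric feature report", ""]
    for title, feats in (("## Positive contributors", pos),
                         ("## Negative (boundary/penalty) features", neg)):
        parts.append(title)
        parts.append("")
        parts.append("| probe pair | distance (Å) | coefficient |")
        parts.append("|---|---|---|")
        for f in feats:
            lo, hi = f.distance_range
            parts.append(
                f"| {f.probe_pair[0]}-{f.probe_pair[1]} | {lo:.1f}–{hi:.1f} | {f.coefficient:.4g} |"
            )
        parts.append("")
    return "\n".join(parts)
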