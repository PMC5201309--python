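"""Node extraction and maximum-correlogram encoding."""

import numpy as np
import pytest

from grindqsar.grind_encode import (
    BLOCK_ORDER,
    CorrelogramBlock,
    EncodingConfig,
    MIFNode,
    build_descriptor_matrix,
    consistency_filter,
    encode,
    extract_nodes,
)
from grindqsar.mif_engine import GridSpec, MIFField


def toy_field(energies: np.ndarray, shape, cutoff=-0.5, spacing=1.0) -> MIFField:
    return MIFField(
        probe="O", grid=GridSpec(spacing=spacing, margin=0.0),
        origin=np.zeros(3), shape=shape, energies=energies.ravel(),
        cutoff=cutoff,
    )


def greedy_oracle(coords, energies, max_nodes, w=0.5):
    """Brute-force re-implementation of the spread-greedy selection."""
    absE = np.abs(energies)
    selected = [int(np.argmax(absE))]
    while len(selected) < min(max_nodes, len(energies)):
        best, best_score = None, -np.inf
        for i in range(len(energies)):
            if i in selected:
                continue
            dmin = min(np.linalg.norm(coords[i] - coords[j]) for j in selected)
            score = absE[i] * (1.0 + w * dmin)
            if score > best_score:
                best, best_score = i, score
        selected.append(best)
    return selected


class TestExtractNodes:
    def test_single_surviving_node(self):
        E = np.full((3, 3, 3), 1.0)
        E[1, 1, 1] = -2.0
        nodes = extract_nodes(toy_field(E, (3, 3, 3)), 10)
        assert len(nodes) == 1
        np.testing.assert_allclose(nodes[0].coords, [1.0, 1.0, 1.0])
        assert nodes[0].energy == -2.0

    def test_all_above_cutoff_empty(self, caplog):
        E = np.full((2, 2, 2), -0.1)
        with caplog.at_level("WARNING"):
            assert extract_nodes(toy_field(E, (2, 2, 2)), 5) == []

    def test_matches_bruteforce_greedy(self):
        rng = np.random.default_rng(9)
        E = -rng.uniform(0.6, 5.0, size=(20, 1, 1))
        field = toy_field(E, (20, 1, 1))
        nodes = extract_nodes(field, 5)
        coords = field.node_coords()
        oracle = greedy_oracle(coords, field.energies, 5)
        expected = [tuple(coords[i]) for i in oracle]
        assert [tuple(n.coords) for n in nodes] == expected


def brute_force_blocks(nodes_by_probe, bin_width, n_bins):
    """Exhaustive O(n²) pair-scan oracle for every probe pair."""
    out = {}
    for p, q in BLOCK_ORDER:
        vals = np.zeros(n_bins)
        a, b = nodes_by_probe.get(p, []), nodes_by_probe.get(q, [])
        pairs = (
            [(i, j) for i in range(len(a)) for j in range(i + 1, len(a))]
            if p == q
            else [(i, j) for i in range(len(a)) for j in range(len(b))]
        )
        src_b = a if p == q else b
        for i, j in pairs:
            d = np.linalg.norm(a[i].coords - src_b[j].coords)
            k = int(d // bin_width)
            if k < n_bins:
                vals[k] = max(vals[k], abs(a[i].energy) * abs(src_b[j].energy))
        out[(p, q)] = vals
    return out


class TestEncode:
    def test_planted_donor_pair_lands_in_its_bin(self):
        """Two donor-probe hotspots 15.4 Å apart with energies −2 and −3:
        the O-O correlogram holds 6.0 in the 15.2–15.6 Å bin and 0 elsewhere."""
        nodes = {
            "O": [
                MIFNode("O", np.array([0.0, 0.0, 0.0]), -2.0),
                MIFNode("O", np.array([15.4, 0.0, 0.0]), -3.0),
            ]
        }
        blocks = {b.probe_pair: b for b in encode(nodes, 0.4, 75)}
        oo = blocks[("O", "O")]
        k = int(15.4 // 0.4)
        assert oo.bin_range(k) == (pytest.approx(15.2), pytest.approx(15.6))
        assert oo.values[k] == pytest.approx(6.0)
        assert np.count_nonzero(oo.values) == 1

    def test_single_node_auto_block_zero(self):
        nodes = {"O": [MIFNode("O", np.zeros(3), -2.0)]}
        blocks = {b.probe_pair: b for b in encode(nodes, 0.4, 10)}
        assert not blocks[("O", "O")].values.any()

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(17)
        nodes = {
            p: [MIFNode(p, rng.uniform(0, 12, 3), -rng.uniform(0.5, 4))
                for _ in range(8)]
            for p in ("DRY", "O", "N1", "TIP")
        }
        blocks = encode(nodes, 0.4, 75)
        oracle = brute_force_blocks(nodes, 0.4, 75)
        for b in blocks:
            np.testing.assert_array_equal(b.values, oracle[b.probe_pair])

    def test_witnesses_reproduce_values(self):
        rng = np.random.default_rng(23)
        nodes = {
            "O": [MIFNode("O", rng.uniform(0, 10, 3), -rng.uniform(1, 3))
                  for _ in range(6)],
            "N1": [MIFNode("N1", rng.uniform(0, 10, 3), -rng.uniform(1, 3))
                   for _ in range(5)],
        }
        for b in encode(nodes, 0.4, 40):
            a = nodes.get(b.probe_pair[0], [])
            c = nodes.get(b.probe_pair[1], [])
            for k, v in enumerate(b.values):
                if v > 0:
                    i, j = b.witnesses[k]
                    assert v == abs(a[i].energy) * abs(c[j].energy)

    def test_window_overflow_raises_unless_truncated(self):
        nodes = {"O": [MIFNode("O", np.zeros(3), -1.0),
                       MIFNode("O", np.array([30.0, 0, 0]), -1.0)]}
        with pytest.raises(ValueError, match="bins"):
            encode(nodes, 0.4, 20)
        blocks = encode(nodes, 0.4, 20, truncate_beyond=True)
        assert not any(b.values.any() for b in blocks)

    def test_deepening_energy_never_decreases_bins(self):
        rng = np.random.default_rng(31)
        nodes = {"N1": [MIFNode("N1", rng.uniform(0, 8, 3), -rng.uniform(1, 2))
                        for _ in range(6)]}
        base = {b.probe_pair: b.values for b in encode(nodes, 0.4, 40)}
        deeper = dict(nodes)
        deeper["N1"] = list(nodes["N1"])
        deeper["N1"][2] = MIFNode("N1", nodes["N1"][2].coords, -5.0)
        after = {b.probe_pair: b.values for b in encode(deeper, 0.4, 40)}
        assert (after[("N1", "N1")] >= base[("N1", "N1")] - 1e-12).all()

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(41)
        pts = rng.uniform(0, 10, (7, 3))
        E = -rng.uniform(1, 3, 7)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.uniform(-5, 5, 3)
        a = {"O": [MIFNode("O", p, e) for p, e in zip(pts, E)]}
        b = {"O": [MIFNode("O", Q @ p + t, e) for p, e in zip(pts, E)]}
        va = {blk.probe_pair: blk.values for blk in encode(a, 0.4, 60)}
        vb = {blk.probe_pair: blk.values for blk in encode(b, 0.4, 60)}
        np.testing.assert_allclose(va[("O", "O")], vb[("O", "O")], atol=1e-9)


@pytest.fixture(scope="module")
def tiny_library():
    from grindqsar.synthetic import GeneratorConfig, generate_library
    mols, _ = generate_library(GeneratorConfig(n_molecules=3, seed=5))
    return mols


class TestDescriptorMatrix:
    def test_duplicated_molecule_identical_rows(self, tiny_library):
        cfg = EncodingConfig()
        X, labels, ids = build_descriptor_matrix(
            [tiny_library[0], tiny_library[0]], cfg
        )
        np.testing.assert_array_equal(X[0], X[1])

    def test_column_labels(self, tiny_library):
        from grindqsar.grind_encode import DEFAULT_N_BINS
        # label contract: first bin of the O-N1 block
        offset = BLOCK_ORDER.index(("O", "N1")) * DEFAULT_N_BINS
        _, labels, _ = build_descriptor_matrix(tiny_library[:1], EncodingConfig())
        assert labels[offset] == "O-N1 0.0–0.4 Å"

    def test_planted_acceptor_pair_hits_its_bin(self):
        """Acceptor atoms ~21.4 Å apart → nonzero N1-N1 value in the
        21.2–21.6 Å bin."""
        from grindqsar.pipeline import paper_like_encoding_config
        from grindqsar.synthetic import GeneratorConfig, generate_library
        cfg = GeneratorConfig(
            n_molecules=6, seed=2,
            planted_pairs=[(("N1", "N1"), 21.4, 1.0)],
            pattern_prob=1.0,
        )
        mols, table = generate_library(cfg)
        X, labels, _ = build_descriptor_matrix(mols, paper_like_encoding_config())
        j = labels.index("N1-N1 21.2–21.6 Å")
        assert (X[:, j] > 0).all()


class TestConsistencyFilter:
    def test_support_threshold(self):
        X = np.zeros((10, 3))
        X[:, 0] = 1.0          # full support
        X[:5, 1] = 1.0         # 50 %
        X[:2, 2] = 1.0         # 20 %
        kept = consistency_filter(X, min_support=0.3)
        assert kept.tolist() == [0, 1]


class TestExports:
    def test_pseudo_atom_pdb(self, tmp_path):
        from grindqsar.grind_encode import export_nodes_pdb
        nodes = {"O": [MIFNode("O", np.array([1.0, 2.0, 3.0]), -2.5)],
                 "DRY": [MIFNode("DRY", np.array([-1.0, 0.0, 4.5]), -0.8)]}
        p = tmp_path / "nodes.pdb"
        export_nodes_pdb(nodes, p)
        text = p.read_text()
        assert text.count("HETATM") == 2
        assert "END" in text
        assert "1.000   2.000   3.000" in text
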