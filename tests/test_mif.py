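"""Molecular interaction field physics: closed forms, oracles, equivariance."""

import numpy as np
import pytest

from grindqsar.chem_io import Atom, AtomType, Molecule
from grindqsar.mif_engine import (
    COULOMB_CONSTANT,
    DEFAULT_PROBES,
    GridSpec,
    ProbeParams,
    build_grid,
    compute_mif,
    probe_energy,
)

from conftest import single_atom_molecule


def lj_only_probe(A: float, B: float) -> ProbeParams:
    return ProbeParams(probe="TIP", lj_table={"X": (A, B)}, hb_partner=None,
                       energy_cutoff=-0.01)


def naive_energy(probe: ProbeParams, point, m: Molecule) -> float:
    """Independent per-atom summation oracle (plain Python loop)."""
    E = 0.0
    for atom in m.atoms:
        r = float(np.linalg.norm(np.asarray(point, float) - atom.coords))
        r = max(r, 0.5)
        if r > 8.0:
            continue
        partner = probe.hb_partner is not None and (
            atom.atom_type is probe.hb_partner
            or (probe.hb_partner is AtomType.ACCEPTOR and atom.acceptor_flag)
        )
        if partner:
            E += probe.hb_emin * np.exp(-((r - probe.hb_r0) ** 2) / 0.25)
        else:
            A, B = probe.lj_coeffs(atom.element)
            if probe.hydrophobe_only_lj and atom.atom_type is not AtomType.HYDROPHOBE:
                E += A / r**12
            else:
                E += A / r**12 - B / r**6
        if probe.polar_penalty and atom.atom_type in (
            AtomType.DONOR_H, AtomType.ACCEPTOR, AtomType.POLAR
        ):
            E += abs(probe.hb_emin) * np.exp(-((r - probe.hb_r0) ** 2) / 0.25)
        if probe.charge and atom.partial_charge:
            E += COULOMB_CONSTANT * probe.charge * atom.partial_charge / (4.0 * r * r)
    return E


class TestGrid:
    def test_single_atom_node_count(self):
        m = single_atom_molecule()
        origin, shape = build_grid(m, GridSpec(spacing=0.5, margin=4.0))
        assert shape == (17, 17, 17)
        np.testing.assert_allclose(origin, [-4.0, -4.0, -4.0])

    def test_coarser_spacing_halves_axis_counts(self):
        m = single_atom_molecule()
        _, fine = build_grid(m, GridSpec(spacing=0.5, margin=4.0))
        _, coarse = build_grid(m, GridSpec(spacing=1.0, margin=4.0))
        for f, c in zip(fine, coarse):
            assert abs(f - 2 * c) <= 2

    def test_invalid_spacing(self):
        with pytest.raises(ValueError):
            GridSpec(spacing=-1.0)


class TestClosedForms:
    def test_lj_minimum_depth(self):
        """At r = (2A/B)^(1/6) the 12-6 potential equals −B²/(4A)."""
        A, B = 4e5, 800.0
        m = Molecule("x", [Atom("Q", np.zeros(3), 0.0, AtomType.OTHER)])
        probe = lj_only_probe(A, B)
        r_min = (2 * A / B) ** (1 / 6)
        E = probe_energy(probe, np.array([r_min, 0.0, 0.0]), m)
        assert E == pytest.approx(-B**2 / (4 * A), abs=1e-9)

    def test_coulomb_with_distance_dielectric(self):
        """Unit charges at 2 Å with ε = 4r: 332.0/(8·2) = 20.75 kcal/mol."""
        m = Molecule("q", [Atom("Q", np.zeros(3), 1.0, AtomType.OTHER)])
        probe = ProbeParams(probe="O", lj_table={"X": (0.0, 0.0)},
                            hb_partner=None, charge=1.0, energy_cutoff=-0.01)
        E = probe_energy(probe, np.array([2.0, 0.0, 0.0]), m)
        assert E == pytest.approx(20.75, abs=1e-9)

    def test_far_field_decays(self):
        m = single_atom_molecule()
        for probe in DEFAULT_PROBES.values():
            assert abs(probe_energy(probe, np.array([50.0, 0, 0]), m)) < 1e-3

    def test_monotone_decay_beyond_minimum(self):
        A, B = 4e5, 800.0
        m = Molecule("x", [Atom("Q", np.zeros(3), 0.0, AtomType.OTHER)])
        probe = lj_only_probe(A, B)
        r_min = (2 * A / B) ** (1 / 6)
        radii = np.linspace(r_min + 0.05, 7.9, 40)
        E = [abs(probe_energy(probe, np.array([r, 0, 0]), m)) for r in radii]
        assert all(a >= b - 1e-12 for a, b in zip(E, E[1:]))


class TestOracleEquivalence:
    @pytest.mark.parametrize("probe_name", ["DRY", "O", "N1", "TIP"])
    def test_matches_naive_per_atom_loop(self, probe_name, methanol):
        rng = np.random.default_rng(11)
        probe = DEFAULT_PROBES[probe_name]
        for _ in range(25):
            pt = rng.uniform(-4, 4, 3)
            assert probe_energy(probe, pt, methanol) == pytest.approx(
                naive_energy(probe, pt, methanol), rel=1e-9, abs=1e-9
            )

    def test_lattice_energies_match_pointwise_path(self, methanol):
        probe = DEFAULT_PROBES["O"]
        spec = GridSpec(spacing=1.5, margin=3.0)
        field = compute_mif(methanol, probe, spec)
        coords = field.node_coords()
        idx = np.random.default_rng(0).choice(len(coords), 40, replace=False)
        for i in idx:
            assert field.energies[i] == pytest.approx(
                probe_energy(probe, coords[i], methanol), abs=1e-9
            )


class TestEquivariance:
    def test_rigid_motion(self, acetone):
        rng = np.random.default_rng(5)
        # random rotation via QR
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        t = rng.uniform(-5, 5, 3)
        moved = Molecule(
            "moved",
            [
                Atom(a.element, Q @ a.coords + t, a.partial_charge, a.atom_type,
                     a.acceptor_flag)
                for a in acetone.atoms
            ],
            acetone.bonds,
        )
        probe = DEFAULT_PROBES["N1"]
        for _ in range(20):
            pt = rng.uniform(-4, 4, 3)
            assert probe_energy(probe, Q @ pt + t, moved) == pytest.approx(
                probe_energy(probe, pt, acetone), abs=1e-6
            )


class TestProbeSemantics:
    def test_carbonyl_gating(self, acetone):
        """The carbonyl O is an acceptor: the acceptor-mapping probe (N1)
        digs an H-bond well there; the donor-mapping probe (O) sees no
        H-bond term because acetone has no donor."""
        o_atom = [a for a in acetone.atoms if a.element == "O"][0]
        assert o_atom.atom_type is AtomType.ACCEPTOR
        # approach point near the carbonyl oxygen at the H-bond optimum
        pt = o_atom.coords + np.array([0.0, 0.0, 1.9])
        e_n1 = probe_energy(DEFAULT_PROBES["N1"], pt, acetone)
        e_o = probe_energy(DEFAULT_PROBES["O"], pt, acetone)
        assert e_n1 < e_o - 2.0  # the −4 kcal/mol well only for N1

    def test_dry_prefers_face_of_benzene(self, benzene):
        centroid = benzene.coords[[a.element == "C" for a in benzene.atoms]].mean(axis=0)
        # ring normal from two C-C vectors
        cs = benzene.coords[[a.element == "C" for a in benzene.atoms]]
        normal = np.cross(cs[1] - cs[0], cs[2] - cs[0])
        normal /= np.linalg.norm(normal)
        in_plane = cs[0] - centroid
        in_plane /= np.linalg.norm(in_plane)
        d = 3.5
        e_face = probe_energy(DEFAULT_PROBES["DRY"], centroid + d * normal, benzene)
        e_edge = probe_energy(DEFAULT_PROBES["DRY"], centroid + d * in_plane, benzene)
        assert e_face < e_edge

    def test_yaml_probe_overrides(self, tmp_path):
        from grindqsar.mif_engine import load_probe_params
        p = tmp_path / "probes.yaml"
        p.write_text("O:\n  energy_cutoff: -3.5\n  hb_emin: -5.0\nDRY:\n  energy_cutoff: -0.9\n")
        probes = load_probe_params(p)
        assert probes["O"].energy_cutoff == -3.5
        assert probes["O"].hb_emin == -5.0
        assert probes["DRY"].energy_cutoff == -0.9
        assert probes["N1"].energy_cutoff == DEFAULT_PROBES["N1"].energy_cutoff
        with pytest.raises(ValueError, match="unknown probe"):
            p.write_text("XX:\n  charge: 1\n")
            load_probe_params(p)

    def test_field_tsv_export(self, methanol, tmp_path):
        from grindqsar.mif_engine import export_field_tsv
        field = compute_mif(methanol, DEFAULT_PROBES["O"], GridSpec(2.0, 2.0))
        out = tmp_path / "field.tsv"
        export_field_tsv(field, out, only_retained=True)
        lines = out.read_text().strip().splitlines()
        assert lines[0] == "x\ty\tz\tenergy"
        assert all(float(l.split("\t")[3]) <= field.cutoff for l in lines[1:])

    def test_untyped_molecule_rejected(self):
        m = Molecule("u", [Atom("C", np.zeros(3), 0.0, AtomType.OTHER)])
        with pytest.raises(ValueError, match="untyped"):
            compute_mif(m, DEFAULT_PROBES["DRY"], GridSpec(spacing=1.0, margin=2.0))


class TestDXExport:
    def test_opendx_header_and_item_count(self, methanol, tmp_path):
        from grindqsar.mif_engine import export_field_dx
        field = compute_mif(methanol, DEFAULT_PROBES["O"], GridSpec(2.0, 2.0))
        p = tmp_path / "f.dx"
        export_field_dx(field, p)
        lines = p.read_text().splitlines()
        assert lines[0].startswith("object 1 class gridpositions counts")
        n_items = int([l for l in lines if "items" in l][0].split("items")[1].split()[0])
        assert n_items == field.energies.size
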