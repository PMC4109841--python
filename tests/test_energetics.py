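import numpy as np
import pytest

from ktgo import _kernels
from ktgo.energetics import (
    bonded_energy_forces,
    nonbonded_energy_forces,
    switching_function,
    total_energy,
    total_energy_forces,
)
from ktgo.fixtures import HelixSpec, make_ideal_helix
from ktgo.geometry import axis_rotation
from ktgo.go_builder import build_go_model
from ktgo.potentials import GoPotential


def brute_force_nonbonded(model, coords):
    """All-pairs loop over every well and repulsive term (the oracle)."""
    r_on, r_off = model.params.switch_r_on, model.params.switch_r_off

    def switch(r):
        if r <= r_on:
            return 1.0
        if r >= r_off:
            return 0.0
        a = r_off**2 - r**2
        return a * a * (r_off**2 + 2 * r**2 - 3 * r_on**2) / (r_off**2 - r_on**2) ** 3

    e = 0.0
    for rec in list(model.contacts) + list(model.hbonds):
        r = np.linalg.norm(coords[rec.i] - coords[rec.j])
        x6 = (rec.r_native / r) ** 6
        e += rec.epsilon * (x6 * x6 - 2 * x6) * switch(r)
    for (i, j), sigma in zip(model.repulsive_pairs, model.repulsive_sigma):
        r = np.linalg.norm(coords[i] - coords[j])
        e += model.params.eps_repulsive * (sigma / r) ** 12 * switch(r)
    return e


class TestBondedTerms:
    def test_native_bonded_energy_is_zero(self, bundle_model):
        eb, _ = bonded_energy_forces(bundle_model, bundle_model.native_coords)
        assert eb.bond + eb.angle + eb.improper == pytest.approx(0.0, abs=1e-15)
        assert eb.dihedral == pytest.approx(0.0, abs=1e-12)

    def test_single_stretched_bond_closed_form(self):
        aa = make_ideal_helix(HelixSpec(2))
        model = build_go_model(aa)
        # stretch the terminal CA-CA bond along its axis by delta
        bond = next(t for t in model.bonded.bonds
                    if model.cg.beads[t.i].site_type == model.cg.beads[t.j].site_type == "CA")
        coords = model.native_coords.copy()
        axis = coords[bond.j] - coords[bond.i]
        axis /= np.linalg.norm(axis)
        delta = 0.2
        # translate residue 2 rigidly along the bond axis: only this one bond
        # leaves its equilibrium, every angle is unchanged
        sc_j = model.cg.bead_index(2, "SC")
        coords[bond.j] += delta * axis
        coords[sc_j] += delta * axis
        eb, forces = bonded_energy_forces(model, coords)
        assert eb.bond == pytest.approx(bond.k * delta**2, rel=1e-9)
        restoring = forces[bond.j] @ axis
        assert restoring == pytest.approx(-2 * bond.k * delta, rel=1e-9)

    def test_coincident_bonded_beads_error(self, bundle_model):
        coords = bundle_model.native_coords.copy()
        b = bundle_model.bonded.bonds[0]
        coords[b.j] = coords[b.i]
        with pytest.raises(ValueError, match="coincident"):
            bonded_energy_forces(bundle_model, coords)


class TestForceConsistency:
    def test_forces_match_finite_differences(self, bundle_model):
        model = bundle_model
        rng = np.random.default_rng(42)
        h = 1e-5
        for _ in range(5):
            x = model.native_coords + rng.normal(0, 0.15, (model.n_beads, 3))
            _, F = total_energy_forces(model, x)
            for _ in range(20):
                i = rng.integers(0, model.n_beads)
                c = rng.integers(0, 3)
                xp = x.copy(); xp[i, c] += h
                xm = x.copy(); xm[i, c] -= h
                fd = -(total_energy(model, xp) - total_energy(model, xm)) / (2 * h)
                assert F[i, c] == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestNonbonded:
    def test_contact_minimum_at_native_distance(self, bundle_model):
        c = bundle_model.contacts[0]
        coords = np.zeros((bundle_model.n_beads, 3))
        # spread the other beads far away so only this pair interacts
        for k in range(bundle_model.n_beads):
            coords[k] = [1000.0 + 50.0 * k, 0.0, 0.0]
        coords[c.i] = [0.0, 0.0, 0.0]
        coords[c.j] = [c.r_native, 0.0, 0.0]
        eb, forces = nonbonded_energy_forces(bundle_model, coords)
        assert eb.lj_native == pytest.approx(-c.epsilon, rel=1e-12)
        assert np.abs(forces[c.i]).max() == pytest.approx(0.0, abs=1e-10)

    def test_zero_beyond_cutoff(self, bundle_model):
        c = bundle_model.contacts[0]
        coords = np.zeros((bundle_model.n_beads, 3))
        for k in range(bundle_model.n_beads):
            coords[k] = [5000.0 + 100.0 * k, 0.0, 0.0]
        coords[c.i] = [0.0, 0.0, 0.0]
        coords[c.j] = [23.0, 0.0, 0.0]
        eb, forces = nonbonded_energy_forces(bundle_model, coords)
        assert eb.lj_native == 0.0
        assert np.abs(forces[c.i]).max() == 0.0

    def test_matches_brute_force_all_pairs(self, bundle_model):
        rng = np.random.default_rng(3)
        x = bundle_model.native_coords + rng.normal(0, 0.3, (bundle_model.n_beads, 3))
        eb, _ = nonbonded_energy_forces(bundle_model, x)
        e_ref = brute_force_nonbonded(bundle_model, x)
        assert eb.lj_native + eb.hbond + eb.lj_repulsive == pytest.approx(e_ref, abs=1e-10)

    def test_switching_continuity(self):
        r_on, r_off = 18.0, 23.0
        for edge in (r_on, r_off):
            s_lo, _ = switching_function(edge - 1e-9, r_on, r_off)
            s_hi, _ = switching_function(edge + 1e-9, r_on, r_off)
            assert abs(float(s_lo) - float(s_hi)) < 1e-8
        s, ds = switching_function(np.array([10.0, 20.0, 30.0]), r_on, r_off)
        assert s[0] == 1.0 and ds[0] == 0.0
        assert 0 < s[1] < 1 and ds[1] < 0
        assert s[2] == 0.0 and ds[2] == 0.0

    def test_small_distance_capped_with_warning(self, bundle_model):
        coords = bundle_model.native_coords.copy()
        i, j = bundle_model.repulsive_pairs[0]
        coords[j] = coords[i] + 1e-4
        with pytest.warns(RuntimeWarning, match="capped"):
            eb, _ = nonbonded_energy_forces(bundle_model, coords)
        assert np.isfinite(eb.total)


class TestTotalEnergy:
    def test_translation_invariance(self, bundle_model):
        x = bundle_model.native_coords
        e0 = total_energy(bundle_model, x)
        e1 = total_energy(bundle_model, x + np.array([7.0, -3.0, 11.0]))
        assert e1 == pytest.approx(e0, abs=1e-10)

    def test_rotation_invariance(self, bundle_model):
        rng = np.random.default_rng(1)
        x = bundle_model.native_coords + rng.normal(0, 0.1, (bundle_model.n_beads, 3))
        R = axis_rotation(np.array([1.0, 1.0, -2.0]), 0.7)
        assert total_energy(bundle_model, x @ R.T) == pytest.approx(
            total_energy(bundle_model, x), rel=1e-10)

    def test_net_force_and_torque_vanish(self, bundle_model):
        rng = np.random.default_rng(2)
        x = bundle_model.native_coords + rng.normal(0, 0.2, (bundle_model.n_beads, 3))
        _, F = total_energy_forces(bundle_model, x)
        assert np.abs(F.sum(axis=0)).max() < 1e-8
        assert np.abs(np.cross(x, F).sum(axis=0)).max() < 1e-8

    def test_breakdown_total_is_component_sum(self, bundle_model):
        rng = np.random.default_rng(4)
        x = bundle_model.native_coords + rng.normal(0, 0.2, (bundle_model.n_beads, 3))
        eb, _ = total_energy_forces(bundle_model, x)
        manual = (eb.bond + eb.angle + eb.dihedral + eb.improper
                  + eb.lj_native + eb.lj_repulsive + eb.hbond)
        assert eb.total == pytest.approx(manual, rel=1e-12)

    def test_energy_at_native_is_well_depth_sum(self, bundle_model):
        # every well sits at its minimum and inside r_on, so the nonbonded
        # attraction equals -(sum of contact and hbond epsilons)
        eb, _ = total_energy_forces(bundle_model, bundle_model.native_coords)
        expected = -(sum(c.epsilon for c in bundle_model.contacts)
                     + sum(h.epsilon for h in bundle_model.hbonds))
        assert eb.lj_native + eb.hbond == pytest.approx(expected, rel=1e-12)


class TestCompiledKernels:
    def test_kernel_agrees_with_reference(self, bundle_model):
        pot = GoPotential(bundle_model)
        rng = np.random.default_rng(9)
        for _ in range(5):
            x = bundle_model.native_coords + rng.normal(0, 0.25,
                                                        (bundle_model.n_beads, 3))
            e_k, f_k = pot.energy_forces(x)
            eb, f_ref = total_energy_forces(bundle_model, x)
            assert e_k == pytest.approx(eb.total, rel=1e-12, abs=1e-10)
            np.testing.assert_allclose(f_k, f_ref, atol=1e-10)

    def test_kernel_switch_matches_reference(self):
        for r in (5.0, 18.0, 19.7, 22.9, 23.0, 30.0):
            s, ds = _kernels._switch(r, 18.0, 23.0)
            s_ref, ds_ref = switching_function(np.array([r]), 18.0, 23.0)
            assert s == pytest.approx(float(s_ref[0]), abs=1e-14)
            assert ds == pytest.approx(float(ds_ref[0]), abs=1e-14)
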