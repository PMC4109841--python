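import numpy as np
import pytest

from ktgo.constants import KB
from ktgo.fixtures import HelixSpec, make_ideal_helix
from ktgo.go_builder import build_go_model
from ktgo.parameters import MinConfig, RexConfig, SimConfig
from ktgo.potentials import DoubleWell1D, Harmonic1D
from ktgo.simulate import (
    LangevinIntegrator,
    langevin_dynamics,
    metropolis_swap_probability,
    minimize,
    replica_exchange,
    tune_nscale,
)


class TestMinimize:
    def test_energy_never_increases_along_sd_trace(self, bundle_model, minimized_bundle):
        _, history = minimized_bundle
        totals = [h.total for h in history]
        assert totals[-1] <= totals[0]
        # the steepest-descent stage (first sd_steps entries) is monotone
        sd_part = totals[:11]
        assert all(b <= a + 1e-12 for a, b in zip(sd_part, sd_part[1:]))

    def test_already_minimal_dimer_stays_put(self):
        aa = make_ideal_helix(HelixSpec(2))
        model = build_go_model(aa)
        x0, _ = minimize(model, cfg=MinConfig(sd_steps=50, qn_steps=200))
        # re-minimizing from the optimum must not move anything appreciably
        x1, history = minimize(model, x0, MinConfig(sd_steps=10, qn_steps=50))
        assert np.abs(x1 - x0).max() < 1e-4
        assert history[-1].total == pytest.approx(history[0].total, abs=1e-8)

    def test_perturbed_dimer_recovers_bond_length(self):
        aa = make_ideal_helix(HelixSpec(2))
        model = build_go_model(aa)
        bond = model.bonded.bonds[0]
        x = model.native_coords.copy()
        rng = np.random.default_rng(0)
        x += rng.normal(0, 0.05, x.shape)
        xmin, _ = minimize(model, x, MinConfig(sd_steps=20, qn_steps=200))
        r = np.linalg.norm(xmin[bond.i] - xmin[bond.j])
        assert r == pytest.approx(bond.r0, abs=1e-4)

    def test_nonfinite_start_rejected(self, bundle_model):
        x = bundle_model.native_coords.copy()
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            minimize(bundle_model, x)


class TestLangevinDynamics:
    def test_nve_limit_conserves_energy(self, bundle_model, minimized_bundle):
        xmin, _ = minimized_bundle
        res = langevin_dynamics(bundle_model, xmin,
                                SimConfig(friction=0.0, n_steps=10000,
                                          save_interval=50, seed=3))
        E = res.total_energy
        n10 = max(len(E) // 10, 1)
        drift = abs(E[-n10:].mean() - E[:n10].mean())
        thermal_scale = res.kinetic_energy.std()
        assert drift < 0.002 * thermal_scale

    def test_seeded_determinism_bit_for_bit(self, bundle_model, minimized_bundle):
        xmin, _ = minimized_bundle
        cfg = SimConfig(n_steps=500, save_interval=50, seed=7)
        a = langevin_dynamics(bundle_model, xmin, cfg)
        b = langevin_dynamics(bundle_model, xmin, cfg)
        np.testing.assert_array_equal(a.trajectory.positions, b.trajectory.positions)
        np.testing.assert_array_equal(a.potential_energy, b.potential_energy)

    def test_python_and_kernel_paths_agree(self, bundle_model, minimized_bundle):
        from ktgo.potentials import GoPotential
        xmin, _ = minimized_bundle

        class NoKernel:
            """GoPotential minus its compiled fast path."""
            def __init__(self, model):
                self._pot = GoPotential(model)
                self.masses = self._pot.masses

            def energy_forces(self, x):
                return self._pot.energy_forces(x)

        cfg = SimConfig(n_steps=200, save_interval=20, seed=5)
        fast = langevin_dynamics(bundle_model, xmin, cfg)
        slow = langevin_dynamics(NoKernel(bundle_model), xmin.copy(), cfg)
        np.testing.assert_allclose(slow.trajectory.positions,
                                   fast.trajectory.positions, atol=1e-9)

    def test_thermostat_holds_bath_temperature(self, bundle_model, minimized_bundle):
        xmin, _ = minimized_bundle
        res = langevin_dynamics(bundle_model, xmin,
                                SimConfig(friction=5.0, temperature=300.0,
                                          n_steps=50000, save_interval=50, seed=11))
        mean_T = res.kinetic_temperature[20:].mean()
        assert mean_T == pytest.approx(300.0, rel=0.03)

    def test_harmonic_bead_position_variance(self):
        pot = Harmonic1D(k=1.0, mass=12.0)
        integ = LangevinIntegrator(pot, np.zeros((1, 3)),
                                   SimConfig(friction=5.0, temperature=300.0, seed=5))
        frames, _, _, _ = integ.run(200000, save_interval=10)
        x = frames[1000:, 0, 0]
        assert x.var() == pytest.approx(KB * 300.0 / pot.k, rel=0.05)

    def test_divergence_aborts_with_diagnostic(self, bundle_model):
        # an absurd timestep blows the integration up immediately
        x = bundle_model.native_coords
        with pytest.raises(RuntimeError, match="diverged"):
            langevin_dynamics(bundle_model, x,
                              SimConfig(dt=10.0, friction=0.0, n_steps=2000,
                                        save_interval=100, seed=0))


class TestReplicaExchange:
    def test_identical_temperatures_always_accept(self, bundle_model, minimized_bundle):
        xmin, _ = minimized_bundle
        # two replicas at the same temperature: Delta is exactly zero
        rex = RexConfig(temperatures=[300.0, 300.0 + 1e-9],
                        steps_per_exchange=50, n_rounds=20, seed=1)
        sim = SimConfig(save_interval=50, seed=1)
        res = replica_exchange(bundle_model, rex, sim, coords=xmin)
        assert res.attempts[0] > 0
        assert res.accepts[0] == res.attempts[0]

    def test_metropolis_probability_closed_form(self):
        b1, b2 = 1.0 / (KB * 300.0), 1.0 / (KB * 400.0)
        e1, e2 = -10.0, -4.0
        expected = min(1.0, np.exp((b1 - b2) * (e1 - e2)))
        assert metropolis_swap_probability(b1, b2, e1, e2) == pytest.approx(expected)
        assert metropolis_swap_probability(b1, b2, 5.0, -5.0) == 1.0
        assert metropolis_swap_probability(b1, b1, 1.0, 2.0) == 1.0

    def test_double_well_occupancy_matches_quadrature(self):
        import emcee.autocorr as autocorr
        dw = DoubleWell1D(height=1.5, a=1.0, tilt=0.5, mass=1.0)
        temps = [300.0, 430.0, 600.0, 850.0]
        rex = RexConfig(temperatures=temps, steps_per_exchange=250,
                        n_rounds=600, seed=2)
        sim = SimConfig(friction=5.0, save_interval=25, seed=2)
        res = replica_exchange(dw, rex, sim, coords=np.array([[-1.0, 0.0, 0.0]]))
        for k, T in enumerate(temps):
            x = res.trajectories[k].positions[:, 0, 0]
            ind = (x[len(x) // 5:] > 0).astype(float)
            tau = max(float(autocorr.integrated_time(ind, c=5, tol=0)[0]), 1.0)
            sigma = max(float(ind.std(ddof=1) * np.sqrt(tau / len(ind))), 1e-4)
            exact = dw.boltzmann_occupancy(T)
            assert abs(ind.mean() - exact) < 3.0 * sigma

    def test_trajectories_are_per_temperature(self, bundle_model, minimized_bundle):
        xmin, _ = minimized_bundle
        rex = RexConfig(temperatures=[250.0, 400.0], steps_per_exchange=100,
                        n_rounds=5, seed=3)
        sim = SimConfig(save_interval=100, seed=3)
        res = replica_exchange(bundle_model, rex, sim, coords=xmin)
        assert len(res.trajectories) == 2
        assert res.trajectories[0].config["temperature"] == 250.0
        assert res.trajectories[0].n_frames == 5


class TestTuneNscale:
    def test_converges_immediately_when_tm_already_on_target(self, bundle):
        calls = []

        def estimator(nscale):
            calls.append(nscale)
            return 300.0

        result = tune_nscale(bundle, target_tm=300.0, tol=15.0,
                             rex=RexConfig(temperatures=[150.0, 450.0]),
                             tm_estimator=estimator)
        assert result.converged
        assert result.history == [(1.0, 300.0)]
        assert calls == [1.0]

    def test_multiplicative_damped_update_converges(self, bundle):
        # a monotone synthetic response: Tm proportional to nScale
        def estimator(nscale):
            return 250.0 * nscale

        result = tune_nscale(bundle, target_tm=330.0, tol=5.0,
                             rex=RexConfig(temperatures=[150.0, 450.0]),
                             tm_estimator=estimator, max_iterations=12)
        assert result.converged
        assert result.nscale == pytest.approx(330.0 / 250.0, rel=0.03)
        nscales = [h[0] for h in result.history]
        assert nscales[0] == 1.0   # default initial guess: no scaling
        assert all(b > a for a, b in zip(nscales, nscales[1:]))

    def test_target_outside_ladder_rejected(self, bundle):
        with pytest.raises(ValueError, match="ladder"):
            tune_nscale(bundle, target_tm=900.0,
                        rex=RexConfig(temperatures=[150.0, 450.0]))
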