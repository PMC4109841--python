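"""Minimization, Langevin dynamics, temperature replica exchange, nScale tuning.

Langevin dynamics uses a BBK discretization: half-kick / drift / half-kick
with friction gamma (the CHARMM "FBETA" collision frequency) and a matched
Gaussian random force of variance 2 gamma m k_B T / dt applied in both half
kicks, so the gamma = 0 limit is exactly velocity Verlet.  All stochastic
operations are bit-reproducible given their seed; replica exchange derives
independent per-replica streams from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as scipy_minimize

from . import _kernels
from .constants import KB, KCAL_PER_AMU_A2_PS2
from .energetics import EnergyBreakdown, total_energy_forces
from .go_builder import GoModel
from .parameters import MinConfig, RexConfig, SimConfig
from .potentials import GoPotential, as_system
from .structure_io import Trajectory

_ENERGY_ABORT = 1e10   # kcal/mol; beyond this the trajectory has diverged
_BLOCK_STEPS = 10000   # random numbers are generated in blocks of this many steps


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------

def minimize(model: GoModel, coords: np.ndarray | None = None,
             cfg: MinConfig | None = None) -> tuple[np.ndarray, list[EnergyBreakdown]]:
    """Steepest-descent stage followed by a limited-memory quasi-Newton stage.

    The SD stage uses a backtracking line search, so the energy is
    non-increasing over accepted steps; the quasi-Newton stage (L-BFGS with
    analytic gradients) then converges the geometry.  Returns the final
    coordinates and the energy-breakdown trace (one entry per accepted SD
    step and per quasi-Newton iterate, starting with the input configuration).
    """
    cfg = cfg or MinConfig()
    cfg.validate()
    x = np.array(model.native_coords if coords is None else coords, dtype=float)
    pot = GoPotential(model)

    def breakdown(xc):
        return total_energy_forces(model, xc)[0]

    e, f = pot.energy_forces(x)
    if not np.isfinite(e):
        raise ValueError("non-finite energy at minimization start")
    history = [breakdown(x)]

    step = 0.01
    for _ in range(cfg.sd_steps):
        gnorm = np.linalg.norm(f)
        if gnorm < cfg.gradient_tol:
            break
        direction = f / gnorm
        accepted = False
        for _try in range(20):
            x_new = x + step * direction
            e_new, f_new = pot.energy_forces(x_new)
            if e_new < e:
                x, e, f = x_new, e_new, f_new
                step *= 1.2
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        history.append(breakdown(x))

    if cfg.qn_steps > 0:
        def fun(flat):
            e_, f_ = pot.energy_forces(flat.reshape(-1, 3))
            return e_, -f_.ravel()

        def cb(flat):
            history.append(breakdown(flat.reshape(-1, 3)))

        res = scipy_minimize(fun, x.ravel(), jac=True, method="L-BFGS-B",
                             callback=cb,
                             options={"maxiter": cfg.qn_steps,
                                      "gtol": cfg.gradient_tol})
        if res.fun <= e:
            x = res.x.reshape(-1, 3)
    history.append(breakdown(x))
    return x, history


# ---------------------------------------------------------------------------
# Langevin dynamics
# ---------------------------------------------------------------------------

@dataclass
class LangevinResult:
    """A trajectory plus the per-saved-frame energies that produced it."""

    trajectory: Trajectory
    potential_energy: np.ndarray   # kcal/mol, per saved frame
    kinetic_energy: np.ndarray     # kcal/mol, per saved frame
    n_dof: int

    @property
    def total_energy(self) -> np.ndarray:
        return self.potential_energy + self.kinetic_energy

    @property
    def kinetic_temperature(self) -> np.ndarray:
        """Instantaneous kinetic temperature per saved frame (K)."""
        return 2.0 * self.kinetic_energy / (self.n_dof * KB)


def _maxwell_boltzmann(rng, masses_kcal, temperature):
    n = len(masses_kcal)
    sigma = np.sqrt(KB * temperature / masses_kcal)[:, None]
    v = rng.normal(size=(n, 3)) * sigma
    if n > 1:   # remove centre-of-mass velocity
        p = (masses_kcal[:, None] * v).sum(axis=0)
        v -= p / masses_kcal.sum()
    return v


def _python_langevin_block(system, x, v, f, masses, dt, gamma, kT, normals,
                           step0, save_interval, frames, epot, ekin, save_start):
    """Pure-python mirror of the compiled stepper (same math, same RNG usage)."""
    c1 = 1.0 - 0.5 * gamma * dt
    c2 = 1.0 / (1.0 + 0.5 * gamma * dt)
    std = np.sqrt(2.0 * gamma * masses * kT / dt)[:, None]
    hdt = (0.5 * dt / masses)[:, None]
    count = save_start
    e = 0.0
    for s in range(normals.shape[0]):
        R = std * normals[s]
        v[:] = c1 * v + hdt * (f + R)
        x += dt * v
        e, f_new = system.energy_forces(x)
        f[:] = f_new
        v[:] = c2 * (v + hdt * (f + R))
        if (step0 + s + 1) % save_interval == 0:
            frames[count] = x
            epot[count] = e
            ekin[count] = 0.5 * float(np.sum(masses[:, None] * v ** 2))
            count += 1
    return count, e


class LangevinIntegrator:
    """Stateful BBK integrator over any system; used directly by replica exchange."""

    def __init__(self, system, coords: np.ndarray, cfg: SimConfig,
                 rng: np.random.Generator | None = None):
        cfg.validate()
        self.system = as_system(system)
        self.cfg = cfg
        self.rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.x = np.array(coords, dtype=float)
        self.masses = np.asarray(self.system.masses, dtype=float) / KCAL_PER_AMU_A2_PS2
        self.v = _maxwell_boltzmann(self.rng, self.masses, cfg.temperature)
        e, self.f = self.system.energy_forces(self.x)
        if not np.isfinite(e):
            raise ValueError("non-finite energy at dynamics start")
        self.e_pot = float(e)
        self.step = 0

    @property
    def kinetic_energy(self) -> float:
        return 0.5 * float(np.sum(self.masses[:, None] * self.v ** 2))

    def set_temperature(self, temperature: float) -> None:
        self.cfg = SimConfig(**{**self.cfg.as_dict(), "temperature": temperature})

    def remove_com_motion(self) -> None:
        if len(self.masses) < 2:   # a single bead's "COM motion" is its motion
            return
        m = self.masses[:, None]
        self.v -= (m * self.v).sum(axis=0) / self.masses.sum()

    def run(self, n_steps: int, save_interval: int | None = None):
        """Advance n_steps; returns (frames, steps_of_frames, epot, ekin) arrays."""
        cfg = self.cfg
        save = save_interval or cfg.save_interval
        kT = KB * cfg.temperature
        n_save_max = n_steps // save + 1
        n = len(self.masses)
        frames = np.empty((n_save_max, n, 3))
        epot = np.empty(n_save_max)
        ekin = np.empty(n_save_max)
        saved_steps = [self.step + s for s in range(1, n_steps + 1)
                       if (self.step + s) % save == 0]
        count = 0
        done = 0
        use_kernel = isinstance(self.system, GoPotential)
        while done < n_steps:
            chunk = min(_BLOCK_STEPS, n_steps - done)
            normals = self.rng.standard_normal((chunk, n, 3))
            if use_kernel:
                count, e = _kernels.langevin_block(
                    self.x, self.v, self.f, self.masses, cfg.dt, cfg.friction,
                    kT, normals, self.step, save, frames, epot, ekin, count,
                    *self.system.kernel_args())
            else:
                count, e = _python_langevin_block(
                    self.system, self.x, self.v, self.f, self.masses, cfg.dt,
                    cfg.friction, kT, normals, self.step, save, frames, epot,
                    ekin, count)
            self.step += chunk
            done += chunk
            self.e_pot = float(e)
            if not np.isfinite(self.e_pot) or abs(self.e_pot) > _ENERGY_ABORT:
                raise RuntimeError(
                    f"energy diverged at step {self.step}: E = {self.e_pot!r}; "
                    "reduce the timestep or re-minimize the starting structure")
        return (frames[:count], np.array(saved_steps[:count]),
                epot[:count], ekin[:count])


def langevin_dynamics(model, coords: np.ndarray | None = None,
                      cfg: SimConfig | None = None) -> LangevinResult:
    """Run Langevin dynamics and return the saved trajectory plus energies.

    Frame 0 (the starting configuration) is always included; subsequent
    frames are saved every ``cfg.save_interval`` steps.  Given the same seed
    the result is bit-for-bit reproducible.
    """
    cfg = cfg or SimConfig()
    cfg.validate()
    if coords is None:
        if not isinstance(model, GoModel):
            raise ValueError("coords are required for non-GoModel systems")
        coords = model.native_coords
    integ = LangevinIntegrator(model, coords, cfg)
    n_dof = 3 * len(integ.masses) - 3   # COM motion removed
    frames0 = [np.array(coords, dtype=float)]
    epot0 = [integ.e_pot]
    ekin0 = [integ.kinetic_energy]
    frames, steps, epot, ekin = integ.run(cfg.n_steps)
    all_frames = np.concatenate([np.array(frames0), frames], axis=0)
    times = np.concatenate([[0.0], steps * cfg.dt])
    traj = Trajectory(all_frames, times, config=cfg.as_dict())
    return LangevinResult(traj, np.concatenate([epot0, epot]),
                          np.concatenate([ekin0, ekin]), max(n_dof, 1))


# ---------------------------------------------------------------------------
# replica exchange
# ---------------------------------------------------------------------------

def metropolis_swap_probability(beta_i: float, beta_j: float,
                                e_i: float, e_j: float) -> float:
    """Closed-form acceptance probability min(1, exp[(b_i - b_j)(E_i - E_j)])."""
    delta = (beta_i - beta_j) * (e_i - e_j)
    return 1.0 if delta >= 0 else float(np.exp(delta))


@dataclass
class RexResult:
    """Per-temperature trajectories plus exchange statistics."""

    temperatures: list[float]
    trajectories: list[Trajectory]
    potential_energies: list[np.ndarray]
    attempts: np.ndarray    # per neighbour pair
    accepts: np.ndarray
    config: dict = field(default_factory=dict)

    @property
    def acceptance_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.attempts > 0, self.accepts / np.maximum(self.attempts, 1),
                            np.nan)


def replica_exchange(model, rex: RexConfig, sim: SimConfig,
                     coords: np.ndarray | None = None) -> RexResult:
    """Temperature replica exchange with alternating even/odd neighbour swaps.

    Each ladder slot holds a fixed temperature; on an accepted swap the
    *coordinates* (and suitably rescaled velocities) move between slots, so
    every output trajectory is continuous in temperature.  Swap acceptance
    uses the Metropolis criterion min(1, exp[(b_i - b_j)(E_i - E_j)]).
    """
    rex.validate()
    sim.validate()
    system = as_system(model)
    if coords is None:
        if not isinstance(model, GoModel):
            raise ValueError("coords are required for non-GoModel systems")
        coords = model.native_coords
    temps = [float(t) for t in rex.temperatures]
    n_rep = len(temps)
    seq = np.random.SeedSequence(rex.seed)
    children = seq.spawn(n_rep + 1)
    swap_rng = np.random.default_rng(children[-1])

    replicas = []
    for k, T in enumerate(temps):
        cfg_k = SimConfig(**{**sim.as_dict(), "temperature": T})
        integ = LangevinIntegrator(system, coords, cfg_k,
                                   rng=np.random.default_rng(children[k]))
        replicas.append(integ)

    betas = np.array([1.0 / (KB * T) for T in temps])
    frames: list[list[np.ndarray]] = [[] for _ in range(n_rep)]
    steps_saved: list[list[int]] = [[] for _ in range(n_rep)]
    epots: list[list[float]] = [[] for _ in range(n_rep)]
    attempts = np.zeros(n_rep - 1)
    accepts = np.zeros(n_rep - 1)

    for rnd in range(rex.n_rounds):
        for k, integ in enumerate(replicas):
            fr, st, ep, _ = integ.run(rex.steps_per_exchange)
            frames[k].extend(fr)
            steps_saved[k].extend(st)
            epots[k].extend(ep)
        start = rnd % 2
        for k in range(start, n_rep - 1, 2):
            attempts[k] += 1
            a, b = replicas[k], replicas[k + 1]
            p = metropolis_swap_probability(betas[k], betas[k + 1], a.e_pot, b.e_pot)
            if swap_rng.random() < p:
                accepts[k] += 1
                scale_ab = np.sqrt(temps[k] / temps[k + 1])
                xa, va, fa, ea = a.x.copy(), a.v.copy(), a.f.copy(), a.e_pot
                a.x, a.v, a.f, a.e_pot = b.x, b.v * scale_ab, b.f, b.e_pot
                b.x, b.v, b.f, b.e_pot = xa, va / scale_ab, fa, ea
                a.remove_com_motion()
                b.remove_com_motion()

    trajectories = []
    for k in range(n_rep):
        if frames[k]:
            traj = Trajectory(np.array(frames[k]),
                              np.array(steps_saved[k]) * sim.dt,
                              config={**sim.as_dict(), "temperature": temps[k]})
        else:
            raise RuntimeError("replica exchange produced no saved frames; "
                               "decrease save_interval or increase run length")
        trajectories.append(traj)
    return RexResult(temps, trajectories, [np.array(e) for e in epots],
                     attempts, accepts,
                     config={"rex": {"temperatures": temps,
                                     "steps_per_exchange": rex.steps_per_exchange,
                                     "n_rounds": rex.n_rounds, "seed": rex.seed},
                             "sim": sim.as_dict()})


# ---------------------------------------------------------------------------
# nScale calibration
# ---------------------------------------------------------------------------

@dataclass
class TuneResult:
    nscale: float
    history: list[tuple[float, float]]   # (nscale, estimated Tm)
    converged: bool


def tune_nscale(aa, target_tm: float, tol: float = 15.0,
                nscale0: float = 1.0,
                rex: RexConfig | None = None,
                sim: SimConfig | None = None,
                params=None,
                max_iterations: int = 8,
                damping: float = 0.5,
                burn_in: float = 0.3,
                tm_estimator=None) -> TuneResult:
    """Calibrate nScale so the model's melting temperature hits a target.

    Starting from ``nscale0`` (default 1, no scaling), each iteration builds
    the Go model, runs a brief replica exchange, estimates Tm from the
    melting curve, and updates nScale multiplicatively by
    ``(target / Tm)**damping``; stronger native wells raise Tm, so the update
    moves nScale up when the model melts too low and down when too high.
    Stops when |Tm - target| <= tol (K) or after ``max_iterations``.

    ``tm_estimator(nscale) -> Tm`` may be supplied to replace the built-in
    REX pipeline (used for fast tests of the control loop).
    """
    from .analysis import estimate_tm, melting_curve, q_series

    rex = rex or RexConfig()
    sim = sim or SimConfig(n_steps=0)
    rex.validate()
    temps = list(rex.temperatures)
    if not temps[0] <= target_tm <= temps[-1]:
        raise ValueError(
            f"target Tm {target_tm} K is outside the replica ladder "
            f"[{temps[0]:.0f}, {temps[-1]:.0f}] K; widen the ladder")

    def default_estimator(nscale: float) -> float:
        from .go_builder import build_go_model
        model = build_go_model(aa, nscale=nscale, params=params)
        result = replica_exchange(model, rex, sim)
        series = {T: q_series(result.trajectories[k], model)
                  for k, T in enumerate(result.temperatures)}
        curve = melting_curve(series, burn_in=burn_in)
        return estimate_tm(curve)

    estimator = tm_estimator or default_estimator
    nscale = float(nscale0)
    history: list[tuple[float, float]] = []
    converged = False
    for _ in range(max_iterations):
        tm = float(estimator(nscale))
        history.append((nscale, tm))
        if abs(tm - target_tm) <= tol:
            converged = True
            break
        nscale = float(np.clip(nscale * (target_tm / tm) ** damping, 0.05, 20.0))
    return TuneResult(nscale=history[-1][0] if converged else nscale,
                      history=history, converged=converged)
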