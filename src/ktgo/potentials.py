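"""Potential-energy systems the integrator can drive.

A *system* is anything with ``masses`` (amu, shape (n,)) and
``energy_forces(coords) -> (E, F)`` for (n, 3) coordinates.  GoPotential
adapts a :class:`~ktgo.go_builder.GoModel` (with compiled kernels when numba
is available); the 1-D toys are used for thermostat and replica-exchange
validation against closed-form statistical mechanics.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .go_builder import GoModel


class GoPotential:
    """Adapter exposing a GoModel to the integrator via packed term arrays."""

    def __init__(self, model: GoModel):
        self.model = model
        b = model.bonded
        self.bond_idx = np.array([[t.i, t.j] for t in b.bonds], dtype=np.int64).reshape(-1, 2)
        self.bond_k = np.array([t.k for t in b.bonds], dtype=float)
        self.bond_r0 = np.array([t.r0 for t in b.bonds], dtype=float)
        self.ang_idx = np.array([[t.i, t.j, t.k_] for t in b.angles], dtype=np.int64).reshape(-1, 3)
        self.ang_k = np.array([t.k for t in b.angles], dtype=float)
        self.ang_t0 = np.deg2rad([t.theta0 for t in b.angles]).astype(float)
        self.dih_idx = np.array([[t.i, t.j, t.k_, t.l] for t in b.dihedrals],
                                dtype=np.int64).reshape(-1, 4)
        self.dih_k = np.array([t.k for t in b.dihedrals], dtype=float)
        self.dih_n = np.array([t.n for t in b.dihedrals], dtype=float)
        self.dih_delta = np.deg2rad([t.delta for t in b.dihedrals]).astype(float)
        self.imp_idx = np.array([[t.i, t.j, t.k_, t.l] for t in b.impropers],
                                dtype=np.int64).reshape(-1, 4)
        self.imp_k = np.array([t.k for t in b.impropers], dtype=float)
        self.imp_w0 = np.deg2rad([t.omega0 for t in b.impropers]).astype(float)
        wells = list(model.contacts) + list(model.hbonds)
        self.well_idx = np.array([[w.i, w.j] for w in wells], dtype=np.int64).reshape(-1, 2)
        self.well_r0 = np.array([w.r_native for w in wells], dtype=float)
        self.well_eps = np.array([w.epsilon for w in wells], dtype=float)
        self.rep_idx = np.asarray(model.repulsive_pairs, dtype=np.int64).reshape(-1, 2)
        self.rep_sigma = np.asarray(model.repulsive_sigma, dtype=float)
        self.rep_eps = float(model.params.eps_repulsive)
        self.r_on = float(model.params.switch_r_on)
        self.r_off = float(model.params.switch_r_off)
        self.masses = model.masses

    def kernel_args(self) -> tuple:
        return (self.bond_idx, self.bond_k, self.bond_r0,
                self.ang_idx, self.ang_k, self.ang_t0,
                self.dih_idx, self.dih_k, self.dih_n, self.dih_delta,
                self.imp_idx, self.imp_k, self.imp_w0,
                self.well_idx, self.well_r0, self.well_eps,
                self.rep_idx, self.rep_sigma, self.rep_eps,
                self.r_on, self.r_off)

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = np.ascontiguousarray(coords, dtype=float)
        f = np.zeros_like(coords)
        e = _kernels.compute_forces(coords, f, *self.kernel_args())
        return float(e), f


class Harmonic1D:
    """Single bead in a 1-D harmonic well E = 1/2 k x^2 (y, z force-free).

    Its stationary position variance under Langevin dynamics is k_B T / k,
    the equipartition closed form used to validate the thermostat.
    """

    def __init__(self, k: float = 1.0, mass: float = 12.0):
        self.k = float(k)
        self.masses = np.array([mass])

    def energy_forces(self, coords):
        coords = np.asarray(coords, dtype=float)
        xcomp = coords[0, 0]
        f = np.zeros_like(coords)
        f[0, 0] = -self.k * xcomp
        return 0.5 * self.k * xcomp ** 2, f


class DoubleWell1D:
    """Asymmetric 1-D double well E(x) = h ((x/a)^2 - 1)^2 + s x / a.

    Minima near x = +-a with the +a well raised by roughly 2 s.  The exact
    Boltzmann occupancy of each well at any temperature follows from 1-D
    quadrature (:meth:`boltzmann_occupancy`), giving an analytic target for
    replica-exchange sampling.
    """

    def __init__(self, height: float = 2.0, a: float = 1.0, tilt: float = 0.5,
                 mass: float = 12.0):
        self.h = float(height)
        self.a = float(a)
        self.s = float(tilt)
        self.masses = np.array([mass])

    def potential(self, xval):
        u = np.asarray(xval, dtype=float) / self.a
        return self.h * (u ** 2 - 1.0) ** 2 + self.s * u

    def energy_forces(self, coords):
        coords = np.asarray(coords, dtype=float)
        u = coords[0, 0] / self.a
        e = self.h * (u ** 2 - 1.0) ** 2 + self.s * u
        dedx = (4.0 * self.h * u * (u ** 2 - 1.0) + self.s) / self.a
        f = np.zeros_like(coords)
        f[0, 0] = -dedx
        return float(e), f

    def boltzmann_occupancy(self, temperature: float) -> float:
        """Exact P(x > 0) at the given temperature by numerical quadrature."""
        from scipy.integrate import quad

        from .constants import KB
        beta = 1.0 / (KB * temperature)
        lo, hi = -6.0 * self.a, 6.0 * self.a
        z_right, _ = quad(lambda xv: np.exp(-beta * self.potential(xv)), 0.0, hi,
                          limit=200)
        z_all, _ = quad(lambda xv: np.exp(-beta * self.potential(xv)), lo, hi,
                        limit=200)
        return z_right / z_all


def as_system(obj):
    """Coerce a GoModel or any (masses, energy_forces) object into a system."""
    if isinstance(obj, GoModel):
        return GoPotential(obj)
    if hasattr(obj, "energy_forces") and hasattr(obj, "masses"):
        return obj
    raise TypeError(f"cannot interpret {type(obj).__name__} as a simulatable system")
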