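"""Potential energy and analytic forces for a Go model configuration.

CHARMM functional forms throughout: harmonic bonds and angles, cosine
dihedrals k(1 + cos(n*phi - delta)), harmonic impropers, and 12-6
Lennard-Jones nonbonded terms (native wells with the minimum at the crystal
separation, pure r^-12 excluded-volume repulsion otherwise), all attenuated
by the CHARMM energy-switching function between r_on and r_off.  Units:
kcal/mol, Angstrom; forces in kcal/mol/A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np

from .go_builder import GoModel

#: pair distances below this evaluate at this value instead of overflowing
MIN_PAIR_DISTANCE = 0.1


@dataclass
class EnergyBreakdown:
    """Energy decomposition in kcal/mol; total is always the component sum."""

    bond: float = 0.0
    angle: float = 0.0
    dihedral: float = 0.0
    improper: float = 0.0
    lj_native: float = 0.0
    lj_repulsive: float = 0.0
    hbond: float = 0.0

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.dihedral + self.improper
                + self.lj_native + self.lj_repulsive + self.hbond)

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(**{f.name: getattr(self, f.name) + getattr(other, f.name)
                                  for f in fields(self)})

    def as_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["total"] = self.total
        return d

    def __str__(self) -> str:
        rows = [f"{name:>12s} {value:14.6f}" for name, value in self.as_dict().items()]
        return "\n".join(rows)


# ---------------------------------------------------------------------------
# switching function
# ---------------------------------------------------------------------------

def switching_function(r: np.ndarray, r_on: float, r_off: float) -> tuple[np.ndarray, np.ndarray]:
    """CHARMM energy-switching function S(r) and its derivative dS/dr.

    S = 1 for r <= r_on, 0 for r >= r_off, and
    (r_off^2 - r^2)^2 (r_off^2 + 2 r^2 - 3 r_on^2) / (r_off^2 - r_on^2)^3
    in between; continuous with continuous first derivative at both edges.
    """
    r = np.asarray(r, dtype=float)
    s = np.ones_like(r)
    ds = np.zeros_like(r)
    mid = (r > r_on) & (r < r_off)
    if np.any(mid):
        rm = r[mid]
        a = r_off ** 2 - rm ** 2
        b = r_off ** 2 + 2 * rm ** 2 - 3 * r_on ** 2
        denom = (r_off ** 2 - r_on ** 2) ** 3
        s[mid] = a ** 2 * b / denom
        ds[mid] = 12.0 * rm * a * (r_on ** 2 - rm ** 2) / denom
    s[r >= r_off] = 0.0
    return s, ds


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------

def _bond_energy_forces(coords, idx, k, r0, forces):
    if len(idx) == 0:
        return 0.0
    rij = coords[idx[:, 0]] - coords[idx[:, 1]]
    r = np.linalg.norm(rij, axis=1)
    if np.any(r < 1e-10):
        raise ValueError("coincident bonded beads (zero bond length)")
    dr = r - r0
    e = float(np.sum(k * dr ** 2))
    fmag = (-2.0 * k * dr / r)[:, None] * rij
    np.add.at(forces, idx[:, 0], fmag)
    np.add.at(forces, idx[:, 1], -fmag)
    return e


def _angle_energy_forces(coords, idx, k, theta0_rad, forces):
    if len(idx) == 0:
        return 0.0
    u = coords[idx[:, 0]] - coords[idx[:, 1]]
    v = coords[idx[:, 2]] - coords[idx[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cos_t = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = np.sqrt(np.clip(1.0 - cos_t ** 2, 1e-12, None))
    dt = theta - theta0_rad
    e = float(np.sum(k * dt ** 2))
    # dtheta/dri = -(1/sin) * (v/(nu*nv) - cos*u/nu^2)
    pref = (2.0 * k * dt / sin_t)[:, None]
    dcos_di = v / (nu * nv)[:, None] - cos_t[:, None] * u / (nu ** 2)[:, None]
    dcos_dk = u / (nu * nv)[:, None] - cos_t[:, None] * v / (nv ** 2)[:, None]
    fi = pref * dcos_di
    fk = pref * dcos_dk
    np.add.at(forces, idx[:, 0], fi)
    np.add.at(forces, idx[:, 2], fk)
    np.add.at(forces, idx[:, 1], -(fi + fk))
    return e


def _dihedral_geometry(coords, idx):
    """Signed dihedral angles and their cartesian gradients for 4-tuples."""
    p0, p1, p2, p3 = (coords[idx[:, c]] for c in range(4))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    m = np.cross(b2 / nb2[:, None], n1)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m, n2)
    phi = np.arctan2(y, x)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    dphi_d0 = -(nb2 / n1sq)[:, None] * n1
    dphi_d3 = (nb2 / n2sq)[:, None] * n2
    s12 = (np.einsum("ij,ij->i", b1, b2) / nb2 ** 2)[:, None]
    s32 = (np.einsum("ij,ij->i", b3, b2) / nb2 ** 2)[:, None]
    dphi_d1 = -(1.0 + s12) * dphi_d0 + s32 * dphi_d3
    dphi_d2 = -(dphi_d0 + dphi_d1 + dphi_d3)
    return phi, (dphi_d0, dphi_d1, dphi_d2, dphi_d3)


def _dihedral_energy_forces(coords, idx, k, n, delta_rad, forces):
    if len(idx) == 0:
        return 0.0
    phi, grads = _dihedral_geometry(coords, idx)
    arg = n * phi - delta_rad
    e = float(np.sum(k * (1.0 + np.cos(arg))))
    dE_dphi = -k * n * np.sin(arg)
    for c in range(4):
        np.add.at(forces, idx[:, c], -dE_dphi[:, None] * grads[c])
    return e


def _improper_energy_forces(coords, idx, k, omega0_rad, forces):
    if len(idx) == 0:
        return 0.0
    omega, grads = _dihedral_geometry(coords, idx)
    d = omega - omega0_rad
    d = (d + np.pi) % (2.0 * np.pi) - np.pi   # wrap to (-pi, pi]
    e = float(np.sum(k * d ** 2))
    dE_domega = 2.0 * k * d
    for c in range(4):
        np.add.at(forces, idx[:, c], -dE_domega[:, None] * grads[c])
    return e


def bonded_energy_forces(model: GoModel, coords: np.ndarray) -> tuple[EnergyBreakdown, np.ndarray]:
    """Bond + angle + dihedral + improper energy and forces (exact gradients)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (model.n_beads, 3):
        raise ValueError(f"coords must have shape ({model.n_beads}, 3)")
    forces = np.zeros_like(coords)
    b = model.bonded
    out = EnergyBreakdown()
    if b.bonds:
        idx = np.array([[t.i, t.j] for t in b.bonds])
        out.bond = _bond_energy_forces(coords, idx, np.array([t.k for t in b.bonds]),
                                       np.array([t.r0 for t in b.bonds]), forces)
    if b.angles:
        idx = np.array([[t.i, t.j, t.k_] for t in b.angles])
        out.angle = _angle_energy_forces(
            coords, idx, np.array([t.k for t in b.angles]),
            np.deg2rad([t.theta0 for t in b.angles]), forces)
    if b.dihedrals:
        idx = np.array([[t.i, t.j, t.k_, t.l] for t in b.dihedrals])
        out.dihedral = _dihedral_energy_forces(
            coords, idx, np.array([t.k for t in b.dihedrals]),
            np.array([t.n for t in b.dihedrals]),
            np.deg2rad([t.delta for t in b.dihedrals]), forces)
    if b.impropers:
        idx = np.array([[t.i, t.j, t.k_, t.l] for t in b.impropers])
        out.improper = _improper_energy_forces(
            coords, idx, np.array([t.k for t in b.impropers]),
            np.deg2rad([t.omega0 for t in b.impropers]), forces)
    if not np.all(np.isfinite(forces)):
        raise ValueError("non-finite bonded forces")
    return out, forces


# ---------------------------------------------------------------------------
# nonbonded terms
# ---------------------------------------------------------------------------

def _pair_distances(coords, idx):
    rij = coords[idx[:, 0]] - coords[idx[:, 1]]
    r = np.linalg.norm(rij, axis=1)
    capped = r < MIN_PAIR_DISTANCE
    if np.any(capped):
        warnings.warn(f"{int(capped.sum())} pair distance(s) below "
                      f"{MIN_PAIR_DISTANCE} A capped during energy evaluation",
                      RuntimeWarning, stacklevel=3)
        r = np.maximum(r, MIN_PAIR_DISTANCE)
    return rij, r


def _lj_well(r, r0, eps):
    """12-6 well with minimum -eps at r0; returns (V, dV/dr)."""
    x6 = (r0 / r) ** 6
    v = eps * (x6 ** 2 - 2.0 * x6)
    dv = -12.0 * eps / r * (x6 ** 2 - x6)
    return v, dv


def _switched_pair_energy_forces(coords, idx, v, dv, rij, r, r_on, r_off, forces):
    s, ds = switching_function(r, r_on, r_off)
    e = float(np.sum(v * s))
    dEdr = dv * s + v * ds
    f = (-dEdr / r)[:, None] * rij
    np.add.at(forces, idx[:, 0], f)
    np.add.at(forces, idx[:, 1], -f)
    return e


def nonbonded_energy_forces(model: GoModel, coords: np.ndarray) -> tuple[EnergyBreakdown, np.ndarray]:
    """Native-contact wells, hydrogen-bond wells and excluded-volume repulsion.

    Every pair term is multiplied by the switching function; energies and
    forces vanish identically beyond r_off.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (model.n_beads, 3):
        raise ValueError(f"coords must have shape ({model.n_beads}, 3)")
    forces = np.zeros_like(coords)
    out = EnergyBreakdown()
    r_on, r_off = model.params.switch_r_on, model.params.switch_r_off

    if model.contacts:
        idx = np.array([[c.i, c.j] for c in model.contacts])
        rij, r = _pair_distances(coords, idx)
        v, dv = _lj_well(r, np.array([c.r_native for c in model.contacts]),
                         np.array([c.epsilon for c in model.contacts]))
        out.lj_native = _switched_pair_energy_forces(coords, idx, v, dv, rij, r,
                                                     r_on, r_off, forces)
    if model.hbonds:
        idx = np.array([[h.i, h.j] for h in model.hbonds])
        rij, r = _pair_distances(coords, idx)
        v, dv = _lj_well(r, np.array([h.r_native for h in model.hbonds]),
                         np.array([h.epsilon for h in model.hbonds]))
        out.hbond = _switched_pair_energy_forces(coords, idx, v, dv, rij, r,
                                                 r_on, r_off, forces)
    if len(model.repulsive_pairs):
        idx = model.repulsive_pairs
        rij, r = _pair_distances(coords, idx)
        x12 = (model.repulsive_sigma / r) ** 12
        v = model.params.eps_repulsive * x12
        dv = -12.0 * v / r
        out.lj_repulsive = _switched_pair_energy_forces(coords, idx, v, dv, rij, r,
                                                        r_on, r_off, forces)
    return out, forces


def total_energy_forces(model: GoModel, coords: np.ndarray) -> tuple[EnergyBreakdown, np.ndarray]:
    """Full potential energy breakdown and per-bead forces."""
    eb, fb = bonded_energy_forces(model, coords)
    en, fn = nonbonded_energy_forces(model, coords)
    return eb + en, fb + fn


def total_energy(model: GoModel, coords: np.ndarray) -> float:
    return total_energy_forces(model, coords)[0].total
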