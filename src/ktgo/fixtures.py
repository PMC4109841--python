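"""Deterministic synthetic structures and synthetic analysis inputs.

These generators make the whole toolkit testable without any structure
download: an ideal alpha-helix built from standard internal coordinates, a
miniature three-helix bundle (the fold topology of small albumin-binding
domains such as 1PRB), and two-state synthetic melting data for exercising
the thermodynamic fitting machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ONE_TO_THREE, element_mass
from .geometry import axis_rotation as _axis_rotation
from .geometry import place_atom, rotation_between as _rotation_between
from .structure_io import AAStructure, AtomRecord, Residue

# Standard backbone internal coordinates (Angstrom / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_N_CA_CB = 110.5
DIHEDRAL_C_N_CA_CB = -122.6   # places CB with L-amino-acid chirality
OMEGA = 180.0


@dataclass
class HelixSpec:
    """Geometry spec for a single ideal helix (default: polyalanine)."""

    n_residues: int = 10
    sequence: str | None = None    # one-letter codes; None -> all alanine
    phi: float = -57.0
    psi: float = -47.0

    def resolved_sequence(self) -> str:
        seq = self.sequence or "A" * self.n_residues
        if len(seq) != self.n_residues:
            raise ValueError("sequence length must equal n_residues")
        return seq


@dataclass
class BundleSpec:
    """Spec for a miniature three-helix bundle joined by short loops."""

    helices: tuple[HelixSpec, HelixSpec, HelixSpec] = field(
        default_factory=lambda: (HelixSpec(10), HelixSpec(10), HelixSpec(10)))
    loop_sequence: str = "GG"      # glycine loops exercise the no-SC-bead path
    packing_distance: float = 8.5  # inter-axis spacing (A)
    jitter_sigma: float = 0.03     # Gaussian jitter on side-chain atoms (A)
    seed: int = 2014


def _atom(name: str, element: str, pos: np.ndarray, residx: int, resname: str) -> AtomRecord:
    return AtomRecord(name, element, element_mass(element), residx, resname, "A",
                      np.asarray(pos, dtype=float))


def _build_chain(sequence_3: list[str], phis: list[float], psis: list[float]) -> AAStructure:
    """Build a chain from per-residue (phi, psi) using ideal covalent geometry."""
    n = len(sequence_3)
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    # first residue in the xy-plane
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    alpha = np.deg2rad(180.0 - ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([np.cos(alpha), np.sin(alpha), 0.0])
    for i in range(1, n):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        C[i] = place_atom(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phis[i])

    residues: list[Residue] = []
    for i, resname in enumerate(sequence_3):
        res = Residue(index=i + 1, name=resname, chain_id="A")
        res.atoms.append(_atom("N", "N", N[i], i + 1, resname))
        res.atoms.append(_atom("CA", "C", CA[i], i + 1, resname))
        res.atoms.append(_atom("C", "C", C[i], i + 1, resname))
        # carbonyl O anti to the next N (or to where it would be for the C-terminus)
        o = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psis[i] + 180.0)
        res.atoms.append(_atom("O", "O", o, i + 1, resname))
        if resname != "GLY":
            cb = place_atom(C[i], N[i], CA[i], BOND_CA_CB, ANGLE_N_CA_CB,
                            DIHEDRAL_C_N_CA_CB)
            res.atoms.append(_atom("CB", "C", cb, i + 1, resname))
        residues.append(res)
    return AAStructure(residues=residues, source="fixture", chain_id="A")


def make_ideal_helix(spec: HelixSpec | None = None, **kwargs) -> AAStructure:
    """Build an ideal helix (backbone + CB) from standard internal coordinates.

    With the default phi = -57, psi = -47 this is a canonical alpha-helix with
    consecutive CA-CA distances of ~3.8 A; other (phi, psi) build extended or
    arbitrary conformations from the same covalent geometry.
    """
    spec = spec or HelixSpec(**kwargs)
    seq = [ONE_TO_THREE[c] for c in spec.resolved_sequence()]
    phis = [spec.phi] * spec.n_residues
    psis = [spec.psi] * spec.n_residues
    aa = _build_chain(seq, phis, psis)
    aa.source = f"ideal_helix_n{spec.n_residues}"
    return aa


# ---------------------------------------------------------------------------
# rigid transforms and helix alignment
# ---------------------------------------------------------------------------

def transform_structure(aa: AAStructure, rotation: np.ndarray,
                        translation: np.ndarray) -> AAStructure:
    """Return a copy with every atom position mapped to R @ x + t."""
    out_res = []
    for res in aa.residues:
        new = Residue(res.index, res.name, res.chain_id)
        for a in res.atoms:
            new.atoms.append(AtomRecord(a.name, a.element, a.mass, a.residue_index,
                                        a.residue_name, a.chain_id,
                                        rotation @ a.position + translation))
        out_res.append(new)
    return AAStructure(out_res, source=aa.source, chain_id=aa.chain_id)


def _align_helix_to_z(aa: AAStructure) -> AAStructure:
    """Center a helix at the origin with its first->last CA axis along +z."""
    ca = aa.backbone_positions("CA")
    center = ca.mean(axis=0)
    # principal axis of the CA cloud, oriented N->C
    u, s, vt = np.linalg.svd(ca - center)
    axis = vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    rot = _rotation_between(axis, np.array([0.0, 0.0, 1.0]))
    return transform_structure(aa, rot, -rot @ center)


def _cb_phase(aa: AAStructure, residue_i: int) -> float:
    """Azimuthal (xy) angle of the CB direction of one residue of a z-aligned helix."""
    res = aa.residues[residue_i]
    v = res.atom("CB").position - res.atom("CA").position
    return float(np.arctan2(v[1], v[0]))


def make_three_helix_bundle(spec: BundleSpec | None = None, **kwargs) -> AAStructure:
    """Build a miniature three-helix bundle as a single continuous chain.

    Three ideal helices are packed up-down-up on a triangular lattice with the
    given inter-axis distance, each rotated about its own axis so side chains
    face the bundle core, and joined by short loops.  Side-chain atoms get a
    small seeded Gaussian jitter so the contact map is not artificially
    degenerate.  The native-contact map of the default spec is non-trivial
    (tens of inter-helix side-chain contacts under the 4.5 A criterion).
    """
    spec = spec or BundleSpec(**kwargs)
    d = spec.packing_distance
    xy = [np.array([0.0, 0.0]), np.array([d, 0.0]),
          np.array([d / 2, d * np.sqrt(3) / 2])]
    centroid = np.mean(xy, axis=0)
    flip_x = _axis_rotation(np.array([1.0, 0.0, 0.0]), np.pi)

    placed: list[AAStructure] = []
    for k, hspec in enumerate(spec.helices):
        helix = _align_helix_to_z(make_ideal_helix(hspec))
        mid = hspec.n_residues // 2
        want = np.arctan2(*(centroid - xy[k])[::-1])
        have = _cb_phase(helix, mid)
        helix = transform_structure(helix, _axis_rotation(np.array([0.0, 0.0, 1.0]),
                                                          want - have), np.zeros(3))
        if k == 1:  # middle helix runs antiparallel
            helix = transform_structure(helix, flip_x, np.zeros(3))
        helix = transform_structure(helix, np.eye(3),
                                    np.array([xy[k][0], xy[k][1], 0.0]))
        placed.append(helix)

    # assemble one chain: helix1, loop, helix2, loop, helix3
    loop3 = [ONE_TO_THREE[c] for c in spec.loop_sequence]
    template = _align_helix_to_z(make_ideal_helix(HelixSpec(4)))
    residues: list[Residue] = []

    def _append(res: Residue) -> None:
        idx = len(residues) + 1
        new = Residue(idx, res.name, "A")
        for a in res.atoms:
            new.atoms.append(AtomRecord(a.name, a.element, a.mass, idx, res.name,
                                        "A", a.position.copy()))
        residues.append(new)

    for k, helix in enumerate(placed):
        for res in helix.residues:
            _append(res)
        if k == 2:
            break
        # loop: template residues translated onto points interpolated between
        # the flanking helix-end CA positions (geometry is crude on purpose;
        # the Go model takes whatever geometry it is given as native)
        end_ca = helix.residues[-1].atom("CA").position
        start_ca = placed[k + 1].residues[0].atom("CA").position
        n_loop = len(loop3)
        # bow the loop outward so consecutive CAs are never collinear
        span = start_ca - end_ca
        perp = np.cross(span, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(span, [1.0, 0.0, 0.0])
        perp = perp / np.linalg.norm(perp)
        midpoint = 0.5 * (end_ca + start_ca)
        outward = midpoint[:2] - centroid
        if np.dot(perp[:2], outward) < 0:
            perp = -perp
        for j, resname in enumerate(loop3):
            frac = (j + 1) / (n_loop + 1)
            bow = 1.5 * np.sin(np.pi * frac) * perp
            target = end_ca + frac * span + bow
            tres = template.residues[j % len(template.residues)]
            shift = target - tres.atom("CA").position
            moved = Residue(0, resname, "A")
            for a in tres.atoms:
                if resname == "GLY" and a.name == "CB":
                    continue
                moved.atoms.append(AtomRecord(a.name, a.element, a.mass, 0, resname,
                                              "A", a.position + shift))
            _append(moved)

    # seeded side-chain jitter
    rng = np.random.default_rng(spec.seed)
    for res in residues:
        for a in res.atoms:
            if not a.is_backbone:
                a.position = a.position + rng.normal(0.0, spec.jitter_sigma, 3)

    return AAStructure(residues, source="three_helix_bundle", chain_id="A")


# ---------------------------------------------------------------------------
# synthetic melting data
# ---------------------------------------------------------------------------

def make_synthetic_melting_data(tm: float, dh: float, dcp: float,
                                temperatures: np.ndarray,
                                n_frames: int = 500,
                                noise: float = 0.02,
                                seed: int = 0):
    """Generate per-temperature Q series from the two-state model.

    At each ladder temperature the folded probability follows the
    Gibbs-Helmholtz closed form.  Frames mimic a time-correlated folding
    trajectory: the folded/unfolded state is drawn once per dwell segment
    (Bernoulli with the closed-form probability) and held for the segment,
    so the per-temperature fraction folded carries a sampling error of about
    ``noise`` at the transition midpoint (sqrt(p(1-p)/n_segments) in
    general), exactly the error structure block averaging is meant to
    estimate.  Q values are drawn from well-separated folded (~0.85) and
    unfolded (~0.20) distributions.

    Returns a dict mapping temperature (K) to a :class:`ktgo.analysis.QSeries`.
    """
    from .analysis import QSeries, two_state_fraction_folded

    rng = np.random.default_rng(seed)
    n_segments = max(4, int(round(0.25 / noise ** 2))) if noise > 0 else n_frames
    n_segments = min(n_segments, n_frames)
    out = {}
    for T in np.asarray(temperatures, dtype=float):
        p = float(two_state_fraction_folded(T, tm, dh, dcp))
        seg_state = rng.random(n_segments) < p
        folded = np.repeat(seg_state, int(np.ceil(n_frames / n_segments)))[:n_frames]
        q = np.where(folded,
                     rng.normal(0.85, 0.05, n_frames),
                     rng.normal(0.20, 0.05, n_frames))
        q = np.clip(q, 0.0, 1.0)
        times = np.arange(n_frames, dtype=float)
        out[float(T)] = QSeries(times=times, values=q)
    return out
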