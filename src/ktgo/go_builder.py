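"""Construction of the complete two-site Go model.

From an all-atom structure this module derives: the secondary-structure
assignment driving the backbone dihedral stiffness, the bonded terms whose
equilibria are the native geometry, the native side-chain contact list
(4.5 A criterion) with Miyazawa-Jernigan-scaled well depths, the backbone
hydrogen-bond pair list (weakly attractive CA-CA wells), and the repulsive
excluded-volume set covering every remaining nonbonded pair.  nScale scales
all native-contact well depths globally and is the handle for tuning the
model's melting temperature.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .geometry import bond_angle, dihedral_angle
from .mj_potential import MJTable, default_mj_table
from .parameters import GoParams
from .structure_io import AAStructure, CGBead, CGStructure, map_to_cg

# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
STRAND_PHI = (-180.0, -90.0)
STRAND_PSI = (90.0, 180.0)


@dataclass
class SSAssignment:
    """Per-residue secondary-structure labels: H (helix), E (strand), C (coil)."""

    labels: list[str]

    def __post_init__(self) -> None:
        bad = set(self.labels) - {"H", "E", "C"}
        if bad:
            raise ValueError(f"invalid SS labels {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, i: int) -> str:
        return self.labels[i]

    def __iter__(self):
        return iter(self.labels)


def assign_secondary_structure(aa: AAStructure) -> SSAssignment:
    """Heuristic H/E/C assignment from backbone phi/psi dihedral windows.

    This is a deterministic convenience; the faithful path is importing a
    STRIDE or DSSP assignment via :func:`read_ss_file`.  Chains shorter than
    3 residues are all coil; terminal residues (missing one dihedral) are
    labelled from the dihedral they do have.
    """
    n = aa.n_residues
    if n < 3:
        return SSAssignment(["C"] * n)
    N = aa.backbone_positions("N")
    CA = aa.backbone_positions("CA")
    C = aa.backbone_positions("C")
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    for i in range(n):
        if i > 0:
            phi[i] = dihedral_angle(C[i - 1], N[i], CA[i], C[i])
        if i < n - 1:
            psi[i] = dihedral_angle(N[i], CA[i], C[i], N[i + 1])

    def in_window(x, lo_hi):
        return not np.isnan(x) and lo_hi[0] <= x <= lo_hi[1]

    labels = []
    for i in range(n):
        h_ok = (in_window(phi[i], HELIX_PHI) or np.isnan(phi[i])) and \
               (in_window(psi[i], HELIX_PSI) or np.isnan(psi[i]))
        e_ok = (in_window(phi[i], STRAND_PHI) or np.isnan(phi[i])) and \
               (in_window(psi[i], STRAND_PSI) or np.isnan(psi[i]))
        if np.isnan(phi[i]) and np.isnan(psi[i]):
            labels.append("C")
        elif h_ok:
            labels.append("H")
        elif e_ok:
            labels.append("E")
        else:
            labels.append("C")
    return SSAssignment(labels)


def read_ss_file(text: str, n_residues: int | None = None) -> SSAssignment:
    """Import a STRIDE/DSSP-style per-residue assignment.

    Accepts either a bare one-letter string ("HHHHCC...") or lines of
    ``<residue_index> <letter>``.  Letters map H/G/I -> H, E/B -> E,
    everything else -> C.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty secondary-structure assignment")
    mapping = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}
    lines = text.splitlines()
    if len(lines) == 1 and " " not in lines[0] and "\t" not in lines[0]:
        raw = list(lines[0].upper())
    else:
        entries = []
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed assignment line: {line!r}")
            entries.append((int(parts[0]), parts[-1].upper()))
        entries.sort()
        raw = [letter for _, letter in entries]
    labels = [mapping.get(c, "C") for c in raw]
    if n_residues is not None and len(labels) != n_residues:
        raise ValueError(
            f"assignment has {len(labels)} labels for {n_residues} residues")
    return SSAssignment(labels)


# ---------------------------------------------------------------------------
# term containers
# ---------------------------------------------------------------------------

@dataclass
class BondTerm:
    i: int
    j: int
    k: float        # kcal/mol/A^2
    r0: float       # A


@dataclass
class AngleTerm:
    i: int
    j: int
    k_: int
    k: float        # kcal/mol/rad^2
    theta0: float   # degrees


@dataclass
class DihedralTerm:
    i: int
    j: int
    k_: int
    l: int
    k: float        # kcal/mol
    n: int          # multiplicity
    delta: float    # phase, degrees


@dataclass
class ImproperTerm:
    i: int
    j: int
    k_: int
    l: int
    k: float        # kcal/mol/rad^2
    omega0: float   # degrees, native improper value


@dataclass
class BondedTerms:
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    dihedrals: list[DihedralTerm] = field(default_factory=list)
    impropers: list[ImproperTerm] = field(default_factory=list)


@dataclass
class ContactRecord:
    i: int              # SC bead index (i < j)
    j: int
    res_i: int          # 1-based residue indices
    res_j: int
    r_native: float     # A
    epsilon: float      # kcal/mol, nScale-scaled well depth


@dataclass
class HBondRecord:
    i: int              # CA bead index (i < j)
    j: int
    res_i: int
    res_j: int
    r_native: float     # native CA-CA distance, A
    epsilon: float      # kcal/mol, small


# ---------------------------------------------------------------------------
# native contacts and hydrogen bonds
# ---------------------------------------------------------------------------

def detect_native_contacts(cg: CGStructure, cutoff: float = 4.5,
                           min_separation: int = 3) -> list[tuple[int, int, float]]:
    """All SC-SC pairs within ``cutoff`` whose residues are >= min_separation apart.

    Returns (bead_i, bead_j, native_distance) sorted by (i, j); an empty list
    is a valid result.
    """
    sc = cg.sc_indices
    if len(sc) == 0:
        return []
    coords = cg.coords[sc]
    res = np.array([cg.beads[b].residue_index for b in sc])
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    out = []
    for a in range(len(sc)):
        for b in range(a + 1, len(sc)):
            if abs(res[a] - res[b]) >= min_separation and dist[a, b] <= cutoff:
                out.append((int(sc[a]), int(sc[b]), float(dist[a, b])))
    out.sort()
    return out


def detect_heavy_atom_contacts(aa: AAStructure, cg: CGStructure,
                               cutoff: float = 4.5,
                               min_separation: int = 3) -> list[tuple[int, int, float]]:
    """Alternative contact criterion: any side-chain heavy-atom pair within cutoff.

    The reported native distance is still the SC bead separation, since that
    is where the well minimum sits.
    """
    coords = cg.coords
    out = []
    residues = aa.residues
    for a in range(len(residues)):
        ia = cg.bead_index(residues[a].index, "SC")
        if ia is None:
            continue
        heavy_a = [at.position for at in residues[a].sidechain_atoms if not at.is_hydrogen]
        for b in range(a + 1, len(residues)):
            if abs(residues[a].index - residues[b].index) < min_separation:
                continue
            ib = cg.bead_index(residues[b].index, "SC")
            if ib is None:
                continue
            heavy_b = [at.position for at in residues[b].sidechain_atoms if not at.is_hydrogen]
            close = any(np.linalg.norm(pa - pb) <= cutoff
                        for pa in heavy_a for pb in heavy_b)
            if close:
                out.append((ia, ib, float(np.linalg.norm(coords[ia] - coords[ib]))))
    out.sort()
    return out


def contact_epsilon(res_i: str, res_j: str, table: MJTable | None = None,
                    nscale: float = 1.0, calibration: float = 0.6) -> float:
    """Native-contact well depth in kcal/mol.

    epsilon = nscale * calibration * (-e_MJ(i, j)); symmetric in the residue
    arguments and linear in nscale.  ``calibration`` converts the table's
    (RT) units to kcal/mol.
    """
    table = table or default_mj_table()
    e = table.energy(res_i, res_j)
    if e > 0:
        raise ValueError(
            f"contact energy for ({res_i}, {res_j}) is repulsive ({e}); "
            "the Go well depth must come from an attractive entry")
    return nscale * calibration * (-e)


def _amide_hydrogens(aa: AAStructure) -> np.ndarray:
    """Amide H positions, taken from the structure or reconstructed DSSP-style.

    When a residue has no backbone amide hydrogen (the usual case for crystal
    structures), H is placed 1.01 A from N along the C=O direction of the
    preceding residue; the first residue (and prolines, which have no amide H)
    get NaN and cannot donate.
    """
    n = aa.n_residues
    H = np.full((n, 3), np.nan)
    for i, res in enumerate(aa.residues):
        for name in ("H", "HN"):
            if res.has_atom(name):
                H[i] = res.atom(name).position
                break
        else:
            if i > 0 and res.name != "PRO":
                prev = aa.residues[i - 1]
                d = prev.atom("O").position - prev.atom("C").position
                H[i] = res.atom("N").position - 1.01 * d / np.linalg.norm(d)
    return H


def detect_hydrogen_bonds(aa: AAStructure, ss: SSAssignment | None = None,
                          threshold: float = 3.5,
                          h_threshold: float = 2.5,
                          min_separation: int = 3) -> list[tuple[int, int]]:
    """Backbone hydrogen-bonded residue pairs.

    A pair (i, j), |i - j| >= min_separation, is hydrogen bonded when a donor
    N...acceptor O distance is within ``threshold`` (A) *and* the amide
    H...O distance is within ``h_threshold``.  The H criterion (with H
    reconstructed from the preceding carbonyl when absent, as DSSP does) is
    what separates the alpha-helical i -> i+4 ladder from the nearby but
    non-bonded i -> i+3 geometry.  Returns 1-based residue index pairs sorted
    by (i, j).  ``ss`` is an optional filter hook: when supplied, pairs whose
    partners are both coil are dropped; pass None (default) for the purely
    geometric criterion.
    """
    n = aa.n_residues
    N = aa.backbone_positions("N")
    O = aa.backbone_positions("O")
    H = _amide_hydrogens(aa)

    def bonded(donor: int, acceptor: int) -> bool:
        if np.linalg.norm(N[donor] - O[acceptor]) > threshold:
            return False
        if np.any(np.isnan(H[donor])):
            return False
        return bool(np.linalg.norm(H[donor] - O[acceptor]) <= h_threshold)

    out = []
    for i in range(n):
        for j in range(i + min_separation, n):
            if bonded(i, j) or bonded(j, i):
                if ss is not None and ss[i] == "C" and ss[j] == "C":
                    continue
                out.append((aa.residues[i].index, aa.residues[j].index))
    return out


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------

def _dihedral_k(ss: SSAssignment, r1: int, r2: int, params: GoParams) -> float:
    """Force constant for the backbone dihedral whose central residues are r1, r2."""
    a, b = ss[r1], ss[r2]
    if a == "H" and b == "H":
        return params.dihedral_k_helix
    if a == "E" and b == "E":
        return params.dihedral_k_strand
    return params.dihedral_k_coil


def build_bonded_terms(cg: CGStructure, ss: SSAssignment,
                       params: GoParams | None = None) -> BondedTerms:
    """Bonded term lists with equilibria taken from the native CG geometry.

    Bonds: CA(i)-CA(i+1) and CA(i)-SC(i).  Angles: CA-CA-CA plus both
    CA-CA-SC flanks.  Backbone dihedrals CA(i)..CA(i+3) carry SS-dependent
    force constants with multiplicity 1 and phase set so the native value is
    the energy minimum.  One harmonic improper per interior non-glycine
    residue, on (CA(i-1), CA(i+1), CA(i), SC(i)), pins side-chain chirality.
    """
    params = params or GoParams()
    n = cg.n_residues
    if len(ss) != n:
        raise ValueError("secondary-structure assignment length mismatch")
    coords = cg.coords
    ca = [cg.bead_index(r + 1, "CA") for r in range(n)]
    sc = [cg.bead_index(r + 1, "SC") for r in range(n)]
    terms = BondedTerms()

    def dist(i, j):
        return float(np.linalg.norm(coords[i] - coords[j]))

    for r in range(n - 1):
        terms.bonds.append(BondTerm(ca[r], ca[r + 1], params.bond_k_backbone,
                                    dist(ca[r], ca[r + 1])))
    for r in range(n):
        if sc[r] is not None:
            terms.bonds.append(BondTerm(ca[r], sc[r], params.bond_k_sidechain,
                                        dist(ca[r], sc[r])))

    for r in range(n - 2):
        theta = bond_angle(coords[ca[r]], coords[ca[r + 1]], coords[ca[r + 2]])
        terms.angles.append(AngleTerm(ca[r], ca[r + 1], ca[r + 2],
                                      params.angle_k, theta))
    for r in range(n):
        if sc[r] is None:
            continue
        for other in (r - 1, r + 1):
            if 0 <= other < n:
                theta = bond_angle(coords[sc[r]], coords[ca[r]], coords[ca[other]])
                terms.angles.append(AngleTerm(sc[r], ca[r], ca[other],
                                              params.angle_k, theta))

    for r in range(n - 3):
        phi = dihedral_angle(coords[ca[r]], coords[ca[r + 1]],
                             coords[ca[r + 2]], coords[ca[r + 3]])
        k = _dihedral_k(ss, r + 1, r + 2, params)
        # E = k (1 + cos(n*phi - delta)); minimum at native requires
        # delta = native + 180 for n = 1
        terms.dihedrals.append(DihedralTerm(ca[r], ca[r + 1], ca[r + 2], ca[r + 3],
                                            k, 1, phi + 180.0))

    for r in range(1, n - 1):
        if sc[r] is None:
            continue
        omega = dihedral_angle(coords[ca[r - 1]], coords[ca[r + 1]],
                               coords[ca[r]], coords[sc[r]])
        terms.impropers.append(ImproperTerm(ca[r - 1], ca[r + 1], ca[r], sc[r],
                                            params.improper_k, omega))
    return terms


# ---------------------------------------------------------------------------
# the assembled model
# ---------------------------------------------------------------------------

@dataclass
class GoModel:
    """The complete coarse-grained Go model for one chain."""

    cg: CGStructure
    ss: SSAssignment
    bonded: BondedTerms
    contacts: list[ContactRecord]
    hbonds: list[HBondRecord]
    nscale: float
    params: GoParams
    exclusions: set[tuple[int, int]] = field(default_factory=set)
    repulsive_pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    repulsive_sigma: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_beads(self) -> int:
        return self.cg.n_beads

    @property
    def native_coords(self) -> np.ndarray:
        return self.cg.coords

    @property
    def masses(self) -> np.ndarray:
        return self.cg.masses

    def bead_sigma(self, bead_index: int) -> float:
        b = self.cg.beads[bead_index]
        return self.params.sigma_ca if b.site_type == "CA" else self.params.sigma_sc

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        beads = [{"site_type": b.site_type, "residue_index": b.residue_index,
                  "residue_name": b.residue_name, "mass": b.mass,
                  "position": list(map(float, b.position))} for b in self.cg.beads]
        data = {
            "format": "ktgo-model-v1",
            "source": self.cg.source,
            "nscale": self.nscale,
            "params": asdict(self.params),
            "ss": list(self.ss),
            "beads": beads,
            "bonds": [asdict(t) for t in self.bonded.bonds],
            "angles": [asdict(t) for t in self.bonded.angles],
            "dihedrals": [asdict(t) for t in self.bonded.dihedrals],
            "impropers": [asdict(t) for t in self.bonded.impropers],
            "contacts": [asdict(c) for c in self.contacts],
            "hbonds": [asdict(h) for h in self.hbonds],
        }
        return json.dumps(data, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GoModel":
        data = json.loads(text)
        if data.get("format") != "ktgo-model-v1":
            raise ValueError("not a ktgo model file")
        beads = [CGBead(b["site_type"], b["residue_index"], b["residue_name"],
                        b["mass"], np.array(b["position"]))
                 for b in data["beads"]]
        cg = CGStructure(beads=beads, source=data.get("source", ""))
        bonded = BondedTerms(
            bonds=[BondTerm(**t) for t in data["bonds"]],
            angles=[AngleTerm(**t) for t in data["angles"]],
            dihedrals=[DihedralTerm(**t) for t in data["dihedrals"]],
            impropers=[ImproperTerm(**t) for t in data["impropers"]],
        )
        model = cls(cg=cg, ss=SSAssignment(data["ss"]), bonded=bonded,
                    contacts=[ContactRecord(**c) for c in data["contacts"]],
                    hbonds=[HBondRecord(**h) for h in data["hbonds"]],
                    nscale=data["nscale"], params=GoParams(**data["params"]))
        _finalize_nonbonded(model)
        return model


def _bonded_exclusions(bonded: BondedTerms, n_beads: int) -> set[tuple[int, int]]:
    """All 1-2 and 1-3 pairs of the bond graph."""
    adj: dict[int, set[int]] = {i: set() for i in range(n_beads)}
    for b in bonded.bonds:
        adj[b.i].add(b.j)
        adj[b.j].add(b.i)
    excl: set[tuple[int, int]] = set()
    for i in range(n_beads):
        for j in adj[i]:
            excl.add((min(i, j), max(i, j)))
            for k in adj[j]:
                if k != i:
                    excl.add((min(i, k), max(i, k)))
    return excl


#: repulsive sigma is capped at this fraction of a pair's native separation,
#: so pairs that sit closer than their nominal excluded-volume radius in the
#: crystal do not frustrate the native state (which must stay the minimum)
NATIVE_SIGMA_CAP = 0.9


def _finalize_nonbonded(model: GoModel) -> None:
    """Derive exclusions and the repulsive pair set from the other term lists."""
    n = model.n_beads
    model.exclusions = _bonded_exclusions(model.bonded, n)
    taken = set(model.exclusions)
    taken |= {(c.i, c.j) for c in model.contacts}
    taken |= {(h.i, h.j) for h in model.hbonds}
    coords = model.cg.coords
    pairs = []
    sigmas = []
    for i in range(n):
        si = model.bead_sigma(i)
        for j in range(i + 1, n):
            if (i, j) in taken:
                continue
            pairs.append((i, j))
            sigma = 0.5 * (si + model.bead_sigma(j))
            d_native = float(np.linalg.norm(coords[i] - coords[j]))
            sigmas.append(min(sigma, NATIVE_SIGMA_CAP * d_native))
    model.repulsive_pairs = np.array(pairs, dtype=int).reshape(-1, 2)
    model.repulsive_sigma = np.array(sigmas)


def build_go_model(aa: AAStructure, nscale: float = 1.0,
                   params: GoParams | None = None,
                   ss: SSAssignment | None = None,
                   mj_table: MJTable | None = None,
                   contact_criterion: str = "sc_bead",
                   allow_incomplete: bool = False) -> GoModel:
    """Assemble the full Go model from an all-atom structure.

    Parameters
    ----------
    nscale:
        Global scale on native-contact well depths (default 1, no scaling).
    ss:
        Imported secondary-structure assignment; when None the built-in
        dihedral heuristic is used.
    contact_criterion:
        "sc_bead" (default): native contacts from SC bead distances;
        "heavy_atom": any side-chain heavy-atom pair within the cutoff.
    """
    params = params or GoParams()
    params.validate()
    table = mj_table or default_mj_table()
    cg = map_to_cg(aa, allow_incomplete=allow_incomplete)
    if ss is None:
        ss = assign_secondary_structure(aa)
    elif len(ss) != aa.n_residues:
        raise ValueError("imported SS assignment length mismatch")
    bonded = build_bonded_terms(cg, ss, params)

    if contact_criterion == "sc_bead":
        raw = detect_native_contacts(cg, params.contact_cutoff, params.min_separation)
    elif contact_criterion == "heavy_atom":
        raw = detect_heavy_atom_contacts(aa, cg, params.contact_cutoff,
                                         params.min_separation)
    else:
        raise ValueError(f"unknown contact criterion {contact_criterion!r}")

    contacts = []
    for i, j, r_nat in raw:
        bi, bj = cg.beads[i], cg.beads[j]
        eps = contact_epsilon(bi.residue_name, bj.residue_name, table,
                              nscale, params.mj_calibration)
        contacts.append(ContactRecord(i, j, bi.residue_index, bj.residue_index,
                                      r_nat, eps))

    if contacts:
        eps_hb = params.hbond_eps_fraction * min(c.epsilon for c in contacts)
    else:
        eps_hb = params.hbond_eps_floor
    hb_pairs = detect_hydrogen_bonds(aa, threshold=params.hbond_distance,
                                     h_threshold=params.hbond_h_distance,
                                     min_separation=params.hbond_min_separation)
    coords = cg.coords
    hbonds = []
    for ri, rj in hb_pairs:
        bi = cg.bead_index(ri, "CA")
        bj = cg.bead_index(rj, "CA")
        i, j = min(bi, bj), max(bi, bj)
        hbonds.append(HBondRecord(i, j, ri, rj,
                                  float(np.linalg.norm(coords[i] - coords[j])),
                                  eps_hb))

    model = GoModel(cg=cg, ss=ss, bonded=bonded, contacts=contacts,
                    hbonds=hbonds, nscale=float(nscale), params=params)
    _finalize_nonbonded(model)
    # hydrogen-bonded pairs that fall inside the exclusion set (e.g. i, i+2 in
    # tight turns) are dropped: bonded terms already govern them
    kept = [h for h in model.hbonds if (h.i, h.j) not in model.exclusions]
    if len(kept) != len(model.hbonds):
        model.hbonds = kept
        _finalize_nonbonded(model)
    return model
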