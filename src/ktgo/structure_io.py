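"""All-atom / coarse-grained structure containers, PDB I/O and the two-bead mapping.

Every residue is reduced to a backbone bead placed on the alpha carbon (CA)
and a side-chain bead (SC) placed at the mass-weighted centre of the
side-chain atoms; glycine carries no SC bead.  Coordinates are Angstrom
throughout.  Residues are renumbered serially (1-based) after parsing so that
insertion codes and numbering gaps cannot produce an ambiguous topology.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .constants import (
    BACKBONE_ATOMS,
    SIDECHAIN_HEAVY_COUNT,
    STANDARD_RESIDUES,
    element_mass,
    guess_element,
)


class PDBParseError(ValueError):
    """Raised when PDB text cannot be interpreted."""


class StructureError(ValueError):
    """Raised when a structure violates the model's requirements."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    name: str
    element: str
    mass: float
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Residue:
    index: int          # serial, 1-based
    name: str           # 3-letter code
    chain_id: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise StructureError(f"residue {self.name}{self.index} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def sidechain_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_backbone]


@dataclass
class AAStructure:
    """An all-atom protein chain: ordered residues holding AtomRecords."""

    residues: list[Residue]
    source: str = ""
    chain_id: str = ""

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> list[str]:
        return [r.name for r in self.residues]

    def backbone_positions(self, atom_name: str) -> np.ndarray:
        return np.array([r.atom(atom_name).position for r in self.residues])


@dataclass
class CGBead:
    site_type: str      # "CA" or "SC"
    residue_index: int  # 1-based
    residue_name: str
    mass: float
    position: np.ndarray


@dataclass
class CGStructure:
    """Ordered coarse-grained beads plus the bead <-> residue back-reference."""

    beads: list[CGBead]
    source: str = ""

    def __post_init__(self) -> None:
        self._index = {(b.residue_index, b.site_type): i for i, b in enumerate(self.beads)}

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def n_residues(self) -> int:
        return len({b.residue_index for b in self.beads})

    @property
    def coords(self) -> np.ndarray:
        return np.array([b.position for b in self.beads])

    @property
    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads])

    def bead_index(self, residue_index: int, site_type: str) -> int | None:
        """0-based bead index for (residue, site), or None if absent (glycine SC)."""
        return self._index.get((residue_index, site_type))

    @property
    def ca_indices(self) -> np.ndarray:
        return np.array([i for i, b in enumerate(self.beads) if b.site_type == "CA"])

    @property
    def sc_indices(self) -> np.ndarray:
        return np.array([i for i, b in enumerate(self.beads) if b.site_type == "SC"],
                        dtype=int)

    def residue_name_of(self, residue_index: int) -> str:
        i = self.bead_index(residue_index, "CA")
        return self.beads[i].residue_name


@dataclass
class Trajectory:
    """Ordered frames of bead coordinates with times in ps."""

    positions: np.ndarray          # (n_frames, n_beads, 3)
    times: np.ndarray              # (n_frames,)
    config: dict | None = None     # the simulation config that produced it
    model_ref: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_beads, 3)")
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions disagree on frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]


# ---------------------------------------------------------------------------
# all-atom PDB parsing
# ---------------------------------------------------------------------------

def parse_pdb(text: str, chain: str | None = None, source: str = "") -> AAStructure:
    """Parse PDB-format text into an :class:`AAStructure`.

    Only the first model of a multi-model file is used; only the selected
    chain (or the first chain if ``chain`` is None) is retained.  HETATM
    records are skipped.  For alternate locations only the blank or "A"
    conformer is kept.  Hydrogens are retained when present.

    Raises
    ------
    PDBParseError
        if the text contains no usable ATOM records.
    StructureError
        if a residue lacks a CA atom or carries a non-standard name.
    """
    if "ATOM" not in text:
        raise PDBParseError("no ATOM records found in PDB input")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure(source or "pdb", io.StringIO(text))
    models = list(structure.get_models())
    if not models:
        raise PDBParseError("no models found in PDB input")
    model = models[0]

    chains = {c.id: c for c in model.get_chains()}
    if chain is not None:
        if chain not in chains:
            raise PDBParseError(f"chain {chain!r} not present (have {sorted(chains)})")
        bio_chain = chains[chain]
    else:
        bio_chain = next(iter(chains.values()))

    residues: list[Residue] = []
    serial = 0
    for res in bio_chain.get_residues():
        hetflag = res.id[0]
        if hetflag != " ":
            continue  # skip HETATM / waters
        name = res.get_resname().strip()
        if name not in STANDARD_RESIDUES:
            raise StructureError(f"non-standard residue {name!r} at {res.id[1]}")
        serial += 1
        out = Residue(index=serial, name=name, chain_id=bio_chain.id)
        seen: set[str] = set()
        for atom in res.get_unpacked_list():
            altloc = atom.get_altloc()
            if altloc not in (" ", "", "A"):
                continue
            aname = atom.get_name().strip()
            if aname in seen:
                continue
            seen.add(aname)
            element = (atom.element or "").strip() or guess_element(aname)
            try:
                mass = element_mass(element)
            except KeyError as exc:
                raise StructureError(
                    f"unsupported element {element!r} in residue {name}{serial}"
                ) from exc
            pos = np.asarray(atom.get_coord(), dtype=float)
            if not np.all(np.isfinite(pos)):
                raise StructureError(f"non-finite coordinates for {name}{serial}:{aname}")
            out.atoms.append(AtomRecord(aname, element, mass, serial, name,
                                        bio_chain.id, pos))
        if not out.has_atom("CA"):
            raise StructureError(f"residue {name}{serial} is missing its CA atom")
        residues.append(out)

    if not residues:
        raise PDBParseError("no standard amino-acid ATOM records in selected chain")
    return AAStructure(residues=residues, source=source, chain_id=bio_chain.id)


# ---------------------------------------------------------------------------
# two-bead mapping
# ---------------------------------------------------------------------------

def map_to_cg(aa: AAStructure, allow_incomplete: bool = False) -> CGStructure:
    """Map an all-atom structure onto the two-bead representation.

    The CA bead sits exactly on the alpha carbon and carries the summed mass
    of the residue's backbone atoms.  The SC bead sits at the mass-weighted
    centroid of all side-chain atoms (CB and beyond, hydrogens included when
    present) and carries their summed mass.  Glycine has no SC bead.

    Parameters
    ----------
    allow_incomplete:
        When True, residues with fewer side-chain heavy atoms than expected
        still get an SC bead at the centroid of whatever atoms are present.
        The default is to raise, because a silently misplaced bead corrupts
        the native-contact map.
    """
    beads: list[CGBead] = []
    for res in aa.residues:
        ca = res.atom("CA")
        bb_mass = sum(a.mass for a in res.atoms if a.is_backbone)
        beads.append(CGBead("CA", res.index, res.name, bb_mass, ca.position.copy()))
        if res.name == "GLY":
            continue
        side = res.sidechain_atoms
        if not side:
            raise StructureError(
                f"residue {res.name}{res.index} has no side-chain atoms; "
                "cannot place its SC bead")
        n_heavy = sum(1 for a in side if not a.is_hydrogen)
        expected = SIDECHAIN_HEAVY_COUNT[res.name]
        if n_heavy < expected and not allow_incomplete:
            raise StructureError(
                f"residue {res.name}{res.index} has {n_heavy} side-chain heavy "
                f"atoms, expected {expected}; pass allow_incomplete=True to place "
                "the SC bead at the centroid of the available atoms")
        masses = np.array([a.mass for a in side])
        pos = np.array([a.position for a in side])
        centroid = (masses[:, None] * pos).sum(axis=0) / masses.sum()
        beads.append(CGBead("SC", res.index, res.name, float(masses.sum()), centroid))
    return CGStructure(beads=beads, source=aa.source)


# ---------------------------------------------------------------------------
# coarse-grained PDB I/O
# ---------------------------------------------------------------------------

_ATOM_FMT = ("ATOM  {serial:>5d} {name:<4s}{resname:>4s} {chain:1s}{resseq:>4d}    "
             "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bf:6.2f}          {elem:>2s}\n")


def write_cg_pdb(cg: CGStructure) -> str:
    """Serialise a CG structure as PDB text.

    The bead mass is stored in the occupancy column so the representation
    round-trips without re-deriving masses from an all-atom parent.
    """
    lines = []
    for i, b in enumerate(cg.beads, start=1):
        name = " CA " if b.site_type == "CA" else " SC "
        lines.append(_ATOM_FMT.format(
            serial=i, name=name, resname=b.residue_name, chain="A",
            resseq=b.residue_index, x=b.position[0], y=b.position[1],
            z=b.position[2], occ=min(b.mass, 999.99), bf=0.0, elem="C"))
    lines.append("TER\nEND\n")
    return "".join(lines)


def read_cg_pdb(text: str) -> CGStructure:
    """Parse CG PDB text written by :func:`write_cg_pdb`.

    Rejects files whose bead names are anything but CA or SC.
    """
    beads: list[CGBead] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            name = line[12:16].strip()
            resname = line[17:20].strip()
            resseq = int(line[22:26])
            pos = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            occ = float(line[54:60]) if line[54:60].strip() else 0.0
        except (ValueError, IndexError) as exc:
            raise PDBParseError(f"malformed ATOM record on line {lineno}") from exc
        if name not in ("CA", "SC"):
            raise PDBParseError(
                f"bead name {name!r} on line {lineno}: expected CA or SC")
        if resname not in STANDARD_RESIDUES:
            raise PDBParseError(f"unknown residue {resname!r} on line {lineno}")
        beads.append(CGBead(name, resseq, resname, occ, pos))
    if not beads:
        raise PDBParseError("no ATOM records in CG PDB input")
    return CGStructure(beads=beads)


# ---------------------------------------------------------------------------
# trajectory I/O (multi-model PDB with per-frame time remarks)
# ---------------------------------------------------------------------------

def trajectory_to_pdb(traj: Trajectory, cg: CGStructure) -> str:
    """Render a trajectory as multi-model PDB text (one MODEL per frame)."""
    if traj.n_beads != cg.n_beads:
        raise ValueError("trajectory and structure disagree on bead count")
    chunks = []
    if traj.config is not None:
        chunks.append("REMARK   6 CONFIG " + json.dumps(traj.config, sort_keys=True) + "\n")
    for f in range(traj.n_frames):
        chunks.append(f"MODEL     {f + 1:>4d}\n")
        chunks.append(f"REMARK   6 TIME_PS {traj.times[f]:.9g}\n")
        frame = CGStructure(
            beads=[CGBead(b.site_type, b.residue_index, b.residue_name, b.mass,
                          traj.positions[f, i]) for i, b in enumerate(cg.beads)],
            source=cg.source)
        body = write_cg_pdb(frame)
        chunks.append(body.replace("TER\nEND\n", "ENDMDL\n"))
    chunks.append("END\n")
    return "".join(chunks)


def write_trajectory(traj: Trajectory, path, cg: CGStructure) -> None:
    with open(path, "w") as fh:
        fh.write(trajectory_to_pdb(traj, cg))


def trajectory_from_pdb(text: str) -> tuple[Trajectory, CGStructure]:
    """Read a multi-model CG PDB back into a Trajectory plus its topology."""
    frames: list[np.ndarray] = []
    times: list[float] = []
    config = None
    first_cg: CGStructure | None = None
    current: list[str] = []
    in_model = False
    for line in text.splitlines():
        if line.startswith("REMARK   6 CONFIG "):
            config = json.loads(line[len("REMARK   6 CONFIG "):])
        elif line.startswith("REMARK   6 TIME_PS "):
            times.append(float(line.split()[-1]))
        elif line.startswith("MODEL"):
            in_model = True
            current = []
        elif line.startswith("ENDMDL"):
            cg = read_cg_pdb("\n".join(current) + "\nEND\n")
            if first_cg is None:
                first_cg = cg
            elif cg.n_beads != first_cg.n_beads:
                raise PDBParseError("frames disagree on bead count")
            frames.append(cg.coords)
            in_model = False
        elif in_model:
            current.append(line)
    if not frames:
        raise PDBParseError("no MODEL frames found in trajectory input")
    if len(times) != len(frames):
        raise PDBParseError("missing TIME_PS remark for one or more frames")
    traj = Trajectory(np.array(frames), np.array(times), config=config)
    return traj, first_cg


def read_trajectory(path) -> tuple[Trajectory, CGStructure]:
    with open(path) as fh:
        return trajectory_from_pdb(fh.read())
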