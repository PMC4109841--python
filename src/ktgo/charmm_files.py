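"""CHARMM-dialect topology (RTF), parameter (PRM) and coordinate (CRD) emitters.

Interop plumbing for running the generated Go models in the wider CHARMM
ecosystem.  Every bead gets its own atom type (G1, G2, ...) so that native
wells can be encoded as NBFIX pairwise entries; the excluded-volume r^-12
repulsion has no exact LJ 12-6 equivalent, so the per-type NONBONDED lines
approximate it by an LJ minimum at 2^(1/6) sigma with well depth
eps_repulsive (documented approximation, flagged in the file header).
Output is deterministic ("golden-file stable") for a given model.
"""

from __future__ import annotations

from .go_builder import GoModel


def _bead_name(model: GoModel, i: int) -> str:
    b = model.cg.beads[i]
    prefix = "A" if b.site_type == "CA" else "B"
    return f"{prefix}{b.residue_index}"


def write_rtf(model: GoModel) -> str:
    lines = ["* Go-model topology (two-site CG); one atom type per bead", "*",
             "   22     1"]
    for i, b in enumerate(model.cg.beads):
        lines.append(f"MASS {i + 1:5d} G{i + 1:<6d} {b.mass:10.4f}")
    lines.append("")
    lines.append("RESI GO          0.00")
    lines.append("GROUP")
    for i in range(model.n_beads):
        lines.append(f"ATOM {_bead_name(model, i):<6s} G{i + 1:<6d} 0.00")
    for t in model.bonded.bonds:
        lines.append(f"BOND {_bead_name(model, t.i):<6s} {_bead_name(model, t.j):<6s}")
    for t in model.bonded.impropers:
        lines.append("IMPR " + " ".join(
            f"{_bead_name(model, a):<6s}" for a in (t.i, t.j, t.k_, t.l)))
    lines.append("")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_prm(model: GoModel) -> str:
    p = model.params
    lines = ["* Go-model parameters; NBFIX carries the native wells",
             "* repulsion approximated per-type as LJ with rmin = 2^(1/6) sigma",
             "*", ""]
    lines.append("BONDS")
    for t in model.bonded.bonds:
        lines.append(f"G{t.i + 1:<6d} G{t.j + 1:<6d} {t.k:10.4f} {t.r0:10.4f}")
    lines.append("")
    lines.append("ANGLES")
    for t in model.bonded.angles:
        lines.append(f"G{t.i + 1:<6d} G{t.j + 1:<6d} G{t.k_ + 1:<6d} "
                     f"{t.k:10.4f} {t.theta0:10.4f}")
    lines.append("")
    lines.append("DIHEDRALS")
    for t in model.bonded.dihedrals:
        lines.append(f"G{t.i + 1:<6d} G{t.j + 1:<6d} G{t.k_ + 1:<6d} G{t.l + 1:<6d} "
                     f"{t.k:10.4f} {t.n:3d} {t.delta:10.4f}")
    lines.append("")
    lines.append("IMPROPER")
    for t in model.bonded.impropers:
        lines.append(f"G{t.i + 1:<6d} G{t.j + 1:<6d} G{t.k_ + 1:<6d} G{t.l + 1:<6d} "
                     f"{t.k:10.4f}   0 {t.omega0:10.4f}")
    lines.append("")
    lines.append(f"NONBONDED NBXMOD 3 SWITCH CTONNB {p.switch_r_on:.1f} "
                 f"CTOFNB {p.switch_r_off:.1f}")
    rmin_scale = 2.0 ** (1.0 / 6.0)
    for i in range(model.n_beads):
        sigma = model.bead_sigma(i)
        lines.append(f"G{i + 1:<6d} 0.0 {-p.eps_repulsive:10.4f} "
                     f"{0.5 * rmin_scale * sigma:10.4f}")
    lines.append("")
    lines.append("NBFIX")
    for c in model.contacts:
        lines.append(f"G{c.i + 1:<6d} G{c.j + 1:<6d} {-c.epsilon:10.4f} {c.r_native:10.4f}")
    for h in model.hbonds:
        lines.append(f"G{h.i + 1:<6d} G{h.j + 1:<6d} {-h.epsilon:10.4f} {h.r_native:10.4f}")
    lines.append("")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_crd(model: GoModel) -> str:
    lines = ["* Go-model coordinates", "*", f"{model.n_beads:5d}"]
    for i, b in enumerate(model.cg.beads):
        lines.append(f"{i + 1:5d}{b.residue_index:5d} {'GO':<4s} "
                     f"{_bead_name(model, i):<4s}{b.position[0]:10.5f}"
                     f"{b.position[1]:10.5f}{b.position[2]:10.5f} "
                     f"{'GO':<4s} {b.residue_index:<4d}{0.0:10.5f}")
    return "\n".join(lines) + "\n"


def write_charmm_files(model: GoModel) -> dict[str, str]:
    """Topology, parameter and coordinate text for a model, keyed rtf/prm/crd."""
    return {"rtf": write_rtf(model), "prm": write_prm(model), "crd": write_crd(model)}
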