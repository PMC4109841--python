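"""Default force-field and protocol parameters, editable via one YAML file.

The numeric defaults below are this package's own pinned parameter set for
the two-site Go model (force constants, excluded-volume radii, the MJ-to-
kcal/mol calibration, hydrogen-bond strength fraction).  They are chosen to
give a stable native basin with a folding/unfolding transition at accessible
temperatures for small helical bundles; every value can be overridden from a
config file or keyword arguments.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class GoParams:
    """Parameters controlling Go-model construction and energetics.

    Units: force constants kcal/mol/A^2 (bonds), kcal/mol/rad^2 (angles,
    impropers), kcal/mol (dihedral barriers); lengths in Angstrom.
    """

    # bonded terms
    bond_k_backbone: float = 50.0     # CA(i)-CA(i+1)
    bond_k_sidechain: float = 50.0    # CA(i)-SC(i)
    angle_k: float = 30.0
    dihedral_k_helix: float = 1.0
    dihedral_k_strand: float = 1.0
    dihedral_k_coil: float = 0.3
    improper_k: float = 20.0          # chirality barrier, ~20x the dihedral scale

    # native contacts
    contact_cutoff: float = 4.5       # A, SC-SC distance in the crystal
    min_separation: int = 3           # minimum |i - j| for nonbonded SC pairs
    mj_calibration: float = 0.6       # kcal/mol per MJ unit (~RT at 300 K)

    # hydrogen bonds
    hbond_distance: float = 3.5       # A, backbone N...O criterion
    hbond_h_distance: float = 2.5     # A, amide H...O criterion (H rebuilt if absent)
    hbond_min_separation: int = 3
    hbond_eps_fraction: float = 0.5   # epsilon_hb = fraction * min contact epsilon
    hbond_eps_floor: float = 0.1      # kcal/mol, used when a model has no contacts

    # excluded volume (non-native pairs): eps_rep * (sigma/r)^12
    eps_repulsive: float = 1.0
    sigma_ca: float = 3.8
    sigma_sc: float = 3.6

    # nonbonded truncation
    switch_r_on: float = 18.0
    switch_r_off: float = 23.0

    def validate(self) -> None:
        if not 0 < self.switch_r_on < self.switch_r_off:
            raise ValueError("require 0 < switch_r_on < switch_r_off")
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v < 0:
                raise ValueError(f"{f.name} must be non-negative")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GoParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown parameter(s) in config: {sorted(unknown)}")
        p = cls(**data)
        p.validate()
        return p

    def replace(self, **kwargs) -> "GoParams":
        data = asdict(self)
        data.update(kwargs)
        p = GoParams(**data)
        p.validate()
        return p


@dataclass
class SimConfig:
    """Langevin dynamics settings (AKMA-like units: ps, K)."""

    dt: float = 0.001              # ps (1 fs)
    friction: float = 5.0          # collision frequency FBETA, ps^-1
    temperature: float = 300.0     # bath temperature, K
    n_steps: int = 1000
    save_interval: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class MinConfig:
    """Minimization protocol: steepest descent then quasi-Newton."""

    sd_steps: int = 10
    qn_steps: int = 100
    gradient_tol: float = 1e-8

    def validate(self) -> None:
        if self.sd_steps < 0 or self.qn_steps < 0:
            raise ValueError("step counts must be non-negative")


@dataclass
class RexConfig:
    """Temperature replica-exchange settings."""

    temperatures: list[float] = field(
        default_factory=lambda: geometric_ladder(250.0, 700.0, 6))
    steps_per_exchange: int = 500
    n_rounds: int = 40
    seed: int = 0

    def validate(self) -> None:
        temps = list(self.temperatures)
        if len(temps) < 2:
            raise ValueError("need at least 2 ladder temperatures")
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("temperature ladder must be strictly increasing")


def default_params_path():
    """Path to the packaged, commented copy of the default parameter file."""
    from importlib.resources import files
    return files("ktgo").joinpath("data/default_params.yaml")


def geometric_ladder(t_min: float, t_max: float, n: int) -> list[float]:
    """Geometrically spaced temperature ladder, the standard REX choice."""
    import numpy as np
    return [float(t) for t in np.geomspace(t_min, t_max, n)]


def load_config(path) -> dict:
    """Load a YAML config file holding 'params', 'sim', 'minimize', 'rex' blocks."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    out = {}
    if "params" in data:
        out["params"] = GoParams(**data["params"])
    if "sim" in data:
        out["sim"] = SimConfig(**data["sim"])
    if "minimize" in data:
        out["minimize"] = MinConfig(**data["minimize"])
    if "rex" in data:
        out["rex"] = RexConfig(**data["rex"])
    return out
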