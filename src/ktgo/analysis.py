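"""Reaction coordinates, folded-fraction statistics and two-state thermodynamics.

The primary reaction coordinate is Q, the fraction of native contacts: the
fraction of native side-chain pairs whose instantaneous separation is within
a tolerance factor (default 1.2) of the crystal separation.  A frame with
Q above a threshold (default 0.5) counts as folded; the fraction of folded
frames per ladder temperature gives the melting curve, and a weighted
two-state Gibbs-Helmholtz fit of that curve yields Tm, the enthalpy of
fusion dH and the heat-capacity change dCp.

Sign convention: dG_u(T) = dH (1 - T/Tm) + dCp [(T - Tm) - T ln(T/Tm)] is
the *unfolding* free energy, zero at Tm, so the folded fraction is
f(T) = 1 / (1 + exp(-dG_u / (R T))).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import KB
from .geometry import kabsch_superpose
from .go_builder import ContactRecord, GoModel
from .structure_io import Trajectory


@dataclass
class QSeries:
    """Per-frame fraction of native contacts."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have the same length")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("Q values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times, "Q": self.values})


@dataclass
class MeltingCurve:
    """(temperature, fraction folded) pairs with per-point uncertainties."""

    temperatures: np.ndarray
    fraction_folded: np.ndarray
    uncertainty: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fraction_folded = np.asarray(self.fraction_folded, dtype=float)
        self.uncertainty = np.asarray(self.uncertainty, dtype=float)
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any((self.fraction_folded < 0) | (self.fraction_folded > 1)):
            raise ValueError("fraction folded must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"temperature_K": self.temperatures,
                             "fraction_folded": self.fraction_folded,
                             "uncertainty": self.uncertainty})


@dataclass
class ThermoFit:
    """Two-state fit: melting temperature, enthalpy of fusion, heat capacity."""

    tm: float                 # K
    dh: float                 # kcal/mol at Tm
    dcp: float                # kcal/mol/K
    tm_err: float
    dh_err: float
    dcp_err: float
    residual: float           # weighted RMS residual

    def as_dict(self) -> dict:
        return {"Tm_K": self.tm, "dH_kcal_mol": self.dh, "dCp_kcal_mol_K": self.dcp,
                "Tm_err": self.tm_err, "dH_err": self.dh_err, "dCp_err": self.dcp_err,
                "residual": self.residual}


# ---------------------------------------------------------------------------
# reaction coordinates
# ---------------------------------------------------------------------------

def fraction_native_contacts(coords: np.ndarray, contacts: list[ContactRecord],
                             tolerance_factor: float = 1.2) -> float:
    """Q for one frame: fraction of contacts with r <= tolerance_factor * r_native."""
    if not contacts:
        raise ValueError("Q is undefined for an empty contact list")
    coords = np.asarray(coords, dtype=float)
    idx = np.array([[c.i, c.j] for c in contacts])
    r0 = np.array([c.r_native for c in contacts])
    r = np.linalg.norm(coords[idx[:, 0]] - coords[idx[:, 1]], axis=1)
    return float(np.mean(r <= tolerance_factor * r0))


def q_series(traj: Trajectory, model: GoModel,
             tolerance_factor: float = 1.2) -> QSeries:
    """Q for every frame of a trajectory."""
    values = [fraction_native_contacts(traj.positions[f], model.contacts,
                                       tolerance_factor)
              for f in range(traj.n_frames)]
    return QSeries(times=traj.times, values=np.array(values))


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration (A)."""
    coords = np.asarray(coords, dtype=float)
    m = np.asarray(masses, dtype=float)
    com = (m[:, None] * coords).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((coords - com) ** 2).sum(axis=1)).sum() / m.sum()))


def backbone_rmsd(coords: np.ndarray, reference: np.ndarray,
                  indices: np.ndarray | None = None) -> float:
    """RMSD (A) after optimal rigid (Kabsch) superposition.

    ``indices`` selects the beads to superpose and measure (typically the CA
    beads); default is all beads.
    """
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if indices is not None:
        coords = coords[indices]
        reference = reference[indices]
    R, t = kabsch_superpose(coords, reference)
    moved = coords @ R.T + t
    return float(np.sqrt(np.mean(((moved - reference) ** 2).sum(axis=1))))


# ---------------------------------------------------------------------------
# folded-fraction statistics
# ---------------------------------------------------------------------------

def fraction_folded(q: QSeries, threshold: float = 0.5,
                    burn_in: float = 0.1, n_blocks: int = 5) -> tuple[float, float]:
    """Fraction of frames with Q > threshold after discarding initial burn-in.

    Returns (f, uncertainty) where the uncertainty is the standard error of
    block means over ``n_blocks`` blocks (correlated-series aware), floored
    by the binomial standard error.
    """
    if not 0 <= burn_in < 1:
        raise ValueError("burn_in must be a fraction in [0, 1)")
    values = q.values[int(len(q) * burn_in):]
    if len(values) == 0:
        raise ValueError("no frames left after burn-in")
    folded = values > threshold
    f = float(np.mean(folded))
    nb = min(n_blocks, len(folded))
    blocks = np.array_split(folded.astype(float), nb)
    block_means = np.array([b.mean() for b in blocks])
    se_block = float(block_means.std(ddof=1) / np.sqrt(nb)) if nb > 1 else 0.0
    se_binom = float(np.sqrt(max(f * (1 - f), 1e-12) / len(folded)))
    return f, max(se_block, se_binom)


def melting_curve(series_by_temperature: dict[float, QSeries],
                  threshold: float = 0.5, burn_in: float = 0.1) -> MeltingCurve:
    """Apply fraction_folded at each ladder temperature."""
    if not series_by_temperature:
        raise ValueError("need at least one temperature")
    temps = sorted(series_by_temperature)
    fs, errs = [], []
    for T in temps:
        f, err = fraction_folded(series_by_temperature[T], threshold, burn_in)
        fs.append(f)
        errs.append(err)
    return MeltingCurve(np.array(temps), np.array(fs), np.array(errs))


# ---------------------------------------------------------------------------
# two-state thermodynamics
# ---------------------------------------------------------------------------

def unfolding_free_energy(T, tm, dh, dcp):
    """Gibbs-Helmholtz dG_u(T); zero at Tm by construction (kcal/mol)."""
    T = np.asarray(T, dtype=float)
    return dh * (1.0 - T / tm) + dcp * ((T - tm) - T * np.log(T / tm))


def two_state_fraction_folded(T, tm, dh, dcp):
    """Closed-form folded fraction f(T) = 1/(1 + exp(-dG_u/(R T)))."""
    T = np.asarray(T, dtype=float)
    return 1.0 / (1.0 + np.exp(-unfolding_free_energy(T, tm, dh, dcp) / (KB * T)))


def _interpolated_crossing(curve: MeltingCurve, level: float = 0.5) -> float:
    """Temperature where the curve crosses ``level``, by linear interpolation."""
    temps = curve.temperatures
    f = curve.fraction_folded
    for k in range(len(temps) - 1):
        lo, hi = f[k], f[k + 1]
        if (lo - level) * (hi - level) <= 0 and lo != hi:
            return float(temps[k] + (level - lo) / (hi - lo) * (temps[k + 1] - temps[k]))
    raise ValueError(
        "melting curve never crosses f = "
        f"{level}: range [{f.min():.3f}, {f.max():.3f}]; widen the ladder")


def fit_gibbs_helmholtz(curve: MeltingCurve) -> ThermoFit:
    """Weighted least-squares two-state fit of a melting curve.

    Needs at least 4 temperatures spanning the transition.  Initial guesses:
    Tm from the interpolated f = 0.5 crossing, dH from the slope there
    (df/dT at Tm equals -dH / (4 R Tm^2)), dCp = 0.
    """
    from scipy.optimize import curve_fit

    temps = curve.temperatures
    f = curve.fraction_folded
    if len(temps) < 4:
        raise ValueError("need at least 4 temperatures for the two-state fit")
    tm0 = _interpolated_crossing(curve)
    k = int(np.argmin(np.abs(temps - tm0)))
    k0, k1 = max(0, k - 1), min(len(temps) - 1, k + 1)
    slope = (f[k1] - f[k0]) / (temps[k1] - temps[k0])
    dh0 = max(-4.0 * KB * tm0 ** 2 * slope, 1.0)
    sigma = np.maximum(curve.uncertainty, 1e-3)

    try:
        popt, pcov = curve_fit(two_state_fraction_folded, temps, f,
                               p0=[tm0, dh0, 0.0], sigma=sigma,
                               absolute_sigma=False, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"two-state fit did not converge (initial guesses Tm={tm0:.1f} K, "
            f"dH={dh0:.1f} kcal/mol, dCp=0)") from exc
    perr = np.sqrt(np.diag(pcov))
    resid = (two_state_fraction_folded(temps, *popt) - f) / sigma
    return ThermoFit(tm=float(popt[0]), dh=float(popt[1]), dcp=float(popt[2]),
                     tm_err=float(perr[0]), dh_err=float(perr[1]),
                     dcp_err=float(perr[2]),
                     residual=float(np.sqrt(np.mean(resid ** 2))))


def estimate_tm(curve: MeltingCurve) -> float:
    """Melting temperature: f = 0.5 from the two-state fit when possible,
    otherwise the monotone interpolated crossing.

    Raises if the curve never crosses 0.5.
    """
    # interpolation both validates the crossing and provides the fallback
    t_interp = _interpolated_crossing(curve)
    if len(curve.temperatures) >= 4:
        try:
            fit = fit_gibbs_helmholtz(curve)
            if curve.temperatures[0] <= fit.tm <= curve.temperatures[-1]:
                return fit.tm
        except RuntimeError:
            pass
    return t_interp
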