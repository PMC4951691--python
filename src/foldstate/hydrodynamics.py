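"""Hydrodynamic analysis chain.

Size-exclusion chromatography (SEC) partition-coefficient calibration and
inversion, sucrose-gradient sedimentation interpolation, the Siegel-Monte
mass estimate M = s*N0*(6*pi*eta*Rh)/(1 - nu2*rho), per-state empirical
Rh-vs-mass scaling laws, and the Q-factor Rg/Rh with its compatibility
bands.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import default_config

AVOGADRO = 6.02214076e23      # mol^-1
SVEDBERG_S = 1e-13            # seconds per Svedberg
NM_M = 1e-9                   # metres per nanometre

STATES = ("native", "molten_globule", "pre_molten_globule",
          "urea_unfolded", "gdmcl_unfolded")


class ExtrapolationWarning(UserWarning):
    """A value was evaluated outside the calibrated range."""


@dataclass(frozen=True)
class SolventModel:
    """Solvent parameters for the Siegel-Monte relation.

    viscosity in Pa*s; buoyancy_product is nu2*rho (partial specific volume
    times solvent density), dimensionless.
    """
    viscosity: float = 0.001
    buoyancy_product: float = 0.73

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        if not 0.0 < self.buoyancy_product < 1.0:
            raise ValueError("buoyancy product nu2*rho must be in (0, 1)")


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    residuals: np.ndarray

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


@dataclass
class SECCalibration:
    void_volume: float            # mL
    total_volume: float           # mL
    standards: pd.DataFrame       # columns: name, Ve_mL, Kav, Rh_nm?, mass_Da?
    fit_rh: LinearFit | None      # Kav vs log10(Rh [nm])
    fit_mass: LinearFit | None    # Kav vs log10(mass [Da])


@dataclass
class HydroRecord:
    """Hydrodynamic observables of one analyte with method provenance."""
    rh_nm: float | None = None
    rh_err_nm: float | None = None
    rg_nm: float | None = None
    rg_err_nm: float | None = None
    s_svedberg: float | None = None
    mass_estimates: list[tuple[str, float]] = field(default_factory=list)

    @property
    def q_factor(self) -> float | None:
        if self.rg_nm is None or self.rh_nm is None:
            return None
        return self.rg_nm / self.rh_nm

    def as_dict(self) -> dict:
        return {
            "Rh_nm": self.rh_nm,
            "Rh_err_nm": self.rh_err_nm,
            "Rg_nm": self.rg_nm,
            "Rg_err_nm": self.rg_err_nm,
            "s_S": self.s_svedberg,
            "mass_estimates_Da": dict(self.mass_estimates),
            "q_factor": self.q_factor,
        }


def partition_coefficient(Ve: float, V0: float, Vt: float) -> float:
    """SEC partition coefficient Kav = (Ve - V0)/(Vt - V0).

    An elution volume outside [V0, Vt] is physically suspect; the value is
    still returned (outside [0, 1]) with a warning.
    """
    if Vt <= V0:
        raise ValueError("total volume must exceed void volume")
    kav = (Ve - V0) / (Vt - V0)
    if not 0.0 <= kav <= 1.0:
        warnings.warn(
            f"elution volume {Ve} mL outside [V0={V0}, Vt={Vt}]; Kav={kav:.3f}",
            ExtrapolationWarning, stacklevel=2,
        )
    return kav


def _ols(x: np.ndarray, y: np.ndarray) -> LinearFit:
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration: all x values identical")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    return LinearFit(res.slope, res.intercept, res.rvalue**2, resid)


def calibrate_sec(
    standards: pd.DataFrame | list[dict],
    V0: float,
    Vt: float,
) -> SECCalibration:
    """Fit Kav vs log10(Rh) and/or Kav vs log10(mass) calibration lines.

    ``standards`` rows need ``name`` and ``Ve_mL`` plus ``Rh_nm`` and/or
    ``mass_Da``.  Each relation needs at least two usable standards.
    """
    df = pd.DataFrame(standards).copy()
    if "Ve_mL" not in df.columns:
        raise ValueError("standards must have an Ve_mL column")
    df["Kav"] = [partition_coefficient(v, V0, Vt) for v in df["Ve_mL"]]
    if df["Kav"].nunique() == 1:
        raise ValueError("degenerate calibration: all standards share one Kav")

    def try_fit(column: str) -> LinearFit | None:
        if column not in df.columns:
            return None
        sub = df.dropna(subset=[column])
        if len(sub) < 2:
            return None
        x = np.log10(sub[column].to_numpy(float))
        if np.ptp(x) == 0:
            warnings.warn(f"all standards share one {column}; relation skipped",
                          stacklevel=3)
            return None
        return _ols(x, sub["Kav"].to_numpy(float))

    fit_rh = try_fit("Rh_nm")
    fit_mass = try_fit("mass_Da")
    if fit_rh is None and fit_mass is None:
        raise ValueError("need >= 2 standards with Rh_nm or mass_Da")
    return SECCalibration(V0, Vt, df, fit_rh, fit_mass)


def read_sec_standards(path: str | Path) -> pd.DataFrame:
    """Read a SEC standards CSV with columns name, Ve_mL[, Rh_nm][, mass_Da]."""
    return pd.read_csv(path, comment="#")


def sec_estimate(
    kav: float, calib: SECCalibration
) -> tuple[float | None, float | None]:
    """Invert the calibration lines at a partition coefficient.

    Returns (Rh in nm, apparent mass in Da); either is None when the
    corresponding relation was not calibrated.  A Kav outside the span of
    the standards triggers an extrapolation warning.
    """
    span = (calib.standards["Kav"].min(), calib.standards["Kav"].max())
    if not span[0] <= kav <= span[1]:
        warnings.warn(
            f"Kav={kav:.3f} outside calibrated range [{span[0]:.3f}, {span[1]:.3f}]",
            ExtrapolationWarning, stacklevel=2,
        )
    rh = mass = None
    if calib.fit_rh is not None:
        rh = 10.0 ** ((kav - calib.fit_rh.intercept) / calib.fit_rh.slope)
    if calib.fit_mass is not None:
        mass = 10.0 ** ((kav - calib.fit_mass.intercept) / calib.fit_mass.slope)
    return rh, mass


def siegel_monte_mass(
    s_svedberg: float, rh_nm: float, solvent: SolventModel | None = None
) -> float:
    """Molecular mass (Da) from sedimentation coefficient and Rh.

    M = s*N0*(6*pi*eta*Rh)/(1 - nu2*rho), with s in seconds (1 S = 1e-13 s)
    and Rh in metres; no globularity assumption is needed.
    """
    if s_svedberg <= 0 or rh_nm <= 0:
        raise ValueError("s and Rh must be positive")
    solvent = solvent or SolventModel()
    s = s_svedberg * SVEDBERG_S
    rh = rh_nm * NM_M
    mass_kg_per_mol = (
        s * AVOGADRO * 6.0 * math.pi * solvent.viscosity * rh
        / (1.0 - solvent.buoyancy_product)
    )
    return mass_kg_per_mol * 1e3      # kg/mol -> g/mol == Da


def conformer_rh(mass_da: float, state: str, config: dict | None = None) -> float:
    """Expected Rh (nm) of a protein of a given mass in a conformational state.

    Uses the empirical power law log10(Rh [A]) = a*log10(M [Da]) + b with
    per-state coefficients from the configuration.
    """
    if mass_da <= 0:
        raise ValueError("mass must be positive")
    laws = (config or default_config())["scaling_laws"]
    if state not in laws:
        raise ValueError(f"unknown state {state!r}; expected one of {sorted(laws)}")
    coeff = laws[state]
    rh_angstrom = 10.0 ** (coeff["a"] * math.log10(mass_da) + coeff["b"])
    return rh_angstrom / 10.0


def q_factor(
    rg_nm: float, rh_nm: float,
    rg_err: float | None = None, rh_err: float | None = None,
) -> tuple[float, float | None]:
    """Q = Rg/Rh with quadrature-propagated uncertainty when errors given."""
    if rg_nm <= 0 or rh_nm <= 0:
        raise ValueError("Rg and Rh must be positive")
    q = rg_nm / rh_nm
    err = None
    if rg_err is not None and rh_err is not None:
        err = q * math.hypot(rg_err / rg_nm, rh_err / rh_nm)
    return q, err


def q_classify(
    q: float, config: dict | None = None
) -> tuple[list[str], list[str]]:
    """Conformational bands compatible with a Q-factor.

    Returns (members, adjacent): ``members`` are all bands containing Q
    (overlaps intentional, all reported); ``adjacent`` are bands whose edge
    lies within the configured adjacency margin — near-miss states a single
    ratio cannot exclude (the Kratky shape is the usual tie-breaker).
    """
    if q <= 0:
        raise ValueError("Q must be positive")
    cfg = config or default_config()
    margin = cfg["q_adjacency_margin"]
    members, adjacent = [], []
    for name, (lo, hi) in cfg["q_bands"].items():
        hi = math.inf if hi is None else hi
        if lo <= q <= hi:
            members.append(name)
        elif min(abs(q - lo), abs(q - hi)) <= margin:
            adjacent.append(name)
    return members, adjacent


def sedimentation_from_gradient(
    sample_position: float,
    standards: list[tuple[float, float]] | pd.DataFrame,
) -> float:
    """Sedimentation coefficient (S) by linear calibration of a sucrose gradient.

    ``standards`` are (position, s) pairs — position may be fraction index or
    % sucrose; the map is linear either way.  Positions must be monotone in s.
    """
    if isinstance(standards, pd.DataFrame):
        pairs = list(zip(standards["position"], standards["s_S"]))
    else:
        pairs = list(standards)
    if len(pairs) < 2:
        raise ValueError("need at least two gradient standards")
    pairs.sort(key=lambda p: p[1])
    positions = np.array([p[0] for p in pairs], float)
    s_values = np.array([p[1] for p in pairs], float)
    diffs = np.diff(positions)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("standard positions are not monotone in s")
    if not min(positions) <= sample_position <= max(positions):
        warnings.warn(
            f"sample position {sample_position} outside standard span",
            ExtrapolationWarning, stacklevel=2,
        )
    fit = _ols(positions, s_values)
    return fit.predict(sample_position)


def coil_q_factor(n_beads: int = 100_000) -> float:
    """Q-factor of an ideal Gaussian chain from the Kirkwood double sum.

    Rg = b*sqrt(N/6); the Kirkwood inverse hydrodynamic radius is
    1/Rh = (1/N^2) * sum_{i != j} <1/r_ij> with <1/r_ij> =
    sqrt(6/pi)/(b*sqrt(|i-j|)) for a Gaussian chain.  The double sum is
    reduced exactly to sum_k 2*(N-k)/sqrt(k) and evaluated numerically, so
    the result carries the finite-N correction (about 1.50 for long chains).
    The bond length b cancels in the ratio.
    """
    if n_beads < 2:
        raise ValueError("need at least two beads")
    n = n_beads
    k = np.arange(1, n, dtype=float)
    double_sum = 2.0 * np.sum((n - k) / np.sqrt(k))
    inv_rh = math.sqrt(6.0 / math.pi) * double_sum / n**2   # units of 1/b
    rg = math.sqrt(n / 6.0)                                 # units of b
    return rg * inv_rh


def sphere_q_factor() -> float:
    """Q-factor of a uniform solid sphere: Rg = sqrt(3/5)*R, Rh = R."""
    return math.sqrt(3.0 / 5.0)
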