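"""Synthetic-data generators.

Every input the analysis consumes can be generated here with the statistical
structure the analysis assumes: scattering from compact spheres, Gaussian
coils and compact+coil hybrids; SEC elution of globular standards plus an
arbitrary analyte; linear Stern-Volmer quenching; sigmoidal two-state and
linear (non-cooperative) unfolding transitions; sucrose-gradient migration
linear in s; and sequences with target composition fractions.

All generators are seed-deterministic (one pseudorandom stream per generator
call, derived from the seed and the generator name) and exactly noise-free
at sigma = 0.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import default_config
from .saxs import ScatteringCurve
from .sequence import DISORDER_PROMOTING, ORDER_PROMOTING, SequenceRecord
from .spectroscopy import GAS_CONSTANT_KCAL, TitrationSeries


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise: 'none', 'gaussian_relative' (sigma as a
    fraction of each value) or 'gaussian_absolute' (sigma in data units)."""
    kind: str = "none"
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian_relative", "gaussian_absolute"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def apply(self, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none" or self.sigma == 0.0:
            return np.asarray(y, float).copy()
        if self.kind == "gaussian_relative":
            return y + rng.normal(0.0, self.sigma * np.abs(y))
        return y + rng.normal(0.0, self.sigma, size=np.shape(y))


@dataclass(frozen=True)
class SimulationSpec:
    seed: int = 0
    noise: NoiseModel = field(default_factory=NoiseModel)
    q_start: float | None = None     # nm^-1; None -> config default
    q_stop: float | None = None
    q_points: int | None = None

    def rng(self, name: str) -> np.random.Generator:
        # independent stream per generator: seed mixed with the name's CRC
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(name.encode())])
        )

    def q_grid(self) -> np.ndarray:
        cfg = default_config()["synthetic"]["q_grid"]
        start = self.q_start if self.q_start is not None else cfg["start"]
        stop = self.q_stop if self.q_stop is not None else cfg["stop"]
        pts = self.q_points if self.q_points is not None else cfg["points"]
        return np.linspace(start, stop, pts)


def sphere_form_factor(q: np.ndarray, radius_nm: float) -> np.ndarray:
    """Normalized intensity of a uniform sphere: P(0) = 1."""
    x = np.asarray(q, float) * radius_nm
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
    # series below x ~ 1e-2: the closed form loses all digits to cancellation
    f = np.where(np.abs(x) < 1e-2, 1.0 - x**2 / 10.0, f)
    return f**2


def debye_coil_intensity(q: np.ndarray, rg_nm: float) -> np.ndarray:
    """Normalized Debye function of a Gaussian coil: I(0) = 1."""
    u = (np.asarray(q, float) * rg_nm) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 2.0 * (np.exp(-u) + u - 1.0) / u**2
    # series below u ~ 1e-4: cancellation kills the closed form
    return np.where(u < 1e-4, 1.0 - u / 3.0 + u**2 / 12.0, f)


def make_sphere_curve(
    radius_nm: float, i0: float = 1.0, spec: SimulationSpec | None = None
) -> ScatteringCurve:
    """Scattering curve of a compact sphere (Rg = sqrt(3/5)*R)."""
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    spec = spec or SimulationSpec()
    q = spec.q_grid()
    i = i0 * sphere_form_factor(q, radius_nm)
    i = spec.noise.apply(i, spec.rng("sphere"))
    return ScatteringCurve(q, i, metadata={"model": "sphere", "R_nm": radius_nm})


def make_debye_coil_curve(
    rg_nm: float, i0: float = 1.0, spec: SimulationSpec | None = None
) -> ScatteringCurve:
    """Scattering curve of an ideal Gaussian coil (Debye function)."""
    if rg_nm <= 0:
        raise ValueError("Rg must be positive")
    spec = spec or SimulationSpec()
    q = spec.q_grid()
    i = i0 * debye_coil_intensity(q, rg_nm)
    i = spec.noise.apply(i, spec.rng("debye_coil"))
    return ScatteringCurve(q, i, metadata={"model": "debye_coil", "Rg_nm": rg_nm})


def make_hybrid_curve(
    sphere_part: ScatteringCurve,
    coil_part: ScatteringCurve,
    weight: float,
    spec: SimulationSpec | None = None,
) -> ScatteringCurve:
    """Intensity mixture w*I_sphere + (1-w)*I_coil on a shared q grid."""
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must be in [0, 1]")
    if len(sphere_part) != len(coil_part) or not np.allclose(
        sphere_part.q, coil_part.q
    ):
        raise ValueError("sphere and coil parts must share a q grid")
    spec = spec or SimulationSpec()
    i = weight * sphere_part.i + (1.0 - weight) * coil_part.i
    i = spec.noise.apply(i, spec.rng("hybrid"))
    return ScatteringCurve(sphere_part.q.copy(), i,
                           metadata={"model": "hybrid", "weight": weight})


def make_sec_run(
    standards_truth: list[tuple[str, float, float]],
    analyte_rh_nm: float,
    V0: float,
    Vt: float,
    line: tuple[float, float],
    spec: SimulationSpec | None = None,
) -> tuple[pd.DataFrame, float]:
    """Synthesize a SEC calibration run plus one analyte elution volume.

    ``standards_truth`` rows are (name, Rh_nm, mass_Da); ``line`` is the
    generating (slope, intercept) of Kav vs log10(Rh [nm]).  Elution volumes
    are Ve = V0 + Kav*(Vt - V0) plus noise.  Returns (standards table,
    analyte Ve).  An analyte Rh outside the standards' span is flagged in the
    table attrs (an extrapolation fixture, not an error).
    """
    if Vt <= V0:
        raise ValueError("Vt must exceed V0")
    spec = spec or SimulationSpec()
    rng = spec.rng("sec_run")
    slope, intercept = line
    rows = []
    for name, rh, mass in standards_truth:
        kav = slope * np.log10(rh) + intercept
        ve = V0 + kav * (Vt - V0)
        rows.append({"name": name, "Ve_mL": ve, "Rh_nm": rh, "mass_Da": mass})
    df = pd.DataFrame(rows)
    df["Ve_mL"] = spec.noise.apply(df["Ve_mL"].to_numpy(), rng)
    kav_a = slope * np.log10(analyte_rh_nm) + intercept
    ve_a = float(spec.noise.apply(np.array([V0 + kav_a * (Vt - V0)]), rng)[0])
    rh_span = (min(r[1] for r in standards_truth), max(r[1] for r in standards_truth))
    df.attrs["analyte_extrapolated"] = not rh_span[0] <= analyte_rh_nm <= rh_span[1]
    return df, ve_a


def make_quenching_series(
    ksv: float, q_grid: np.ndarray, spec: SimulationSpec | None = None
) -> TitrationSeries:
    """Linear Stern-Volmer series F0/F = 1 + KSV*[Q]."""
    spec = spec or SimulationSpec()
    q = np.asarray(q_grid, float)
    y = 1.0 + ksv * q
    y = spec.noise.apply(y, spec.rng("quenching"))
    y[q == 0] = 1.0            # F0/F is exactly 1 at zero quencher by definition
    return TitrationSeries(q, y, "quenching")


def make_two_population_quenching(
    ksv1: float, ksv2: float, fraction1: float,
    q_grid: np.ndarray, spec: SimulationSpec | None = None,
) -> TitrationSeries:
    """Downward-curved Stern-Volmer series from two fluorophore populations
    of differing accessibility: F/F0 = f1/(1+K1*Q) + f2/(1+K2*Q)."""
    spec = spec or SimulationSpec()
    q = np.asarray(q_grid, float)
    f_over_f0 = fraction1 / (1.0 + ksv1 * q) + (1.0 - fraction1) / (1.0 + ksv2 * q)
    y = spec.noise.apply(1.0 / f_over_f0, spec.rng("quenching_2pop"))
    y[q == 0] = 1.0
    return TitrationSeries(q, y, "quenching")


def make_unfolding_series(
    model: str,
    x_grid: np.ndarray,
    spec: SimulationSpec | None = None,
    *,
    dg0: float = 5.0,
    m: float = 2.0,
    native_baseline: tuple[float, float] = (0.0, 1.0),
    denatured_baseline: tuple[float, float] = (0.0, 0.0),
    slope: float = -0.1,
    intercept: float = 1.0,
    temperature_k: float = 298.15,
    kind: str = "chemical_unfolding",
) -> TitrationSeries:
    """Synthesize an unfolding titration.

    ``model`` 'two_state': linear-extrapolation two-state transition with
    dG = dg0 - m*x (midpoint Cm = dg0/m gives f_d = 0.5 before noise) mixed
    between the given baselines.  'linear': y = slope*x + intercept, the
    non-cooperative pattern.
    """
    spec = spec or SimulationSpec()
    x = np.asarray(x_grid, float)
    if model == "two_state":
        k_eq = np.exp(-(dg0 - m * x) / (GAS_CONSTANT_KCAL * temperature_k))
        f_d = k_eq / (1.0 + k_eq)
        aN, bN = native_baseline
        aD, bD = denatured_baseline
        y = (aN * x + bN) * (1.0 - f_d) + (aD * x + bD) * f_d
    elif model == "linear":
        y = slope * x + intercept
    else:
        raise ValueError("model must be 'two_state' or 'linear'")
    y = spec.noise.apply(y, spec.rng("unfolding_" + model))
    return TitrationSeries(x, y, kind)


def make_gradient_run(
    s_truth: list[tuple[str, float]],
    line: tuple[float, float],
    spec: SimulationSpec | None = None,
) -> pd.DataFrame:
    """Synthesize a sucrose-gradient migration table, position linear in s.

    ``s_truth`` rows are (name, s in Svedberg); ``line`` is the generating
    (slope, intercept) of position vs s.
    """
    spec = spec or SimulationSpec()
    rng = spec.rng("gradient")
    slope, intercept = line
    names = [n for n, _ in s_truth]
    s = np.array([v for _, v in s_truth], float)
    pos = spec.noise.apply(slope * s + intercept, rng)
    return pd.DataFrame({"name": names, "position": pos, "s_S": s})


def make_spectral_series(
    x_grid: np.ndarray,
    centers_nm: np.ndarray,
    wavelength_nm: np.ndarray | None = None,
    width_nm: float = 25.0,
    spec: SimulationSpec | None = None,
) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Gaussian emission bands whose centre shifts across a titration —
    the red-shift pattern of an exposing fluorophore."""
    spec = spec or SimulationSpec()
    rng = spec.rng("spectra")
    if wavelength_nm is None:
        wavelength_nm = np.arange(310.0, 400.0 + 1e-9, 1.0)
    out = []
    for x, c in zip(np.asarray(x_grid, float), np.asarray(centers_nm, float)):
        inten = np.exp(-0.5 * ((wavelength_nm - c) / width_nm) ** 2)
        out.append((float(x), wavelength_nm.copy(),
                    spec.noise.apply(inten, rng)))
    return out


def make_sequence(
    length: int,
    order_fraction: float,
    proline_fraction: float,
    spec: SimulationSpec | None = None,
    identifier: str = "synthetic",
) -> SequenceRecord:
    """Random sequence whose realized order-promoting and proline fractions
    match the targets within 1/length."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= order_fraction <= 1 or not 0 <= proline_fraction <= 1:
        raise ValueError("fractions must be in [0, 1]")
    if order_fraction + proline_fraction > 1.0 + 1e-12:
        raise ValueError("order and proline fractions cannot exceed 1 combined")
    spec = spec or SimulationSpec()
    rng = spec.rng("sequence")
    n_order = round(order_fraction * length)
    n_pro = round(proline_fraction * length)
    n_pro = min(n_pro, length - n_order)
    order_pool = sorted(ORDER_PROMOTING)
    other_pool = sorted(DISORDER_PROMOTING - {"P"})
    residues = (
        list(rng.choice(order_pool, size=n_order))
        + ["P"] * n_pro
        + list(rng.choice(other_pool, size=length - n_order - n_pro))
    )
    rng.shuffle(residues)
    return SequenceRecord(identifier, "".join(residues))
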