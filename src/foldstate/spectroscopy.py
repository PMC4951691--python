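"""Titration analytics.

Stern-Volmer collisional-quenching fits, unfolded-fraction computation from
a spectroscopic signal between native and denatured baselines, emission
lambda-max tracking across a titration, and the cooperative-vs-linear
unfolding model comparison: a two-state transition (free energy linear in
denaturant, dG = dG0 - m*[D]) against a plain line, decided by corrected
Akaike information criterion (AICc).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from statsmodels.sandbox.stats.runs import runstest_1samp

from .config import default_config

GAS_CONSTANT_KCAL = 1.987204259e-3   # kcal / (mol K)

KINDS = ("quenching", "chemical_unfolding", "thermal_unfolding",
         "lambda_max", "anisotropy", "generic")


@dataclass
class TitrationSeries:
    """An (x, y) titration: x is quencher (M), denaturant (M) or temperature."""
    x: np.ndarray
    y: np.ndarray
    kind: str = "generic"
    y_uncertainty: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y lengths differ")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.x)


def read_titration_csv(path: str | Path, kind: str | None = None) -> TitrationSeries:
    """Read an (x, y[, sigma]) CSV; a '# kind: <tag>' comment sets the kind."""
    meta_kind = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "kind:" in line:
                meta_kind = line.split("kind:", 1)[1].strip()
    df = pd.read_csv(path, comment="#")
    cols = list(df.columns)
    sigma = df[cols[2]].to_numpy(float) if len(cols) >= 3 else None
    return TitrationSeries(
        df[cols[0]].to_numpy(float), df[cols[1]].to_numpy(float),
        kind or meta_kind or "generic", sigma,
    )


@dataclass
class SternVolmerFit:
    ksv: float                 # M^-1
    ksv_err: float
    r_squared: float
    linear: bool
    runs_p_value: float | None


def stern_volmer_fit(
    series: TitrationSeries, config: dict | None = None
) -> SternVolmerFit:
    """Fit F0/F = 1 + KSV*[Q] with the intercept fixed at 1.

    The linearity verdict (single accessible fluorophore population) combines
    an R^2 threshold with a Wald-Wolfowitz runs test on the residual signs;
    systematic curvature (e.g. two populations of differing accessibility)
    fails either check.
    """
    if series.kind != "quenching":
        raise ValueError("series kind must be 'quenching'")
    if len(series) < 5:
        raise ValueError("need at least 5 points")
    cfg = (config or default_config())["titration"]
    x, y = series.x, series.y
    if x[0] != 0.0:                       # model pins F0/F = 1 at [Q] = 0
        x = np.concatenate([[0.0], x])
        y = np.concatenate([[1.0], y])
    noise = np.std(series.y_uncertainty) if series.y_uncertainty is not None else 0.0
    if np.any(y < 1.0 - 3.0 * noise - 1e-12):
        warnings.warn("F0/F below 1: static quenching artefact or data error",
                      stacklevel=2)
    # least squares through the fixed intercept: minimize sum (y-1 - k x)^2
    sxx = float(np.sum(x**2))
    ksv = float(np.sum(x * (y - 1.0)) / sxx)
    resid = y - (1.0 + ksv * x)
    dof = max(len(x) - 1, 1)
    ksv_err = math.sqrt(float(np.sum(resid**2)) / dof / sxx)
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    runs_p = None
    linear = r2 >= cfg["stern_volmer_r2_threshold"]
    if linear and np.any(np.abs(resid) > 1e-12 * max(1.0, np.max(np.abs(y)))):
        _, runs_p = runstest_1samp(resid, cutoff=0.0)
        linear = runs_p >= cfg["runs_test_alpha"]
    return SternVolmerFit(ksv, ksv_err, r2, linear, runs_p)


def unfolded_fraction(
    series: TitrationSeries,
    native_baseline: tuple[float, float],
    denatured_baseline: tuple[float, float],
) -> TitrationSeries:
    """Unfolded fraction f_d(x) = (y - yN(x)) / (yD(x) - yN(x)).

    Baselines are (slope, intercept).  Values slightly outside [0, 1] from
    noise are kept (not clipped) and flagged in the metadata.
    """
    mN, bN = native_baseline
    mD, bD = denatured_baseline
    yn = mN * series.x + bN
    yd = mD * series.x + bD
    denom = yd - yn
    if np.any(np.abs(denom) < 1e-12):
        raise ValueError("native and denatured baselines coincide at some x")
    fd = (series.y - yn) / denom
    out_of_range = bool(np.any((fd < 0) | (fd > 1)))
    return TitrationSeries(series.x, fd, series.kind,
                           metadata={"out_of_range": out_of_range})


def baselines_from_flanks(
    series: TitrationSeries, n_native: int = 3, n_denatured: int = 3
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Fit linear native/denatured baselines from the flanking x-ranges."""
    pn = np.polyfit(series.x[:n_native], series.y[:n_native], 1)
    pd_ = np.polyfit(series.x[-n_denatured:], series.y[-n_denatured:], 1)
    return (float(pn[0]), float(pn[1])), (float(pd_[0]), float(pd_[1]))


@dataclass
class UnfoldingFit:
    model: str                         # 'two_state' or 'linear'
    parameters: dict
    aicc_two_state: float | None
    aicc_linear: float
    verdict: str                       # 'cooperative' | 'weakly_cooperative_or_linear'
    flags: list[str] = field(default_factory=list)


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def _two_state_chemical(x, dg0, m, aN, bN, aD, bD, T):
    k_eq = np.exp(-(dg0 - m * x) / (GAS_CONSTANT_KCAL * T))
    f_d = k_eq / (1.0 + k_eq)
    return (aN * x + bN) * (1.0 - f_d) + (aD * x + bD) * f_d


def _two_state_thermal(x, dh, tm, aN, bN, aD, bD):
    # van 't Hoff two-state form, x in kelvin
    k_eq = np.exp(-dh / GAS_CONSTANT_KCAL * (1.0 / x - 1.0 / tm))
    f_d = k_eq / (1.0 + k_eq)
    return (aN * x + bN) * (1.0 - f_d) + (aD * x + bD) * f_d


def fit_unfolding(series: TitrationSeries, config: dict | None = None) -> UnfoldingFit:
    """Compare a two-state unfolding model against a plain line.

    Chemical unfolding uses the linear-extrapolation model dG = dG0 - m*[D]
    with linear native and denatured baselines; thermal unfolding uses a
    van 't Hoff two-state form.  The verdict is ``cooperative`` only when the
    two-state model wins by more than the configured AICc margin AND the
    fitted midpoint lies inside the sampled x range; otherwise
    ``weakly_cooperative_or_linear``.
    """
    if series.kind not in ("chemical_unfolding", "thermal_unfolding",
                           "lambda_max", "anisotropy", "generic"):
        raise ValueError(f"cannot fit unfolding on kind {series.kind!r}")
    n = len(series)
    if n < 6:
        raise ValueError("need at least 6 points")
    cfg = (config or default_config())["titration"]
    x, y = series.x, series.y
    flags: list[str] = []

    if np.ptp(y) < 1e-12 * max(1.0, np.max(np.abs(y))):
        return UnfoldingFit("linear", {"slope": 0.0, "intercept": float(np.mean(y))},
                            None, _aicc(float(np.sum((y - np.mean(y))**2)), n, 2),
                            "weakly_cooperative_or_linear", ["degenerate_constant_signal"])

    lin = np.polyfit(x, y, 1)
    rss_lin = float(np.sum((np.polyval(lin, x) - y) ** 2))
    aicc_lin = _aicc(rss_lin, n, 2)

    # a line that already fits to numerical precision cannot be beaten by a
    # sigmoid in any meaningful way: the richer model would only chase
    # rounding error (and at exactly zero residual AICc is undefined)
    if rss_lin <= (1e-8 * np.ptp(y)) ** 2 * n:
        return UnfoldingFit("linear",
                            {"slope": float(lin[0]), "intercept": float(lin[1])},
                            None, aicc_lin, "weakly_cooperative_or_linear",
                            ["perfect_linear_fit"])

    thermal = series.kind == "thermal_unfolding"
    # initial midpoint guess: where the signal crosses halfway between ends
    mid_idx = int(np.argmin(np.abs((y - y[0]) / (y[-1] - y[0] + 1e-300) - 0.5)))
    x_mid = float(x[mid_idx])
    try:
        if thermal:
            model = _two_state_thermal
            p0 = [50.0, x_mid, 0.0, float(y[0]), 0.0, float(y[-1])]
            popt, pcov = curve_fit(model, x, y, p0=p0, maxfev=20000)
            dh, tm, aN, bN, aD, bD = popt
            params = {"dH_kcal_mol": float(dh), "Tm": float(tm),
                      "native_baseline": (float(aN), float(bN)),
                      "denatured_baseline": (float(aD), float(bD))}
            midpoint = float(tm)
            m_ok = dh > 0
        else:
            T = cfg["temperature_k"]
            model = lambda xx, dg0, m, aN, bN, aD, bD: _two_state_chemical(
                xx, dg0, m, aN, bN, aD, bD, T)
            p0 = [2.0 * x_mid, 2.0, 0.0, float(y[0]), 0.0, float(y[-1])]
            popt, pcov = curve_fit(model, x, y, p0=p0, maxfev=20000)
            dg0, m, aN, bN, aD, bD = popt
            params = {"dG0_kcal_mol": float(dg0), "m_kcal_mol_M": float(m),
                      "Cm_M": float(dg0 / m) if m != 0 else math.inf,
                      "native_baseline": (float(aN), float(bN)),
                      "denatured_baseline": (float(aD), float(bD))}
            midpoint = params["Cm_M"]
            m_ok = m > 0
        rss_two = float(np.sum((model(x, *popt) - y) ** 2))
        aicc_two = _aicc(rss_two, n, 6)
    except RuntimeError:
        flags.append("two_state_nonconvergent")
        return UnfoldingFit("linear",
                            {"slope": float(lin[0]), "intercept": float(lin[1])},
                            None, aicc_lin, "weakly_cooperative_or_linear", flags)

    delta = aicc_lin - aicc_two
    interior = x[0] < midpoint < x[-1]
    cooperative = (delta > cfg["delta_aicc_threshold"]) and interior and m_ok
    if cooperative:
        return UnfoldingFit("two_state", params, aicc_two, aicc_lin,
                            "cooperative", flags)
    if not interior:
        flags.append("midpoint_outside_data")
    return UnfoldingFit("linear" if delta <= cfg["delta_aicc_threshold"] else "two_state",
                        {"slope": float(lin[0]), "intercept": float(lin[1]),
                         "two_state": params},
                        aicc_two, aicc_lin, "weakly_cooperative_or_linear", flags)


def lambda_max_series(
    spectra: list[tuple[float, np.ndarray, np.ndarray]],
    kind: str = "lambda_max",
) -> TitrationSeries:
    """Track the emission maximum wavelength across a titration.

    Each element is (x, wavelength array, intensity array); lambda-max is
    located by parabolic interpolation around the grid maximum.  A maximum
    sitting on a spectrum edge is flagged in the metadata.
    """
    xs, lams, edge = [], [], []
    for x, wl, inten in spectra:
        wl = np.asarray(wl, float)
        inten = np.asarray(inten, float)
        i = int(np.argmax(inten))
        if i == 0 or i == len(wl) - 1:
            edge.append(x)
            lams.append(float(wl[i]))
        else:
            coeffs = np.polyfit(wl[i - 1 : i + 2], inten[i - 1 : i + 2], 2)
            lams.append(float(-coeffs[1] / (2 * coeffs[0])))
        xs.append(float(x))
    order = np.argsort(xs)
    meta = {"edge_maxima_at": edge} if edge else {}
    return TitrationSeries(np.array(xs)[order], np.array(lams)[order],
                           kind, metadata=meta)
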