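"""Small-angle X-ray scattering shape analysis.

Guinier fitting with an iteratively selected qRg window, the dimensionless
Kratky transform (qRg)^2 * I/I0 vs qRg, and a pattern-based shape
classification: a decaying interior maximum marks a compact particle, a
persistent high-qRg level marks chain-like flexibility, and the combination
(maximum plus elevated tail) marks a particle with both a compact and a
disordered part.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .config import default_config


@dataclass
class ScatteringCurve:
    """A 1-D scattering profile: q in nm^-1, I in arbitrary units."""
    q: np.ndarray
    i: np.ndarray
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, float)
        self.i = np.asarray(self.i, float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma length differs from q")
        if self.q.shape != self.i.shape:
            raise ValueError("q and I lengths differ")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be positive and strictly increasing")
        if not np.all(np.isfinite(self.i)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class GuinierResult:
    rg_nm: float
    rg_err_nm: float
    i0: float
    i0_err: float
    q_window: tuple[float, float]
    qrg_window: tuple[float, float]
    n_points: int
    r_squared: float
    converged: bool
    n_iterations: int


@dataclass
class KratkyProfile:
    x: np.ndarray                 # qRg
    y: np.ndarray                 # (qRg)^2 * I/I0
    peak: tuple[float, float, float] | None   # (x_peak, y_peak, prominence)
    tail_level: float | None      # mean y over the configured high-x band
    tail_band: tuple[float, float]
    inconclusive: bool = False


def read_scattering(path: str | Path, q_units: str = "nm") -> ScatteringCurve:
    """Read a 2- or 3-column ASCII scattering file (q, I[, sigma]).

    Whitespace- or comma-delimited; '#' starts a comment.  Non-finite rows
    are dropped with a warning.  ``q_units`` may be "nm" (nm^-1, the internal
    unit) or "ang" (A^-1, converted by a factor of 10 — never guessed).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                continue
            rows.append([float(p) for p in parts[:3]])
    if not rows:
        raise ValueError(f"{path}: no data rows")
    ncol = min(len(r) for r in rows)
    data = np.array([r[:ncol] for r in rows], float)
    finite = np.all(np.isfinite(data), axis=1)
    if not finite.all():
        warnings.warn(f"{path}: dropped {int((~finite).sum())} non-finite row(s)",
                      stacklevel=2)
        data = data[finite]
    if len(data) < 10:
        raise ValueError(f"{path}: fewer than 10 usable points")
    q = data[:, 0]
    if q_units == "ang":
        q = q * 10.0
    elif q_units != "nm":
        raise ValueError("q_units must be 'nm' or 'ang'")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return ScatteringCurve(q, data[:, 1], sigma, {"source": str(path)})


def write_scattering(curve: ScatteringCurve, path: str | Path) -> None:
    """Write a curve as 3-column (or 2-column) ASCII with a comment header."""
    cols = [curve.q, curve.i] + ([curve.sigma] if curve.sigma is not None else [])
    header = "q_nm^-1 I" + (" sigma" if curve.sigma is not None else "")
    np.savetxt(path, np.column_stack(cols), header=header)


def _guinier_ols(q: np.ndarray, i: np.ndarray, sigma: np.ndarray | None):
    """Weighted linear fit of ln I on q^2; returns (Rg, I0, errors, R^2)."""
    x = q**2
    y = np.log(i)
    if sigma is not None:
        w = (i / sigma) ** 2          # var(ln I) = (sigma/I)^2
    else:
        w = np.ones_like(y)
    W = np.sum(w)
    xbar = np.sum(w * x) / W
    ybar = np.sum(w * y) / W
    sxx = np.sum(w * (x - xbar) ** 2)
    slope = np.sum(w * (x - xbar) * (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    resid = y - (slope * x + intercept)
    dof = max(len(x) - 2, 1)
    s2 = np.sum(w * resid**2) / dof
    slope_err = math.sqrt(s2 / sxx)
    intercept_err = math.sqrt(s2 * (1.0 / W + xbar**2 / sxx))
    ss_tot = np.sum(w * (y - ybar) ** 2)
    r2 = 1.0 - np.sum(w * resid**2) / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, slope_err, intercept_err, r2


def guinier_fit(
    curve: ScatteringCurve,
    qrg_window: tuple[float, float] | None = None,
    config: dict | None = None,
) -> GuinierResult:
    """Guinier analysis: ln I = ln I0 - (q*Rg)^2/3 on an iterated qRg window.

    Starting from the lowest-q decade of the curve, the fit is repeated with
    the point set recomputed from the current Rg until the set is stable
    (fixed point) or the iteration cap is reached; an oscillating selection
    keeps the smaller window.  Weighted by 1/sigma^2 on ln I when sigma is
    present.
    """
    cfg = (config or default_config())["guinier"]
    lo, hi = qrg_window if qrg_window is not None else tuple(cfg["qrg_window"])
    min_pts = cfg["min_points"]

    # initial window: the lowest decade of measured q (positive I only)
    mask = (curve.q <= curve.q[0] * 10.0) & (curve.i > 0)
    if mask.sum() < min_pts:
        mask = (np.arange(len(curve)) < max(min_pts, 1)) & (curve.i > 0)

    seen: list[frozenset] = [frozenset(np.flatnonzero(mask))]
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg["max_iterations"] + 1):
        q = curve.q[mask]
        i = curve.i[mask]
        if len(q) < min_pts:
            raise ValueError("Guinier window contains too few points")
        sig = curve.sigma[mask] if curve.sigma is not None else None
        slope, intercept, *_ = _guinier_ols(q, i, sig)
        if slope >= 0:
            raise ValueError("non-negative Guinier slope: Rg^2 <= 0")
        rg = math.sqrt(-3.0 * slope)
        new_mask = (curve.q * rg >= lo) & (curve.q * rg <= hi) & (curve.i > 0)
        if new_mask.sum() < min_pts:
            raise ValueError(
                f"qRg window [{lo}, {hi}] selects fewer than {min_pts} points"
            )
        key = frozenset(np.flatnonzero(new_mask))
        if key == seen[-1]:
            mask = new_mask
            converged = True
            break
        if key in seen:              # oscillation: keep the smaller window
            prev = seen[-1]
            mask = new_mask if len(key) < len(prev) else _mask_from(prev, len(curve))
            converged = True
            break
        seen.append(key)
        mask = new_mask

    q = curve.q[mask]
    i = curve.i[mask]
    sig = curve.sigma[mask] if curve.sigma is not None else None
    slope, intercept, slope_err, intercept_err, r2 = _guinier_ols(q, i, sig)
    if slope >= 0:
        raise ValueError("non-negative Guinier slope: Rg^2 <= 0")
    rg = math.sqrt(-3.0 * slope)
    rg_err = 3.0 * slope_err / (2.0 * rg)      # propagate through Rg = sqrt(-3m)
    i0 = math.exp(intercept)
    return GuinierResult(
        rg_nm=rg, rg_err_nm=rg_err, i0=i0, i0_err=i0 * intercept_err,
        q_window=(float(q[0]), float(q[-1])),
        qrg_window=(float(q[0] * rg), float(q[-1] * rg)),
        n_points=int(mask.sum()), r_squared=float(r2),
        converged=converged, n_iterations=n_iter,
    )


def _mask_from(indices: frozenset, n: int) -> np.ndarray:
    mask = np.zeros(n, bool)
    mask[sorted(indices)] = True
    return mask


def dimensionless_kratky(
    curve: ScatteringCurve,
    guinier: GuinierResult,
    config: dict | None = None,
    smooth: bool = True,
) -> KratkyProfile:
    """Dimensionless Kratky transform x = q*Rg, y = x^2 * I(q)/I0.

    The peak is the global interior maximum (prominence above the configured
    floor) of the optionally Savitzky-Golay-smoothed profile, refined by
    parabolic interpolation; the tail level is the mean of y over the
    configured high-x band.
    """
    if not guinier.converged:
        raise ValueError("Guinier fit did not converge")
    if guinier.i0 <= 0:
        raise ValueError("I0 must be positive")
    cfg = (config or default_config())["kratky"]
    x = curve.q * guinier.rg_nm
    y = x**2 * curve.i / guinier.i0

    ys = y
    win = cfg["smooth_window"]
    if smooth and len(y) > win:
        ys = savgol_filter(y, win, cfg["smooth_order"])

    floor = cfg["prominence_floor_fraction"] * float(np.max(ys))
    idx, props = find_peaks(ys, prominence=floor)
    peak = None
    if len(idx):
        best = idx[np.argmax(ys[idx])]
        xp, yp = _parabolic_refine(x, ys, best)
        peak = (xp, yp, float(props["prominences"][np.argmax(ys[idx])]))

    t_lo, t_hi = cfg["tail_band"]
    band = (x >= t_lo) & (x <= t_hi)
    inconclusive = not band.any()
    tail = float(np.mean(y[band])) if band.any() else None
    return KratkyProfile(x, y, peak, tail, (t_lo, t_hi), inconclusive)


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    if i == 0 or i == len(x) - 1:
        return float(x[i]), float(y[i])
    coeffs = np.polyfit(x[i - 1 : i + 2], y[i - 1 : i + 2], 2)
    if coeffs[0] >= 0:
        return float(x[i]), float(y[i])
    xp = -coeffs[1] / (2 * coeffs[0])
    return float(xp), float(np.polyval(coeffs, xp))


def kratky_classify(profile: KratkyProfile, config: dict | None = None) -> str:
    """Classify a Kratky profile shape.

    globular_compact      — interior maximum with a decayed tail;
    compact_plus_flexible — interior maximum but the tail stays at or above
                            peak_fraction of the peak height (compact core
                            plus a disordered part);
    extended              — no qualifying interior maximum.
    """
    cfg = (config or default_config())["kratky"]
    if profile.inconclusive:
        raise ValueError("profile does not cover the tail band; inconclusive")
    if profile.peak is None:
        return "extended"
    _, y_peak, _ = profile.peak
    if profile.tail_level is not None and profile.tail_level >= cfg["peak_fraction"] * y_peak:
        return "compact_plus_flexible"
    return "globular_compact"
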