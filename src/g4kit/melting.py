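"""CD melting-curve normalization and sigmoid Tm fitting.

A melting curve is a CD signal followed versus temperature at a fixed
wavelength (260 nm for parallel G4s, 290 nm for antiparallel/hybrid).  The
signal is min-max normalized, ``(y - min) / (max - min)``, and the melting
temperature Tm is the inflection of a Boltzmann sigmoid fitted by ordinary
least squares:

    y(T) = bottom + (top - bottom) / (1 + exp((Tm - T) / s))

Biphasic curves are fitted with a two-component mixture of unit Boltzmann
sigmoids with component fraction f, reported as tm1 < tm2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "MeltingCurve",
    "MeltingFit",
    "DegenerateCurveError",
    "normalize",
    "fit_boltzmann",
    "fit_double_sigmoid",
    "read_curve_csv",
    "simulate_noop",
]


class DegenerateCurveError(ValueError):
    """Signal carries no transition (constant, or too few points)."""


@dataclass
class MeltingCurve:
    temperature: np.ndarray  # degrees C, strictly increasing
    signal: np.ndarray
    wavelength_nm: float | None = None
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature.shape != self.signal.shape:
            raise ValueError("temperature and signal must have equal length")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature grid must be strictly increasing")

    def restrict(self, t_lo: float | None = None, t_hi: float | None = None) -> "MeltingCurve":
        """Sub-curve on [t_lo, t_hi] (fit-range option)."""
        mask = np.ones_like(self.temperature, dtype=bool)
        if t_lo is not None:
            mask &= self.temperature >= t_lo
        if t_hi is not None:
            mask &= self.temperature <= t_hi
        return MeltingCurve(self.temperature[mask], self.signal[mask], self.wavelength_nm)


@dataclass
class MeltingFit:
    model: str  # boltzmann | double_sigmoid
    tm: float | None = None
    slope: float | None = None
    tm1: float | None = None
    tm2: float | None = None
    slope1: float | None = None
    slope2: float | None = None
    fraction: float | None = None
    bottom: float | None = None
    top: float | None = None
    residual_rms: float = float("nan")
    converged: bool = False
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if v is not None}
        out["warnings"] = list(self.warnings)
        return out


def normalize(curve: MeltingCurve) -> MeltingCurve:
    """Min-max normalize the signal: (y - min) / (max - min).

    Affine and order-preserving; the extremes map exactly to 0 and 1.
    Idempotent on an already-normalized curve.
    """
    y = curve.signal
    lo, hi = float(np.min(y)), float(np.max(y))
    if hi <= lo:
        raise DegenerateCurveError("constant signal: normalization undefined")
    out = MeltingCurve(curve.temperature.copy(), curve.signal.copy(), curve.wavelength_nm)
    out.normalized = (y - lo) / (hi - lo)
    return out


def _unit_boltzmann(T, tm, s):
    # overflow-safe logistic
    z = np.clip((tm - T) / s, -500, 500)
    return 1.0 / (1.0 + np.exp(z))


def boltzmann(T, bottom, top, tm, s):
    return bottom + (top - bottom) * _unit_boltzmann(T, tm, s)


def _crossing(T, y, level) -> float | None:
    """Temperature where y first crosses `level` (linear interpolation)."""
    d = y - level
    sign = np.sign(d)
    idx = np.where(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        return None
    i = int(idx[0])
    t0, t1, y0, y1 = T[i], T[i + 1], y[i], y[i + 1]
    if y1 == y0:
        return float(t0)
    return float(t0 + (level - y0) * (t1 - t0) / (y1 - y0))


def _ensure_normalized(curve: MeltingCurve) -> MeltingCurve:
    if curve.normalized is None:
        curve = normalize(curve)
    return curve


def fit_boltzmann(
    curve: MeltingCurve,
    fix_baselines: bool = False,
    max_iter: int = 500,
) -> MeltingFit:
    """Least-squares Boltzmann sigmoid fit of a normalized melting curve.

    Initialization: Tm0 at the 0.5-crossing of the normalized signal
    (mid-span fallback with a warning when no crossing exists), s0 = span/10,
    bottom0 = 0, top0 = 1.  ``fix_baselines`` pins bottom/top at 0/1.
    """
    curve = _ensure_normalized(curve)
    T, y = curve.temperature, curve.normalized
    if len(T) < 8:
        raise DegenerateCurveError("need >= 8 points spanning the transition")
    fit = MeltingFit(model="boltzmann")
    span = float(T[-1] - T[0])
    tm0 = _crossing(T, y, 0.5)
    if tm0 is None:
        tm0 = float(T[0] + span / 2)
        fit.warnings.append("no 0.5-crossing: Tm initialized at mid-span")
    # rising or falling transition: sign of the slope at the crossing
    rising = y[-1] >= y[0]
    s0 = (span / 10.0) * (1.0 if rising else -1.0)

    if fix_baselines:
        fun = lambda p: boltzmann(T, 0.0, 1.0, p[0], p[1]) - y
        p0 = [tm0, s0]
    else:
        fun = lambda p: boltzmann(T, p[2], p[3], p[0], p[1]) - y
        p0 = [tm0, s0, 0.0, 1.0]
    sol = least_squares(fun, p0, xtol=1e-12, ftol=1e-10, max_nfev=max_iter * len(p0))
    fit.converged = bool(sol.status > 0 and sol.nfev < max_iter * len(p0))
    fit.tm, fit.slope = float(sol.x[0]), float(sol.x[1])
    if fix_baselines:
        fit.bottom, fit.top = 0.0, 1.0
    else:
        fit.bottom, fit.top = float(sol.x[2]), float(sol.x[3])
    fit.residual_rms = float(np.sqrt(np.mean(sol.fun**2)))
    return fit


def double_sigmoid(T, f, tm1, s1, tm2, s2, bottom=0.0, top=1.0):
    mix = f * _unit_boltzmann(T, tm1, s1) + (1.0 - f) * _unit_boltzmann(T, tm2, s2)
    return bottom + (top - bottom) * mix


def fit_double_sigmoid(
    curve: MeltingCurve,
    collapse_tol: float = 1.0,
    max_iter: int = 500,
) -> MeltingFit:
    """Two-component Boltzmann mixture fit for biphasic melting curves.

    Multi-start initialization: (Tm1, Tm2) pairs at the 0.25/0.75 crossings
    and at mid-span +/- span/4.  The result is reported with tm1 < tm2 and
    component fraction f in [0, 1].  A fit collapsing to tm1 == tm2 (within
    ``collapse_tol`` degrees C) falls back to the single-sigmoid result with
    ``model="boltzmann"`` flagged.
    """
    curve = _ensure_normalized(curve)
    T, y = curve.temperature, curve.normalized
    span = float(T[-1] - T[0])
    rising = y[-1] >= y[0]
    yy = y if rising else 1.0 - y
    c25 = _crossing(T, yy, 0.25)
    c75 = _crossing(T, yy, 0.75)
    mid = float(T[0] + span / 2)
    starts = []
    if c25 is not None and c75 is not None:
        starts.append((min(c25, c75), max(c25, c75)))
    starts.append((mid - span / 4, mid + span / 4))
    sign = 1.0 if rising else -1.0
    s0 = span / 20.0 * sign

    def fun(p):
        f, tm1, s1, tm2, s2, bottom, top = p
        return double_sigmoid(T, f, tm1, s1, tm2, s2, bottom, top) - y

    best = None
    for tma, tmb in starts:
        sol = least_squares(
            fun,
            [0.5, tma, s0, tmb, s0, 0.0, 1.0],
            bounds=([0.0] + [-np.inf] * 6, [1.0] + [np.inf] * 6),
            xtol=1e-12,
            ftol=1e-12,
            max_nfev=max_iter * 7,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    f, tm1, s1, tm2, s2, bottom, top = (float(v) for v in best.x)
    if tm1 > tm2:
        tm1, tm2 = tm2, tm1
        s1, s2 = s2, s1
        f = 1.0 - f
    if abs(tm2 - tm1) < collapse_tol:
        single = fit_boltzmann(curve)
        single.warnings.append("double-sigmoid collapsed to a single transition")
        return single
    fit = MeltingFit(model="double_sigmoid", tm1=tm1, tm2=tm2, slope1=s1, slope2=s2,
                     fraction=f, bottom=bottom, top=top)
    fit.converged = bool(best.status > 0)
    fit.residual_rms = float(np.sqrt(np.mean(best.fun**2)))
    return fit


def read_curve_csv(path: str | Path) -> MeltingCurve:
    """Read a two-column CSV with header ``temperature_C, signal``.

    An optional ``wavelength_nm`` column carries metadata only.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "temperature_c" not in cols or "signal" not in cols:
        raise ValueError(f"{path}: need columns temperature_C and signal")
    wl = None
    if "wavelength_nm" in cols:
        wl = float(df[cols["wavelength_nm"]].iloc[0])
    return MeltingCurve(
        df[cols["temperature_c"]].to_numpy(float),
        df[cols["signal"]].to_numpy(float),
        wavelength_nm=wl,
    )
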