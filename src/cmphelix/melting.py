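"""Thermal-stability analysis: Tm extraction, delta-Tm tables, DSC enthalpy.

The melting temperature of a CMP triple helix is defined operationally as
the steepest point of the two-state CD unfolding transition (mean residue
ellipticity at 225 nm vs temperature).  ``extract_tm`` implements that
definition directly: smooth, differentiate, locate the extremal slope, and
refine it by quadratic interpolation.  ``vant_hoff_fit`` provides an
independent cross-check by fitting the full two-state sigmoid.

DSC thermograms are integrated after linear-endpoint baseline subtraction
to give the calorimetric unfolding enthalpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal

__all__ = [
    "MeltingCurve",
    "TmResult",
    "DSCThermogram",
    "DSCEnthalpyResult",
    "VantHoffResult",
    "extract_tm",
    "delta_tm",
    "dsc_enthalpy",
    "vant_hoff_fit",
]

R_KCAL = 1.987204e-3  # kcal / (mol K)


@dataclass(frozen=True)
class MeltingCurve:
    """CD unfolding curve: temperature grid and MRE at 225 nm.

    Signal units: 10^3 deg cm^2 dmol^-1.  ``heating_rate_C_per_h`` is
    metadata only; no kinetic correction is applied.
    """

    T: np.ndarray
    signal: np.ndarray
    name: str = ""
    heating_rate_C_per_h: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "T", np.asarray(self.T, dtype=float))
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=float))
        if self.T.shape != self.signal.shape or self.T.ndim != 1:
            raise ValueError("T and signal must be matching 1-D arrays")
        if len(self.T) < 15:
            raise ValueError(f"need >= 15 points, got {len(self.T)}")
        if not (np.all(np.isfinite(self.T)) and np.all(np.isfinite(self.signal))):
            raise ValueError("non-finite values in curve")
        if np.any(np.diff(self.T) <= 0):
            raise ValueError("temperature grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"T_C": self.T, "signal": self.signal})


@dataclass(frozen=True)
class TmResult:
    """Outcome of the steepest-point extraction."""

    Tm: float
    peak_height: float
    detected: bool
    smooth_window: int
    name: str = ""


@dataclass(frozen=True)
class DSCThermogram:
    """Excess heat capacity (kcal mol^-1 C^-1) on a temperature grid."""

    T: np.ndarray
    Cp_excess: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "T", np.asarray(self.T, dtype=float))
        object.__setattr__(self, "Cp_excess", np.asarray(self.Cp_excess, dtype=float))
        if self.T.shape != self.Cp_excess.shape or self.T.ndim != 1:
            raise ValueError("T and Cp_excess must be matching 1-D arrays")
        if np.any(np.diff(self.T) <= 0):
            raise ValueError("temperature grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"T_C": self.T, "Cp_excess": self.Cp_excess})


@dataclass(frozen=True)
class DSCEnthalpyResult:
    dH: float  # kcal/mol
    baseline: str
    truncated: bool = False


@dataclass(frozen=True)
class VantHoffResult:
    Tm: float
    dH_vH: float  # kcal/mol, from the transition width
    width: float
    converged: bool


def extract_tm(curve: MeltingCurve, smooth_window: int = 7) -> TmResult:
    """Steepest-point melting temperature.

    The signal is smoothed with a centred Savitzky-Golay filter (local
    quadratic), differentiated by central differences, and the location of
    the extremal |dS/dT| refined by a parabola through the three grid
    points around the maximum.  Unfolding at 225 nm lowers the MRE, so the
    steepest point is a slope minimum; |derivative| keeps the extraction
    orientation-agnostic.  A transition is declared only when the peak
    exceeds three times the derivative's robust baseline spread.
    """
    n = len(curve.T)
    w = int(smooth_window)
    if w < 3:
        w = 3
    if w % 2 == 0:
        w += 1
    w = min(w, n if n % 2 else n - 1)
    smoothed = signal.savgol_filter(curve.signal, window_length=w, polyorder=2)
    deriv = np.gradient(smoothed, curve.T)
    a = np.abs(deriv)
    i = int(np.argmax(a[1:-1])) + 1  # interior extremum
    peak = float(a[i])
    # robust spread of the derivative away from the peak
    half = max(w, 5)
    mask = np.ones(n, dtype=bool)
    mask[max(0, i - half) : i + half + 1] = False
    base = a[mask] if mask.any() else a
    mad = np.median(np.abs(base - np.median(base)))
    spread = 1.4826 * mad
    rng = float(np.ptp(curve.signal))
    floor = 1e-9 * max(1.0, float(np.max(np.abs(curve.signal))))
    detected = bool(rng > 1e3 * floor and peak > 3.0 * spread and peak > floor)
    if not detected:
        return TmResult(Tm=float("nan"), peak_height=peak, detected=False,
                        smooth_window=w, name=curve.name)
    # quadratic refinement around the grid maximum
    x0, x1, x2 = curve.T[i - 1 : i + 2]
    y0, y1, y2 = a[i - 1 : i + 2]
    denom = (y0 - 2 * y1 + y2)
    if denom == 0:
        tm = float(x1)
    else:
        # uniform-grid vertex formula generalised to the local spacing
        tm = float(x1 + 0.5 * (x2 - x0) / 2 * (y0 - y2) / denom)
    return TmResult(Tm=tm, peak_height=peak, detected=True, smooth_window=w,
                    name=curve.name)


def delta_tm(results: Mapping[str, TmResult], reference: str) -> pd.DataFrame:
    """Signed Tm(reference) - Tm(x) table.

    Members without a detected transition are excluded, with a warning
    recorded in the ``note`` column of a trailing row set.
    """
    if reference not in results:
        raise KeyError(f"reference {reference!r} not among results")
    ref = results[reference]
    if not ref.detected:
        raise ValueError(f"reference {reference!r} has no detected transition")
    rows = []
    for label, res in results.items():
        if not res.detected:
            rows.append({"name": label, "Tm_C": np.nan, "delta_Tm_C": np.nan,
                         "note": "no transition detected; excluded"})
            continue
        rows.append({"name": label, "Tm_C": res.Tm,
                     "delta_Tm_C": ref.Tm - res.Tm, "note": ""})
    return pd.DataFrame(rows)


def dsc_enthalpy(
    tg: DSCThermogram,
    baseline: str = "linear-endpoints",
    flank: int = 10,
) -> DSCEnthalpyResult:
    """Integrate a DSC peak to the calorimetric unfolding enthalpy.

    ``linear-endpoints`` draws a line through the mean of the first and
    last ``flank`` points and subtracts it before trapezoid integration;
    ``none`` integrates the raw trace.  A result is flagged truncated when
    the baseline-corrected signal at either grid edge still carries more
    than 5% of the peak.
    """
    if len(tg.T) < 20:
        raise ValueError(f"need >= 20 points spanning the peak, got {len(tg.T)}")
    cp = tg.Cp_excess.astype(float)
    if baseline == "linear-endpoints":
        k = max(2, min(int(flank), len(tg.T) // 4))
        t1, c1 = float(np.mean(tg.T[:k])), float(np.mean(cp[:k]))
        t2, c2 = float(np.mean(tg.T[-k:])), float(np.mean(cp[-k:]))
        slope = (c2 - c1) / (t2 - t1)
        corrected = cp - (c1 + slope * (tg.T - t1))
    elif baseline == "none":
        corrected = cp
    else:
        raise ValueError(f"unknown baseline model {baseline!r}")
    dh = float(np.trapezoid(corrected, tg.T))
    peak = float(np.max(np.abs(corrected))) or 1.0
    truncated = bool(
        abs(corrected[0]) > 0.05 * peak or abs(corrected[-1]) > 0.05 * peak
    )
    return DSCEnthalpyResult(dH=dh, baseline=baseline, truncated=truncated)


def _two_state(T, tm, width, af, bf, au, bu):
    frac = 1.0 / (1.0 + np.exp((tm - T) / width))
    return (af + bf * T) * (1 - frac) + (au + bu * T) * frac


def vant_hoff_fit(curve: MeltingCurve) -> VantHoffResult:
    """Least-squares two-state fit with linear folded/unfolded baselines.

    Returns the fitted Tm and the van't Hoff enthalpy implied by the
    transition width (dH = R Tm^2 / width with Tm in kelvin).  Agrees with
    :func:`extract_tm` within 0.1 C on noiseless generator output.
    """
    first = extract_tm(curve)
    if not first.detected:
        return VantHoffResult(Tm=float("nan"), dH_vH=float("nan"),
                              width=float("nan"), converged=False)
    t = curve.T
    s = curve.signal
    p0 = [first.Tm, 2.0, float(s[0]), 0.0, float(s[-1]), 0.0]
    try:
        popt, _ = optimize.curve_fit(_two_state, t, s, p0=p0, maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning):
        return VantHoffResult(Tm=float("nan"), dH_vH=float("nan"),
                              width=float("nan"), converged=False)
    tm, width = float(popt[0]), abs(float(popt[1]))
    if not (t[0] < tm < t[-1]) or width <= 0:
        return VantHoffResult(Tm=tm, dH_vH=float("nan"), width=width,
                              converged=False)
    tm_k = tm + 273.15
    dh = R_KCAL * tm_k**2 / width
    return VantHoffResult(Tm=tm, dH_vH=dh, width=width, converged=True)
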