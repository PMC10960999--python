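"""Crop water stress index (CWSI) chain.

The CWSI locates the midday canopy-air temperature difference Tc - Ta
between a non-water-stressed lower baseline Tmin = A + B*VPD and a fully
stressed upper limit Tmax = A + B*VPG, where VPD is the air vapour
pressure deficit and VPG the saturation-pressure difference between Ta
and Ta + A (Idso's construction):

    CWSI = ((Tc - Ta) - Tmin) / (Tmax - Tmin)

A and B are fit by ordinary least squares of Tc - Ta on VPD over
well-watered (CK) plots inside the midday measurement window.  CWSI is
reported unclamped; values outside [0, 1] are flagged rather than hidden,
since they usually indicate baseline misfit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import ValidationError


@dataclass(frozen=True)
class CwsiBaseline:
    """Non-water-stressed baseline Tc - Ta = A + B*VPD (A in degC, B in degC/kPa)."""

    A: float
    B: float
    n_fit: int
    r2_fit: float


@dataclass(frozen=True)
class CwsiResult:
    VPD: float
    VPG: float
    Tmin: float
    Tmax: float
    CWSI: float
    out_of_envelope: bool


def saturation_vapor_pressure(Ta):
    """Saturation vapour pressure es(Ta) = 0.61*exp(17.27*Ta/(Ta+237.3)), kPa."""
    Ta = np.asarray(Ta, dtype=float)
    if np.any(Ta <= -237.3):
        raise ValidationError("air temperature at or below -237.3 degC")
    out = 0.61 * np.exp(17.27 * Ta / (Ta + 237.3))
    return float(out) if out.ndim == 0 else out


def vpd(Ta, RH):
    """Vapour pressure deficit es(Ta)*(1 - RH/100), kPa.  RH in percent."""
    RH = np.asarray(RH, dtype=float)
    if np.any((RH < 0) | (RH > 100)):
        raise ValidationError("RH outside [0, 100]")
    out = saturation_vapor_pressure(Ta) * (1.0 - RH / 100.0)
    return float(out) if np.ndim(out) == 0 else out


def vpg(Ta, A, convention: str = "idso"):
    """Vapour pressure gradient between Ta and Ta + A.

    ``idso`` (default): es(Ta) - es(Ta + A), negative for A > 0, which with
    a negative baseline slope B makes Tmax > Tmin.  ``reversed`` flips the
    sign for users who read the ambiguous textbook prose the other way.
    """
    g = saturation_vapor_pressure(Ta) - saturation_vapor_pressure(np.asarray(Ta) + A)
    if convention == "reversed":
        g = -g
    elif convention != "idso":
        raise ValueError(f"unknown VPG convention {convention!r}")
    return float(g) if np.ndim(g) == 0 else g


def fit_baseline(micro: pd.DataFrame, window: tuple[int, int] = (10, 14)) -> CwsiBaseline:
    """Fit the non-stressed baseline from well-watered hourly records.

    ``micro`` needs columns Tc, Ta, RH, timestamp and should already be
    restricted to non-stressed (CK) plots; rows outside the hour window
    [start, end] (inclusive) are dropped before the OLS fit of Tc - Ta
    on VPD.
    """
    sel = micro
    if "timestamp" in micro.columns and window is not None:
        hours = pd.to_datetime(micro["timestamp"]).dt.hour
        sel = micro[(hours >= window[0]) & (hours <= window[1])]
    if len(sel) < 2:
        raise ValidationError(f"need >= 2 in-window records to fit a baseline, got {len(sel)}")
    x = vpd(sel["Ta"].to_numpy(float), sel["RH"].to_numpy(float))
    y = sel["Tc"].to_numpy(float) - sel["Ta"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValidationError("all VPD values identical; baseline slope is unidentifiable")
    B, A = np.polyfit(x, y, 1)
    resid = y - (A + B * x)
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if sst == 0 else max(0.0, 1.0 - np.sum(resid ** 2) / sst)
    return CwsiBaseline(A=float(A), B=float(B), n_fit=len(sel), r2_fit=float(r2))


def cwsi(Tc: float, Ta: float, RH: float, baseline: CwsiBaseline,
         convention: str = "idso") -> CwsiResult:
    """CWSI for a single reading; unclamped, flagged when outside [0, 1]."""
    d = vpd(Ta, RH)
    g = vpg(Ta, baseline.A, convention)
    tmin = baseline.A + baseline.B * d
    tmax = baseline.A + baseline.B * g
    if tmax - tmin <= 0:
        raise ValidationError(
            f"degenerate CWSI envelope (Tmax {tmax:.3f} <= Tmin {tmin:.3f}) "
            f"for Ta={Ta}, RH={RH}, A={baseline.A}, B={baseline.B}"
        )
    value = ((Tc - Ta) - tmin) / (tmax - tmin)
    return CwsiResult(VPD=d, VPG=g, Tmin=tmin, Tmax=tmax, CWSI=float(value),
                      out_of_envelope=not (0.0 <= value <= 1.0))


def plot_stage_cwsi(micro: pd.DataFrame, baseline: CwsiBaseline,
                    window: tuple[int, int] = (10, 14),
                    convention: str = "idso") -> pd.DataFrame:
    """Mean in-window hourly CWSI per (plot_id, stage).

    ``micro`` needs plot_id, stage, timestamp, Tc, Ta, RH columns.  Returns
    a frame with one row per (plot_id, stage) and a CWSI column.
    """
    hours = pd.to_datetime(micro["timestamp"]).dt.hour
    sel = micro[(hours >= window[0]) & (hours <= window[1])].copy()
    if sel.empty:
        raise ValidationError("no microclimate records inside the hour window")
    d = vpd(sel["Ta"].to_numpy(float), sel["RH"].to_numpy(float))
    g = vpg(sel["Ta"].to_numpy(float), baseline.A, convention)
    tmin = baseline.A + baseline.B * d
    tmax = baseline.A + baseline.B * g
    if np.any(tmax - tmin <= 0):
        raise ValidationError("degenerate CWSI envelope in hourly series")
    sel["CWSI"] = ((sel["Tc"].to_numpy(float) - sel["Ta"].to_numpy(float)) - tmin) / (tmax - tmin)
    out = sel.groupby(["plot_id", "stage"], as_index=False)["CWSI"].mean()
    return out
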