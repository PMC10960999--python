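"""Physiological derivations: chlorophyll-fluorescence parameters,
gravimetric leaf water content, SPAD aggregation, and leaf area index.

All four quantities are simple ratios or linear forms computed on plot
means; ratio guards raise typed errors rather than returning NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import ValidationError


class UndefinedRatioError(ZeroDivisionError, ValueError):
    """A physiological ratio has a zero denominator."""


@dataclass(frozen=True)
class FluorescenceRecord:
    """Dark- and light-adapted PAM fluorescence levels (instrument units)."""

    Fo: float
    Fm: float
    Fs: float | None = None
    Fm_prime: float | None = None

    def __post_init__(self):
        if self.Fo < 0 or self.Fm < 0:
            raise ValidationError("fluorescence levels must be non-negative")
        if self.Fm < self.Fo:
            raise ValidationError(f"Fm ({self.Fm}) < Fo ({self.Fo})")
        if (self.Fm_prime is not None and self.Fs is not None
                and self.Fm_prime < self.Fs):
            raise ValidationError(f"Fm' ({self.Fm_prime}) < Fs ({self.Fs})")


@dataclass(frozen=True)
class LeafSample:
    """Fresh (FW) and oven-dry (DW) leaf mass in grams."""

    FW: float
    DW: float

    def __post_init__(self):
        if not (self.FW >= self.DW >= 0):
            raise ValidationError(f"need FW >= DW >= 0, got FW={self.FW}, DW={self.DW}")


@dataclass(frozen=True)
class CanopySample:
    """Green leaf area per hill D (cm^2) and planting density rho (hills m^-2)."""

    D: float
    rho: float

    def __post_init__(self):
        if self.D < 0:
            raise ValidationError("leaf area D must be >= 0")
        if self.rho <= 0:
            raise ValidationError("planting density rho must be > 0")


def fv_fm(rec: FluorescenceRecord) -> float:
    """Maximum photochemical efficiency of PSII, (Fm - Fo)/Fm."""
    if rec.Fm == 0:
        raise UndefinedRatioError("Fv/Fm undefined: Fm = 0")
    return (rec.Fm - rec.Fo) / rec.Fm


def y_ii(rec: FluorescenceRecord) -> float:
    """Actual photochemical efficiency under light, (Fm' - Fs)/Fm'."""
    if rec.Fm_prime is None or rec.Fs is None:
        raise ValidationError("Y(II) needs Fs and Fm'")
    if rec.Fm_prime == 0:
        raise UndefinedRatioError("Y(II) undefined: Fm' = 0")
    return (rec.Fm_prime - rec.Fs) / rec.Fm_prime


def leaf_water_content(sample: LeafSample) -> float:
    """Gravimetric leaf water content, (FW - DW)/FW, a fraction in [0, 1]."""
    if sample.FW == 0:
        raise UndefinedRatioError("LWC undefined: FW = 0")
    return (sample.FW - sample.DW) / sample.FW


def leaf_area_index(sample: CanopySample) -> float:
    """Leaf area index D*rho/10000 (cm^2 per hill times hills m^-2 to m^2 m^-2)."""
    return sample.D * sample.rho / 10000.0


def aggregate_spad(readings: Sequence[float]) -> float:
    """Plot-level SPAD: the arithmetic mean of the individual leaf readings."""
    readings = np.asarray(readings, dtype=float)
    if readings.size == 0:
        raise ValidationError("no SPAD readings to aggregate")
    return float(readings.mean())
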