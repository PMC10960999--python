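"""Vegetation indices computed directly on the 1-nm reflectance grid.

Besides the free two-band normalised difference ND(l1, l2), the classical
set is: NDVI (895/675), NDII (819/1600), NDWI (860/1240), WI (970/900) and
MSI (1600/820).  No interpolation or smoothing is applied; every index is
an exact grid lookup, so all of them are invariant under multiplying the
whole spectrum by a positive constant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records import SpectraCollection, SpectrumRecord
from .physio import UndefinedRatioError

# name -> (kind, bands): normalised differences and simple ratios
CLASSIC_INDEX_REGISTRY: dict[str, tuple[str, tuple[int, int]]] = {
    "NDVI": ("nd", (895, 675)),
    "NDII": ("nd", (819, 1600)),
    "NDWI": ("nd", (860, 1240)),
    "WI": ("ratio", (970, 900)),
    "MSI": ("ratio", (1600, 820)),
}


def reflectance_at(spec: SpectrumRecord, wavelength: int) -> float:
    """Exact grid lookup of reflectance at an integer wavelength in nm."""
    wl = spec.wavelengths
    idx = np.searchsorted(wl, wavelength)
    if (wavelength != int(wavelength) or idx >= wl.size or wl[idx] != wavelength):
        below = wl[min(max(idx - 1, 0), wl.size - 1)]
        above = wl[min(idx, wl.size - 1)]
        raise KeyError(
            f"{wavelength} nm is not on the grid (nearest grid bands: {below}, {above})")
    return float(spec.reflectance[idx])


def normalized_difference(spec: SpectrumRecord, l1: int, l2: int) -> float:
    """ND(l1, l2) = (R_l1 - R_l2)/(R_l1 + R_l2); antisymmetric in (l1, l2)."""
    r1, r2 = reflectance_at(spec, l1), reflectance_at(spec, l2)
    if r1 + r2 == 0:
        raise UndefinedRatioError(f"ND({l1},{l2}) undefined: R_{l1} + R_{l2} = 0")
    return (r1 - r2) / (r1 + r2)


def classic_indices(spec: SpectrumRecord) -> dict[str, float]:
    """All five classical indices for one spectrum, keyed by name."""
    out = {}
    for name, (kind, (a, b)) in CLASSIC_INDEX_REGISTRY.items():
        ra, rb = reflectance_at(spec, a), reflectance_at(spec, b)
        if kind == "nd":
            if ra + rb == 0:
                raise UndefinedRatioError(f"{name} undefined: zero denominator")
            out[name] = (ra - rb) / (ra + rb)
        else:
            if rb == 0:
                raise UndefinedRatioError(f"{name} undefined: zero denominator")
            out[name] = ra / rb
    return out


def index_table(coll: SpectraCollection, nd_pair: tuple[int, int] | None = None,
                registry: dict | None = None) -> pd.DataFrame:
    """One row per spectrum with all index columns (vectorised).

    ``nd_pair`` adds an ``ND`` column for that band pair; extra two-band
    indices can be declared through ``registry`` entries of the same shape
    as :data:`CLASSIC_INDEX_REGISTRY`.
    """
    reg = dict(CLASSIC_INDEX_REGISTRY)
    if registry:
        reg.update(registry)
    out = coll.meta.copy()
    if nd_pair is not None:
        r1, r2 = coll.column(nd_pair[0]), coll.column(nd_pair[1])
        out["ND"] = (r1 - r2) / (r1 + r2)
    for name, (kind, (a, b)) in reg.items():
        ra, rb = coll.column(a), coll.column(b)
        out[name] = (ra - rb) / (ra + rb) if kind == "nd" else ra / rb
    return out
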