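"""Tabular I/O and domain records for the leaf-water-content pipeline.

Input tables are delimited text (comma default, tab accepted), UTF-8, one
header row.  Wide spectra use column names ``R350`` .. ``R2500``; a long
dialect with ``wavelength_nm`` / ``reflectance`` columns is also accepted.
The wavelength grid is fixed at 1-nm integer steps from 350 to 2500 nm
(2151 bands); inputs on any other grid are rejected rather than resampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ricelwc")

WAVELENGTH_MIN = 350
WAVELENGTH_MAX = 2500
WAVELENGTH_GRID = np.arange(WAVELENGTH_MIN, WAVELENGTH_MAX + 1)
N_BANDS = WAVELENGTH_GRID.size  # 2151

TREATMENTS = ("CK", "MADW", "SADW")
STAGES = ("booting", "flowering", "initial_filling", "middle_filling")

META_COLUMNS = ["plot_id", "year", "site", "cultivar", "treatment", "stage"]


class SchemaError(ValueError):
    """A table is missing required columns or declares an unsupported grid."""


class ValidationError(ValueError):
    """Record values violate a domain invariant."""


@dataclass
class SpectrumRecord:
    """One canopy reflectance spectrum for a plot at a growth stage.

    Reflectance is stored as a fraction in [0, 1], aligned to an integer
    wavelength grid in nm.  ``n_scans`` counts the replicate spectrometer
    scans averaged into this record (1 for a raw scan).
    """

    plot_id: str
    year: int
    site: str
    cultivar: str
    treatment: str
    stage: str
    wavelengths: np.ndarray
    reflectance: np.ndarray
    n_scans: int = 1

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=int)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.size != self.reflectance.size:
            raise ValidationError(
                f"plot {self.plot_id}: {self.wavelengths.size} wavelengths but "
                f"{self.reflectance.size} reflectance values"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValidationError(f"plot {self.plot_id}: wavelengths not strictly increasing")
        if self.wavelengths[0] < WAVELENGTH_MIN or self.wavelengths[-1] > WAVELENGTH_MAX:
            raise ValidationError(
                f"plot {self.plot_id}: wavelengths outside [{WAVELENGTH_MIN}, {WAVELENGTH_MAX}]"
            )
        bad = np.flatnonzero((self.reflectance < 0) | (self.reflectance > 1))
        if bad.size:
            raise ValidationError(
                f"plot {self.plot_id} stage {self.stage}: reflectance outside [0, 1] at "
                f"{self.wavelengths[bad[0]]} nm (value {self.reflectance[bad[0]]:g})"
            )

    @property
    def key(self) -> tuple:
        return (self.plot_id, self.stage)


@dataclass
class MicroclimateRecord:
    """One hourly canopy/air reading: canopy temperature Tc and air
    temperature Ta in degrees C, relative humidity RH in percent."""

    plot_id: str
    timestamp: pd.Timestamp
    Tc: float
    Ta: float
    RH: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.RH <= 100.0):
            raise ValidationError(f"plot {self.plot_id}: RH {self.RH} outside [0, 100]")
        if not (np.isfinite(self.Tc) and np.isfinite(self.Ta)):
            raise ValidationError(f"plot {self.plot_id}: non-finite temperature")


@dataclass
class PlotObservation:
    """Merged per-plot trait row used by the screening and modelling stages."""

    plot_id: str
    year: int
    site: str
    cultivar: str
    treatment: str
    stage: str
    LWC: float
    SPAD: float | None = None
    Fo: float | None = None
    Fm: float | None = None
    Fs: float | None = None
    Fm_prime: float | None = None
    FvFm: float | None = None
    YII: float | None = None
    CWSI: float | None = None
    LAI: float | None = None
    biomass: float | None = None
    yield_t_ha: float | None = None

    def __post_init__(self) -> None:
        for name in ("LWC", "FvFm", "YII"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"plot {self.plot_id}: {name}={v} outside [0, 1]")
        if self.Fm is not None and self.Fo is not None and self.Fm < self.Fo:
            raise ValidationError(f"plot {self.plot_id}: Fm < Fo")


class SpectraCollection:
    """A set of spectra as a metadata frame plus an (n, bands) matrix.

    The analysis stages (vegetation indices, band search) operate on this
    vectorised container; :func:`records_to_collection` and
    :func:`collection_to_records` convert to and from per-record form.
    """

    def __init__(self, meta: pd.DataFrame, reflectance: np.ndarray,
                 wavelengths: np.ndarray | None = None):
        self.meta = meta.reset_index(drop=True)
        self.reflectance = np.asarray(reflectance, dtype=float)
        self.wavelengths = (WAVELENGTH_GRID if wavelengths is None
                            else np.asarray(wavelengths, dtype=int))
        if self.reflectance.shape != (len(self.meta), self.wavelengths.size):
            raise ValidationError("reflectance matrix shape does not match meta/wavelengths")

    def __len__(self) -> int:
        return len(self.meta)

    def band_index(self, wavelength: int) -> int:
        idx = np.searchsorted(self.wavelengths, wavelength)
        if idx >= self.wavelengths.size or self.wavelengths[idx] != wavelength:
            raise KeyError(f"wavelength {wavelength} nm not on grid")
        return int(idx)

    def column(self, wavelength: int) -> np.ndarray:
        return self.reflectance[:, self.band_index(wavelength)]

    def subset(self, mask: np.ndarray) -> "SpectraCollection":
        mask = np.asarray(mask)
        return SpectraCollection(self.meta.loc[mask], self.reflectance[mask],
                                 self.wavelengths)


def records_to_collection(records: Sequence[SpectrumRecord]) -> SpectraCollection:
    if not records:
        raise ValidationError("no spectra")
    grid = records[0].wavelengths
    for r in records[1:]:
        if not np.array_equal(r.wavelengths, grid):
            raise ValidationError("records are on different wavelength grids")
    meta = pd.DataFrame(
        [{c: getattr(r, c) for c in META_COLUMNS} | {"n_scans": r.n_scans} for r in records]
    )
    return SpectraCollection(meta, np.vstack([r.reflectance for r in records]), grid)


def collection_to_records(coll: SpectraCollection) -> list[SpectrumRecord]:
    out = []
    for i, row in coll.meta.iterrows():
        out.append(SpectrumRecord(
            plot_id=str(row["plot_id"]), year=int(row["year"]), site=str(row["site"]),
            cultivar=str(row["cultivar"]), treatment=str(row["treatment"]),
            stage=str(row["stage"]), wavelengths=coll.wavelengths,
            reflectance=coll.reflectance[i],
            n_scans=int(row.get("n_scans", 1)),
        ))
    return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_table(path, sep=None) -> pd.DataFrame:
    # sep=None lets pandas sniff comma vs tab
    return pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")


def read_spectra(path, sep=None) -> list[SpectrumRecord]:
    """Read spectra from wide (``R350``..``R2500`` columns) or long
    (``wavelength_nm``/``reflectance`` columns) delimited text.

    Percent-scale reflectance (max > 1.5) is auto-detected and converted to
    fractions with a logged warning.  Replicate scans (rows sharing
    plot/stage, distinguished by a ``scan_id`` column if present) are
    returned as separate records, not yet averaged.
    """
    df = _read_table(path, sep)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"spectra table missing metadata columns: {missing}")

    if "wavelength_nm" in df.columns:  # long dialect
        if "reflectance" not in df.columns:
            raise SchemaError("long-format spectra need a 'reflectance' column")
        values = df["reflectance"].to_numpy(float)
        values = _maybe_percent(values, path)
        df = df.assign(reflectance=values)
        keys = META_COLUMNS + (["scan_id"] if "scan_id" in df.columns else [])
        records = []
        for key, grp in df.groupby(keys, sort=False):
            grp = grp.sort_values("wavelength_nm")
            wl = grp["wavelength_nm"].to_numpy(int)
            _check_grid(wl)
            meta = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
            records.append(SpectrumRecord(
                plot_id=str(meta["plot_id"]), year=int(meta["year"]), site=str(meta["site"]),
                cultivar=str(meta["cultivar"]), treatment=str(meta["treatment"]),
                stage=str(meta["stage"]), wavelengths=wl,
                reflectance=grp["reflectance"].to_numpy(float)))
        return records

    band_cols = [c for c in df.columns if c.startswith("R") and c[1:].isdigit()]
    if not band_cols:
        raise SchemaError(f"spectra table has no wavelength columns (first absent band: R{WAVELENGTH_MIN})")
    wl = np.array(sorted(int(c[1:]) for c in band_cols))
    _check_grid(wl)
    ordered = [f"R{w}" for w in wl]
    values = df[ordered].to_numpy(float)
    values = _maybe_percent(values, path)
    records = []
    for i, row in df.iterrows():
        try:
            records.append(SpectrumRecord(
                plot_id=str(row["plot_id"]), year=int(row["year"]), site=str(row["site"]),
                cultivar=str(row["cultivar"]), treatment=str(row["treatment"]),
                stage=str(row["stage"]), wavelengths=wl, reflectance=values[i],
                n_scans=int(row["n_scans"]) if "n_scans" in df.columns else 1))
        except ValidationError as e:
            raise ValidationError(f"row {i}: {e}") from None
    return records


def _check_grid(wl: np.ndarray) -> None:
    if wl[0] != WAVELENGTH_MIN or wl[-1] != WAVELENGTH_MAX or np.any(np.diff(wl) != 1):
        raise SchemaError(
            "spectra must be on the 1-nm grid 350-2500 nm (2151 bands); "
            f"got {wl.size} bands spanning {wl[0]}-{wl[-1]} nm"
        )


def _maybe_percent(values: np.ndarray, path) -> np.ndarray:
    if np.nanmax(values) > 1.5:
        logger.warning("%s: reflectance looks percent-scaled (max %.3g); dividing by 100",
                       path, np.nanmax(values))
        values = values / 100.0
    return values


def write_spectra(records_or_coll, path, sep=",", fmt="wide") -> None:
    coll = (records_or_coll if isinstance(records_or_coll, SpectraCollection)
            else records_to_collection(records_or_coll))
    if fmt == "wide":
        wide = pd.DataFrame(coll.reflectance, columns=[f"R{w}" for w in coll.wavelengths])
        pd.concat([coll.meta, wide], axis=1).to_csv(path, sep=sep, index=False,
                                                    float_format="%.6f")
    elif fmt == "long":
        rows = []
        for i, meta in coll.meta.iterrows():
            block = pd.DataFrame({
                "wavelength_nm": coll.wavelengths,
                "reflectance": coll.reflectance[i]})
            for c in META_COLUMNS:
                block[c] = meta[c]
            rows.append(block[META_COLUMNS + ["wavelength_nm", "reflectance"]])
        pd.concat(rows).to_csv(path, sep=sep, index=False, float_format="%.6f")
    else:
        raise ValueError(f"unknown spectra format {fmt!r}")


def read_microclimate(path, sep=None) -> pd.DataFrame:
    df = _read_table(path, sep)
    need = {"plot_id", "timestamp", "Tc", "Ta", "RH"}
    missing = need - set(df.columns)
    if missing:
        raise SchemaError(f"microclimate table missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if ((df["RH"] < 0) | (df["RH"] > 100)).any():
        raise ValidationError("RH outside [0, 100]")
    dup = df.duplicated(subset=["plot_id", "timestamp"])
    if dup.any():
        raise ValidationError(f"{int(dup.sum())} duplicate (plot_id, timestamp) readings")
    return df


def read_observations(path, sep=None) -> pd.DataFrame:
    df = _read_table(path, sep)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"observation table missing columns: {missing}")
    return df


def write_table(df: pd.DataFrame, path, sep=",") -> None:
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def average_replicate_scans(scans: Sequence[SpectrumRecord]) -> SpectrumRecord:
    """Element-wise arithmetic mean of replicate scans of one plot/stage.

    All scans must share metadata (plot, stage) and the wavelength grid;
    ``n_scans`` of the result is the total input scan count.
    """
    if not scans:
        raise ValidationError("no scans to average")
    first = scans[0]
    for s in scans[1:]:
        if s.key != first.key:
            raise ValidationError(f"scans mix plots/stages: {s.key} vs {first.key}")
        if not np.array_equal(s.wavelengths, first.wavelengths):
            raise ValidationError("scans are on different wavelength grids")
    # mean as first + mean(deviations): exactly idempotent for identical scans
    mean = first.reflectance + np.mean(
        [s.reflectance - first.reflectance for s in scans], axis=0)
    return replace(first, reflectance=mean, n_scans=int(sum(s.n_scans for s in scans)))


def group_and_average(records: Iterable[SpectrumRecord]) -> list[SpectrumRecord]:
    """Group records by (plot_id, stage) and average each group."""
    groups: dict[tuple, list[SpectrumRecord]] = {}
    for r in records:
        groups.setdefault(r.key, []).append(r)
    return [average_replicate_scans(g) for g in groups.values()]


def merge_observations(*sources: pd.DataFrame) -> pd.DataFrame:
    """Inner-join trait tables on (plot_id, stage); orphan keys are logged.

    Each source must have unique (plot_id, stage) keys; metadata columns
    present in several sources are taken from the first.
    """
    keys = ["plot_id", "stage"]
    merged = None
    for src in sources:
        dup = src.duplicated(subset=keys)
        if dup.any():
            dups = src.loc[dup, keys].to_records(index=False).tolist()
            raise ValidationError(f"duplicate (plot_id, stage) keys: {dups}")
        if merged is None:
            merged = src.copy()
            continue
        overlap = [c for c in src.columns if c in merged.columns and c not in keys]
        before = len(merged)
        merged = merged.merge(src.drop(columns=overlap), on=keys, how="inner")
        lost = before - len(merged)
        if lost:
            logger.info("merge_observations: %d rows dropped joining a source "
                        "(unmatched keys)", lost)
    return merged
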