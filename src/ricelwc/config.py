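"""Run configuration: one structured text (YAML) file drives the pipeline."""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

logger = logging.getLogger("ricelwc")


@dataclass
class RunConfig:
    out_dir: str = "lwc_run"
    seed: int = 0
    simulate: bool = True
    # input paths (used when simulate is False)
    spectra_path: str | None = None
    microclimate_path: str | None = None
    physiology_path: str | None = None
    # analysis settings
    nd_pair: tuple[int, int] | None = None   # None: take the band-search optimum
    band_step: int = 1
    train_year: int = 2022
    train_fraction: float = 0.7
    baseline_window: tuple[int, int] = (10, 14)
    vpg_convention: str = "idso"
    outlier_rule: str = "sd"
    outlier_n_sd: float = 3.0
    drop_outliers: bool = False
    covariates: tuple[str, ...] = ("CWSI", "FvFm", "SPAD")
    benchmark_stage: str = "flowering"
    design_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        for name in ("nd_pair", "baseline_window", "covariates"):
            v = getattr(cfg, name)
            if isinstance(v, list):
                setattr(cfg, name, tuple(v))
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def stage_seed(self, stage_name: str) -> int:
        """Deterministic per-stage seed derived from the global one."""
        return (self.seed ^ zlib.crc32(stage_name.encode())) % (2 ** 31)
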