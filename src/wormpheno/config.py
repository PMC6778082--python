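"""Run configuration and manifest plumbing for the pipeline commands.

A RunConfig captures everything a reproducible run needs: calibration,
simulation design, segmentation/centerline/fit parameter blocks, and the
master seed. It round-trips through YAML (write -> read -> identical) and
hashes canonically for provenance stamps.

Concentrations are stored in mol/L as numbers (0 = control) and rendered
with SI prefixes only in reports, which avoids "1 mM" vs "1000 µM"
string-parsing ambiguity. Time points are hours post-hatch.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .wormsim import DEFAULT_CONCENTRATIONS


@dataclass
class RunConfig:
    outdir: str = "wormpheno_run"
    seed: int = 0
    log_level: str = "INFO"

    # calibration / acquisition
    px_um: float = 1.3
    fps: float = 5.0
    duration_s: float = 10.0
    chamber_px: int = 984

    # simulated experiment design
    n_worms_per_cond: int = 6
    timepoints_h: list[float] = field(
        default_factory=lambda: [12.0, 24.0, 36.0, 48.0, 60.0, 72.0]
    )
    concentrations: list[float] = field(
        default_factory=lambda: list(DEFAULT_CONCENTRATIONS)
    )
    noise_sd: float = 0.02
    worm_cv: float = 0.10
    embryo_n_per_cond: int = 12
    embryo_hatch_prob: float = 0.70
    embryo_dead_l1_prob: float = 0.10
    embryo_mean_dev_h: float = 9.0
    embryo_sd_dev_h: float = 1.0

    # growth/dose truth of the simulator
    growth: dict = field(
        default_factory=lambda: {
            "L_max_um": 1100.0,
            "L0_um": 250.0,
            "t_mid_h": 30.0,
            "k_h": 0.12,
            "ic50_growth": 4.6e-5,
            "hill_growth": 1.2,
            "ic50_motility": 5e-6,
            "hill_motility": 1.0,
        }
    )

    # analysis parameter blocks
    segmentation: dict = field(
        default_factory=lambda: {
            "threshold": None,
            "background_percentile": 90.0,
            "min_area_px": 30,
        }
    )
    centerline: dict = field(default_factory=lambda: {"K": 101, "smooth": 1.0})
    fit: dict = field(
        default_factory=lambda: {"weighted": True, "sem_floor": 1.0}
    )
    analysis_times_h: list[float] = field(
        default_factory=lambda: [24.0, 36.0, 48.0]
    )

    def validate(self) -> None:
        if self.n_worms_per_cond < 1:
            raise ValueError("n_worms_per_cond must be >= 1")
        if not self.timepoints_h:
            raise ValueError("timepoints_h must not be empty")
        if self.px_um <= 0 or self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("calibration values must be positive")
        cs = list(self.concentrations)
        if cs != sorted(cs) or not cs or cs[0] != 0.0:
            raise ValueError("concentrations must be ascending with 0 first")

    # -- serialisation -----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


MANIFEST_COLUMNS = ["clip_path", "worm_id", "condition_mol", "time_h"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a manifest CSV (clip_path, worm_id, condition_mol,
    time_h); (worm_id, time_h) pairs must be unique and concentrations
    nonnegative."""
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if (df["condition_mol"] < 0).any():
        raise ValueError("conditions must be nonnegative mol/L")
    if df.duplicated(["worm_id", "time_h"]).any():
        raise ValueError("duplicate (worm_id, time_h) rows in manifest")
    return df


_SI = [(1e-3, "mM"), (1e-6, "uM"), (1e-9, "nM"), (1e-12, "pM")]


def format_concentration(c_mol: float) -> str:
    """Render mol/L with an SI prefix: 4.6e-5 -> '46 uM'; 0 -> 'control'."""
    if c_mol == 0:
        return "control"
    for scale, unit in _SI:
        if c_mol >= scale:
            v = c_mol / scale
            return f"{v:g} {unit}"
    return f"{c_mol:g} M"
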