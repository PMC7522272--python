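"""Dataset serialization: CSV schemas, TIFF stacks, YAML configuration.

CSV is the canonical interchange format.  Image stacks are written as
multi-page 32-bit float TIFF with a JSON sidecar carrying the acquisition
metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import InvalidConfigError, SchemaError
from .nba import ITEM_MAX
from .segmentation import REGIONS, MBRFrameSequence, RegionMasks, ROIRect
from .synthetic import PWF_PARAMS, LongitudinalDataset, StudyConfig

__all__ = [
    "SERIES_COLUMNS",
    "PWF_COLUMNS",
    "NBA_COLUMNS",
    "RECORD_COLUMNS",
    "AnalysisConfig",
    "PipelineConfig",
    "write_frame_sequence",
    "read_frame_sequence",
    "write_masks",
    "read_masks",
    "write_series_dataset",
    "read_series_dataset",
    "write_pwf_table",
    "read_pwf_table",
    "write_nba_table",
    "read_nba_table",
    "write_longitudinal_dataset",
    "read_longitudinal_dataset",
    "load_pipeline_config",
]

SERIES_COLUMNS = ("rabbit_id", "day", "is_baseline", "region", "frame_index", "time_s", "mbr")
PWF_COLUMNS = (
    "rabbit_id", "day", "region",
    "mbr", "mbr_max", "mbr_min", "ac", "bos", "bot", "rr", "fr",
    "fai", "ati", "ri", "s1_area", "s2_area", "w", "f", "n_frames",
)
NBA_COLUMNS = ("rabbit_id", "day", "session", *ITEM_MAX, "is_dead", "total")
RECORD_COLUMNS = (
    "rabbit_id", "day", "session", "is_baseline", "region", "nba_total", *PWF_PARAMS,
)


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def write_frame_sequence(seq: MBRFrameSequence, path: Path | str) -> tuple[Path, Path]:
    """Write a multi-page float32 TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, seq.frames.astype(np.float32))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "frame_rate_hz": seq.frame_rate_hz,
                "acquisition_s": seq.acquisition_s,
                "units": "AU",
            },
            indent=2,
        )
    )
    return path, sidecar


def read_frame_sequence(path: Path | str) -> MBRFrameSequence:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise SchemaError(f"missing JSON sidecar for {path}")
    meta = json.loads(sidecar.read_text())
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    return MBRFrameSequence(
        frames=frames,
        frame_rate_hz=float(meta["frame_rate_hz"]),
        acquisition_s=float(meta["acquisition_s"]),
    )


def write_masks(masks: RegionMasks, path: Path | str) -> Path:
    """8-bit mask image: 255 = vessel, 0 = tissue."""
    path = Path(path)
    tifffile.imwrite(path, np.where(masks.vessel, 255, 0).astype(np.uint8))
    return path


def read_masks(path: Path | str) -> RegionMasks:
    img = tifffile.imread(Path(path))
    vessel = img > 0
    return RegionMasks(vessel=vessel, tissue=~vessel)


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def _read_csv(path: Path | str, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise SchemaError(f"cannot read dataset {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if "region" in df.columns:
        bad = set(df["region"].unique()) - set(REGIONS)
        if bad:
            raise SchemaError(f"{path}: unknown region labels {sorted(bad)}")
    return df


def write_series_dataset(df: pd.DataFrame, path: Path | str) -> Path:
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"series dataset missing columns {missing}")
    path = Path(path)
    df.loc[:, list(SERIES_COLUMNS)].to_csv(path, index=False)
    return path


def read_series_dataset(path: Path | str) -> pd.DataFrame:
    return _read_csv(path, SERIES_COLUMNS)


def write_pwf_table(df: pd.DataFrame, path: Path | str) -> Path:
    missing = [c for c in PWF_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"PWF table missing columns {missing}")
    path = Path(path)
    df.loc[:, list(PWF_COLUMNS)].to_csv(path, index=False)
    return path


def read_pwf_table(path: Path | str) -> pd.DataFrame:
    return _read_csv(path, PWF_COLUMNS)


def write_nba_table(df: pd.DataFrame, path: Path | str) -> Path:
    missing = [c for c in NBA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"NBA table missing columns {missing}")
    path = Path(path)
    df.loc[:, list(NBA_COLUMNS)].to_csv(path, index=False)
    return path


def read_nba_table(path: Path | str) -> pd.DataFrame:
    return _read_csv(path, NBA_COLUMNS)


def write_longitudinal_dataset(
    dataset: LongitudinalDataset, records_path: Path | str, truth_path: Path | str
) -> tuple[Path, Path]:
    records_path, truth_path = Path(records_path), Path(truth_path)
    dataset.data.to_csv(records_path, index=False)
    dataset.ground_truth.to_csv(truth_path, index=False)
    return records_path, truth_path


def read_longitudinal_dataset(
    records_path: Path | str, truth_path: Optional[Path | str] = None,
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    records = _read_csv(records_path, RECORD_COLUMNS)
    truth = None
    if truth_path is not None:
        truth = _read_csv(truth_path, ("rabbit_id", "day", "region", "regime"))
    return records, truth


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisConfig:
    n_frames: int = 30
    segmentation_method: str = "otsu"
    quantile_q: float = 0.2
    roi: Optional[tuple[int, int, int, int]] = None  # row0, col0, height, width
    vrp_window: tuple[int, int] = (1, 19)
    vep_window: tuple[int, int] = (20, 28)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InvalidConfigError("alpha must lie in (0, 1)")
        if self.n_frames < 8:
            raise InvalidConfigError("n_frames must be >= 8")

    def roi_rect(self) -> Optional[ROIRect]:
        if self.roi is None:
            return None
        return ROIRect(*self.roi)


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: Path
    study: StudyConfig = field(default_factory=StudyConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0
    log_level: str = "INFO"
    in_path: Optional[Path] = None  # optional pre-existing input instead of simulation

    def __post_init__(self) -> None:
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        if self.in_path is not None:
            object.__setattr__(self, "in_path", Path(self.in_path))
            if not Path(self.in_path).exists():
                raise InvalidConfigError(f"input path does not exist: {self.in_path}")


def load_pipeline_config(path: Path | str) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    study_raw = dict(raw.get("study", {}))
    if "days" in study_raw:
        study_raw["days"] = tuple(int(d) for d in study_raw["days"])
    analysis_raw = dict(raw.get("analysis", {}))
    for key in ("roi", "vrp_window", "vep_window"):
        if analysis_raw.get(key) is not None:
            analysis_raw[key] = tuple(int(v) for v in analysis_raw[key])
    seed = int(raw.get("seed", 0))
    study_raw.setdefault("seed", seed)
    return PipelineConfig(
        out_dir=Path(raw.get("out_dir", "opwf-out")),
        study=StudyConfig(**study_raw),
        analysis=AnalysisConfig(**analysis_raw),
        seed=seed,
        log_level=str(raw.get("log_level", "INFO")),
        in_path=raw.get("in_path"),
    )
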