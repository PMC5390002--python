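"""Readers, writers and configuration for the pipeline artifacts.

Tables travel as CSV/TSV with documented column names, images as PNG, maps
as compressed ``.npz`` array containers, configs and manifests as
YAML/JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .feature_maps import FeatureMapConfig, FeatureMapSet, SceneImage

__all__ = [
    "PipelineConfig",
    "FixationTableError",
    "read_fixation_table",
    "write_table",
    "read_scene_image",
    "write_scene_image",
    "save_feature_maps",
    "load_feature_maps",
]

#: required columns of a fixation report and their coercions
FIXATION_SCHEMA = {
    "subject_id": str,
    "scene_id": str,
    "task": str,
    "trial_index": int,
    "fixation_index": int,
    "x": float,
    "y": float,
    "duration_ms": float,
    "onset_ms": float,
    "blink": bool,
}
OPTIONAL_COLUMNS = {"response_time_ms": float}


class FixationTableError(ValueError):
    """Schema or row-level problem in a fixation report."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, serializable to YAML losslessly."""

    scenes_dir: str = "scenes"
    fixations_path: str = "fixations.csv"
    output_dir: str = "out"
    px_per_deg: float = 31.03
    patch_radius_deg: float = 1.0
    min_duration_ms: float = 50.0
    max_duration_ms: float = 1000.0
    min_saccade_deg: float = 2.0
    n_bins: int = 10
    seed: int = 0
    image_size: tuple[int, int] = (600, 800)
    tasks: tuple[str, ...] = ("memorization",)
    feature_maps: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("px_per_deg", "patch_radius_deg", "min_duration_ms",
                     "max_duration_ms", "min_saccade_deg"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        self.image_size = tuple(self.image_size)
        self.tasks = tuple(self.tasks)

    def feature_map_config(self) -> FeatureMapConfig:
        return FeatureMapConfig(**self.feature_maps)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["image_size"] = list(self.image_size)
        data["tasks"] = list(self.tasks)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=list
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def read_fixation_table(path) -> pd.DataFrame:
    """Read and validate a fixation report (CSV, or TSV by extension).

    Missing required columns raise :class:`FixationTableError` naming the
    column; rows with non-coercible numeric fields are collected and
    reported in the error.  The returned frame is typed per the schema.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in FIXATION_SCHEMA if c not in df.columns]
    if missing:
        raise FixationTableError(f"missing required column(s): {missing}")
    bad_rows: list[int] = []
    for col, typ in FIXATION_SCHEMA.items():
        if typ in (int, float):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            bad_rows.extend(df.index[bad].tolist())
            df[col] = coerced
        elif typ is bool:
            df[col] = df[col].astype(bool)
        else:
            df[col] = df[col].astype(str)
    for col, typ in OPTIONAL_COLUMNS.items():
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        else:
            df[col] = np.nan
    if bad_rows:
        raise FixationTableError(
            f"non-numeric values in rows {sorted(set(bad_rows))[:20]}"
        )
    na = df[list(FIXATION_SCHEMA)].isna().any(axis=1)
    if na.any():
        raise FixationTableError(
            f"missing values in required columns at rows {df.index[na].tolist()[:20]}"
        )
    df["trial_index"] = df["trial_index"].astype(int)
    df["fixation_index"] = df["fixation_index"].astype(int)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)


def read_scene_image(path, px_per_deg: float, scene_id: str | None = None) -> SceneImage:
    img = np.asarray(Image.open(path).convert("RGB"))
    return SceneImage(
        pixels=img, px_per_deg=px_per_deg, scene_id=scene_id or Path(path).stem
    )


def write_scene_image(scene: SceneImage, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(scene.pixels).save(path)


def save_feature_maps(maps: FeatureMapSet, path) -> None:
    """One compressed array container per scene."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        luminance=maps.luminance,
        edges=maps.edges,
        clutter=maps.clutter,
        segments=maps.segments,
        n_segments_total=np.array(maps.n_segments_total),
        constant_luminance=np.array(maps.constant_luminance),
    )


def load_feature_maps(path) -> FeatureMapSet:
    with np.load(path) as z:
        return FeatureMapSet(
            luminance=z["luminance"],
            edges=z["edges"],
            clutter=z["clutter"],
            segments=z["segments"],
            n_segments_total=int(z["n_segments_total"]),
            constant_luminance=bool(z["constant_luminance"]),
        )
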