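"""End-to-end orchestration: simulate → segment → measure → stats.

A :class:`RunConfig` names the conditions (each a scene preset), the
regions, and the number of fields per (region × condition).  Every
stage's random stream is derived from the single top-level seed by
stable hashing of (seed, region, condition, field), so stages can be
re-run independently yet reproducibly.  Each run directory is
self-describing: it receives a frozen JSON snapshot of the resolved
configuration and seed next to the output tables.

I/O helpers keep the formats plain: multi-page TIFF for stacks, 16-bit
TIFF for label images, UTF-8 CSV (period decimal separator, header row
mandatory) for tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .segmentation import SegmentationParams, segment_stack
from .simulate import PRESETS, ScenePreset, SyntheticScene, derive_seed, render_scene
from .morphometry import PARAMETERS, measure_scene
from .group_stats import anova_table, normalize_to_control


class SchemaError(ValueError):
    """A table file is missing required columns."""


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF as a (z, y, x) array."""
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the file name
        raise ValueError(f"cannot read TIFF {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_stack(path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(stack))


def write_labels(path, labels: np.ndarray) -> None:
    """Write a label image as 16-bit TIFF (errors if > 65535 labels)."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit image")
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_table(path, required: Sequence[str] = ()) -> pd.DataFrame:
    """Read a CSV table; verify required columns are present."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot read CSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run.

    ``conditions`` maps a condition label to a preset name (key of
    :data:`gliamorph.simulate.PRESETS`); ``control`` names the
    condition whose per-stratum mean defines 100 %.
    """

    conditions: dict = field(
        default_factory=lambda: {"HC": "resting", "SD": "resting", "LPS": "activated"}
    )
    regions: tuple[str, ...] = ("PFC", "HIPP", "PVN")
    n_fields: int = 6
    control: str = "HC"
    seed: int = 0
    preset_overrides: dict = field(default_factory=dict)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    write_images: bool = False

    def validate(self) -> None:
        if self.control not in self.conditions:
            raise ValueError(f"control {self.control!r} is not a condition")
        for cond, preset in self.conditions.items():
            if preset not in PRESETS:
                raise ValueError(f"unknown preset {preset!r} for condition {cond!r}")
        if self.n_fields < 1:
            raise ValueError("n_fields must be ≥ 1")


@dataclass
class RunResult:
    """Bundle of a pipeline run's tables."""

    records: pd.DataFrame       # per-cell wide table
    long: pd.DataFrame          # per-field means, long format
    normalized: pd.DataFrame    # long format, percent of control
    anova: pd.DataFrame         # per-(region, parameter) ANOVA + post hoc
    qc_log: pd.DataFrame


def field_preset(config: RunConfig, region: str, condition: str, idx: int) -> ScenePreset:
    """Preset for one field with its stage-derived seed."""
    name = config.conditions[condition]
    seed = derive_seed(config.seed, "scene", region, condition, idx)
    return PRESETS[name](seed=seed, **config.preset_overrides.get(condition, {}))


def measure_field(
    config: RunConfig, region: str, condition: str, idx: int
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticScene]:
    """Simulate, segment and measure one field.

    Returns (per-cell records, qc log, scene).
    """
    preset = field_preset(config, region, condition, idx)
    scene = render_scene(preset)
    accepted, log, _mip = segment_stack(scene.stack, config.segmentation)
    records = measure_scene(
        accepted,
        preset.pixel_size_um,
        region=region,
        condition=condition,
        animal=f"{condition}-{idx}",
    )
    records.insert(0, "field", idx)
    qc = pd.DataFrame(log, columns=["label", "qc_status"])
    qc.insert(0, "field", idx)
    qc.insert(0, "condition", condition)
    qc.insert(0, "region", region)
    return records, qc, scene


def records_to_field_means(records: pd.DataFrame) -> pd.DataFrame:
    """Per-field mean of each parameter, long format.

    The field (one imaged stack) is the statistical unit, matching the
    per-animal averaging of per-cell measures before group inference.
    Degenerate-eccentricity cells are excluded.
    """
    cols = ["region", "condition", "field"]
    usable = records.loc[~records["eccentricity_degenerate"].astype(bool)]
    rows = []
    for key, sub in usable.groupby(cols, sort=True):
        for param in PARAMETERS:
            rows.append(
                dict(zip(cols, key), parameter=param,
                     value=float(sub[param].mean()))
            )
    return pd.DataFrame(rows, columns=cols + ["parameter", "value"])


def run_pipeline(config: RunConfig, out_dir=None) -> RunResult:
    """Run the full demo pipeline and (optionally) write its outputs.

    Deterministic given ``config.seed``: running twice writes
    byte-identical CSVs.  When ``out_dir`` is given it receives
    ``records.csv``, ``field_means.csv``, ``normalized.csv``,
    ``anova.csv``, ``qc_log.csv`` and ``run_config.json`` (the frozen
    config snapshot with seed and package version).
    """
    config.validate()
    all_records = []
    all_qc = []
    for region in config.regions:
        for condition in config.conditions:
            for idx in range(config.n_fields):
                rec, qc, scene = measure_field(config, region, condition, idx)
                all_records.append(rec)
                all_qc.append(qc)
                if out_dir is not None and config.write_images:
                    img_dir = Path(out_dir) / "images"
                    img_dir.mkdir(parents=True, exist_ok=True)
                    tag = f"{region}_{condition}_{idx}"
                    write_stack(img_dir / f"{tag}_stack.tif", scene.stack)
                    write_labels(img_dir / f"{tag}_truth_labels.tif", scene.truth_labels)
    records = pd.concat(all_records, ignore_index=True)
    qc_log = pd.concat(all_qc, ignore_index=True)
    long = records_to_field_means(records)
    normalized = normalize_to_control(long, config.control)
    anova = (
        anova_table(normalized) if len(normalized) else pd.DataFrame()
    )
    result = RunResult(records, long, normalized, anova, qc_log)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(out / "records.csv", records)
        write_table(out / "field_means.csv", long)
        write_table(out / "normalized.csv", normalized)
        write_table(out / "anova.csv", anova)
        write_table(out / "qc_log.csv", qc_log)
        snapshot = dataclasses.asdict(config)
        snapshot["segmentation"] = dataclasses.asdict(config.segmentation)
        snapshot["gliamorph_version"] = __version__
        (out / "run_config.json").write_text(json.dumps(snapshot, indent=2, default=str))
    return result
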