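"""Image-stack, label-mask, feature-table and configuration I/O.

Conventions used throughout the package:

* pixel grid is row-major with 0-based indices; ``(row 0, col 0)`` is the
  top-left corner of the image;
* frame stacks are ``(T, H, W)`` arrays of non-negative integers bounded by
  the bit depth;
* label masks are ``(T, H, W)`` integer arrays with background 0 and labels
  contiguous ``1..n`` within each frame.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("mitoflow")

#: float format used for CSV tables: 12 significant digits round-trips every
#: feature value we compute while keeping tables diffable.
CSV_FLOAT_FORMAT = "%.12g"


def configure_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> None:
    """Attach a console (and optionally file) handler to the package logger."""
    logger.setLevel(level)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(fh)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class FrameStack:
    """An ordered grayscale image sequence with physical metadata.

    Parameters
    ----------
    frames
        ``(T, H, W)`` array of non-negative intensities.
    bit_depth
        8 or 16; intensities must not exceed ``2**bit_depth - 1``.
    pixel_size_um
        Physical pixel size in micrometres per pixel.
    frame_interval_s
        Time between consecutive frames in seconds (0 for still images).
    channel_name
        Free-text channel identifier (e.g. ``"red"``).
    """

    frames: np.ndarray
    bit_depth: int = 8
    pixel_size_um: float = 1.0
    frame_interval_s: float = 1.0
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError(f"frames must be (T, H, W) with T >= 1, got {self.frames.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.frames.min() < 0:
            raise ValueError("negative intensities")
        if self.frames.max() > self.max_value:
            raise ValueError(
                f"intensity {self.frames.max()} exceeds bit depth limit {self.max_value}"
            )
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_s < 0:
            raise ValueError("frame_interval_s must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape  # type: ignore[return-value]

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)

    def frame(self, t: int) -> np.ndarray:
        return self.frames[t]


@dataclass
class LabelMask:
    """Per-frame integer object labels; 0 is background.

    Labels are relabelled to contiguous ``1..n`` per frame on construction
    (ascending original label order), so ``n_objects_per_frame[t]`` equals
    ``labels[t].max()``.
    """

    labels: np.ndarray
    n_objects_per_frame: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim == 2:
            lab = lab[None]
        if lab.ndim != 3:
            raise ValueError(f"labels must be (T, H, W), got {lab.shape}")
        if lab.min() < 0:
            raise ValueError("negative labels")
        out = np.empty_like(lab, dtype=np.int32)
        counts = []
        for t in range(lab.shape[0]):
            ids = np.unique(lab[t])
            ids = ids[ids > 0]
            lut = np.zeros(int(lab[t].max()) + 1, dtype=np.int32)
            lut[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
            out[t] = lut[lab[t]]
            counts.append(int(ids.size))
        self.labels = out
        self.n_objects_per_frame = counts

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    def frame(self, t: int) -> np.ndarray:
        return self.labels[t]

    def foreground(self, t: int | None = None) -> np.ndarray:
        if t is None:
            return self.labels > 0
        return self.labels[t] > 0


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

#: Documented defaults for every pipeline stage.  Unknown keys are rejected
#: when a config file is loaded, so typos fail fast.
CONFIG_DEFAULTS: dict[str, dict[str, Any]] = {
    "run": {
        "seed": 0,
        "stages": ["segment", "features", "motion", "classify"],
    },
    "segment": {
        "mode": "global_otsu",        # or "adaptive_otsu"
        "adaptive_block": 65,          # odd tile size for adaptive mode
        "tophat_radius": 0,            # 0 disables the white top-hat
        "min_object_area": 5,          # px
        "declump": True,
        "h_maxima": None,              # None -> 5% of frame dynamic range
    },
    "features": {
        "schema": "mito22",
        "texture_window": 33,
        "box_sizes": [2, 3, 4, 6, 8, 12, 16],
        "grid_stride": 16,
    },
    "motion": {
        "enabled": True,
        "roi_mode": "adaptive_otsu",
        "reference_point": None,       # (row, col) for directional analysis
        "lk_window": 15,
    },
    "classify": {
        "enabled": False,
        "algorithm": "knn",
        "k": 5,
        "feature_subset": None,        # None -> all schema slots
        "standardize": True,
        "cv_folds": 5,
        "library": None,               # path to a training library CSV
    },
}


@dataclass
class RunConfig:
    """Validated stage-name -> parameter mapping with documented defaults."""

    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged: dict[str, dict[str, Any]] = {}
        for stage, defaults in CONFIG_DEFAULTS.items():
            given = self.stages.get(stage, {})
            unknown = set(given) - set(defaults)
            if unknown:
                raise ValueError(f"unknown keys in stage '{stage}': {sorted(unknown)}")
            merged[stage] = {**defaults, **given}
        unknown_stages = set(self.stages) - set(CONFIG_DEFAULTS)
        if unknown_stages:
            raise ValueError(f"unknown config stages: {sorted(unknown_stages)}")
        self.stages = merged

    def __getitem__(self, stage: str) -> dict[str, Any]:
        return self.stages[stage]

    @property
    def seed(self) -> int:
        return int(self.stages["run"]["seed"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ValueError("config file must contain a mapping of stages")
        return cls(stages={k: dict(v or {}) for k, v in data.items()})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.stages, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Stack / mask I/O
# ---------------------------------------------------------------------------

def read_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
    channel_name: str = "",
    allow_conversion: bool = False,
) -> FrameStack:
    """Read a single- or multi-page grayscale TIFF into a :class:`FrameStack`.

    Bit depth is inferred from the sample format (uint8 -> 8, uint16 -> 16).
    RGB or floating-point input is rejected unless ``allow_conversion`` is
    set, in which case RGB is converted by luminance averaging and floats are
    rescaled to 8-bit.  Missing physical metadata falls back to unit pixel
    size and unit frame interval with a logged warning.
    """
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"{path}: zero frames")
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
        if not allow_conversion:
            raise ValueError(f"{path}: RGB input; pass allow_conversion=True to average channels")
        arr = arr[..., :3].mean(axis=-1).round().astype(np.uint8)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected (T, H, W) grayscale data, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating):
        if not allow_conversion:
            raise ValueError(f"{path}: float input; pass allow_conversion=True to rescale")
        lo, hi = float(arr.min()), float(arr.max())
        arr = np.zeros(arr.shape, np.uint8) if hi == lo else (
            np.round((arr - lo) / (hi - lo) * 255).astype(np.uint8)
        )
    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}; expected uint8 or uint16")
    if pixel_size_um is None:
        logger.warning("%s: no pixel size given; defaulting to 1.0 um/px", path)
        pixel_size_um = 1.0
    if frame_interval_s is None:
        logger.warning("%s: no frame interval given; defaulting to 1.0 s", path)
        frame_interval_s = 1.0
    return FrameStack(
        frames=arr,
        bit_depth=bit_depth,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        channel_name=channel_name,
    )


def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a :class:`FrameStack` to a multi-page TIFF, preserving dtype."""
    tifffile.imwrite(str(path), stack.frames.astype(stack.dtype))


def write_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a :class:`LabelMask` as a 16-bit multi-page label TIFF."""
    if mask.labels.max() > 65535:
        raise ValueError("more than 65535 objects per frame cannot be stored as 16-bit labels")
    tifffile.imwrite(str(path), mask.labels.astype(np.uint16))


def import_masks(path: str | Path, stack: FrameStack) -> LabelMask:
    """Import a label-image TIFF produced by external segmentation software.

    Labels are relabelled to contiguous ``1..n`` per frame (ascending
    original order); background stays 0.  The mask must match the stack's
    ``(T, H, W)`` shape.
    """
    arr = np.asarray(tifffile.imread(str(path)))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape != stack.shape:
        raise ValueError(f"mask shape {arr.shape} does not match stack shape {stack.shape}")
    if np.issubdtype(arr.dtype, np.signedinteger) and arr.min() < 0:
        raise ValueError("negative labels in imported mask")
    return LabelMask(labels=arr.astype(np.int64))


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def features_to_frame(features: Sequence["object"]) -> pd.DataFrame:
    """Convert FeatureVectors into a tidy DataFrame (identity cols first)."""
    from .features import FeatureVector  # local import: avoid cycle

    rows = []
    schema = None
    for fv in features:
        if not isinstance(fv, FeatureVector):
            raise TypeError(f"expected FeatureVector, got {type(fv)!r}")
        if schema is None:
            schema = (fv.schema_id, tuple(fv.values))
        elif schema != (fv.schema_id, tuple(fv.values)):
            raise ValueError("mixed feature schemas in one table")
        row = {"frame": fv.frame, "label": fv.label, "class": fv.class_label}
        row.update(fv.values)
        rows.append(row)
    if not rows:
        from .features import SLOT_NAMES

        return pd.DataFrame(columns=["frame", "label", "class", *SLOT_NAMES])
    return pd.DataFrame(rows)


def write_feature_table(features: Sequence["object"], path: str | Path) -> None:
    """Write FeatureVectors to CSV: one row per object/video.

    Floats are printed with 12 significant digits so re-reading reproduces
    every value; identical inputs produce byte-identical files.
    """
    features_to_frame(features).to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def run_pipeline(
    config: RunConfig,
    stack_path: str | Path,
    out_dir: str | Path,
    mask_path: str | Path | None = None,
) -> dict[str, Path]:
    """Run the enabled stages (segment -> features -> motion -> classify).

    Writes label TIFFs, per-object feature CSVs, motion time-series CSVs,
    class-fraction CSVs, a resolved copy of the configuration, and a log of
    all parameters and seeds.  Returns a mapping of output names to paths.
    Any stage failure raises with a stage-tagged message.
    """
    from . import classify as _classify
    from . import features as _features
    from . import motion as _motion
    from . import segment as _segment

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    configure_logging(logfile=out / "run.log")
    config.to_yaml(out / "config.resolved.yaml")
    logger.info("run_pipeline seed=%d stages=%s", config.seed, config["run"]["stages"])
    outputs: dict[str, Path] = {"config": out / "config.resolved.yaml", "log": out / "run.log"}
    stages = config["run"]["stages"]
    stack = read_stack(stack_path)

    try:
        if mask_path is not None:
            mask = import_masks(mask_path, stack)
        else:
            params = _segment.SegmentationParams(
                mode=config["segment"]["mode"],
                adaptive_block=config["segment"]["adaptive_block"],
                tophat_radius=config["segment"]["tophat_radius"],
                min_object_area=config["segment"]["min_object_area"],
                declump=config["segment"]["declump"],
                h_maxima=config["segment"]["h_maxima"],
            )
            mask = _segment.segment_stack(stack, params)
        if "segment" in stages:
            write_mask(mask, out / "labels.tif")
            outputs["labels"] = out / "labels.tif"
    except Exception as exc:  # pragma: no cover - error path
        raise RuntimeError(f"[segment] {exc}") from exc

    feats = None
    if "features" in stages:
        try:
            feats = []
            for t in range(stack.n_frames):
                feats.extend(
                    _features.frame_object_features(stack.frame(t), mask.frame(t), frame_index=t)
                )
            write_feature_table(feats, out / "features.csv")
            outputs["features"] = out / "features.csv"
        except Exception as exc:
            raise RuntimeError(f"[features] {exc}") from exc

    if "motion" in stages and config["motion"]["enabled"] and stack.n_frames > 1:
        try:
            rows = []
            ref = config["motion"]["reference_point"]
            for t in range(stack.n_frames - 1):
                field_ = _motion.frame_pair_field(
                    stack, t, roi_mode=config["motion"]["roi_mode"],
                    adaptive_block=config["segment"]["adaptive_block"],
                )
                vec = _motion.aggregate_vector(field_)
                row = {"t": t, "M": vec.magnitude, "theta_deg": vec.theta_deg}
                if ref is not None:
                    row["directional"] = _motion.directional_component(field_, tuple(ref))
                rows.append(row)
            pd.DataFrame(rows).to_csv(out / "motion.csv", index=False,
                                      float_format=CSV_FLOAT_FORMAT)
            outputs["motion"] = out / "motion.csv"
        except Exception as exc:
            raise RuntimeError(f"[motion] {exc}") from exc

    if "classify" in stages and config["classify"]["enabled"]:
        try:
            lib_path = config["classify"]["library"]
            if lib_path is None:
                raise ValueError("classification enabled but no training library given")
            library = _classify.TrainingLibrary.from_csv(lib_path)
            spec = _classify.ClassifierSpec(
                algorithm=config["classify"]["algorithm"],
                k=config["classify"]["k"],
                feature_subset=config["classify"]["feature_subset"] or library.feature_names,
                standardize=config["classify"]["standardize"],
                seed=config.seed,
            )
            model = _classify.train(library, spec)
            table = features_to_frame(feats if feats is not None else [])
            labels_pred, _ = _classify.predict_morphology(
                model, table[spec.feature_subset].to_numpy(float)
            )
            table = table.assign(predicted_class=labels_pred)
            table.to_csv(out / "classified.csv", index=False, float_format=CSV_FLOAT_FORMAT)
            fr_rows = []
            for t, sub in table.groupby("frame"):
                fracs = _classify.class_area_fractions(
                    sub["area"].to_numpy(float), list(sub["predicted_class"])
                )
                fr_rows.append({"frame": t, **fracs})
            pd.DataFrame(fr_rows).to_csv(out / "class_fractions.csv", index=False,
                                         float_format=CSV_FLOAT_FORMAT)
            outputs["classified"] = out / "classified.csv"
            outputs["class_fractions"] = out / "class_fractions.csv"
        except Exception as exc:
            raise RuntimeError(f"[classify] {exc}") from exc

    logger.info("run_pipeline complete: %s", sorted(outputs))
    return outputs
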