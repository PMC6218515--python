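"""The 22-slot feature schema: morphology, intensity, texture, motion summaries.

Slots 1-11 and 22 are morphology, 12-14 intensity, 15-18 motion and 19-21
texture.  Object-scale vectors fill the morphology and intensity slots;
motion and texture slots are filled at the cell or video scale, where frame
pairs and windows are available.

Texture follows two classic estimators:

* fractal dimension by differential box counting (DBC) of the grey-level
  intensity surface — flat surfaces have dimension 2, rough ones approach 3;
* lacunarity by the gliding-box algorithm on the binary segmentation —
  1 for perfectly uniform patterns, larger for gappy/clumped ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import regionprops

from .io import logger

SCHEMA_ID = "mito22"

#: Slot number -> feature name.  Morphology 1-11 & 22, intensity 12-14,
#: motion 15-18, texture 19-21.  The motion slots summarise frame pairs:
#: 15/16 are the mean/SD over pairs of the ROI-mean per-pixel vector
#: magnitude (motion activity), 17 the mean absolute radial component per
#: ROI pixel about the reference point, 18 the magnitude of the net
#: resultant summed over all pairs (directional persistence).
SLOT_FEATURES: dict[int, str] = {
    1: "area",
    2: "perimeter",
    3: "major_axis",
    4: "minor_axis",
    5: "eccentricity",
    6: "solidity",
    7: "extent",
    8: "form_factor",
    9: "max_radius",
    10: "median_radius",
    11: "aspect_ratio",
    12: "integrated_intensity",
    13: "mean_intensity",
    14: "sd_intensity",
    15: "mean_frame_magnitude",
    16: "sd_frame_magnitude",
    17: "mean_abs_directional",
    18: "net_magnitude",
    19: "fractal_dim_mean",
    20: "fractal_dim_sd",
    21: "lacunarity",
    22: "convex_area",
}
SLOT_NAMES: tuple[str, ...] = tuple(SLOT_FEATURES[i] for i in sorted(SLOT_FEATURES))
NAME_TO_SLOT: dict[str, int] = {v: k for k, v in SLOT_FEATURES.items()}

#: The eight-feature morphology subset used for classifier validation.
EIGHT_FEATURES: tuple[str, ...] = (
    "area",
    "major_axis",
    "minor_axis",
    "solidity",
    "perimeter",
    "max_radius",
    "median_radius",
    "integrated_intensity",
)


@dataclass
class FeatureVector:
    """Named feature values for one object, cell, or video."""

    values: dict[str, float]
    schema_id: str = SCHEMA_ID
    frame: int = 0
    label: int = 0
    class_label: str | None = None

    def subset(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.values[n] for n in names], float)


@dataclass
class TextureParams:
    """Window and scale parameters of the texture estimators."""

    window: int = 33
    box_sizes: tuple[int, ...] = (2, 3, 4, 6, 8, 12, 16)
    grid_stride: int = 16

    def __post_init__(self) -> None:
        if self.window < 9 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 9")
        sizes = tuple(int(s) for s in self.box_sizes)
        if sorted(sizes) != list(sizes) or len(set(sizes)) != len(sizes):
            raise ValueError("box_sizes must be strictly increasing")
        if max(sizes) > self.window:
            raise ValueError("largest box size exceeds the window")
        self.box_sizes = sizes


# ---------------------------------------------------------------------------
# Object-scale morphology + intensity (slots 1-14, 22)
# ---------------------------------------------------------------------------

def region_features(
    object_mask: np.ndarray,
    intensity: np.ndarray,
    frame: int = 0,
    label: int = 0,
    class_label: str | None = None,
) -> FeatureVector:
    """Morphology and intensity features of one object.

    The radius features come from the Euclidean distance transform inside
    the object: ``max_radius`` is the largest inscribed-disc radius and
    ``median_radius`` the median over object pixels.  Axis lengths are those
    of the ellipse with matching second central moments; ``form_factor`` is
    the isoperimetric ratio 4*pi*A/P^2 (1 for a circle).

    Degenerate digitisations are regularised: a perimeter of 0 (single
    pixels / 1-px lines) yields form_factor 1; the minor axis is floored at
    one inter-pixel distance for the aspect ratio; eccentricity is capped
    just below 1.
    """
    object_mask = np.asarray(object_mask).astype(bool)
    if not object_mask.any():
        raise ValueError("empty object")
    if object_mask.shape != np.asarray(intensity).shape:
        raise ValueError("mask and intensity shapes differ")
    props = regionprops(object_mask.astype(np.uint8), intensity_image=np.asarray(intensity, float))[0]
    area = float(props.area)
    perimeter = float(props.perimeter)
    form_factor = 1.0 if perimeter == 0 else min(4 * math.pi * area / perimeter**2, 1.0)
    minor = float(props.axis_minor_length)
    major = float(props.axis_major_length)
    aspect = major / max(minor, 1.0)
    ecc = min(float(props.eccentricity), 1.0 - 1e-12)
    # distance transform on a padded crop so the object boundary is seen
    r0, c0, r1, c1 = props.bbox
    crop = np.pad(object_mask[r0:r1, c0:c1], 1)
    dist = ndi.distance_transform_edt(crop)
    inside = dist[crop]
    vals = np.asarray(intensity, float)[object_mask]
    values = {
        "area": area,
        "perimeter": perimeter,
        "major_axis": major,
        "minor_axis": minor,
        "eccentricity": ecc,
        "solidity": float(props.solidity),
        "extent": float(props.extent),
        "form_factor": form_factor,
        "max_radius": float(inside.max()),
        "median_radius": float(np.median(inside)),
        "aspect_ratio": aspect,
        "integrated_intensity": float(vals.sum()),
        "mean_intensity": float(vals.mean()),
        "sd_intensity": float(vals.std()),
        "convex_area": float(props.area_convex),
    }
    return FeatureVector(values=values, frame=frame, label=label, class_label=class_label)


def frame_object_features(
    frame_image: np.ndarray,
    label_image: np.ndarray,
    frame_index: int = 0,
    classes: Mapping[int, str] | None = None,
) -> list[FeatureVector]:
    """Object-scale features for every labelled object in one frame."""
    out = []
    for lab in range(1, int(np.max(label_image)) + 1):
        sel = label_image == lab
        if not sel.any():
            continue
        out.append(
            region_features(
                sel,
                frame_image,
                frame=frame_index,
                label=lab,
                class_label=None if classes is None else classes.get(lab),
            )
        )
    return out


def channel_ratio(
    object_mask: np.ndarray, red: np.ndarray, green: np.ndarray
) -> float:
    """Integrated red / integrated green over an object or cell mask.

    The red/green ratio of a maturation reporter reads out protein
    oxidation; the denominator must carry signal.
    """
    object_mask = np.asarray(object_mask).astype(bool)
    red = np.asarray(red, float)
    green = np.asarray(green, float)
    if red.shape != green.shape or red.shape != object_mask.shape:
        raise ValueError("mask and channel shapes differ")
    g = float(green[object_mask].sum())
    if g <= 0:
        raise ValueError("zero green signal in region")
    return float(red[object_mask].sum()) / g


# ---------------------------------------------------------------------------
# Texture: differential box counting fractal dimension (slot 19-20)
# ---------------------------------------------------------------------------

def _dbc_box_count(window: np.ndarray, r: int, grey_range: float) -> tuple[int, int]:
    """Box count N(r) and grid side M for one box size (vectorised)."""
    W = window.shape[0]
    M = W // r
    if M < 1:
        raise ValueError(f"box size {r} larger than window {W}")
    crop = window[: M * r, : M * r].reshape(M, r, M, r)
    mx = crop.max(axis=(1, 3)).astype(float)
    mn = crop.min(axis=(1, 3)).astype(float)
    h = r * grey_range / W
    n = np.ceil(mx / h) - np.ceil(mn / h) + 1
    return int(n.sum()), M


def fractal_dimension_dbc(
    window: np.ndarray,
    box_sizes: Iterable[int] = (2, 3, 4, 6, 8, 12, 16),
    bit_depth: int = 8,
) -> float:
    """Fractal dimension of a grey-level surface by differential box counting.

    For each box size ``r`` the window is partitioned into an ``M x M`` grid
    of ``r x r`` columns (``M = W // r``; the remainder strip is cropped).
    Within each column the number of grey-level boxes of height
    ``h = r * G / W`` spanned by the surface is
    ``ceil(max/h) - ceil(min/h) + 1`` (G = grey-level range of the bit
    depth).  The dimension is the least-squares slope of ``log N(r)``
    against ``log M(r)``; using the realised grid side as the abscissa makes
    a flat surface come out at exactly 2 even when ``r`` does not divide the
    window side.  The result is clamped to the admissible surface range
    [2, 3].
    """
    window = np.asarray(window, float)
    if window.ndim != 2 or window.shape[0] != window.shape[1]:
        raise ValueError("window must be square")
    sizes = sorted(int(s) for s in box_sizes)
    if len(sizes) < 3:
        raise ValueError("need at least 3 box sizes")
    if sizes[-1] > window.shape[0]:
        raise ValueError("largest box size exceeds window side")
    G = float(2**bit_depth - 1)
    xs, ys = [], []
    for r in sizes:
        N, M = _dbc_box_count(window, r, G)
        xs.append(math.log(M))
        ys.append(math.log(N))
    slope = np.polyfit(xs, ys, 1)[0]
    return float(min(max(slope, 2.0), 3.0))


# ---------------------------------------------------------------------------
# Texture: gliding-box lacunarity (slot 21)
# ---------------------------------------------------------------------------

def lacunarity_gliding_box(
    mask: np.ndarray, box_sizes: Iterable[int] = (2, 3, 4, 6, 8, 12, 16)
) -> float:
    """Gliding-box lacunarity of a binary pattern.

    For each box size ``r`` an ``r x r`` box glides over every position in
    the window; the box mass is its foreground count and
    ``Lambda(r) = var(mass) / mean(mass)^2 + 1`` (population variance).  The
    reported feature is the mean of Lambda over the box sizes that fit in
    the window.  A fully uniform pattern gives exactly 1.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        raise ValueError("empty window")
    H, W = mask.shape
    m = mask.astype(np.int64)
    # integral image for exact box sums at every gliding position
    ii = np.zeros((H + 1, W + 1), np.int64)
    ii[1:, 1:] = m.cumsum(0).cumsum(1)
    lams = []
    for r in sorted(int(s) for s in box_sizes):
        if r > min(H, W):
            continue
        sums = (
            ii[r:, r:] - ii[:-r, r:] - ii[r:, :-r] + ii[:-r, :-r]
        ).astype(float)
        mean = sums.mean()
        if mean == 0:
            continue
        lams.append(sums.var() / mean**2 + 1.0)
    if not lams:
        raise ValueError("no box size fits the window")
    return float(np.mean(lams))


# ---------------------------------------------------------------------------
# Cell-scale texture summary
# ---------------------------------------------------------------------------

def cell_texture_summary(
    frame: np.ndarray,
    cell_mask: np.ndarray,
    params: TextureParams | None = None,
    segmentation: np.ndarray | None = None,
    bit_depth: int = 8,
) -> tuple[float, float, float]:
    """(FD mean, FD sd, lacunarity) for one cell.

    Fractal dimension is evaluated on square windows centred on a
    ``grid_stride`` lattice of points inside the cell mask (windows must fit
    inside the frame); mean and population SD over windows are reported.
    Lacunarity is computed on the binary segmentation restricted to the
    cell's bounding box; when no segmentation is supplied the frame is
    Otsu-binarised inside the mask.
    """
    params = params or TextureParams()
    frame = np.asarray(frame, float)
    cell_mask = np.asarray(cell_mask).astype(bool)
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    H, W = frame.shape
    half = params.window // 2
    if min(H, W) < params.window:
        raise ValueError("mask/frame smaller than the texture window")
    rows = np.arange(half, H - half, params.grid_stride)
    cols = np.arange(half, W - half, params.grid_stride)
    fds = []
    for r in rows:
        for c in cols:
            if cell_mask[r, c]:
                win = frame[r - half : r + half + 1, c - half : c + half + 1]
                fds.append(fractal_dimension_dbc(win, params.box_sizes, bit_depth))
    if not fds:
        raise ValueError("no texture window centre falls inside the cell mask")
    if segmentation is None:
        from .segment import otsu_threshold

        inside = frame[cell_mask]
        thr = otsu_threshold(inside) if inside.max() > inside.min() else inside.max()
        segmentation = (frame > thr) & cell_mask
    rr, cc = np.nonzero(cell_mask)
    bbox = segmentation[rr.min() : rr.max() + 1, cc.min() : cc.max() + 1]
    lac = lacunarity_gliding_box(bbox, params.box_sizes) if bbox.any() else 1.0
    fds_arr = np.asarray(fds)
    return float(fds_arr.mean()), float(fds_arr.std()), float(lac)


# ---------------------------------------------------------------------------
# Video-scale summary (slot means over frames)
# ---------------------------------------------------------------------------

def video_feature_summary(per_frame: Sequence[FeatureVector]) -> FeatureVector:
    """Mean of each feature slot over the frames of a video.

    Motion slots, present only for frame pairs, average over the pairs that
    carry them.
    """
    if not per_frame:
        raise ValueError("no frames to summarise")
    keys: list[str] = []
    for fv in per_frame:
        for k in fv.values:
            if k not in keys:
                keys.append(k)
    values = {}
    for k in keys:
        vals = [fv.values[k] for fv in per_frame if k in fv.values]
        values[k] = float(np.mean(vals))
    return FeatureVector(values=values, schema_id=per_frame[0].schema_id)


def extract_video_features(
    stack,
    texture_params: TextureParams | None = None,
    reference_point: tuple[float, float] | None = None,
) -> FeatureVector:
    """Per-video mean feature vector across all 22 slots.

    Per frame: segment (global Otsu), average the object-scale morphology
    features over objects, pool intensity over the segmented foreground, and
    compute the cell-scale texture summary.  Per frame pair: whole-frame
    summed motion vector magnitude and the radial directional component
    about ``reference_point`` (frame centre by default).  Health
    classification consumes these per-video means.
    """
    from .motion import (
        aggregate_vector,
        difference_image,
        directional_component,
        gradient_field,
        motion_activity,
        motion_roi,
    )
    from .segment import SegmentationParams, segment_frame

    texture_params = texture_params or TextureParams()
    params = SegmentationParams(mode="global_otsu", declump=False, min_object_area=4)
    T = stack.n_frames
    if reference_point is None:
        reference_point = (stack.shape[1] / 2, stack.shape[2] / 2)
    per_frame_vectors: list[FeatureVector] = []
    fg_masks: list[np.ndarray] = []
    for t in range(T):
        frame = stack.frame(t)
        mask = segment_frame(frame, params)
        fg = mask.foreground(0)
        fg_masks.append(fg)
        objs = frame_object_features(frame, mask.frame(0), frame_index=t)
        morph = {}
        morph_names = [SLOT_FEATURES[i] for i in (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 22)]
        for name in morph_names:
            morph[name] = float(np.mean([o.values[name] for o in objs])) if objs else 0.0
        if fg.any():
            vals = frame[fg].astype(float)
            morph["integrated_intensity"] = float(vals.sum())
            morph["mean_intensity"] = float(vals.mean())
            morph["sd_intensity"] = float(vals.std())
        else:
            morph["integrated_intensity"] = morph["mean_intensity"] = morph["sd_intensity"] = 0.0
        cell_mask = np.ones(frame.shape, bool)
        fd_mean, fd_sd, lac = cell_texture_summary(
            frame, cell_mask, texture_params, segmentation=fg, bit_depth=stack.bit_depth
        )
        morph["fractal_dim_mean"] = fd_mean
        morph["fractal_dim_sd"] = fd_sd
        morph["lacunarity"] = lac
        per_frame_vectors.append(FeatureVector(values=morph, frame=t))
    acts, dirs = [], []
    net_u = net_v = 0.0
    for t in range(T - 1):
        diff = difference_image(stack.frame(t), stack.frame(t + 1), stack.bit_depth)
        roi = motion_roi(fg_masks[t], fg_masks[t + 1])
        fld = gradient_field(diff, roi)
        acts.append(motion_activity(fld))
        vec = aggregate_vector(fld)
        net_u += vec.u_sum
        net_v += vec.v_sum
        n_roi = max(int(roi.sum()), 1)
        dirs.append(directional_component(fld, reference_point) / n_roi)
    motion_values = {
        "mean_frame_magnitude": float(np.mean(acts)) if acts else 0.0,
        "sd_frame_magnitude": float(np.std(acts)) if acts else 0.0,
        "mean_abs_directional": float(np.mean(np.abs(dirs))) if dirs else 0.0,
        "net_magnitude": float(math.hypot(net_u, net_v)),
    }
    summary = video_feature_summary(per_frame_vectors)
    summary.values.update(motion_values)
    # fixed slot order for downstream tables
    summary.values = {name: summary.values[name] for name in SLOT_NAMES}
    return summary
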