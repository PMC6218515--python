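"""Intensity-flow motion estimation, aggregation, and the optical-flow baseline.

The estimator interprets frame-to-frame intensity change of a fluorescently
tagged structure as flow of the tagged molecules.  For a frame pair
``(I_t, I_{t+1})``:

1. difference image ``D = I_{t+1} - I_t`` (negative = intensity loss);
2. rescale ``D' = (D + G) / (2G)`` with ``G = 2**bit_depth - 1`` so values
   lie in [0, 1] and no change maps to 0.5 (for 8-bit data this is exactly
   ``(D + 255) / 510``);
3. region of interest ``ROI = S_t | S_{t+1}``, the union of the per-frame
   segmentations, which filters out background and other structures;
4. per-pixel motion vectors ``(u, v) = (dD'/dx, dD'/dy)`` by central
   differences (one-sided at borders), restricted to the ROI.

Unlike optical flow this makes no brightness-constancy assumption: it reads
the gradient of intensity *change*, so fading or redistributing signal still
produces meaningful vectors.

Axis convention: x = +columns (right), y = up (the row gradient is negated),
``theta = atan2(v, u)`` in (-180, 180], and ``theta = 0`` when the magnitude
is 0.  Magnitudes are sums of dimensionless rescaled-intensity gradients;
no physical calibration is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import FrameStack, LabelMask
from .segment import binary_segmentation


@dataclass
class DifferenceImage:
    """Signed frame difference and its [0, 1] rescaling."""

    d: np.ndarray
    d_rescaled: np.ndarray
    t_index: int = 0
    bit_depth: int = 8


@dataclass
class MotionField:
    """Per-pixel gradient vectors (u right, v up) masked to an ROI."""

    u: np.ndarray
    v: np.ndarray
    roi: np.ndarray


@dataclass
class SummedVector:
    """Resultant of vector addition over a region."""

    u_sum: float
    v_sum: float

    @property
    def magnitude(self) -> float:
        return math.hypot(self.u_sum, self.v_sum)

    @property
    def theta_deg(self) -> float:
        if self.magnitude == 0:
            return 0.0
        return math.degrees(math.atan2(self.v_sum, self.u_sum))


# ---------------------------------------------------------------------------
# The estimator
# ---------------------------------------------------------------------------

def difference_image(
    i_t: np.ndarray, i_t1: np.ndarray, bit_depth: int = 8, t_index: int = 0
) -> DifferenceImage:
    """``D = I_{t+1} - I_t`` and its rescale ``D' = (D + G) / (2G)``."""
    i_t = np.asarray(i_t)
    i_t1 = np.asarray(i_t1)
    if i_t.shape != i_t1.shape:
        raise ValueError("frame shapes differ")
    G = float(2**bit_depth - 1)
    d = i_t1.astype(float) - i_t.astype(float)
    return DifferenceImage(d=d, d_rescaled=(d + G) / (2 * G), t_index=t_index, bit_depth=bit_depth)


def motion_roi(s_t: np.ndarray, s_t1: np.ndarray) -> np.ndarray:
    """Elementwise union of the two frames' segmentations."""
    s_t = np.asarray(s_t).astype(bool)
    s_t1 = np.asarray(s_t1).astype(bool)
    if s_t.shape != s_t1.shape:
        raise ValueError("mask shapes differ")
    return s_t | s_t1


def gradient_field(diff: DifferenceImage, roi: np.ndarray) -> MotionField:
    """Central-difference gradient of D', zeroed outside the ROI.

    The row gradient is negated so v points up (mathematical y axis).
    """
    roi = np.asarray(roi).astype(bool)
    if roi.shape != diff.d_rescaled.shape:
        raise ValueError("roi shape differs from difference image")
    gy, gx = np.gradient(diff.d_rescaled)
    u = np.where(roi, gx, 0.0)
    v = np.where(roi, -gy, 0.0)
    return MotionField(u=u, v=v, roi=roi)


def aggregate_vector(field: MotionField, region: np.ndarray | None = None) -> SummedVector:
    """Vector addition over ``region & roi`` (whole ROI when region is None)."""
    if region is None:
        sel = field.roi
    else:
        region = np.asarray(region).astype(bool)
        if region.shape != field.u.shape:
            raise ValueError("region shape differs from field")
        sel = region & field.roi
    return SummedVector(u_sum=float(field.u[sel].sum()), v_sum=float(field.v[sel].sum()))


def motion_activity(field: MotionField, region: np.ndarray | None = None) -> float:
    """Mean per-pixel vector magnitude over ``region & roi``.

    Unlike the summed resultant (which cancels over structures moving in
    different directions), this measures the total amount of local motion
    and is the per-frame-pair magnitude used by the video feature schema.
    Returns 0 for an empty selection.
    """
    sel = field.roi if region is None else (field.roi & np.asarray(region).astype(bool))
    if not sel.any():
        return 0.0
    return float(np.hypot(field.u[sel], field.v[sel]).mean())


def frame_pair_field(
    stack: FrameStack,
    t: int,
    roi_mode: str = "adaptive_otsu",
    adaptive_block: int = 65,
) -> MotionField:
    """Difference -> rescale -> ROI union -> gradient for frames (t, t+1)."""
    s_t = binary_segmentation(stack.frame(t), mode=roi_mode, adaptive_block=adaptive_block)
    s_t1 = binary_segmentation(stack.frame(t + 1), mode=roi_mode, adaptive_block=adaptive_block)
    diff = difference_image(stack.frame(t), stack.frame(t + 1), stack.bit_depth, t_index=t)
    return gradient_field(diff, motion_roi(s_t, s_t1))


# ---------------------------------------------------------------------------
# Aggregation at object / class / cell scales
# ---------------------------------------------------------------------------

def per_class_motion(
    field: MotionField,
    labels: LabelMask | np.ndarray,
    class_assignment: Mapping[int, str],
) -> dict[str, dict]:
    """Per-object summed vectors grouped by morphology class.

    Returns, per class, the mean magnitude, the raw per-object magnitude
    list, and the class-area-normalised mean (magnitude per foreground
    pixel), since either normalisation may be wanted when comparing classes
    of very different total area.
    """
    lab = labels.frame(0) if isinstance(labels, LabelMask) else np.asarray(labels)
    per_class: dict[str, list[tuple[int, float, int]]] = {}
    for obj in range(1, int(lab.max()) + 1):
        sel = lab == obj
        if not sel.any():
            continue
        if obj not in class_assignment:
            raise KeyError(f"object {obj} has no class assignment")
        vec = aggregate_vector(field, sel)
        per_class.setdefault(class_assignment[obj], []).append(
            (obj, vec.magnitude, int(sel.sum()))
        )
    out = {}
    for cls, rows in per_class.items():
        mags = [m for _, m, _ in rows]
        areas = [a for _, _, a in rows]
        out[cls] = {
            "mean_magnitude": float(np.mean(mags)),
            "objects": [{"label": o, "magnitude": m, "area": a} for o, m, a in rows],
            "area_normalized_mean": float(np.sum(mags) / np.sum(areas)),
        }
    return out


def directional_component(
    field: MotionField,
    reference_point: tuple[float, float],
    region: np.ndarray | None = None,
) -> float:
    """Signed radial motion about a reference point for one frame pair.

    Each pixel vector is projected onto the unit vector pointing from the
    reference ``(row, col)`` to that pixel: positive = motion away from the
    reference, negative = towards it.  The value is the sum of projections
    over ``region & roi``; a pixel coinciding with the reference contributes
    0 (its radial direction is undefined).
    """
    rr, cc = np.mgrid[0 : field.u.shape[0], 0 : field.u.shape[1]].astype(float)
    dx = cc - reference_point[1]
    dy_up = -(rr - reference_point[0])  # y-up convention
    norm = np.hypot(dx, dy_up)
    with np.errstate(invalid="ignore", divide="ignore"):
        proj = (field.u * dx + field.v * dy_up) / norm
    proj = np.where(norm == 0, 0.0, proj)
    sel = field.roi if region is None else (field.roi & np.asarray(region).astype(bool))
    return float(proj[sel].sum())


def directional_series(
    fields: Sequence[MotionField],
    reference_point: tuple[float, float],
    regions: Sequence[np.ndarray] | None = None,
) -> tuple[list[float], float]:
    """Per-frame-pair signed radial sums and their net total over the video."""
    H, W = fields[0].u.shape
    if not (0 <= reference_point[0] < H and 0 <= reference_point[1] < W):
        raise ValueError("reference point outside the frame")
    series = [
        directional_component(f, reference_point, None if regions is None else regions[i])
        for i, f in enumerate(fields)
    ]
    return series, float(sum(series))


# ---------------------------------------------------------------------------
# Lucas-Kanade baseline
# ---------------------------------------------------------------------------

def lucas_kanade_baseline(
    i_t: np.ndarray,
    i_t1: np.ndarray,
    region: np.ndarray | None = None,
    window: int = 15,
    max_condition: float = 1e4,
    bit_depth: int = 8,
) -> SummedVector:
    """Classic local least-squares optical flow, summed over a region.

    Per pixel, the structure tensor of the windowed spatial gradients is
    solved against the temporal derivative; pixels whose tensor condition
    number exceeds ``max_condition`` (aperture problem / no texture)
    contribute zero.  Flow units are pixels/frame; the summed vector uses
    the same y-up convention as the intensity-flow estimator so angles are
    directly comparable.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    G = float(2**bit_depth - 1)
    a = np.asarray(i_t, float) / G
    b = np.asarray(i_t1, float) / G
    if a.shape != b.shape:
        raise ValueError("frame shapes differ")
    gy, gx = np.gradient((a + b) / 2)
    it = b - a
    w2 = window * window

    def box(x: np.ndarray) -> np.ndarray:
        return ndi.uniform_filter(x, window, mode="nearest") * w2

    sxx, syy, sxy = box(gx * gx), box(gy * gy), box(gx * gy)
    sxt, syt = box(gx * it), box(gy * it)
    tr = sxx + syy
    det = sxx * syy - sxy**2
    disc = np.sqrt(np.maximum(tr**2 / 4 - det, 0.0))
    lam1 = tr / 2 + disc
    lam2 = tr / 2 - disc
    ok = (lam2 > 0) & (lam1 <= max_condition * lam2)
    safe_det = np.where(det == 0, 1.0, det)
    fx = np.where(ok, -(syy * sxt - sxy * syt) / safe_det, 0.0)
    fy = np.where(ok, -(sxx * syt - sxy * sxt) / safe_det, 0.0)
    sel = np.ones(a.shape, bool) if region is None else np.asarray(region).astype(bool)
    return SummedVector(u_sum=float(fx[sel].sum()), v_sum=float(-fy[sel].sum()))


# ---------------------------------------------------------------------------
# Accuracy metrics and the six-scene validation suite
# ---------------------------------------------------------------------------

def wrapped_angle_error_deg(theta_est: float, theta_true: float) -> float:
    """Absolute angular error wrapped into [0, 180]."""
    return abs((theta_est - theta_true + 180.0) % 360.0 - 180.0)


def angle_accuracy(theta_est: float, theta_true: float) -> float:
    """``100 * (1 - |wrapped error| / 180)``: 100 at 0 deg error, 0 at 180."""
    return 100.0 * (1.0 - wrapped_angle_error_deg(theta_est, theta_true) / 180.0)


def magnitude_accuracy(m_est: float, m_ref: float) -> float:
    """``100 * max(0, 1 - |M_est - M_ref| / M_ref)``.

    ``M_ref`` is the same estimator applied to the noiseless, non-fading
    version of the scene (self-referenced normalisation: the summed-gradient
    magnitude has no ground truth in displacement units).
    """
    if m_ref == 0:
        raise ValueError("reference magnitude is zero")
    return 100.0 * max(0.0, 1.0 - abs(m_est - m_ref) / m_ref)


def motion_accuracy(estimate: SummedVector, truth) -> tuple[float | None, None]:
    """Angle accuracy of a summed vector against a scene's ground truth.

    Returns ``(angle_acc, None)``; the angle accuracy is None (missing) for
    a zero-displacement truth, where the true angle is undefined.  Magnitude
    accuracy needs a reference estimate and lives in
    :func:`magnitude_accuracy`.
    """
    if truth.truth_magnitude_px == 0:
        return None, None
    return angle_accuracy(estimate.theta_deg, truth.truth_angle_deg), None


def _scene_vector(scene, estimator: str, roi_mode: str, lk_window: int) -> SummedVector:
    a, b = scene.frame_a, scene.frame_b
    s_a = binary_segmentation(a, mode=roi_mode)
    s_b = binary_segmentation(b, mode=roi_mode)
    roi = motion_roi(s_a, s_b)
    if estimator == "intensity_flow":
        return aggregate_vector(gradient_field(difference_image(a, b, 8), roi))
    if estimator == "lucas_kanade":
        return lucas_kanade_baseline(a, b, region=roi, window=lk_window)
    raise ValueError(f"unknown estimator {estimator!r}")


def validate_motion_suite(
    displacement_px: float = 4.0,
    angle_deg: float = 30.0,
    size: tuple[int, int] = (128, 128),
    seed: int = 1,
    roi_mode: str = "adaptive_otsu",
    lk_window: int = 15,
) -> pd.DataFrame:
    """Run the six-scene validation and return per-case accuracy rows.

    Regenerates the six canonical two-frame scenes (solid/uneven dot,
    fading disc, solid/uneven/fading rectangle) at the given displacement,
    runs both the intensity-flow estimator and the Lucas-Kanade baseline,
    and scores angle accuracy against the known translation direction and
    magnitude accuracy against each estimator's own output on the
    non-fading version of the scene.
    """
    from .synth import MOTION_CASES, displacement_from_polar, make_motion_scene

    disp = displacement_from_polar(displacement_px, angle_deg)
    rows = []
    for case in MOTION_CASES:
        scene = make_motion_scene(case, disp, size=size, seed=seed)
        ref_scene = make_motion_scene(case, disp, size=size, seed=seed, fade_override=1.0)
        row: dict = {"case": case, "truth_angle_deg": scene.truth_angle_deg}
        for est, tag in (("intensity_flow", "if"), ("lucas_kanade", "lk")):
            vec = _scene_vector(scene, est, roi_mode, lk_window)
            ref = _scene_vector(ref_scene, est, roi_mode, lk_window)
            row[f"{tag}_theta_deg"] = vec.theta_deg
            row[f"{tag}_magnitude"] = vec.magnitude
            row[f"{tag}_angle_acc"] = angle_accuracy(vec.theta_deg, scene.truth_angle_deg)
            row[f"{tag}_mag_acc"] = magnitude_accuracy(vec.magnitude, ref.magnitude)
        rows.append(row)
    return pd.DataFrame(rows)
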