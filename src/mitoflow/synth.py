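"""Synthetic fixtures with known ground truth.

Four generator families:

* two-frame motion-validation scenes (dot / disc / rectangle; uniform or
  uneven intensity; constant brightness or fading to half) with a known
  translation;
* still morphology fields containing punctate, networked and swollen
  mitochondria with per-object class labels;
* morphogenesis videos whose class composition follows a user timeline;
* paired control/stressed video sets that differ in per-frame jitter
  magnitude, global intensity drift and object clustering.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi

from .io import FrameStack, LabelMask

MOTION_CASES = (
    "solid_dot",
    "uneven_dot",
    "fading_disc",
    "solid_rect",
    "uneven_rect",
    "fading_rect",
)

MORPHOLOGY_CLASSES = ("punctate", "networked", "swollen")

#: Peak object intensity used by all generators (8-bit scale).
PEAK_INTENSITY = 200.0
#: "Uneven" intra-object pattern: linear ramp from this fraction of peak to
#: full peak across the object's bounding box along +x.
RAMP_LOW = 0.4


# ---------------------------------------------------------------------------
# Motion-validation scenes
# ---------------------------------------------------------------------------

@dataclass
class MotionScene:
    """A two-frame scene with known translation ground truth.

    ``displacement`` is ``(dx, dy)`` with dx along +columns and dy along
    +rows (screen-down).  ``truth_angle_deg`` uses the motion module's
    convention (x right, y up): ``atan2(-dy, dx)``.
    """

    frame_a: np.ndarray
    frame_b: np.ndarray
    truth_displacement: tuple[float, float]
    truth_angle_deg: float
    case_id: str
    fade_factor: float = 1.0

    @property
    def truth_magnitude_px(self) -> float:
        dx, dy = self.truth_displacement
        return math.hypot(dx, dy)


def _draw_object(
    case_id: str,
    size: tuple[int, int],
    center: tuple[float, float],
    brightness: float,
) -> np.ndarray:
    """Analytic anti-aliased rendering at a (sub-pixel) centre.

    Edge pixels get fractional coverage so that sub-pixel displacements are
    realised exactly by re-drawing, not by resampling a quantised image.
    """
    H, W = size
    cy, cx = center
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    if "rect" in case_id:
        half_h, half_w = 12.0, 20.0
        cov = (
            np.clip(half_h - np.abs(rows - cy) + 0.5, 0.0, 1.0)
            * np.clip(half_w - np.abs(cols - cx) + 0.5, 0.0, 1.0)
        )
        extent_x = 2 * half_w
    else:
        radius = 8.0 if "dot" in case_id else 16.0
        cov = np.clip(radius - np.hypot(rows - cy, cols - cx) + 0.5, 0.0, 1.0)
        extent_x = 2 * radius
    img = PEAK_INTENSITY * cov
    if case_id.startswith(("uneven", "fading")):
        frac = np.clip((cols - (cx - extent_x / 2)) / extent_x, 0.0, 1.0)
        img *= RAMP_LOW + (1.0 - RAMP_LOW) * frac
    return img * brightness


def make_motion_scene(
    case_id: str,
    displacement: tuple[float, float],
    size: tuple[int, int] = (128, 128),
    seed: int = 0,
    fade_override: float | None = None,
    noise_sigma: float = 0.0,
) -> MotionScene:
    """Generate one two-frame validation scene.

    Parameters
    ----------
    case_id
        One of :data:`MOTION_CASES`.
    displacement
        ``(dx, dy)`` pixel translation of the object between frames
        (dx -> +columns, dy -> +rows).  May be fractional.
    size
        Frame shape ``(H, W)``.
    seed
        Controls additive noise only (scenes are noiseless by default).
    fade_override
        Force a fade factor (e.g. 1.0 to build the non-fading reference of
        a fading case).
    noise_sigma
        Gaussian read-noise standard deviation in grey levels.
    """
    if case_id not in MOTION_CASES:
        raise ValueError(f"unknown case_id {case_id!r}; expected one of {MOTION_CASES}")
    H, W = size
    dx, dy = float(displacement[0]), float(displacement[1])
    fade = 0.5 if case_id.startswith("fading") else 1.0
    if fade_override is not None:
        fade = float(fade_override)
    if not 0.0 < fade <= 1.0:
        raise ValueError("fade factor must be in (0, 1]")
    # centre the trajectory midpoint in the frame
    cy0, cx0 = H / 2 - dy / 2, W / 2 - dx / 2
    margin = 22.0  # max object half-extent + antialias skirt
    for cy, cx in ((cy0, cx0), (cy0 + dy, cx0 + dx)):
        if not (margin <= cy <= H - margin and margin <= cx <= W - margin):
            raise ValueError("object out of bounds for this displacement/size")
    a = _draw_object(case_id, size, (cy0, cx0), 1.0)
    b = _draw_object(case_id, size, (cy0 + dy, cx0 + dx), fade)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sigma, a.shape)
        b = b + rng.normal(0.0, noise_sigma, b.shape)
    quant = lambda img: np.clip(np.round(img), 0, 255).astype(np.uint8)
    return MotionScene(
        frame_a=quant(a),
        frame_b=quant(b),
        truth_displacement=(dx, dy),
        truth_angle_deg=math.degrees(math.atan2(-dy, dx)),
        case_id=case_id,
        fade_factor=fade,
    )


def displacement_from_polar(magnitude_px: float, angle_deg: float) -> tuple[float, float]:
    """Convert (magnitude, angle with y-up) to a ``(dx, dy_row)`` displacement."""
    rad = math.radians(angle_deg)
    return magnitude_px * math.cos(rad), -magnitude_px * math.sin(rad)


# ---------------------------------------------------------------------------
# Morphology fields
# ---------------------------------------------------------------------------

@dataclass
class SceneGroundTruth:
    """Ground truth for a generated still frame: labels, classes, areas."""

    label_image: np.ndarray
    classes: dict[int, str]
    class_areas: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        areas: dict[str, int] = {c: 0 for c in MORPHOLOGY_CLASSES}
        for lab, cls in self.classes.items():
            areas[cls] = areas.get(cls, 0) + int((self.label_image == lab).sum())
        self.class_areas = areas

    @property
    def n_objects(self) -> int:
        return len(self.classes)

    def mask(self) -> LabelMask:
        return LabelMask(labels=self.label_image[None])


def _punctate_footprint(rng: np.random.Generator) -> np.ndarray:
    """Small near-circular blob, area ~10-40 px."""
    r = rng.uniform(1.9, 3.4)
    n = int(2 * math.ceil(r) + 3)
    c = n // 2
    rows, cols = np.mgrid[0:n, 0:n]
    return (np.hypot(rows - c, cols - c) <= r).astype(bool)


def _swollen_footprint(rng: np.random.Generator) -> np.ndarray:
    """Large elliptical blob, area ~200-800 px."""
    ra = rng.uniform(8.0, 14.0)
    rb = rng.uniform(0.7, 1.0) * ra
    theta = rng.uniform(0, math.pi)
    n = int(2 * math.ceil(ra) + 3)
    c = n / 2
    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    yr = (rows - c) * math.cos(theta) + (cols - c) * math.sin(theta)
    xr = -(rows - c) * math.sin(theta) + (cols - c) * math.cos(theta)
    return (yr / ra) ** 2 + (xr / rb) ** 2 <= 1.0


def _networked_footprint(rng: np.random.Generator, ring: bool = False) -> np.ndarray:
    """Dilated branched random-walk skeleton (elongated, low solidity).

    With ``ring=True`` a small annulus ("donut") is produced instead; rings
    appear as transitional shapes in morphogenesis timelines and carry the
    networked class label.
    """
    if ring:
        r_out = rng.uniform(4.0, 6.0)
        r_in = r_out - rng.uniform(1.8, 2.5)
        n = int(2 * math.ceil(r_out) + 3)
        c = n // 2
        rows, cols = np.mgrid[0:n, 0:n]
        d = np.hypot(rows - c, cols - c)
        return (d <= r_out) & (d >= r_in)
    n = 48
    canvas = np.zeros((n, n), bool)
    n_steps = rng.integers(25, 55)
    pos = np.array([n / 2, n / 2], float)
    ang = rng.uniform(0, 2 * math.pi)
    pts = [pos.copy()]
    branch_pts = []
    for _ in range(int(n_steps)):
        ang += rng.normal(0.0, 0.45)  # momentum walk -> elongated path
        pos = pos + np.array([math.sin(ang), math.cos(ang)])
        pos = np.clip(pos, 1, n - 2)
        pts.append(pos.copy())
        if rng.random() < 0.06:
            branch_pts.append((pos.copy(), ang + rng.choice([-1, 1]) * math.pi / 2))
    for start, bang in branch_pts[:2]:
        bpos = start.copy()
        for _ in range(int(rng.integers(5, 14))):
            bang += rng.normal(0.0, 0.45)
            bpos = bpos + np.array([math.sin(bang), math.cos(bang)])
            bpos = np.clip(bpos, 1, n - 2)
            pts.append(bpos.copy())
    idx = np.rint(np.array(pts)).astype(int)
    canvas[idx[:, 0], idx[:, 1]] = True
    canvas = ndi.binary_dilation(canvas, structure=ndi.generate_binary_structure(2, 1), iterations=1)
    return canvas


def _object_intensity(
    footprint: np.ndarray, cls: str, rng: np.random.Generator
) -> np.ndarray:
    """Per-class intensity pattern on the footprint (float, 8-bit scale).

    Swollen objects carry strong smooth internal heterogeneity so that their
    per-object intensity standard deviation exceeds the other classes.
    """
    peak = rng.uniform(140.0, PEAK_INTENSITY)
    img = footprint.astype(float) * peak
    if cls == "swollen":
        h, w = footprint.shape
        rows, cols = np.mgrid[0:h, 0:w].astype(float)
        ph1, ph2 = rng.uniform(0, 2 * math.pi, 2)
        fy, fx = rng.uniform(0.15, 0.35, 2)
        mod = 0.75 + 0.30 * np.sin(2 * math.pi * fy * rows + ph1) * np.sin(
            2 * math.pi * fx * cols + ph2
        )
        img *= mod
    else:
        img *= rng.uniform(0.95, 1.05)
    return img


def _place_objects(
    specs: Sequence[str],
    size: tuple[int, int],
    rng: np.random.Generator,
    centers: Sequence[tuple[float, float]] | None = None,
    rings: Sequence[bool] | None = None,
    max_attempts: int = 1000,
) -> tuple[np.ndarray, np.ndarray, dict[int, str], list[tuple[float, float]]]:
    """Rejection-sample non-overlapping object placements.

    Returns (intensity image, label image, label->class, centres used).
    A 2-px dilation gap keeps neighbouring objects from touching so that
    connected-component ground truth stays unambiguous.
    """
    H, W = size
    image = np.zeros((H, W), float)
    labels = np.zeros((H, W), np.int32)
    occupied = np.zeros((H, W), bool)
    classes: dict[int, str] = {}
    placed_centers: list[tuple[float, float]] = []
    for i, cls in enumerate(specs):
        ring = bool(rings[i]) if rings is not None else False
        for attempt in range(max_attempts):
            sub_rng = rng  # footprint shape varies per attempt
            if cls == "punctate":
                fp = _punctate_footprint(sub_rng)
            elif cls == "swollen":
                fp = _swollen_footprint(sub_rng)
            elif cls == "networked":
                fp = _networked_footprint(sub_rng, ring=ring)
            else:
                raise ValueError(f"unknown class {cls!r}")
            fh, fw = fp.shape
            if centers is not None and attempt == 0:
                r0 = int(round(centers[i][0] - fh / 2))
                c0 = int(round(centers[i][1] - fw / 2))
                r0 = min(max(r0, 0), H - fh)
                c0 = min(max(c0, 0), W - fw)
            else:
                if H - fh <= 0 or W - fw <= 0:
                    raise ValueError("object larger than frame")
                r0 = int(rng.integers(0, H - fh + 1))
                c0 = int(rng.integers(0, W - fw + 1))
            region = occupied[r0 : r0 + fh, c0 : c0 + fw]
            if not (region & ndi.binary_dilation(fp, iterations=2)).any():
                img_obj = _object_intensity(fp, cls, rng)
                image[r0 : r0 + fh, c0 : c0 + fw] += img_obj
                labels[r0 : r0 + fh, c0 : c0 + fw][fp] = i + 1
                occupied[r0 : r0 + fh, c0 : c0 + fw] |= ndi.binary_dilation(fp, iterations=2)
                classes[i + 1] = cls
                placed_centers.append((r0 + fh / 2, c0 + fw / 2))
                break
        else:
            raise RuntimeError(
                f"could not place object {i} ({cls}) in {max_attempts} attempts"
            )
    return image, labels, classes, placed_centers


def _apply_noise(
    image: np.ndarray, rng: np.random.Generator, read_sigma: float, poisson: bool
) -> np.ndarray:
    out = image.copy()
    if poisson:
        out = rng.poisson(np.maximum(out, 0.0)).astype(float)
    if read_sigma > 0:
        out += rng.normal(0.0, read_sigma, out.shape)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def make_morphology_field(
    n_punctate: int,
    n_networked: int,
    n_swollen: int,
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
    read_sigma: float = 2.0,
    poisson: bool = True,
) -> tuple[FrameStack, SceneGroundTruth]:
    """Generate a still frame with labelled mitochondria of the three classes.

    Noise model: Poisson shot noise on the expected intensity plus Gaussian
    read noise (``read_sigma`` grey levels, default 2).
    """
    if min(n_punctate, n_networked, n_swollen) < 0:
        raise ValueError("object counts must be >= 0")
    rng = np.random.default_rng(seed)
    specs = (
        ["punctate"] * n_punctate + ["networked"] * n_networked + ["swollen"] * n_swollen
    )
    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]
    image, labels, classes, _ = _place_objects(specs, size, rng)
    frame = _apply_noise(image, rng, read_sigma, poisson)
    stack = FrameStack(frames=frame[None], bit_depth=8, frame_interval_s=0.0)
    return stack, SceneGroundTruth(label_image=labels, classes=classes)


# ---------------------------------------------------------------------------
# Morphogenesis videos
# ---------------------------------------------------------------------------

def make_morphogenesis_video(
    timeline: Sequence[Mapping[str, int]],
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
    jitter_px: float = 0.7,
    read_sigma: float = 2.0,
    ring_fraction: float = 0.0,
) -> tuple[FrameStack, list[SceneGroundTruth]]:
    """Generate a video whose class mix follows ``timeline`` frame by frame.

    Each timeline record maps class name -> object count.  Object positions
    persist across frames with Gaussian jitter; when the mix changes, slots
    keep their positions but switch class (fragmentation/swelling in place).
    ``ring_fraction`` of networked objects are drawn as small annuli
    ("donuts", transitional shapes) and still labelled networked.
    """
    if not timeline:
        raise ValueError("timeline must have at least one record")
    rng = np.random.default_rng(seed)
    n_slots = max(sum(int(rec.get(c, 0)) for c in MORPHOLOGY_CLASSES) for rec in timeline)
    H, W = size
    slot_centers = [
        (rng.uniform(0.1 * H, 0.9 * H), rng.uniform(0.1 * W, 0.9 * W)) for _ in range(n_slots)
    ]
    frames = []
    truths = []
    for rec in timeline:
        specs: list[str] = []
        for cls in MORPHOLOGY_CLASSES:
            cnt = int(rec.get(cls, 0))
            if cnt < 0:
                raise ValueError(f"negative count for class {cls!r}")
            specs.extend([cls] * cnt)
        rings = [
            cls == "networked" and rng.random() < ring_fraction for cls in specs
        ]
        centers = [
            (r + rng.normal(0, jitter_px), c + rng.normal(0, jitter_px))
            for (r, c) in slot_centers[: len(specs)]
        ]
        image, labels, classes, _ = _place_objects(specs, size, rng, centers=centers, rings=rings)
        frames.append(_apply_noise(image, rng, read_sigma, poisson=True))
        truths.append(SceneGroundTruth(label_image=labels, classes=classes))
    stack = FrameStack(frames=np.stack(frames), bit_depth=8)
    return stack, truths


# ---------------------------------------------------------------------------
# Control / stressed condition pairs
# ---------------------------------------------------------------------------

#: Default stressed-arm profile: doubled per-frame jitter, a subtle global
#: fade (to 93% of initial brightness by the last frame) and mildly
#: increased object clustering — individually weak signals meant to be
#: detectable mainly in combination.
DEFAULT_STRESS = {"motion_scale": 2.0, "intensity_drift": 0.93, "texture_clumping": 1.3}


def _stamp(canvas: np.ndarray, pattern: np.ndarray, center: tuple[float, float]) -> None:
    """Add ``pattern`` to ``canvas`` at a sub-pixel centre (bilinear shift)."""
    H, W = canvas.shape
    ph, pw = pattern.shape
    r_f = center[0] - ph / 2
    c_f = center[1] - pw / 2
    r0, c0 = int(np.floor(r_f)), int(np.floor(c_f))
    frac = (r_f - r0, c_f - c0)
    pad = np.pad(pattern, ((0, 1), (0, 1)))
    shifted = ndi.shift(pad, frac, order=1, mode="constant", cval=0.0, prefilter=False)
    sh, sw = shifted.shape
    rs, cs = max(r0, 0), max(c0, 0)
    re, ce = min(r0 + sh, H), min(c0 + sw, W)
    if re <= rs or ce <= cs:
        return
    canvas[rs:re, cs:ce] += shifted[rs - r0 : re - r0, cs - c0 : ce - c0]


def _condition_video(
    rng: np.random.Generator,
    size: tuple[int, int],
    n_frames: int,
    motion_scale: float,
    intensity_drift: float,
    texture_clumping: float,
    base_jitter: float = 0.6,
) -> FrameStack:
    """One networked-dominant video; stress factors multiply the baseline.

    Object shapes are generated once and persist across frames; only their
    positions jitter (sub-pixel, Gaussian around a fixed anchor), so the
    arms differ in motion statistics rather than in shape turnover.
    """
    H, W = size
    specs = ["networked"] * 5 + ["punctate"] * 3
    # clustering: centres drawn around k attractors; larger clumping pulls
    # objects closer to their attractor, raising lacunarity
    k = 2
    attractors = [
        (rng.uniform(0.3 * H, 0.7 * H), rng.uniform(0.3 * W, 0.7 * W)) for _ in range(k)
    ]
    spread = 0.28 * min(H, W) / texture_clumping
    objects = []
    for cls in specs:
        fp = _networked_footprint(rng) if cls == "networked" else _punctate_footprint(rng)
        pattern = _object_intensity(fp, cls, rng)
        ar, ac = attractors[int(rng.integers(0, k))]
        center = (
            float(np.clip(ar + rng.normal(0, spread), 0.15 * H, 0.85 * H)),
            float(np.clip(ac + rng.normal(0, spread), 0.15 * W, 0.85 * W)),
        )
        objects.append((pattern, center))
    jitter = base_jitter * motion_scale
    frames = []
    for t in range(n_frames):
        # global intensity drift: brightness ramps linearly towards
        # `intensity_drift` x initial by the final frame (1.0 = no drift)
        gain = 1.0 + (intensity_drift - 1.0) * (t / max(n_frames - 1, 1))
        canvas = np.zeros((H, W), float)
        for pattern, (r, c) in objects:
            _stamp(canvas, pattern, (r + rng.normal(0, jitter), c + rng.normal(0, jitter)))
        frames.append(_apply_noise(canvas * gain, rng, read_sigma=2.0, poisson=True))
    return FrameStack(frames=np.stack(frames), bit_depth=8)


def make_condition_pair(
    n_videos_per_arm: int,
    stress_params: Mapping[str, float] | None = None,
    seed: int = 0,
    size: tuple[int, int] = (96, 96),
    n_frames: int = 6,
) -> tuple[list[FrameStack], list[str]]:
    """Generate paired control/stressed video sets for health classification.

    Both arms are networked-dominant and visually similar; the stressed arm
    multiplies per-frame jitter by ``motion_scale``, ramps global brightness
    to ``intensity_drift`` x initial by the last frame, and pulls objects
    towards cluster attractors by ``texture_clumping``.  All factors default
    to the values in :data:`DEFAULT_STRESS`; a factor of 1 reproduces the
    control arm's distribution.

    Returns ``(videos, arm_labels)`` with labels in {"control", "stressed"}.
    """
    if n_videos_per_arm < 2:
        raise ValueError("need at least 2 videos per arm")
    if stress_params is None:
        params = dict(DEFAULT_STRESS)
    else:
        unknown = set(stress_params) - set(DEFAULT_STRESS)
        if unknown:
            raise ValueError(f"unknown stress parameters: {sorted(unknown)}")
        # unspecified factors are neutral: only the stated ones differ
        params = {k: 1.0 for k in DEFAULT_STRESS}
        params.update(stress_params)
    if any(v <= 0 for v in params.values()):
        raise ValueError("stress factors must be > 0")
    rng = np.random.default_rng(seed)
    videos: list[FrameStack] = []
    labels: list[str] = []
    for arm, (ms, idr, tc) in (
        ("control", (1.0, 1.0, 1.0)),
        ("stressed", (params["motion_scale"], params["intensity_drift"], params["texture_clumping"])),
    ):
        for _ in range(n_videos_per_arm):
            vid_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
            videos.append(
                _condition_video(vid_rng, size, n_frames, ms, idr, tc)
            )
            labels.append(arm)
    return videos, labels
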