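"""Synthetic ground truth and a simulated bounding-box detector.

Training a convolutional polyp detector is far outside desk scale, and the
clinical image cohorts involved are request-only. This module provides the
two stand-ins that make the rest of the pipeline fully testable:

* :func:`generate_dataset` builds a manifest of synthetic *polyp* images
  (each carrying >= 1 ground-truth box) and *not-polyp* images (carrying
  none), with optional rendered ellipse masks so the mask-to-box conversion
  path is exercised on real rasters;
* :func:`simulate_detections` emulates a trained detector's output
  interface: each truth box is detected independently with probability
  ``p_detect`` (optionally jittered, confidence drawn from a TP law), and
  each image receives spurious boxes at a Poisson rate that differs between
  polyp and not-polyp imagery — modelling a network that fires on
  out-of-distribution artifacts (instruments, water jets, blur, proximity to
  mucosa) it never saw during training.

Under zero jitter and with spurious boxes placed off the truth boxes, the
evaluated micro-averaged metrics have the closed form of
:func:`expected_metrics`:

    recall    = p_detect
    precision = p·b·n_p / (p·b·n_p + r_p·n_p + r_n·n_n)

with ``b`` the mean boxes per polyp image, ``n_p``/``n_n`` the polyp /
not-polyp image counts and ``r_p``/``r_n`` the per-image spurious-box rates.
The formula makes the precision-dilution effect of adding negatives to a
test set explicit: recall cannot move (negatives carry no truth boxes),
while precision decays with ``r_n·n_n`` in the denominator.

Per-image randomness is derived from ``(seed, image_id)``, so a given image
receives the same simulated detections regardless of which evaluation set it
appears in — exactly the situation when one fixed model is run over nested
test partitions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
import numpy as np

from .datasets_io import BoundingBox, DatasetManifest, Detection, GroundTruthImage
from .errors import SpecError, UndefinedMetricError

__all__ = [
    "ConfidenceLaw", "DatasetSpec", "DetectorProfile",
    "generate_dataset", "render_mask", "simulate_detections",
    "simulate_video", "expected_metrics", "profile_from_metrics",
]


@dataclass(frozen=True)
class ConfidenceLaw:
    """Parametric distribution on [0, 1] for confidence scores.

    ``kind`` is ``"beta"`` (params ``(a, b)``), ``"uniform"`` (params
    ``(low, high)``) or ``"fixed"`` (params ``(value,)``).
    """

    kind: str = "beta"
    params: tuple[float, ...] = (6.0, 3.0)

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "beta":
            return float(rng.beta(*self.params))
        if self.kind == "uniform":
            low, high = self.params
            return float(rng.uniform(low, high))
        if self.kind == "fixed":
            return float(self.params[0])
        raise SpecError(f"unknown confidence law {self.kind!r}")

    @property
    def mean(self) -> float:
        if self.kind == "beta":
            a, b = self.params
            return a / (a + b)
        if self.kind == "uniform":
            return (self.params[0] + self.params[1]) / 2
        return self.params[0]


@dataclass(frozen=True)
class DatasetSpec:
    """Parameters of a synthetic polyp/not-polyp image collection.

    Defaults emulate a colonoscopy still-image cohort: 640x480 frames, one
    polyp box in most polyp images with an occasional second or third
    (public datasets do contain multiple-polyp frames), box sides between 24
    and 96 px, and a 49/21/30 training/validation/test split of the polyp
    images. Not-polyp images are left unassigned — they form the pool from
    which injection plans draw.
    """

    n_polyp_images: int
    n_negative_images: int
    width: int = 640
    height: int = 480
    boxes_per_image_weights: tuple[float, ...] = (0.90, 0.08, 0.02)
    box_size_range: tuple[int, int] = (24, 96)
    partition_fractions: tuple[float, float, float] = (0.49, 0.21, 0.30)
    id_prefix: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_polyp_images < 0 or self.n_negative_images < 0:
            raise SpecError("image counts must be non-negative")
        lo, hi = self.box_size_range
        if lo < 4 or hi < lo:
            raise SpecError("box_size_range must satisfy 4 <= lo <= hi")
        if hi > min(self.width, self.height):
            raise SpecError(
                f"box_size_range upper bound {hi} exceeds image side "
                f"{min(self.width, self.height)}"
            )
        if not np.isclose(sum(self.partition_fractions), 1.0):
            raise SpecError("partition_fractions must sum to 1")
        if any(w < 0 for w in self.boxes_per_image_weights) or \
                sum(self.boxes_per_image_weights) <= 0:
            raise SpecError("boxes_per_image_weights must be non-negative, not all 0")


@dataclass(frozen=True)
class DetectorProfile:
    """Behavioural parameters of the simulated detector.

    ``fp_rate_negative`` may exceed ``fp_rate_polyp``: artifact-bearing
    not-polyp frames are out-of-distribution for a detector trained only on
    polyp imagery and draw disproportionately many spurious boxes.
    """

    p_detect: float = 0.9
    jitter_frac: float = 0.0
    fp_rate_polyp: float = 0.0
    fp_rate_negative: float = 0.0
    tp_confidence_law: ConfidenceLaw = ConfidenceLaw("beta", (6.0, 3.0))
    fp_confidence_law: ConfidenceLaw = ConfidenceLaw("beta", (3.0, 3.0))
    fp_box_frac_range: tuple[float, float] = (0.05, 0.20)
    fp_overlap_allowed: bool = False
    fp_count_mode: str = "poisson"  # or "fixed": exact round(rate) boxes/image
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_detect <= 1.0:
            raise SpecError("p_detect must lie in [0, 1]")
        if self.fp_rate_polyp < 0 or self.fp_rate_negative < 0:
            raise SpecError("false-positive rates must be non-negative")
        if not 0.0 <= self.jitter_frac < 0.5:
            raise SpecError("jitter_frac must lie in [0, 0.5)")
        if self.fp_count_mode not in ("poisson", "fixed"):
            raise SpecError("fp_count_mode must be 'poisson' or 'fixed'")

    def with_seed(self, seed: int) -> "DetectorProfile":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _sample_box(rng: np.random.Generator, spec: DatasetSpec,
                existing: list[BoundingBox]) -> BoundingBox | None:
    """Sample a box not touching any existing box (1-px margin, so rendered
    mask components stay separate under 8-connectivity)."""
    lo, hi = spec.box_size_range
    for _ in range(100):
        w = int(rng.integers(lo, hi + 1))
        h = int(rng.integers(lo, hi + 1))
        x0 = int(rng.integers(0, spec.width - w + 1))
        y0 = int(rng.integers(0, spec.height - h + 1))
        box = BoundingBox(x0, y0, x0 + w, y0 + h)
        grown = BoundingBox(max(0, x0 - 1), max(0, y0 - 1),
                            min(spec.width, x0 + w + 1),
                            min(spec.height, y0 + h + 1))
        if all(grown.intersection_area(b) == 0 for b in existing):
            return box
    return None


def generate_dataset(spec: DatasetSpec, name: str = "synthetic") -> DatasetManifest:
    """Generate a synthetic manifest, deterministic given ``spec.seed``.

    Polyp images are split into training/validation/test per
    ``partition_fractions`` (rounded counts, remainder to test); negatives
    stay ``unassigned``.
    """
    rng = np.random.default_rng(spec.seed)
    weights = np.asarray(spec.boxes_per_image_weights, dtype=float)
    weights = weights / weights.sum()

    n = spec.n_polyp_images
    n_train = int(round(spec.partition_fractions[0] * n))
    n_val = int(round(spec.partition_fractions[1] * n))
    partitions = (["training"] * n_train + ["validation"] * n_val
                  + ["test"] * (n - n_train - n_val))

    images: list[GroundTruthImage] = []
    for i in range(n):
        k = 1 + int(rng.choice(len(weights), p=weights))
        boxes: list[BoundingBox] = []
        for _ in range(k):
            box = _sample_box(rng, spec, boxes)
            if box is None:  # image too crowded; keep what fits (>= 1)
                break
            boxes.append(box)
        images.append(GroundTruthImage(
            image_id=f"{spec.id_prefix}polyp_{i:05d}",
            width=spec.width, height=spec.height,
            truth_boxes=boxes, partition=partitions[i],
        ))
    for i in range(spec.n_negative_images):
        images.append(GroundTruthImage(
            image_id=f"{spec.id_prefix}negative_{i:05d}",
            width=spec.width, height=spec.height,
            truth_boxes=[], partition="unassigned",
        ))
    return DatasetManifest(images, name=name)


def render_mask(image: GroundTruthImage) -> np.ndarray:
    """Render truth boxes as filled ellipses into a binary uint8 mask.

    Each ellipse is inscribed in its box and the midpoint pixel of each box
    side is set explicitly, so the tight pixel extent of every component
    equals the generating box exactly (round-trip with the mask-to-box
    conversion).
    """
    mask = np.zeros((image.height, image.width), dtype=np.uint8)
    yy, xx = np.mgrid[0:image.height, 0:image.width]
    for box in image.truth_boxes:
        cy = (box.y_min + box.y_max - 1) / 2.0
        cx = (box.x_min + box.x_max - 1) / 2.0
        ry = max((box.height - 1) / 2.0, 0.5)
        rx = max((box.width - 1) / 2.0, 0.5)
        inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        mask[inside] = 255
        icy, icx = int(round(cy)), int(round(cx))
        mask[box.y_min, icx] = 255
        mask[box.y_max - 1, icx] = 255
        mask[icy, box.x_min] = 255
        mask[icy, box.x_max - 1] = 255
    return mask


# ---------------------------------------------------------------------------
# Detection simulation
# ---------------------------------------------------------------------------

def _image_rng(seed: int, image_id: str) -> np.random.Generator:
    # stable per (seed, image): the same image gets the same detections no
    # matter which evaluation set it is part of
    return np.random.default_rng([seed, zlib.crc32(image_id.encode())])


def _jitter_box(rng: np.random.Generator, box: BoundingBox,
                frac: float, width: int, height: int) -> BoundingBox:
    if frac == 0:
        return box
    dx0, dx1 = rng.uniform(-frac, frac, 2) * box.width
    dy0, dy1 = rng.uniform(-frac, frac, 2) * box.height
    x0 = int(np.clip(round(box.x_min + dx0), 0, width - 1))
    x1 = int(np.clip(round(box.x_max + dx1), x0 + 1, width))
    y0 = int(np.clip(round(box.y_min + dy0), 0, height - 1))
    y1 = int(np.clip(round(box.y_max + dy1), y0 + 1, height))
    return BoundingBox(x0, y0, x1, y1)


def _spurious_box(rng: np.random.Generator, image: GroundTruthImage,
                  profile: DetectorProfile) -> BoundingBox | None:
    lo, hi = profile.fp_box_frac_range
    side = min(image.width, image.height)
    for _ in range(50):
        w = max(2, int(round(rng.uniform(lo, hi) * side)))
        h = max(2, int(round(rng.uniform(lo, hi) * side)))
        x0 = int(rng.integers(0, max(1, image.width - w)))
        y0 = int(rng.integers(0, max(1, image.height - h)))
        box = BoundingBox(x0, y0, min(x0 + w, image.width),
                          min(y0 + h, image.height))
        if profile.fp_overlap_allowed or all(
                box.intersection_area(t) == 0 for t in image.truth_boxes):
            return box
    return None


def simulate_detections(
    manifest: DatasetManifest,
    profile: DetectorProfile,
) -> list[Detection]:
    """Simulate the detector over every image of a manifest.

    Each truth box yields a detection with probability ``p_detect`` (edges
    jittered by up to ``jitter_frac`` of the box dimensions, confidence from
    the TP law). Each image then receives spurious boxes — Poisson count at
    the class-appropriate rate (or an exact ``round(rate)`` in ``fixed``
    mode) — placed uniformly, by default rejecting overlap with truth boxes
    so the closed-form metrics stay exact. Deterministic given
    ``profile.seed``.
    """
    detections: list[Detection] = []
    for image in manifest.images:
        rng = _image_rng(profile.seed, image.image_id)
        for box in image.truth_boxes:
            if rng.random() < profile.p_detect:
                jittered = _jitter_box(rng, box, profile.jitter_frac,
                                       image.width, image.height)
                detections.append(Detection(
                    image.image_id, jittered,
                    profile.tp_confidence_law.sample(rng)))
        rate = (profile.fp_rate_polyp if image.has_polyp
                else profile.fp_rate_negative)
        if profile.fp_count_mode == "poisson":
            n_fp = int(rng.poisson(rate))
        else:
            n_fp = int(round(rate))
        for _ in range(n_fp):
            box = _spurious_box(rng, image, profile)
            if box is not None:
                detections.append(Detection(
                    image.image_id, box,
                    profile.fp_confidence_law.sample(rng)))
    return detections


def simulate_video(
    n_frames: int,
    has_polyp: bool,
    profile: DetectorProfile,
    *,
    width: int = 640,
    height: int = 480,
    box_size: int = 64,
    id_prefix: str = "frame",
) -> dict[int, list[Detection]]:
    """Simulate per-frame detections for a short video clip.

    A polyp video carries one persistent truth box (centred, ``box_size``
    px); a not-polyp video carries none, so every emitted box is a false
    positive. Returns a mapping frame index -> detections, suitable for
    :func:`negdetect.video_frames.summarize_video`.
    """
    images = []
    for i in range(n_frames):
        if has_polyp:
            x0 = (width - box_size) // 2
            y0 = (height - box_size) // 2
            boxes = [BoundingBox(x0, y0, x0 + box_size, y0 + box_size)]
        else:
            boxes = []
        images.append(GroundTruthImage(
            image_id=f"{id_prefix}_{i:05d}", width=width, height=height,
            truth_boxes=boxes, partition="unassigned"))
    manifest = DatasetManifest(images, name=id_prefix)
    detections = simulate_detections(manifest, profile)
    frames: dict[int, list[Detection]] = {i: [] for i in range(n_frames)}
    for det in detections:
        frames[int(det.image_id.rsplit("_", 1)[1])].append(det)
    return frames


# ---------------------------------------------------------------------------
# Closed-form expectations and calibration
# ---------------------------------------------------------------------------

def expected_metrics(
    profile: DetectorProfile,
    n_polyp: int,
    mean_boxes_per_polyp: float,
    n_negative: int,
) -> tuple[float, float]:
    """Expected (recall, precision) in the zero-jitter, non-overlapping-FP
    regime.

    recall = p_detect; precision = p·b·n_p / (p·b·n_p + r_p·n_p + r_n·n_n).
    """
    tp = profile.p_detect * mean_boxes_per_polyp * n_polyp
    fp = profile.fp_rate_polyp * n_polyp + profile.fp_rate_negative * n_negative
    if tp + fp == 0:
        raise UndefinedMetricError("expected precision undefined: no detections")
    if n_polyp * mean_boxes_per_polyp == 0:
        raise UndefinedMetricError("expected recall undefined: no truth boxes")
    return profile.p_detect, tp / (tp + fp)


def profile_from_metrics(
    recall: float,
    precision_clean: float,
    precision_at_level: float,
    level_pct: float,
    *,
    mean_boxes_per_polyp: float = 1.0,
    **overrides,
) -> DetectorProfile:
    """Calibrate a profile so its expected metrics match observed ones.

    Given a detector's recall, its precision on a polyp-only test set and
    its precision after injecting ``level_pct`` % not-polyp images, invert
    the closed form of :func:`expected_metrics` for the two spurious-box
    rates. This lets the simulator reproduce the operating points of real
    trained models.
    """
    if not 0 < precision_at_level <= precision_clean <= 1:
        raise SpecError("need 0 < precision_at_level <= precision_clean <= 1")
    q = recall * mean_boxes_per_polyp  # expected TPs per polyp image
    r_p = q * (1.0 - precision_clean) / precision_clean
    r_n = (q * (1.0 / precision_at_level - 1.0) - r_p) / (level_pct / 100.0)
    return DetectorProfile(p_detect=recall, fp_rate_polyp=r_p,
                           fp_rate_negative=max(r_n, 0.0), **overrides)
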