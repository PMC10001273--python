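"""Frame-level summaries for qualitative video analysis.

For a video of a polyp, per-frame ground-truth boxes are typically not
available; the fraction of frames carrying at least one emitted bounding box
serves as a recall proxy (it assumes that at least one of the boxes in a
frame is placed over the polyp — the summary reports the proxy, not true
recall). For a video of normal mucosa with no polyp, every emitted box is a
false positive, so the total box count measures the false-positive burden
directly. Relative changes between detector variants are reported as signed
percentages of a reference count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .datasets_io import Detection
from .errors import ConsistencyError, UndefinedMetricError
from .rounding import percent_round

RECALL_PROXY_NOTE = (
    "frames_with_box is a recall proxy: it assumes at least one bounding box "
    "in each counted frame is placed over the polyp; it is not a box-level "
    "recall."
)


@dataclass(frozen=True)
class FrameSummary:
    """Per-video tally of frames with detections and total emitted boxes."""

    n_frames: int
    frames_with_box: int
    total_boxes: int

    def __post_init__(self) -> None:
        if not 0 <= self.frames_with_box <= self.n_frames:
            raise ConsistencyError(
                f"frames_with_box {self.frames_with_box} outside "
                f"[0, {self.n_frames}]"
            )

    @property
    def frames_with_box_pct(self) -> float:
        """Percentage of frames with >= 1 box, rounded at 2 decimals."""
        return percent_round(100.0 * self.frames_with_box / self.n_frames)


def summarize_video(
    frame_detections: Mapping[int, Sequence[Detection]],
    n_frames: int,
    threshold: float,
) -> FrameSummary:
    """Tally surviving detections per frame at a confidence threshold.

    ``frame_detections`` maps frame index (in ``[0, n_frames)``) to that
    frame's detections; frames absent from the mapping have none.
    """
    frames_with_box = 0
    total_boxes = 0
    for idx, dets in frame_detections.items():
        if not 0 <= idx < n_frames:
            raise ConsistencyError(
                f"frame index {idx} outside [0, {n_frames})"
            )
        surviving = sum(1 for d in dets if d.confidence >= threshold)
        if surviving:
            frames_with_box += 1
            total_boxes += surviving
    return FrameSummary(n_frames=n_frames, frames_with_box=frames_with_box,
                        total_boxes=total_boxes)


def relative_change(reference: float, value: float) -> float:
    """Signed percentage change of ``value`` with respect to ``reference``."""
    if reference == 0:
        raise UndefinedMetricError("relative change undefined for reference 0")
    return 100.0 * (value - reference) / reference
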