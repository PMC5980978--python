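"""Four-class audit overlays.

Each slice is rendered as an RGB image with one color per nucleus class —
live islet nuclei blue, live MSC nuclei purple, dead islet nuclei red,
dead MSC nuclei orange — and the dilated MSC ROI outlines in green, so the
automated classification can be verified by eye.  Duplicate detections
(suppressed by the next-slide rule) are drawn dimmed.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
from skimage.segmentation import find_boundaries

from .nuclei import NucleusRecord
from .segmentation import RoiSet

CLASS_COLORS = {
    "islet_live": (0, 0, 255),
    "msc_live": (160, 32, 240),
    "islet_dead": (255, 0, 0),
    "msc_dead": (255, 165, 0),
}
ROI_OUTLINE_COLOR = (0, 255, 0)


def render_overlay(
    records: Sequence[NucleusRecord],
    rois: RoiSet,
    shape: Tuple[int, int],
    n_slices: int,
) -> List[np.ndarray]:
    """Render per-slice RGB overlays of classified, deduplicated nuclei.

    Every surviving record's footprint is painted exactly once in its
    class color; duplicates are painted at half intensity for audit.
    Returns one (H, W, 3) uint8 image per slice.
    """
    out = [np.zeros(shape + (3,), dtype=np.uint8) for _ in range(n_slices)]
    for z in range(min(n_slices, rois.n_slices)):
        edge = find_boundaries(rois.labels[z], mode="outer")
        out[z][edge] = ROI_OUTLINE_COLOR
    for rec in records:
        if rec.pixels is None or rec.compartment is None:
            continue
        color = np.array(CLASS_COLORS[f"{rec.compartment}_{rec.vital_state}"], dtype=np.uint8)
        if rec.is_duplicate:
            color = color // 2
        out[rec.slice_index][rec.pixels[:, 0], rec.pixels[:, 1]] = color
    return out
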