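"""Per-slice segmentation: binarization, debris suppression, MSC ROIs.

The binary transform is a fixed user-supplied closed intensity window
``[tmin, tmax]`` — the thresholds are experiment-specific dial settings,
not an automatic method.  :func:`otsu_window` is offered as a convenience
to pick ``tmin`` automatically, but it is never applied implicitly.

All connected-component operations use 8-connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
from skimage import exposure, filters, measure, morphology

from .config import RunConfig
from .errors import ValidationError
from .stacks import ChannelStack

#: fraction of pixels saturated at each tail by the contrast stretch
CONTRAST_SATURATION = 0.007


def enhance_contrast(image: np.ndarray, saturation: float = CONTRAST_SATURATION) -> np.ndarray:
    """Linear percentile contrast stretch, saturating ``saturation`` of pixels.

    The saturated fraction is split evenly between the two tails (0.35% each
    by default), then intensities are rescaled linearly to the full range of
    the input dtype.  The mapping is monotone, so pixel ranks are preserved.
    A constant image is returned unchanged.
    """
    image = np.asarray(image)
    half = 100.0 * saturation / 2.0
    lo, hi = np.percentile(image, [half, 100.0 - half])
    if hi <= lo:
        return image.copy()
    return exposure.rescale_intensity(image, in_range=(lo, hi))


def otsu_window(image: np.ndarray) -> tuple:
    """Convenience auto-threshold: (otsu, dtype max). Never applied implicitly."""
    tmin = filters.threshold_otsu(np.asarray(image))
    tmax = np.iinfo(image.dtype).max if np.issubdtype(image.dtype, np.integer) else float(image.max())
    return float(tmin), float(tmax)


def binarize(image: np.ndarray, tmin: float, tmax: float) -> np.ndarray:
    """Boolean mask: pixel is foreground iff ``tmin <= intensity <= tmax``."""
    if tmin >= tmax:
        raise ValidationError(f"tmin ({tmin}) must be strictly below tmax ({tmax})")
    image = np.asarray(image)
    return (image >= tmin) & (image <= tmax)


def filter_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove 8-connected components with area strictly below ``min_area``."""
    if min_area < 0:
        raise ValidationError("min_area must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    if min_area <= 1:
        return mask.copy()
    # max_size removes components of area <= value, hence min_area - 1
    return morphology.remove_small_objects(mask, max_size=min_area - 1, connectivity=2)


@dataclass
class RoiSet:
    """Per-slice labeled MSC-cytosol regions (0 = background).

    Labels are contiguous positive integers within each slice.  Regions
    are the 8-connected components of the binarized green channel after
    debris filtering, dilated by ``dilation`` pixels; dilated regions that
    touch merge into one label.
    """

    labels: List[np.ndarray]
    dilation: int
    region_areas: List[Dict[int, int]] = field(default_factory=list)

    @property
    def n_slices(self) -> int:
        return len(self.labels)

    def n_regions(self, slice_index: int | None = None) -> int:
        if slice_index is not None:
            return int(self.labels[slice_index].max())
        return sum(int(l.max()) for l in self.labels)


def detect_rois(green_stack: ChannelStack, cfg: RunConfig) -> RoiSet:
    """Derive the dilated MSC ROI set from the cytosol (green) channel.

    Per slice: binarize -> suppress sub-area debris -> label 8-connected
    components -> dilate by a disk of radius ``cfg.roi_dilation``.  Because
    the whole mask is dilated before labeling, regions whose dilations
    overlap merge into a single ROI.
    """
    min_area = cfg.min_area_for("msc_cytosol")
    selem = morphology.disk(cfg.roi_dilation) if cfg.roi_dilation > 0 else None
    labels, areas = [], []
    for s in green_stack.slices:
        m = binarize(s, cfg.threshold_min, cfg.threshold_max)
        m = filter_small(m, min_area)
        if selem is not None:
            m = morphology.dilation(m, selem)
        lab = measure.label(m, connectivity=2)
        labels.append(lab)
        areas.append({int(r.label): int(r.area) for r in measure.regionprops(lab)})
    return RoiSet(labels=labels, dilation=cfg.roi_dilation, region_areas=areas)
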