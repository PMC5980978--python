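"""Nucleus detection, compartment assignment, erasure, and z-dedup.

The analysis is deliberately 2D-per-slice: nuclei are detected on each
optical section independently, and a nucleus spanning several sections is
collapsed to a single count by the *next-slide rule* — a detection on
slice z is a duplicate iff a detection of the same vital state exists at
the same location on slice z-1.  Consecutive-slice chains therefore
collapse to their first occurrence, while a reappearance after a one-slice
gap is counted again.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, morphology, segmentation as skseg

from .config import RunConfig
from .errors import ValidationError
from .segmentation import RoiSet, binarize, detect_rois, enhance_contrast, filter_small
from .stacks import ChannelStack

VITAL_STATES = ("live", "dead")
COMPARTMENTS = ("islet", "msc")

#: (vital_state, channel_role) processing order: live/blue first, dead/red second
VITAL_CHANNELS = (("live", "live_nuclei"), ("dead", "dead_nuclei"))


@dataclass
class NucleusRecord:
    """One detected nucleus on one slice.

    ``seed_xy`` is the (x, y) = (column, row) pixel used for flood-fill
    selection: the foreground pixel of the component nearest to its exact
    centroid (ties broken by lowest row, then column).  ``pixels`` is the
    (N, 2) array of (row, col) footprint coordinates; it backs the overlap
    dedup rule, mask erasure, and overlay rendering.  ``dedup_of`` points
    at the record on the immediately preceding slice this one repeats.
    """

    id: int
    slice_index: int
    seed_xy: Tuple[int, int]
    area_px: int
    vital_state: str
    compartment: Optional[str] = None
    dedup_of: Optional[int] = None
    pixels: Optional[np.ndarray] = None

    @property
    def is_duplicate(self) -> bool:
        return self.dedup_of is not None

    def pixel_set(self) -> frozenset:
        if self.pixels is None:
            return frozenset()
        return frozenset(map(tuple, self.pixels))


def _seed_pixel(coords: np.ndarray) -> Tuple[int, int]:
    """Component pixel nearest the exact centroid; ties -> lowest (row, col)."""
    centroid = coords.mean(axis=0)
    d2 = ((coords - centroid) ** 2).sum(axis=1)
    best = coords[d2 == d2.min()]
    order = np.lexsort((best[:, 1], best[:, 0]))
    r, c = best[order[0]]
    return int(c), int(r)  # (x, y)


def detect_nuclei(
    mask: np.ndarray,
    min_area: int,
    h: float = 2.0,
    slice_index: int = 0,
    vital_state: str = "live",
    start_id: int = 0,
) -> List[NucleusRecord]:
    """Detect and split nuclei in a filtered binary mask of one slice.

    Touching nuclei are separated by a watershed on the negated Euclidean
    distance transform, seeded at the h-maxima of the distance map (depth
    ``h``); a component whose relief is too shallow to produce an h-maximum
    still yields one seed at its distance peak, so no object is lost.
    Watershed fragments below ``min_area`` are discarded.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    dist = ndi.distance_transform_edt(mask)
    if h > 0:
        # regional maxima of the h-maxima reconstruction: peaks separated by
        # a dip shallower than h stay one connected seed region, so slightly
        # elongated nuclei are not split spuriously
        rec = morphology.reconstruction(dist - h, dist, method="dilation")
        seeds = morphology.local_maxima(rec, connectivity=2)
    else:
        seeds = morphology.local_maxima(dist, connectivity=2)
    markers, _ = ndi.label(seeds, structure=np.ones((3, 3), dtype=int))
    comps, n_comps = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    # fallback seed for components without any h-maximum
    seeded = set(np.unique(comps[markers > 0]))
    next_marker = markers.max() + 1
    for comp_id in range(1, n_comps + 1):
        if comp_id in seeded:
            continue
        inside = comps == comp_id
        peak = np.unravel_index(np.argmax(np.where(inside, dist, -1)), dist.shape)
        markers[peak] = next_marker
        next_marker += 1
    ws = skseg.watershed(-dist, markers, mask=mask, connectivity=2)

    records = []
    next_id = start_id
    for region in measure.regionprops(ws):
        if region.area < max(min_area, 1):
            continue
        coords = region.coords
        records.append(
            NucleusRecord(
                id=next_id,
                slice_index=slice_index,
                seed_xy=_seed_pixel(coords),
                area_px=int(region.area),
                vital_state=vital_state,
                pixels=coords.copy(),
            )
        )
        next_id += 1
    return records


def classify_compartment(
    nuclei: Sequence[NucleusRecord], rois: RoiSet
) -> List[NucleusRecord]:
    """Assign each nucleus to the MSC or islet compartment.

    A nucleus belongs to the MSC compartment iff its seed pixel lies on a
    labeled (dilated) ROI pixel of its own slice; otherwise it is an islet
    nucleus.  Colocalisation of the nuclear stain with the cytosol dye is
    the only classification signal.
    """
    out = []
    for rec in nuclei:
        if not 0 <= rec.slice_index < rois.n_slices:
            raise ValidationError(
                f"nucleus {rec.id} on slice {rec.slice_index} outside ROI set "
                f"of {rois.n_slices} slices"
            )
        x, y = rec.seed_xy
        on_roi = rois.labels[rec.slice_index][y, x] > 0
        out.append(replace(rec, compartment="msc" if on_roi else "islet"))
    return out


def erase_nuclei(mask: np.ndarray, records: Sequence[NucleusRecord]) -> np.ndarray:
    """Remove the full 8-connected component under each record's seed.

    The flood-fill analog of an ImageJ MagicWand selection followed by
    clearing: only the selected components change, every other pixel is
    preserved.  A seed that falls on background (possible after watershed
    boundary erosion) raises a warning and is skipped.
    """
    mask = np.asarray(mask, dtype=bool)
    lab, _ = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    doomed = set()
    for rec in records:
        x, y = rec.seed_xy
        l = lab[y, x]
        if l == 0:
            warnings.warn(
                f"seed {rec.seed_xy} of nucleus {rec.id} on background; skipped",
                stacklevel=2,
            )
            continue
        doomed.add(int(l))
    if not doomed:
        return mask.copy()
    out = mask.copy()
    out[np.isin(lab, list(doomed))] = False
    return out


def _matches(rec: NucleusRecord, prev: NucleusRecord, mode: str, tolerance: float) -> bool:
    if mode == "centroid":
        dx = rec.seed_xy[0] - prev.seed_xy[0]
        dy = rec.seed_xy[1] - prev.seed_xy[1]
        return dx * dx + dy * dy <= tolerance * tolerance
    return bool(rec.pixel_set() & prev.pixel_set())


def dedup_across_slices(
    nuclei: Sequence[NucleusRecord], mode: str = "overlap", tolerance: float = 5.0
) -> List[NucleusRecord]:
    """Mark nuclei that repeat a same-state detection on the previous slice.

    A record on slice z gets ``dedup_of`` set iff a record of the same
    vital state exists on slice z-1 at the same location — footprints
    intersect (``overlap`` mode) or seed distance <= ``tolerance`` pixels
    (``centroid`` mode).  Because a duplicate on z-1 still anchors a match
    on z, a chain over consecutive slices collapses to its first
    occurrence, while the same position recurring after a one-slice gap is
    counted again.  Records are never removed, only marked, so the
    operation is idempotent.
    """
    if mode not in ("overlap", "centroid"):
        raise ValidationError(f"unknown dedup mode {mode!r}")
    if tolerance < 0:
        raise ValidationError("dedup tolerance must be non-negative")
    by_slice: Dict[int, List[NucleusRecord]] = {}
    out = []
    for rec in sorted(nuclei, key=lambda r: (r.slice_index, r.id)):
        dedup_of = None
        for prev in by_slice.get(rec.slice_index - 1, []):
            if prev.vital_state == rec.vital_state and _matches(rec, prev, mode, tolerance):
                dedup_of = prev.id
                break
        new = replace(rec, dedup_of=dedup_of)
        by_slice.setdefault(rec.slice_index, []).append(new)
        out.append(new)
    return out


def _paint(shape, records: Sequence[NucleusRecord]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    for rec in records:
        if rec.pixels is not None and len(rec.pixels):
            m[rec.pixels[:, 0], rec.pixels[:, 1]] = True
    return m


def run_nucleus_pass(
    stacks: Dict[str, ChannelStack], cfg: RunConfig, rois: Optional[RoiSet] = None
):
    """Run the full per-slice nucleus pipeline over the three channels.

    Per vital channel and slice: (optional contrast stretch on the
    live-nuclei channel) -> binarize -> debris filter -> detect/split
    nuclei -> assign compartment by ROI membership -> erase MSC-assigned
    nuclei from the islet working mask; finally duplicates across
    consecutive slices are marked and their signal removed from the saved
    masks.  MSC nuclei are always detected and erased; they are dropped
    from the returned records when ``cfg.analyze_msc`` is false.

    Returns
    -------
    records : list of NucleusRecord
        All surviving + duplicate-marked records (islet-only if MSC
        analysis is off).
    masks : dict
        Per-class lists of per-slice boolean masks, post-erasure and with
        duplicate signal deleted.
    rois : RoiSet
        The ROI set used (computed from the green channel when not given).
    """
    required = {"live_nuclei", "dead_nuclei", "msc_cytosol"}
    missing = required - set(stacks)
    if missing:
        raise ValidationError(f"missing channel stacks: {sorted(missing)}")
    counts = {r: stacks[r].n_slices for r in required}
    if len(set(counts.values())) != 1:
        raise ValidationError(f"slice counts differ across channels: {counts}")
    shapes = {stacks[r].shape for r in required}
    if len(shapes) != 1:
        raise ValidationError(f"slice dimensions differ across channels: {shapes}")

    if rois is None:
        rois = detect_rois(stacks["msc_cytosol"], cfg)

    records: List[NucleusRecord] = []
    masks = {f"{comp}_{vital}": [] for comp in COMPARTMENTS for vital in VITAL_STATES}
    next_id = 0
    shape = stacks["live_nuclei"].shape

    for vital, role in VITAL_CHANNELS:
        min_area = cfg.min_area_for(role)
        for z, img in enumerate(stacks[role].slices):
            if vital == "live" and cfg.enhance_blue_contrast:
                img = enhance_contrast(img)
            m = binarize(img, cfg.threshold_min, cfg.threshold_max)
            m = filter_small(m, min_area)
            recs = detect_nuclei(
                m, min_area, h=cfg.watershed_h, slice_index=z,
                vital_state=vital, start_id=next_id,
            )
            next_id += len(recs)
            recs = classify_compartment(recs, rois)
            msc_recs = [r for r in recs if r.compartment == "msc"]
            masks[f"islet_{vital}"].append(erase_nuclei(m, msc_recs))
            masks[f"msc_{vital}"].append(_paint(shape, msc_recs))
            records.extend(recs)

    records = dedup_across_slices(records, cfg.dedup_mode, cfg.dedup_tolerance)

    # delete duplicate signal from the saved masks as well
    for rec in records:
        if rec.is_duplicate and rec.pixels is not None:
            key = f"{rec.compartment}_{rec.vital_state}"
            masks[key][rec.slice_index][rec.pixels[:, 0], rec.pixels[:, 1]] = False

    if not cfg.analyze_msc:
        records = [r for r in records if r.compartment == "islet"]

    return records, masks, rois


def check_erasure_safety(records: Sequence[NucleusRecord], rois: RoiSet) -> bool:
    """True iff no islet-class record sits on a dilated ROI pixel."""
    for rec in records:
        if rec.compartment == "islet":
            x, y = rec.seed_xy
            if rois.labels[rec.slice_index][y, x] > 0:
                return False
    return True


def records_to_frame(records: Sequence[NucleusRecord]) -> pd.DataFrame:
    """Tabular export of nucleus records (one row per record)."""
    rows = [
        {
            "id": r.id,
            "slice": r.slice_index,
            "x": r.seed_xy[0],
            "y": r.seed_xy[1],
            "area_px": r.area_px,
            "vital_state": r.vital_state,
            "compartment": r.compartment,
            "dedup_of": r.dedup_of if r.dedup_of is not None else "",
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["id", "slice", "x", "y", "area_px", "vital_state", "compartment", "dedup_of"],
    )
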