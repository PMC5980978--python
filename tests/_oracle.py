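"""Independent brute-force reference implementation for small stacks.

Everything here is deliberately naive — per-pixel loops, BFS component
labeling, exhaustive pairwise dedup — and shares no code with the package
under test.  It only handles scenes whose objects are disjoint convex
blobs (no touching-nuclei splitting), which is how the random equivalence
fixtures are constructed.
"""

from collections import deque

import numpy as np


def threshold(img, tmin, tmax):
    h, w = img.shape
    out = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            out[r, c] = tmin <= img[r, c] <= tmax
    return out


def components(mask):
    """8-connected components as lists of (row, col) pixel sets, via BFS."""
    h, w = mask.shape
    seen = np.zeros((h, w), dtype=bool)
    comps = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                q = deque([(r, c)])
                seen[r, c] = True
                while q:
                    cr, cc = q.popleft()
                    comp.add((cr, cc))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = cr + dr, cc + dc
                            if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                                seen[nr, nc] = True
                                q.append((nr, nc))
                comps.append(comp)
    return comps


def area_filter(comps, min_area):
    return [c for c in comps if len(c) >= min_area]


def comps_to_mask(comps, shape):
    out = np.zeros(shape, dtype=bool)
    for comp in comps:
        for r, c in comp:
            out[r, c] = True
    return out


def dilate_disk(mask, radius):
    """Pixel true iff some mask pixel lies within Euclidean distance radius."""
    h, w = mask.shape
    offs = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]
    out = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                for dr, dc in offs:
                    nr, nc = r + dr, c + dc
                    if 0 <= nr < h and 0 <= nc < w:
                        out[nr, nc] = True
    return out


def seed_of(comp):
    """(x, y) of the pixel nearest the centroid; ties -> lowest (row, col)."""
    pts = np.array(sorted(comp), dtype=float)
    cr = pts[:, 0].mean()
    cc = pts[:, 1].mean()
    best = None
    best_d = None
    for r, c in sorted(comp):
        d = (r - cr) ** 2 + (c - cc) ** 2
        if best_d is None or d < best_d:
            best_d, best = d, (r, c)
    return int(best[1]), int(best[0])


def pipeline(green, blue, red, tmin, tmax, min_area, dilation):
    """Full reference pass on (z, h, w) arrays, overlap-mode dedup.

    Returns a set of record tuples
    ``(slice, seed_x, seed_y, area, vital_state, compartment, is_duplicate)``.
    """
    n_slices = green.shape[0]
    roi_masks = []
    for z in range(n_slices):
        comps = area_filter(components(threshold(green[z], tmin, tmax)), min_area)
        roi_masks.append(dilate_disk(comps_to_mask(comps, green[z].shape), dilation))

    raw = []  # (slice, seed, comp, vital)
    for vital, chan in (("live", blue), ("dead", red)):
        for z in range(n_slices):
            for comp in area_filter(components(threshold(chan[z], tmin, tmax)), min_area):
                raw.append((z, seed_of(comp), comp, vital))

    records = set()
    prev_by_state = {}
    for z in range(n_slices):
        cur_by_state = {"live": [], "dead": []}
        for rz, seed, comp, vital in raw:
            if rz != z:
                continue
            dup = any(comp & pc for pc in prev_by_state.get(vital, []))
            x, y = seed
            compartment = "msc" if roi_masks[z][y, x] else "islet"
            records.add((z, x, y, len(comp), vital, compartment, dup))
            cur_by_state[vital].append(comp)
        prev_by_state = cur_by_state
    return records


def class_counts(records):
    counts = {f"{c}_{v}": 0 for c in ("islet", "msc") for v in ("live", "dead")}
    for z, x, y, area, vital, comp, dup in records:
        if not dup:
            counts[f"{comp}_{vital}"] += 1
    return counts
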