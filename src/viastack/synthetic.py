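"""Synthetic three-channel z-stacks with exact ground truth.

The generator emulates confocal imagery of two cell types co-encapsulated
in a 3D hydrogel: nuclei of an islet-like aggregate and of MSCs rendered
as filled ellipses on a live (blue) or dead (red) channel, MSC cytosol
rendered as larger irregular blobs on a green channel, plus Gaussian
sensor noise and sub-threshold debris.  A nucleus occupies 1-3 consecutive
optical sections (its z-extent against a ~10 µm z-step) with at most 1 px
of lateral jitter per section, which is exactly the situation the
next-slide deduplication rule must correct.

Placement is rejection sampling under separation constraints, so that a
noise-free default scene is recovered *exactly* by the pipeline:

* every MSC nucleus center sits well inside a cytosol blob (its seed stays
  on ROI pixels after jitter);
* every islet nucleus clears all blobs by more than the ROI dilation
  radius;
* distinct nuclei never touch, in-plane or across neighbouring slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage import draw, filters

from .errors import GenerationError, ValidationError
from .stacks import ChannelStack
from .viability import CLASSES

_MAX_TRIES = 5000


@dataclass
class PlantedNucleus:
    """One ground-truth nucleus: geometry, z-extent, and true class."""

    center_xy: Tuple[float, float]
    radii: Tuple[float, float]  # (rx, ry) in pixels
    angle: float  # radians
    slice_start: int
    z_extent: int  # 1-3 consecutive slices
    vital_state: str  # live | dead
    compartment: str  # islet | msc

    @property
    def cls(self) -> str:
        return f"{self.compartment}_{self.vital_state}"


@dataclass
class CytosolBlob:
    """One MSC-cytosol region on the green channel."""

    center_xy: Tuple[float, float]
    radius: float
    irregularity: float = 0.15  # relative axis perturbation
    angle: float = 0.0

    @property
    def r_max(self) -> float:
        return self.radius * (1 + self.irregularity)

    @property
    def r_min(self) -> float:
        return self.radius * (1 - self.irregularity)


@dataclass
class SceneSpec:
    """Parameters of one synthetic stack.

    The defaults describe a realistic desk-scale scene: a 512 x 512 field
    (half the linear size of a typical 1,024 x 1,024 confocal frame), 15
    optical sections, ~100 nuclei of which ~20% are MSCs, nucleus radii
    4-7 px, cytosol blobs 15-30 px, 8-bit intensities with Gaussian noise
    of sd 8.  When ``nuclei``/``blobs`` are given explicitly, the counts
    are ignored and no placement sampling happens.
    """

    shape: Tuple[int, int] = (512, 512)
    n_slices: int = 15
    n_islet_live: int = 60
    n_islet_dead: int = 20
    n_msc_live: int = 15
    n_msc_dead: int = 5
    n_blobs: int = 10
    nucleus_radius_range: Tuple[float, float] = (4.0, 7.0)
    blob_radius_range: Tuple[float, float] = (18.0, 32.0)
    blob_irregularity: float = 0.15
    z_extent_range: Tuple[int, int] = (1, 3)
    min_separation: float = 3.0
    roi_clearance: float = 4.0  # islet margin beyond blob edge: dilation radius + 1
    msc_margin: float = 3.0  # how far inside a blob an MSC center must sit
    nucleus_intensity: float = 200.0
    blob_intensity: float = 120.0
    noise_sd: float = 8.0
    n_debris: int = 20
    debris_max_area: int = 10
    blur_sigma: float = 0.0
    bit_depth: int = 8
    nuclei: Optional[List[PlantedNucleus]] = None
    blobs: Optional[List[CytosolBlob]] = None

    def validate(self) -> None:
        if self.n_slices < 1:
            raise ValidationError("n_slices must be >= 1")
        lo, hi = self.z_extent_range
        if not (1 <= lo <= hi):
            raise ValidationError("z_extent_range must satisfy 1 <= lo <= hi")
        if hi > self.n_slices:
            raise ValidationError("z extent cannot exceed the number of slices")
        if self.bit_depth not in (8, 16):
            raise ValidationError("bit_depth must be 8 or 16")
        n_msc = self.n_msc_live + self.n_msc_dead
        if self.nuclei is None and n_msc > 0 and self.n_blobs == 0:
            raise ValidationError("MSC nuclei require at least one cytosol blob")


@dataclass
class GroundTruth:
    """Planted objects with true labels and the counts a perfect analysis yields."""

    nuclei: List[PlantedNucleus]
    blobs: List[CytosolBlob]
    counts: Dict[str, int]
    islet_viability: Optional[float]
    msc_viability: Optional[float]

    def expected_counts_per_slice(self, n_slices: int) -> Dict[Tuple[int, str], int]:
        """Each nucleus counted once, on its first slice (next-slide rule)."""
        out = {(z, c): 0 for z in range(n_slices) for c in CLASSES}
        for n in self.nuclei:
            out[(n.slice_start, n.cls)] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "x": n.center_xy[0],
                "y": n.center_xy[1],
                "rx": n.radii[0],
                "ry": n.radii[1],
                "slice_start": n.slice_start,
                "z_extent": n.z_extent,
                "vital_state": n.vital_state,
                "compartment": n.compartment,
            }
            for n in self.nuclei
        ]
        return pd.DataFrame(
            rows,
            columns=["x", "y", "rx", "ry", "slice_start", "z_extent",
                     "vital_state", "compartment"],
        )


def _truth_from(nuclei: Sequence[PlantedNucleus], blobs: Sequence[CytosolBlob]) -> GroundTruth:
    counts = {c: 0 for c in CLASSES}
    for n in nuclei:
        counts[n.cls] += 1

    def ratio(live, dead):
        return live / (live + dead) if live + dead else None

    return GroundTruth(
        nuclei=list(nuclei),
        blobs=list(blobs),
        counts=counts,
        islet_viability=ratio(counts["islet_live"], counts["islet_dead"]),
        msc_viability=ratio(counts["msc_live"], counts["msc_dead"]),
    )


def _place_blobs(spec: SceneSpec, rng: np.random.Generator) -> List[CytosolBlob]:
    h, w = spec.shape
    blobs: List[CytosolBlob] = []
    for _ in range(spec.n_blobs):
        for _try in range(_MAX_TRIES):
            r = rng.uniform(*spec.blob_radius_range)
            margin = r * (1 + spec.blob_irregularity) + 2
            if 2 * margin >= min(h, w):
                continue
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            # keep blobs apart so MSC territories stay unambiguous
            if all(
                np.hypot(cx - b.center_xy[0], cy - b.center_xy[1])
                > r + b.radius + 2 * spec.roi_clearance + 4
                for b in blobs
            ):
                blobs.append(
                    CytosolBlob(
                        center_xy=(cx, cy),
                        radius=r,
                        irregularity=spec.blob_irregularity,
                        angle=rng.uniform(0, np.pi),
                    )
                )
                break
        else:
            raise GenerationError("could not place cytosol blobs; scene too crowded")
    return blobs


def _far_from_nuclei(cx, cy, rmax, placed: Sequence[PlantedNucleus], gap: float) -> bool:
    for n in placed:
        need = rmax + max(n.radii) + gap
        if np.hypot(cx - n.center_xy[0], cy - n.center_xy[1]) < need:
            return False
    return True


def _place_nuclei(
    spec: SceneSpec, blobs: Sequence[CytosolBlob], rng: np.random.Generator
) -> List[PlantedNucleus]:
    h, w = spec.shape
    zlo, zhi = spec.z_extent_range
    # +2 keeps jittered footprints (<=1 px per slice, both nuclei) disjoint
    gap = spec.min_separation + 2.0
    nuclei: List[PlantedNucleus] = []

    def sample_geometry():
        rx = rng.uniform(*spec.nucleus_radius_range)
        ry = rng.uniform(*spec.nucleus_radius_range)
        angle = rng.uniform(0, np.pi)
        k = int(rng.integers(zlo, zhi + 1))
        z0 = int(rng.integers(0, spec.n_slices - k + 1))
        return rx, ry, angle, k, z0

    plan = (
        [("live", "msc")] * spec.n_msc_live
        + [("dead", "msc")] * spec.n_msc_dead
        + [("live", "islet")] * spec.n_islet_live
        + [("dead", "islet")] * spec.n_islet_dead
    )
    for vital, comp in plan:
        for _try in range(_MAX_TRIES):
            rx, ry, angle, k, z0 = sample_geometry()
            rmax = max(rx, ry)
            if comp == "msc":
                blob = blobs[int(rng.integers(0, len(blobs)))]
                reach = blob.r_min - spec.msc_margin - 2
                if reach <= 0:
                    continue
                rad = reach * np.sqrt(rng.uniform())
                theta = rng.uniform(0, 2 * np.pi)
                cx = blob.center_xy[0] + rad * np.cos(theta)
                cy = blob.center_xy[1] + rad * np.sin(theta)
            else:
                margin = rmax + 3
                cx = rng.uniform(margin, w - margin)
                cy = rng.uniform(margin, h - margin)
                # clear every (dilated) blob by more than the ROI dilation
                if any(
                    np.hypot(cx - b.center_xy[0], cy - b.center_xy[1])
                    < b.r_max + spec.roi_clearance + rmax + 2
                    for b in blobs
                ):
                    continue
            if not (rmax + 2 <= cx <= w - rmax - 3 and rmax + 2 <= cy <= h - rmax - 3):
                continue
            if _far_from_nuclei(cx, cy, rmax, nuclei, gap):
                nuclei.append(
                    PlantedNucleus(
                        center_xy=(cx, cy),
                        radii=(rx, ry),
                        angle=angle,
                        slice_start=z0,
                        z_extent=k,
                        vital_state=vital,
                        compartment=comp,
                    )
                )
                break
        else:
            raise GenerationError(
                f"could not place a {vital} {comp} nucleus; scene too crowded"
            )
    return nuclei


def _draw_ellipse(canvas, cx, cy, rx, ry, angle, value):
    rr, cc = draw.ellipse(cy, cx, ry, rx, shape=canvas.shape, rotation=angle)
    canvas[rr, cc] = value


def generate_scene(spec: SceneSpec, seed: int):
    """Render a scene spec into three channel stacks plus its ground truth.

    Deterministic given (spec, seed).  Returns ``(stacks, truth)`` where
    ``stacks`` maps channel role (live_nuclei / dead_nuclei / msc_cytosol)
    to a :class:`ChannelStack`.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    h, w = spec.shape

    if spec.blobs is not None:
        blobs = list(spec.blobs)
    else:
        blobs = _place_blobs(spec, rng)
    if spec.nuclei is not None:
        nuclei = list(spec.nuclei)
    else:
        nuclei = _place_nuclei(spec, blobs, rng)

    base = {
        role: np.zeros((spec.n_slices, h, w), dtype=float)
        for role in ("live_nuclei", "dead_nuclei", "msc_cytosol")
    }
    # cytosol blobs persist through the whole stack
    for b in blobs:
        for z in range(spec.n_slices):
            _draw_ellipse(
                base["msc_cytosol"][z],
                b.center_xy[0], b.center_xy[1],
                b.radius * (1 + b.irregularity), b.radius * (1 - b.irregularity),
                b.angle, spec.blob_intensity,
            )
    role_of = {"live": "live_nuclei", "dead": "dead_nuclei"}
    for n in nuclei:
        for dz in range(n.z_extent):
            jx, jy = rng.integers(-1, 2, size=2)
            _draw_ellipse(
                base[role_of[n.vital_state]][n.slice_start + dz],
                n.center_xy[0] + jx, n.center_xy[1] + jy,
                n.radii[0], n.radii[1], n.angle, spec.nucleus_intensity,
            )

    # sub-threshold-area debris on the nuclei channels; kept clear of nuclei
    # and of other debris so specks never merge into a supra-area component
    debris_r = 1
    debris_at = []
    for _ in range(spec.n_debris):
        for _try in range(_MAX_TRIES):
            cx = rng.uniform(4, w - 4)
            cy = rng.uniform(4, h - 4)
            if _far_from_nuclei(cx, cy, debris_r + 3, nuclei, 4.0) and all(
                np.hypot(cx - px, cy - py) > 2 * (debris_r + 1) + 4 for px, py in debris_at
            ):
                debris_at.append((cx, cy))
                break
        else:
            raise GenerationError("could not place debris")
        z = int(rng.integers(0, spec.n_slices))
        role = role_of[("live", "dead")[int(rng.integers(0, 2))]]
        rr, cc = draw.disk((cy, cx), debris_r + 1, shape=(h, w))
        if len(rr) > spec.debris_max_area:
            keep = rng.choice(len(rr), size=spec.debris_max_area, replace=False)
            rr, cc = rr[keep], cc[keep]
        base[role][z, rr, cc] = spec.nucleus_intensity

    maxval = 255.0 if spec.bit_depth == 8 else 65535.0
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    stacks = {}
    for role, vol in base.items():
        if spec.blur_sigma > 0:
            vol = np.stack([filters.gaussian(s, spec.blur_sigma, preserve_range=True) for s in vol])
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd, vol.shape)
        vol = np.clip(np.rint(vol), 0, maxval).astype(dtype)
        stacks[role] = ChannelStack(slices=list(vol), channel_role=role)

    return stacks, _truth_from(nuclei, blobs)


def sweep_viability(
    n_stacks: int,
    viability_range: Tuple[float, float] = (0.5, 0.95),
    seed: int = 0,
    islet_total: int = 80,
    msc_total: int = 20,
    spec: Optional[SceneSpec] = None,
):
    """Generate stacks whose true viabilities sweep a range evenly.

    Both cell types of stack i get true viability ``linspace(lo, hi,
    n_stacks)[i]`` (up to rounding live counts to integers).  Stack i is
    generated with seed ``seed + i``.  Returns a list of
    ``(stacks, truth)`` pairs.
    """
    if n_stacks < 3:
        raise ValidationError("a sweep needs at least 3 stacks")
    lo, hi = viability_range
    if not (0 <= lo < hi <= 1):
        raise ValidationError(f"viability_range must satisfy 0 <= lo < hi <= 1, got {viability_range}")
    template = spec if spec is not None else SceneSpec()
    out = []
    for i, v in enumerate(np.linspace(lo, hi, n_stacks)):
        n_il = int(round(v * islet_total))
        n_ml = int(round(v * msc_total))
        s = replace(
            template,
            n_islet_live=n_il,
            n_islet_dead=islet_total - n_il,
            n_msc_live=n_ml,
            n_msc_dead=msc_total - n_ml,
            nuclei=None,
            blobs=None,
        )
        out.append(generate_scene(s, seed + i))
    return out


def write_scene(stacks, truth: GroundTruth, out_dir, cfg=None) -> List[Path]:
    """Write a scene to disk in the per-slice TIFF layout the reader expects.

    Uses the file pattern and channel tokens of ``cfg`` (defaults when
    omitted) and drops a ``truth.csv`` with the planted nuclei next to the
    images.  Returns the manifest of written files.
    """
    from .config import DEFAULT_CHANNEL_NAMES
    from .stacks import write_stack

    pattern = cfg.file_pattern if cfg is not None else "z{slice:02d}_{channel}.tif"
    names = cfg.channel_names if cfg is not None else DEFAULT_CHANNEL_NAMES
    out_dir = Path(out_dir)
    manifest: List[Path] = []
    for role, stack in stacks.items():
        manifest += write_stack(stack, out_dir, pattern, names[role])
    truth_path = out_dir / "truth.csv"
    truth.to_frame().to_csv(truth_path, index=False)
    manifest.append(truth_path)
    return manifest
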