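"""Channel z-stack I/O and the output folder layout.

Stacks come in as per-slice grayscale TIFFs (one file per slice and
channel, 1-based slice numbers in the filename) or as one multi-page TIFF
per channel.  All pipeline outputs land under ``<output_dir>/Analyse/`` in
a fixed layout so every intermediate the analysis produced can be audited:

.. code-block:: text

    Analyse/
      ROI_Save/               per-slice 16-bit label images of the MSC ROIs
      Islets_Nucleus/         post-erasure live-nuclei masks (islet cells)
      Necrotic_Islets_Nucleus/  post-erasure dead-nuclei masks (islet cells)
      MSC_Nucleus/            live MSC nucleus masks   (when analyze_msc)
      Necrotic_MSC_Nucleus/   dead MSC nucleus masks   (when analyze_msc)
      counts.csv, nuclei.csv, viability.txt
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Mapping, Optional, Sequence

import numpy as np
import tifffile

from .config import RunConfig
from .errors import StackReadError, ValidationError

#: Map of nucleus class to its output subfolder.  The dead-MSC masks get
#: their own folder, parallel to the islet layout.
CLASS_FOLDERS = {
    "islet_live": "Islets_Nucleus",
    "islet_dead": "Necrotic_Islets_Nucleus",
    "msc_live": "MSC_Nucleus",
    "msc_dead": "Necrotic_MSC_Nucleus",
}

ROI_FOLDER = "ROI_Save"


@dataclass
class ChannelStack:
    """An ordered z-series of aligned 2D grayscale slices for one channel.

    ``pixel_size_um`` and ``z_step_um`` are carried as metadata only; all
    analysis is in pixel space.  The 10 µm default z-step matches typical
    confocal sectioning of encapsulated cell aggregates.
    """

    slices: List[np.ndarray]
    channel_role: str
    pixel_size_um: Optional[float] = None
    z_step_um: float = 10.0

    def __post_init__(self):
        if len(self.slices) == 0:
            raise ValidationError("a ChannelStack needs at least one slice")
        first = self.slices[0]
        for i, s in enumerate(self.slices):
            if s.ndim != 2:
                raise ValidationError(f"slice {i} is not 2D")
            if s.shape != first.shape:
                raise ValidationError(
                    f"slice {i} shape {s.shape} differs from slice 0 {first.shape}"
                )
            if s.dtype != first.dtype:
                raise ValidationError(
                    f"slice {i} dtype {s.dtype} differs from slice 0 {first.dtype}"
                )
            if np.issubdtype(s.dtype, np.signedinteger) and (s < 0).any():
                raise ValidationError(f"slice {i} has negative intensities")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def shape(self):
        return self.slices[0].shape

    @property
    def dtype(self):
        return self.slices[0].dtype

    def as_array(self) -> np.ndarray:
        """Stack the slices into a (z, y, x) array."""
        return np.stack(self.slices)


def _pattern_regex(pattern: str, token: str) -> re.Pattern:
    """Turn a filename template into a regex capturing the slice number."""
    # Split on the placeholders, escape the literal parts.
    parts = re.split(r"\{slice[^}]*\}", pattern)
    escaped = [re.escape(p.replace("{channel}", token)) for p in parts]
    return re.compile("^" + r"(?P<slice>\d+)".join(escaped) + "$")


def read_stack(cfg: RunConfig, role: str) -> ChannelStack:
    """Read the z-stack of one channel role according to the config.

    Slices are ordered by their filename slice number (1-based on disk,
    0-based in the returned list).  Raises :class:`StackReadError` when
    the numbering has gaps, no file matches, or slice dimensions differ.
    """
    if role not in cfg.channel_names:
        raise ValidationError(f"unknown channel role {role!r}")
    token = cfg.channel_names[role]
    if "{slice" not in cfg.file_pattern:
        # one multi-page TIFF per channel
        path = cfg.input_dir / cfg.file_pattern.format(channel=token)
        if not path.exists():
            raise StackReadError(f"stack file not found: {path}")
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise StackReadError(f"{path} is not a 2D/3D grayscale TIFF (shape {data.shape})")
        return ChannelStack(slices=list(data), channel_role=role)

    rx = _pattern_regex(cfg.file_pattern, token)
    found = {}
    for p in cfg.input_dir.iterdir():
        m = rx.match(p.name)
        if m:
            found[int(m.group("slice"))] = p
    if not found:
        raise StackReadError(
            f"no files in {cfg.input_dir} match pattern {cfg.file_pattern!r} "
            f"for channel {token!r}"
        )
    numbers = sorted(found)
    missing = sorted(set(range(numbers[0], numbers[-1] + 1)) - set(numbers))
    if missing:
        raise StackReadError(
            f"slice numbering for channel {token!r} has gaps; missing: {missing}"
        )
    slices = [tifffile.imread(found[n]) for n in numbers]
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise StackReadError(f"slice dimensions differ across files: {sorted(shapes)}")
    return ChannelStack(slices=slices, channel_role=role)


def write_stack(stack: ChannelStack, out_dir, pattern: str, token: str) -> List[Path]:
    """Write a stack as per-slice TIFFs using the config filename pattern."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, s in enumerate(stack.slices):
        p = out_dir / pattern.format(slice=i + 1, channel=token)
        tifffile.imwrite(p, s)
        paths.append(p)
    return paths


def _mask_to_u8(mask: np.ndarray) -> np.ndarray:
    return np.where(mask, 255, 0).astype(np.uint8)


def write_outputs(
    masks: Mapping[str, Sequence[np.ndarray]],
    counts,
    cfg: RunConfig,
    rois=None,
    records=None,
    report=None,
) -> List[Path]:
    """Write all pipeline outputs and return the manifest of created files.

    Parameters
    ----------
    masks
        Map of nucleus class (``islet_live`` ...) to the per-slice boolean
        masks to save.  All classes are expected; the MSC folders are only
        written when ``cfg.analyze_msc``.
    counts
        A :class:`~viastack.viability.CountTable`.
    rois
        Optional :class:`~viastack.segmentation.RoiSet`; its label images
        go to ``Analyse/ROI_Save`` as 16-bit TIFFs.
    records
        Optional nucleus records, exported as ``nuclei.csv``.
    report
        Optional :class:`~viastack.viability.ViabilityReport`, exported as
        a text summary.
    """
    n_slices = {len(v) for v in masks.values()}
    if not masks or n_slices == {0}:
        raise ValidationError("no slices to write")
    base = Path(cfg.output_dir) / "Analyse"
    manifest: List[Path] = []

    for cls, folder in CLASS_FOLDERS.items():
        if cls.startswith("msc") and not cfg.analyze_msc:
            continue
        sub = base / folder
        sub.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(masks[cls]):
            p = sub / f"slice_{i + 1:02d}.tif"
            tifffile.imwrite(p, _mask_to_u8(np.asarray(m)))
            manifest.append(p)

    if rois is not None:
        sub = base / ROI_FOLDER
        sub.mkdir(parents=True, exist_ok=True)
        for i, lab in enumerate(rois.labels):
            p = sub / f"slice_{i + 1:02d}.tif"
            tifffile.imwrite(p, lab.astype(np.uint16))
            manifest.append(p)

    base.mkdir(parents=True, exist_ok=True)
    counts_path = base / "counts.csv"
    counts.to_frame().to_csv(counts_path, index=False)
    manifest.append(counts_path)

    if records is not None:
        from .nuclei import records_to_frame

        rec_path = base / "nuclei.csv"
        records_to_frame(records).to_csv(rec_path, index=False)
        manifest.append(rec_path)

    if report is not None:
        rep_path = base / "viability.txt"
        rep_path.write_text(report.summary())
        manifest.append(rep_path)

    return manifest
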