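"""Run configuration: a declarative YAML file replacing an interactive dialog.

Every tunable of the analysis is a named key so that runs are reproducible
and scriptable.  The three fluorescence channels are addressed by *role*:

``live_nuclei``
    DNA stain of all (living) cells, e.g. Hoechst 33342 — the blue channel.
``dead_nuclei``
    Membrane-impermeant DNA stain of necrotic cells, e.g. propidium
    iodide — the red channel.
``msc_cytosol``
    Membrane dye applied to the second cell type (MSCs) before
    encapsulation, e.g. PKH67 — the green channel that defines MSC
    territory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigurationError, ValidationError

CHANNEL_ROLES = ("live_nuclei", "dead_nuclei", "msc_cytosol")

DEFAULT_CHANNEL_NAMES = {
    "live_nuclei": "blue",
    "dead_nuclei": "red",
    "msc_cytosol": "green",
}

#: Keys that must be present in every config file.
REQUIRED_KEYS = ("input_dir",)

DEDUP_MODES = ("overlap", "centroid")


@dataclass
class RunConfig:
    """Validated parameters of one analysis run.

    Parameters
    ----------
    input_dir
        Folder holding the TIFF z-stacks.
    file_pattern
        Filename template with ``{slice}`` (1-based slice number, format
        specs like ``{slice:02d}`` allowed) and ``{channel}`` placeholders.
        A pattern without ``{slice}`` denotes one multi-page TIFF per
        channel.
    channel_names
        Map from channel role to the token substituted for ``{channel}``.
    threshold_min, threshold_max
        Closed intensity window ``[tmin, tmax]`` of the binary transform,
        on the same scale as the images.
    roi_dilation
        Radius in pixels of the isotropic disk dilation applied to
        detected cytosol regions before nuclei are assigned to them.
    min_area
        Minimum connected-component area in pixels^2; smaller signal is
        treated as debris and suppressed.  ``min_area_overrides`` may give
        a different value per channel role.
    enhance_blue_contrast
        Apply a percentile contrast stretch to the live-nuclei channel
        before thresholding (for dim stains).
    analyze_msc
        Whether MSC nuclei are reported.  They are always detected and
        erased from the islet working mask either way.
    dedup_mode, dedup_tolerance
        Rule deciding that a nucleus on slice z repeats one on slice z-1:
        ``overlap`` (footprints intersect) or ``centroid`` (seed distance
        <= tolerance pixels).
    watershed_h
        h-maxima depth used when splitting touching nuclei.
    """

    input_dir: Path
    output_dir: Optional[Path] = None
    file_pattern: str = "z{slice:02d}_{channel}.tif"
    channel_names: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_NAMES))
    threshold_min: float = 50.0
    threshold_max: float = 255.0
    roi_dilation: int = 3
    min_area: int = 20
    min_area_overrides: dict = field(default_factory=dict)
    enhance_blue_contrast: bool = False
    analyze_msc: bool = True
    dedup_mode: str = "overlap"
    dedup_tolerance: float = 5.0
    watershed_h: float = 2.0
    seed: Optional[int] = None

    def __post_init__(self):
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir) if self.output_dir is not None else self.input_dir
        self.validate()

    def validate(self) -> None:
        if self.threshold_min >= self.threshold_max:
            raise ValidationError(
                f"threshold_min ({self.threshold_min}) must be strictly below "
                f"threshold_max ({self.threshold_max})"
            )
        for name in ("roi_dilation", "min_area", "dedup_tolerance", "watershed_h"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        missing = [r for r in CHANNEL_ROLES if r not in self.channel_names]
        if missing:
            raise ConfigurationError(f"channel_names lacks roles: {', '.join(missing)}")
        tokens = [self.channel_names[r] for r in CHANNEL_ROLES]
        if len(set(tokens)) != len(tokens):
            raise ValidationError(f"channel_names tokens must be distinct, got {tokens}")
        if self.dedup_mode not in DEDUP_MODES:
            raise ValidationError(
                f"dedup_mode must be one of {DEDUP_MODES}, got {self.dedup_mode!r}"
            )

    def min_area_for(self, role: str) -> int:
        """Effective minimum area for a channel role (override or global)."""
        return int(self.min_area_overrides.get(role, self.min_area))

    def with_overrides(self, **kwargs) -> "RunConfig":
        """Return a copy with the given fields replaced (None values ignored)."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates)


_FIELD_NAMES = {f.name for f in fields(RunConfig)}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Raises
    ------
    ConfigurationError
        If the file is missing, unparseable, has unknown keys, or lacks a
        required key (the message names the key).
    ValidationError
        If a value violates an invariant, e.g. an empty threshold window.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _FIELD_NAMES
    if unknown:
        raise ConfigurationError(f"unknown config keys: {', '.join(sorted(unknown))}")
    for key in REQUIRED_KEYS:
        if key not in raw:
            raise ConfigurationError(f"missing required config key: {key!r}")
    return RunConfig(**raw)
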