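"""End-to-end orchestration: stacks in, viability report and files out."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

from .config import CHANNEL_ROLES, RunConfig
from .nuclei import NucleusRecord, run_nucleus_pass
from .segmentation import RoiSet
from .stacks import ChannelStack, read_stack
from .viability import CountTable, ViabilityReport, compute_viability, tabulate


@dataclass
class AnalysisResult:
    """Everything one run produces, before anything touches disk."""

    records: List[NucleusRecord]
    masks: Dict[str, list]
    rois: RoiSet
    counts: CountTable
    report: ViabilityReport


def analyze(stacks: Dict[str, ChannelStack], cfg: RunConfig) -> AnalysisResult:
    """Run segmentation, the nucleus pass, and viability on in-memory stacks."""
    records, masks, rois = run_nucleus_pass(stacks, cfg)
    counts = tabulate(records, n_slices=stacks["live_nuclei"].n_slices)
    report = compute_viability(counts)
    return AnalysisResult(records=records, masks=masks, rois=rois, counts=counts, report=report)


def analyze_folder(cfg: RunConfig) -> AnalysisResult:
    """Read the three channel stacks per the config and analyze them."""
    stacks = {role: read_stack(cfg, role) for role in CHANNEL_ROLES}
    return analyze(stacks, cfg)
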