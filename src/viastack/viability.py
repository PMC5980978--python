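"""Counting, per-cell-type viability, and method comparison statistics.

Viability of a cell type is the fraction of its nuclei carrying the
live-cell stain:

    viability = live / (live + dead)

computed separately for islet and MSC nuclei.  It is kept as a fraction in
[0, 1] internally and rendered as a percentage on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .nuclei import NucleusRecord

CLASSES = ("islet_live", "islet_dead", "msc_live", "msc_dead")


@dataclass
class CountTable:
    """Per-slice and total nucleus counts and summed areas per class."""

    per_slice: pd.DataFrame  # columns: slice, class, count, total_area_px
    totals: Dict[str, int]
    total_areas: Dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with per-slice rows plus 'total' rows."""
        total_rows = pd.DataFrame(
            {
                "slice": "total",
                "class": list(CLASSES),
                "count": [self.totals[c] for c in CLASSES],
                "total_area_px": [self.total_areas[c] for c in CLASSES],
            }
        )
        return pd.concat([self.per_slice, total_rows], ignore_index=True)

    def scaled(self, k: int) -> "CountTable":
        """Counts and areas multiplied by a positive integer (for invariance checks)."""
        if k <= 0:
            raise ValidationError("scale factor must be positive")
        ps = self.per_slice.copy()
        ps["count"] *= k
        ps["total_area_px"] *= k
        return CountTable(
            per_slice=ps,
            totals={c: v * k for c, v in self.totals.items()},
            total_areas={c: v * k for c, v in self.total_areas.items()},
        )


def tabulate(records: Sequence[NucleusRecord], n_slices: Optional[int] = None) -> CountTable:
    """Aggregate deduplicated nucleus records into a count table.

    Records with ``dedup_of`` set are excluded from both counts and summed
    areas.  ``n_slices`` pads the per-slice table with empty slices (zero
    rows are kept so every slice appears for every class).
    """
    surviving = [r for r in records if not r.is_duplicate]
    if n_slices is None:
        n_slices = 1 + max((r.slice_index for r in records), default=-1)
    counts = {(z, c): 0 for z in range(n_slices) for c in CLASSES}
    areas = {(z, c): 0 for z in range(n_slices) for c in CLASSES}
    for r in surviving:
        if r.compartment not in ("islet", "msc") or r.vital_state not in ("live", "dead"):
            raise ValidationError(f"record {r.id} lacks a class assignment")
        key = (r.slice_index, f"{r.compartment}_{r.vital_state}")
        counts[key] += 1
        areas[key] += r.area_px
    per_slice = pd.DataFrame(
        [
            {"slice": z, "class": c, "count": counts[(z, c)], "total_area_px": areas[(z, c)]}
            for z in range(n_slices)
            for c in CLASSES
        ]
    )
    totals = {c: sum(counts[(z, c)] for z in range(n_slices)) for c in CLASSES}
    total_areas = {c: sum(areas[(z, c)] for z in range(n_slices)) for c in CLASSES}
    return CountTable(per_slice=per_slice, totals=totals, total_areas=total_areas)


@dataclass
class ViabilityReport:
    """Per-cell-type viability fractions; None when no nuclei of that type."""

    islet_viability: Optional[float]
    msc_viability: Optional[float]
    counts: CountTable

    def summary(self) -> str:
        lines = []
        for name, v in (("islet", self.islet_viability), ("MSC", self.msc_viability)):
            if v is None:
                lines.append(f"{name} viability: undefined (no nuclei detected)")
            else:
                lines.append(f"{name} viability: {100 * v:.2f}%")
        t = self.counts.totals
        lines.append(
            "counts: islet live=%d dead=%d, MSC live=%d dead=%d"
            % (t["islet_live"], t["islet_dead"], t["msc_live"], t["msc_dead"])
        )
        return "\n".join(lines) + "\n"


def _ratio(live: int, dead: int) -> Optional[float]:
    total = live + dead
    return live / total if total > 0 else None


def compute_viability(counts: CountTable) -> ViabilityReport:
    """live / (live + dead) per cell type; flagged None on a zero denominator."""
    t = counts.totals
    return ViabilityReport(
        islet_viability=_ratio(t["islet_live"], t["islet_dead"]),
        msc_viability=_ratio(t["msc_live"], t["msc_dead"]),
        counts=counts,
    )


@dataclass
class MethodComparison:
    """Agreement statistics between two viability measurements of the same stacks."""

    pairs: List[Tuple[float, float]]
    mean_abs_diff_pp: float
    reference_mean: float
    reference_sd: float
    automated_mean: float
    automated_sd: float
    pearson_r: Optional[float]
    pearson_p: Optional[float]

    def summary(self) -> str:
        r = "undefined (zero variance)" if self.pearson_r is None else f"{self.pearson_r:.3f}"
        p = "-" if self.pearson_p is None else f"{self.pearson_p:.3g}"
        return (
            f"n pairs: {len(self.pairs)}\n"
            f"reference: {100 * self.reference_mean:.2f} +/- {100 * self.reference_sd:.2f}%\n"
            f"automated: {100 * self.automated_mean:.2f} +/- {100 * self.automated_sd:.2f}%\n"
            f"mean |difference|: {self.mean_abs_diff_pp:.2f} percentage points\n"
            f"Pearson r: {r} (p = {p})\n"
        )


def compare_methods(pairs: Sequence[Tuple[float, float]]) -> MethodComparison:
    """Compare paired viabilities (reference vs automated) across stacks.

    Reports mean +/- SD per method, the mean absolute difference in
    percentage points, and the Pearson product-moment correlation with a
    two-sided p-value from the t transform on n-2 degrees of freedom.
    Requires at least 3 pairs; a zero-variance vector leaves r flagged as
    undefined rather than raising.
    """
    pairs = [(float(a), float(b)) for a, b in pairs]
    if len(pairs) < 3:
        raise ValidationError(f"need at least 3 pairs for a correlation, got {len(pairs)}")
    arr = np.asarray(pairs, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValidationError("viabilities must be fractions in [0, 1]")
    ref, auto = arr[:, 0], arr[:, 1]
    if np.ptp(ref) == 0 or np.ptp(auto) == 0:
        r = p = None
    else:
        r, p = stats.pearsonr(ref, auto)
        r, p = float(r), float(p)
    return MethodComparison(
        pairs=pairs,
        mean_abs_diff_pp=float(np.mean(np.abs(ref - auto)) * 100.0),
        reference_mean=float(ref.mean()),
        reference_sd=float(ref.std(ddof=1)),
        automated_mean=float(auto.mean()),
        automated_sd=float(auto.std(ddof=1)),
        pearson_r=r,
        pearson_p=p,
    )
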