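"""Mutant allele burden and limit-of-blank thresholds for MRD calling.

The mutant allele burden (MAB) at a tracked mutation locus is the
percentage of all reads carrying the mutant base. A sample is called
MRD-positive at a marker when its MAB strictly exceeds that marker's
limit of blank (LoB), estimated from mutation-negative ("blank")
samples as mean background error + 3 standard deviations. The SD is the
sample SD (n-1 denominator), following standard limit-of-blank
practice.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .io_counts import BaseCount, CountTable, MutationMarker

LOB_SD_MULTIPLIER = 3.0


@dataclass(frozen=True)
class LoB:
    """Limit of blank for one mutation marker: mean blank %BE + 3 SD."""

    label: str
    mean_be: float
    sd_be: float
    lob: float
    n_blanks: int


@dataclass(frozen=True)
class MABResult:
    label: str
    mab: float          # percent of all reads carrying the mutant base
    depth: int
    above_lob: Optional[bool] = None
    lob: Optional[float] = None


def mutant_allele_burden(bc: BaseCount, marker: MutationMarker) -> MABResult:
    """MAB = 100 * mutant-base count / total depth.

    The denominator is the full four-base depth, the conventional
    allele-burden definition; hemizygous X loci use the same formula.
    """
    depth = bc.depth
    if depth == 0:
        raise ZeroDivisionError(f"zero depth at {bc.locus}: marker {marker.label} not evaluable")
    return MABResult(label=marker.label, mab=100.0 * bc.counts[marker.mut] / depth, depth=depth)


def estimate_lob(blank_mabs: Sequence[float], label: str = "", k: float = LOB_SD_MULTIPLIER) -> LoB:
    """LoB from mutant-base percentages observed in mutation-negative samples."""
    if len(blank_mabs) < 2:
        raise ValueError("at least 2 blank measurements required (SD undefined otherwise)")
    mean = statistics.fmean(blank_mabs)
    sd = statistics.stdev(blank_mabs)
    return LoB(label=label, mean_be=mean, sd_be=sd, lob=mean + k * sd, n_blanks=len(blank_mabs))


def call_mrd(mab: MABResult, lob: LoB) -> MABResult:
    """Flag a measurement as MRD-positive when MAB is strictly above the LoB."""
    if mab.label != lob.label:
        raise ValueError(f"marker label mismatch: {mab.label!r} vs {lob.label!r}")
    return MABResult(
        label=mab.label, mab=mab.mab, depth=mab.depth,
        above_lob=mab.mab > lob.lob, lob=lob.lob,
    )


def lob_from_blanks(
    blanks: Sequence[CountTable], marker: MutationMarker, k: float = LOB_SD_MULTIPLIER
) -> LoB:
    """Estimate a marker's LoB directly from blank-sample count tables.

    Blanks that do not cover the locus are skipped; at least two covering
    blanks are required.
    """
    mabs = []
    for table in blanks:
        bc = table.get(marker.locus)
        if bc is None or bc.depth == 0:
            continue
        mabs.append(mutant_allele_burden(bc, marker).mab)
    return estimate_lob(mabs, label=marker.label, k=k)


def mrd_report_frame(sample_id: str, results: Sequence[MABResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": sample_id,
                "label": r.label,
                "mab": round(r.mab, 2),
                "depth": r.depth,
                "lob": round(r.lob, 3) if r.lob is not None else "NA",
                "above_lob": r.above_lob if r.above_lob is not None else "NA",
            }
            for r in results
        ]
    )
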