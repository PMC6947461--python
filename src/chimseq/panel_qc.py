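"""Stepwise SNP-marker evaluation and selection for chimerism analysis.

Candidate panel SNPs are first restricted to a population heterozygosity
window (default 0.2–0.8) so that unrelated donor–recipient pairs are
likely to differ in genotype, then evaluated over a cohort of samples
against three per-marker criteria:

1. mean read depth strictly greater than 500,
2. mean % background error (reads supporting neither panel allele) at
   most 0.2%,
3. mean % measurement error of heterozygous calls (imbalance between
   the two allele counts) strictly below 10%.

Sex-chromosome SNPs are excluded by default: the burden formulas assume
two autosomal copies per cell.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import pandas as pd

from .chimerism import DEFAULT_BANDS, Genotype, GenotypeBands, call_genotype
from .io_counts import BaseCount, CountTable, SNPMarker

logger = logging.getLogger(__name__)

SEX_CHROMS = {"X", "Y"}

DEPTH_MIN = 500.0     # mean depth must exceed this
BE_MAX = 0.2          # %BE at most this
ME_MAX = 10.0         # %ME strictly below this


def background_error(bc: BaseCount, marker: SNPMarker) -> float:
    """% of reads supporting neither panel allele at a SNP.

    Treats ref+alt as signal and everything else as noise; with
    four-base counts this is ``100 * (depth - ref - alt) / depth``.
    """
    depth = bc.depth
    if depth == 0:
        raise ZeroDivisionError(f"zero depth at {bc.locus}")
    off = depth - bc.counts[marker.ref_allele] - bc.counts[marker.alt_allele]
    return 100.0 * off / depth


def measurement_error(bc: BaseCount, marker: SNPMarker) -> float:
    """% imbalance between the two allele counts of a heterozygous call:
    ``100 * |ref - alt| / (ref + alt)``."""
    n_ref = bc.counts[marker.ref_allele]
    n_alt = bc.counts[marker.alt_allele]
    total = n_ref + n_alt
    if total == 0:
        raise ZeroDivisionError(f"no reads on panel alleles at {bc.locus}")
    return 100.0 * abs(n_ref - n_alt) / total


def filter_by_het_freq(
    panel: Sequence[SNPMarker], lo: float = 0.2, hi: float = 0.8
) -> list[SNPMarker]:
    """Markers whose population heterozygosity lies in [lo, hi], order preserved."""
    if not 0.0 <= lo <= hi <= 1.0:
        raise ValueError(f"invalid heterozygosity window [{lo}, {hi}]")
    return [m for m in panel if lo <= m.het_freq <= hi]


def filter_autosomal(panel: Sequence[SNPMarker]) -> list[SNPMarker]:
    return [m for m in panel if m.locus.chrom.upper() not in SEX_CHROMS]


@dataclass
class SNPQCRecord:
    """Per-marker QC summary over the evaluation cohort.

    ``pct_me`` is ``None`` when the marker was never called heterozygous
    in the cohort; the measurement-error criterion then passes vacuously
    but ``me_evaluable`` flags the gap in the report.
    """

    marker: SNPMarker
    mean_depth: float
    pct_be: float
    pct_me: Optional[float]
    n_samples: int
    n_het: int
    pass_depth: bool
    pass_be: bool
    pass_me: bool

    @property
    def me_evaluable(self) -> bool:
        return self.n_het > 0

    @property
    def passed(self) -> bool:
        return self.pass_depth and self.pass_be and self.pass_me


Genotyper = Callable[[BaseCount, SNPMarker], object]


def evaluate_panel(
    panel: Sequence[SNPMarker],
    cohort: Sequence[CountTable],
    genotyper: Optional[Genotyper] = None,
    *,
    depth_min: float = DEPTH_MIN,
    be_max: float = BE_MAX,
    me_max: float = ME_MAX,
    bands: GenotypeBands = DEFAULT_BANDS,
) -> list[SNPQCRecord]:
    """Evaluate every marker over the cohort and apply the three criteria.

    Depth and %BE are unweighted means over all samples covering the
    marker; %ME is the unweighted mean over samples genotyped
    heterozygous. Comparisons are exactly ``depth > depth_min``,
    ``be <= be_max``, ``me < me_max``.
    """
    if not cohort:
        raise ValueError("QC cohort must be non-empty")
    if genotyper is None:
        genotyper = lambda bc, m: call_genotype(bc, m, bands)  # noqa: E731
    records = []
    for marker in panel:
        depths: list[float] = []
        bes: list[float] = []
        mes: list[float] = []
        for table in cohort:
            bc = table.get(marker.locus)
            if bc is None or bc.depth == 0:
                continue
            depths.append(float(bc.depth))
            bes.append(background_error(bc, marker))
            gt = genotyper(bc, marker)
            if getattr(gt, "call", gt) == Genotype.HET:
                mes.append(measurement_error(bc, marker))
        if not depths:
            records.append(
                SNPQCRecord(marker, 0.0, 0.0, None, 0, 0, False, False, False)
            )
            continue
        mean_depth = sum(depths) / len(depths)
        pct_be = sum(bes) / len(bes)
        pct_me = sum(mes) / len(mes) if mes else None
        records.append(
            SNPQCRecord(
                marker=marker,
                mean_depth=mean_depth,
                pct_be=pct_be,
                pct_me=pct_me,
                n_samples=len(depths),
                n_het=len(mes),
                pass_depth=mean_depth > depth_min,
                pass_be=pct_be <= be_max,
                # never-het markers pass vacuously; flagged via me_evaluable
                pass_me=(pct_me < me_max) if pct_me is not None else True,
            )
        )
    return records


def select_markers(qc: Sequence[SNPQCRecord]) -> list[SNPMarker]:
    """Markers passing all three criteria; warns (not errors) when none do."""
    selected = [rec.marker for rec in qc if rec.passed]
    if qc and not selected:
        warnings.warn("no SNP markers passed QC selection", stacklevel=2)
    for rec in qc:
        if rec.passed and not rec.me_evaluable:
            logger.info(
                "marker %s selected with no heterozygous sample in cohort "
                "(measurement error unassessed)", rec.marker.id,
            )
    return selected


def qc_report_frame(qc: Sequence[SNPQCRecord]) -> pd.DataFrame:
    rows = [
        {
            "id": rec.marker.id,
            "chrom": rec.marker.locus.chrom,
            "pos": rec.marker.locus.pos,
            "mean_depth": round(rec.mean_depth, 1),
            "pct_be": round(rec.pct_be, 4),
            "pct_me": round(rec.pct_me, 4) if rec.pct_me is not None else "NA",
            "n_samples": rec.n_samples,
            "pass_depth": rec.pass_depth,
            "pass_be": rec.pass_be,
            "pass_me": rec.pass_me,
            "pass": rec.passed,
        }
        for rec in qc
    ]
    return pd.DataFrame(rows)


def write_qc_report(qc: Sequence[SNPQCRecord], path) -> None:
    qc_report_frame(qc).to_csv(path, sep="\t", index=False)
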