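"""Rule chain reducing an annotated variant table to MRD markers.

Candidate somatic variants from the myeloid panel are filtered against
population databases (any minor allele frequency > 0.01 removes the
variant), then retained as leukemia-associated markers when either
recurrently reported in hematopoietic tissue in a somatic-mutation
catalogue (> 3 entries) or a truncating/splice variant in a gene whose
known mechanism is loss of function. All database evidence arrives as
input columns; this module never queries external services.

A simplified, configurable evidence map assigns clinical tiers
(1 strong ... 4 benign/common); the full AMP guideline is a clinical
framework rather than an algorithm, so the map is an explicit
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import pandas as pd

from .io_counts import GenomicLocus

LOF_CONSEQUENCES = {"nonsense", "frameshift", "splice_site"}
CONSEQUENCES = {"missense", "nonsense", "frameshift", "splice_site", "synonymous", "other"}

MAF_COMMON = 0.01        # strictly greater is filtered out
COSMIC_MIN = 3           # "more than three" -> strictly greater


@dataclass(frozen=True)
class AnnotatedVariant:
    locus: GenomicLocus
    ref: str
    alt: str
    gene: str
    consequence: str
    maf_exac: Optional[float] = None
    maf_gnomad: Optional[float] = None
    maf_kova: Optional[float] = None
    cosmic_haem_count: Optional[int] = None
    gene_mechanism_lof: bool = False
    tier: Optional[int] = None
    review_flag: str = ""    # manual-review annotation; passed through untouched

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        for name in ("maf_exac", "maf_gnomad", "maf_kova"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1] (got {v})")
        if self.cosmic_haem_count is not None and self.cosmic_haem_count < 0:
            raise ValueError("cosmic_haem_count must be >= 0")

    @property
    def mafs(self) -> list[float]:
        return [v for v in (self.maf_exac, self.maf_gnomad, self.maf_kova) if v is not None]

    @property
    def is_common(self) -> bool:
        return any(v > MAF_COMMON for v in self.mafs)


def filter_common(variants: Sequence[AnnotatedVariant]) -> list[AnnotatedVariant]:
    """Remove variants common in any population database (MAF > 0.01).

    Absent MAF values are treated as not common — a variant unseen in
    the databases is a candidate somatic event, not a polymorphism.
    """
    return [v for v in variants if not v.is_common]


def _has_marker_evidence(v: AnnotatedVariant) -> bool:
    recurrent = (v.cosmic_haem_count or 0) > COSMIC_MIN
    lof = v.consequence in LOF_CONSEQUENCES and v.gene_mechanism_lof
    return recurrent or lof


def select_markers(variants: Sequence[AnnotatedVariant]) -> list[AnnotatedVariant]:
    """Keep leukemia-associated candidates: hematopoietic recurrence in the
    somatic catalogue (> 3 reports) or loss-of-function variants in
    LoF-mechanism genes. Input should already have passed
    :func:`filter_common`."""
    return [v for v in variants if _has_marker_evidence(v)]


@dataclass(frozen=True)
class TierConfig:
    """Evidence map for the simplified tier assignment.

    ``tier1_min_cosmic``: hematopoietic recurrence count at or above
    which a retained variant is tier 1 (well-established hotspot).
    """

    tier1_min_cosmic: int = 10


DEFAULT_TIERS = TierConfig()


def assign_tier(v: AnnotatedVariant, config: TierConfig = DEFAULT_TIERS) -> AnnotatedVariant:
    """Return a copy with a tier set; the input variant is not mutated.

    Tier 4: common polymorphism (would be removed by filter_common).
    Tier 1: retained with strong catalogue recurrence.
    Tier 2: retained on recurrence or LoF-mechanism evidence.
    Tier 3: rare but evidence-light (variant of uncertain significance).
    """
    if v.is_common:
        tier = 4
    elif (v.cosmic_haem_count or 0) >= config.tier1_min_cosmic:
        tier = 1
    elif _has_marker_evidence(v):
        tier = 2
    else:
        tier = 3
    return replace(v, tier=tier)


def filter_pipeline(
    variants: Sequence[AnnotatedVariant], config: TierConfig = DEFAULT_TIERS
) -> list[AnnotatedVariant]:
    """filter_common -> select_markers -> assign_tier, in order."""
    kept = select_markers(filter_common(variants))
    return [assign_tier(v, config) for v in kept]


_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence",
    "maf_exac", "maf_gnomad", "maf_kova", "cosmic_haem_count",
    "gene_mechanism_lof", "tier", "review_flag",
]


def _opt_float(x) -> Optional[float]:
    if x is None or (isinstance(x, str) and x.strip() in ("", "NA", ".")) or pd.isna(x):
        return None
    return float(x)


def read_variant_table(path) -> list[AnnotatedVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    out = []
    for _, row in df.iterrows():
        cosmic = _opt_float(row.get("cosmic_haem_count"))
        tier = _opt_float(row.get("tier"))
        out.append(
            AnnotatedVariant(
                locus=GenomicLocus(row["chrom"], int(row["pos"])),
                ref=row["ref"],
                alt=row["alt"],
                gene=row["gene"],
                consequence=row["consequence"],
                maf_exac=_opt_float(row.get("maf_exac")),
                maf_gnomad=_opt_float(row.get("maf_gnomad")),
                maf_kova=_opt_float(row.get("maf_kova")),
                cosmic_haem_count=int(cosmic) if cosmic is not None else None,
                gene_mechanism_lof=str(row.get("gene_mechanism_lof", "False")).strip().lower()
                in ("true", "1", "yes"),
                tier=int(tier) if tier is not None else None,
                review_flag="" if pd.isna(row.get("review_flag")) else str(row.get("review_flag")),
            )
        )
    return out


def write_variant_table(variants: Sequence[AnnotatedVariant], path) -> None:
    rows = []
    for v in variants:
        rows.append(
            {
                "chrom": f"chr{v.locus.chrom}",
                "pos": v.locus.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "consequence": v.consequence,
                "maf_exac": v.maf_exac if v.maf_exac is not None else "NA",
                "maf_gnomad": v.maf_gnomad if v.maf_gnomad is not None else "NA",
                "maf_kova": v.maf_kova if v.maf_kova is not None else "NA",
                "cosmic_haem_count": v.cosmic_haem_count if v.cosmic_haem_count is not None else "NA",
                "gene_mechanism_lof": v.gene_mechanism_lof,
                "tier": v.tier if v.tier is not None else "NA",
                "review_flag": v.review_flag,
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)
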