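"""Per-locus base-count tables and marker panel I/O.

The whole pipeline operates on counts of the four bases (A, C, G, T) at
targeted genomic positions, one table per sample, as produced by an
upstream pileup-counting step. This module defines the domain types
(:class:`GenomicLocus`, :class:`BaseCount`, :class:`CountTable`,
:class:`SNPMarker`, :class:`MutationMarker`), the TSV readers/writers,
and the elementary allele-fraction computation every downstream module
builds on.

Coordinates are 1-based and fully closed throughout. Chromosome names
are compared after stripping an optional ``chr`` prefix, so ``chr1``,
``Chr1`` and ``1`` all refer to the same chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

import pandas as pd

BASES = ("A", "C", "G", "T")

COUNT_TABLE_COLUMNS = ["chrom", "pos", "ref", "A", "C", "G", "T"]
SNP_PANEL_COLUMNS = ["id", "chrom", "pos", "ref_allele", "alt_allele", "het_freq"]
MUTATION_MARKER_COLUMNS = ["label", "chrom", "pos", "ref", "mut"]


class CountTableError(ValueError):
    """Malformed or inconsistent count-table input."""


class UndefinedFractionError(ZeroDivisionError):
    """Allele fraction requested over a zero-count denominator."""


def normalize_chrom(chrom: str) -> str:
    """Strip an optional ``chr`` prefix (case-insensitive) from a chromosome name."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        return c[3:]
    # tolerate the occasional 'Ch21'-style truncation seen in clinical tables
    if c.lower().startswith("ch") and c[2:3].isdigit():
        return c[2:]
    return c


@dataclass(frozen=True, order=True)
class GenomicLocus:
    """A 1-based genomic position; chromosome names are stored normalised."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        norm = normalize_chrom(self.chrom)
        if not norm:
            raise ValueError("chromosome name must be non-empty")
        object.__setattr__(self, "chrom", norm)
        if self.pos < 1:
            raise ValueError(f"position must be >= 1 (got {self.pos})")

    def __str__(self) -> str:  # Chr1:115258747 style
        return f"Chr{self.chrom}:{self.pos}"


def _check_base(base: str, what: str = "base") -> str:
    b = str(base).strip().upper()
    if b not in BASES:
        raise ValueError(f"{what} must be one of A/C/G/T (got {base!r})")
    return b


@dataclass(frozen=True)
class BaseCount:
    """Counts of the four bases at one locus in one sample.

    ``depth`` is always the sum of the four counts; it is derived, never
    supplied independently.
    """

    locus: GenomicLocus
    ref: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", _check_base(self.ref, "ref"))
        clean = {}
        for b in BASES:
            n = int(self.counts.get(b, 0))
            if n < 0:
                raise ValueError(f"negative count for {b} at {self.locus}: {n}")
            clean[b] = n
        extra = set(self.counts) - set(BASES)
        if extra:
            raise ValueError(f"non-ACGT base keys at {self.locus}: {sorted(extra)}")
        object.__setattr__(self, "counts", clean)

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def count(self, base: str) -> int:
        return self.counts[_check_base(base)]


def allele_fraction(bc: BaseCount, allele: str, denominator_alleles: Iterable[str]) -> float:
    """Fraction of reads supporting ``allele`` among reads supporting any
    of ``denominator_alleles``.

    Raises :class:`UndefinedFractionError` when no read supports any
    denominator allele — a zero denominator carries no information and is
    never silently treated as 0.
    """
    allele = _check_base(allele, "allele")
    denom_set = {_check_base(b, "denominator allele") for b in denominator_alleles}
    denom = sum(bc.counts[b] for b in denom_set)
    if denom == 0:
        raise UndefinedFractionError(
            f"no reads support any of {sorted(denom_set)} at {bc.locus}"
        )
    return bc.counts[allele] / denom


@dataclass(frozen=True)
class SNPMarker:
    """A biallelic panel SNP with its population heterozygosity frequency."""

    locus: GenomicLocus
    ref_allele: str
    alt_allele: str
    het_freq: float
    id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref_allele", _check_base(self.ref_allele, "ref_allele"))
        object.__setattr__(self, "alt_allele", _check_base(self.alt_allele, "alt_allele"))
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.locus}")
        if not 0.0 <= self.het_freq <= 1.0:
            raise ValueError(f"het_freq must be in [0,1] (got {self.het_freq})")
        if not self.id:
            object.__setattr__(self, "id", str(self.locus))

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class MutationMarker:
    """A patient-specific mutation locus tracked for residual disease."""

    locus: GenomicLocus
    ref: str
    mut: str
    label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", _check_base(self.ref, "ref"))
        object.__setattr__(self, "mut", _check_base(self.mut, "mut"))
        if self.ref == self.mut:
            raise ValueError(f"ref and mut bases identical at {self.locus}")


@dataclass
class CountTable:
    """All base counts for one sample, indexed by locus."""

    sample_id: str
    records: dict[GenomicLocus, BaseCount] = field(default_factory=dict)

    def add(self, bc: BaseCount) -> None:
        if bc.locus in self.records:
            raise CountTableError(
                f"duplicate locus {bc.locus} in sample {self.sample_id!r}"
            )
        self.records[bc.locus] = bc

    def get(self, locus: GenomicLocus) -> Optional[BaseCount]:
        """The stored record, or ``None`` when the locus is not covered.

        Absence is explicit: downstream code treats it as "marker not
        covered", never as a zero-count observation.
        """
        return self.records.get(locus)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BaseCount]:
        return iter(self.records.values())

    def __contains__(self, locus: GenomicLocus) -> bool:
        return locus in self.records


def counts_at(table: CountTable, locus: GenomicLocus) -> Optional[BaseCount]:
    """Functional alias for :meth:`CountTable.get`."""
    return table.get(locus)


def _read_tsv(path, required_columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise CountTableError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {required_columns}"
        )
    return df


def read_count_table(path, sample_id: str) -> CountTable:
    """Read a per-locus base-count TSV (header ``chrom pos ref A C G T``).

    Every row becomes one :class:`BaseCount`; depth is the sum of the four
    counts. Malformed rows raise :class:`CountTableError` naming the line
    number (header = line 1); duplicated loci are rejected.
    """
    df = _read_tsv(path, COUNT_TABLE_COLUMNS)
    table = CountTable(sample_id=sample_id)
    for idx, row in df.iterrows():
        line_no = int(idx) + 2
        try:
            locus = GenomicLocus(row["chrom"], int(row["pos"]))
            counts = {}
            for b in BASES:
                n = int(row[b])
                if n < 0:
                    raise ValueError(f"negative count {n} for base {b}")
                counts[b] = n
            bc = BaseCount(locus=locus, ref=row["ref"], counts=counts)
        except (ValueError, TypeError) as exc:
            raise CountTableError(f"{path}: line {line_no}: {exc}") from exc
        table.add(bc)
    return table


def write_count_table(table: CountTable, path) -> None:
    rows = [
        {
            "chrom": f"chr{bc.locus.chrom}",
            "pos": bc.locus.pos,
            "ref": bc.ref,
            **{b: bc.counts[b] for b in BASES},
        }
        for bc in sorted(table, key=lambda bc: bc.locus)
    ]
    pd.DataFrame(rows, columns=COUNT_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_snp_panel(path) -> list[SNPMarker]:
    """Read a SNP panel TSV (header ``id chrom pos ref_allele alt_allele het_freq``)."""
    df = _read_tsv(path, SNP_PANEL_COLUMNS)
    markers = []
    seen: set[GenomicLocus] = set()
    for idx, row in df.iterrows():
        line_no = int(idx) + 2
        try:
            marker = SNPMarker(
                locus=GenomicLocus(row["chrom"], int(row["pos"])),
                ref_allele=row["ref_allele"],
                alt_allele=row["alt_allele"],
                het_freq=float(row["het_freq"]),
                id=str(row["id"]),
            )
        except (ValueError, TypeError) as exc:
            raise CountTableError(f"{path}: line {line_no}: {exc}") from exc
        if marker.locus in seen:
            raise CountTableError(f"{path}: line {line_no}: duplicate locus {marker.locus}")
        seen.add(marker.locus)
        markers.append(marker)
    return markers


def read_mutation_markers(path) -> list[MutationMarker]:
    """Read a mutation-marker TSV (header ``label chrom pos ref mut``)."""
    df = _read_tsv(path, MUTATION_MARKER_COLUMNS)
    markers = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2
        try:
            markers.append(
                MutationMarker(
                    locus=GenomicLocus(row["chrom"], int(row["pos"])),
                    ref=row["ref"],
                    mut=row["mut"],
                    label=str(row["label"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise CountTableError(f"{path}: line {line_no}: {exc}") from exc
    return markers
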