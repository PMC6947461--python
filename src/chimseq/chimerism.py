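"""SNP-based donor chimerism from panel allele counts.

After allogeneic HSCT the blood is a mixture of donor- and
recipient-derived cells. At a biallelic SNP where the donor is
homozygous and differs in genotype from the recipient, the donor cell
fraction f is identifiable from the post-transplant allele counts alone.
Writing A for the donor's homozygous allele and a for the other panel
allele, the per-SNP donor allele burden is

* ``A/(A+a)``        donor hom-A, recipient hom-a  (and the mirrored
  ``a/(A+a)`` when the labels are swapped),
* ``1 - 2*(a/(A+a))``  donor hom-A, recipient heterozygous (and its
  mirror).

Donor chimerism is the unweighted average of the per-SNP burdens, as a
percentage. Donor-heterozygous configurations carry no single-formula
estimator and are treated as non-informative.

Genotypes are called from allele fractions over the two panel alleles
only: homozygous when the major allele fraction is in [0.90, 1.00],
heterozygous when both fractions are in [0.45, 0.60]; fractions in the
gap give no call and the marker is dropped for that donor–recipient
pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .io_counts import BaseCount, CountTable, SNPMarker


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    NO_CALL = "no_call"


@dataclass(frozen=True)
class GenotypeBands:
    """Allele-fraction windows for genotype calling.

    Defaults follow established practice for count-based SNP genotyping:
    homozygous at major-allele fraction 0.90–1.00, heterozygous when both
    alleles fall in 0.45–0.60.
    """

    hom_lo: float = 0.90
    het_lo: float = 0.45
    het_hi: float = 0.60

    def __post_init__(self) -> None:
        if not (0.5 <= self.hom_lo <= 1.0 and 0.0 <= self.het_lo <= self.het_hi <= 1.0):
            raise ValueError(f"inconsistent genotype bands: {self}")


DEFAULT_BANDS = GenotypeBands()


@dataclass(frozen=True)
class GenotypeCall:
    marker_id: str
    call: Genotype
    major_fraction: Optional[float] = None  # over ref+alt counts; in [0.5, 1] when called
    reason: str = ""

    @property
    def is_called(self) -> bool:
        return self.call is not Genotype.NO_CALL


def call_genotype(bc: BaseCount, marker: SNPMarker, bands: GenotypeBands = DEFAULT_BANDS) -> GenotypeCall:
    """Call hom-ref / het / hom-alt from the ref+alt count fractions.

    Fractions are computed over the two panel alleles only; reads on the
    other two bases are background error and do not enter the denominator.
    """
    n_ref = bc.counts[marker.ref_allele]
    n_alt = bc.counts[marker.alt_allele]
    total = n_ref + n_alt
    if total == 0:
        return GenotypeCall(marker.id, Genotype.NO_CALL, None, "no coverage of panel alleles")
    f_ref = n_ref / total
    f_alt = n_alt / total
    major = max(f_ref, f_alt)
    if f_ref >= bands.hom_lo:
        return GenotypeCall(marker.id, Genotype.HOM_REF, major)
    if f_alt >= bands.hom_lo:
        return GenotypeCall(marker.id, Genotype.HOM_ALT, major)
    if bands.het_lo <= f_ref <= bands.het_hi and bands.het_lo <= f_alt <= bands.het_hi:
        return GenotypeCall(marker.id, Genotype.HET, major)
    return GenotypeCall(
        marker.id, Genotype.NO_CALL, major,
        f"allele fraction {major:.3f} outside genotype bands",
    )


@dataclass(frozen=True)
class InformativeConfig:
    """A donor/recipient genotype pair from which f is estimable.

    ``donor_allele`` is the donor's homozygous panel allele (the A of the
    burden formulas); ``other_allele`` is the remaining panel allele (a).
    ``formula_id`` 1/2 are the two hom/hom orientations, 3/4 the two
    donor-hom / recipient-het orientations.
    """

    marker_id: str
    donor_allele: str
    other_allele: str
    formula_id: int
    recipient_het: bool

    def __post_init__(self) -> None:
        if self.donor_allele == self.other_allele:
            raise ValueError("donor and other allele must differ")
        if self.formula_id not in (1, 2, 3, 4):
            raise ValueError(f"formula_id must be 1-4 (got {self.formula_id})")


def classify_informative(
    donor: GenotypeCall, recipient: GenotypeCall, marker: SNPMarker
) -> Optional[InformativeConfig]:
    """Map a (donor, recipient) genotype pair to one of the four
    informative configurations, or ``None`` when the pair carries no
    mixture signal (identical genotypes, donor het, or any no-call)."""
    if not donor.is_called or not recipient.is_called:
        return None
    d, r = donor.call, recipient.call
    ref, alt = marker.ref_allele, marker.alt_allele
    if d is Genotype.HOM_REF and r is Genotype.HOM_ALT:
        return InformativeConfig(marker.id, ref, alt, 1, recipient_het=False)
    if d is Genotype.HOM_ALT and r is Genotype.HOM_REF:
        return InformativeConfig(marker.id, alt, ref, 2, recipient_het=False)
    if d is Genotype.HOM_REF and r is Genotype.HET:
        return InformativeConfig(marker.id, ref, alt, 3, recipient_het=True)
    if d is Genotype.HOM_ALT and r is Genotype.HET:
        return InformativeConfig(marker.id, alt, ref, 4, recipient_het=True)
    return None


def donor_allele_burden(bc: BaseCount, config: InformativeConfig) -> tuple[float, float]:
    """Per-SNP donor-fraction estimate from post-transplant counts.

    Returns ``(raw, clamped)``: hom/hom configurations give
    ``raw = A/(A+a)``; donor-hom/recipient-het give
    ``raw = 1 - 2*(a/(A+a))``. Sampling noise can push raw values
    slightly outside [0, 1]; the clamped value is used for averaging.
    """
    n_A = bc.counts[config.donor_allele]
    n_a = bc.counts[config.other_allele]
    total = n_A + n_a
    if total == 0:
        raise ZeroDivisionError(
            f"no reads on panel alleles at {bc.locus} for marker {config.marker_id}"
        )
    if config.recipient_het:
        raw = 1.0 - 2.0 * (n_a / total)
    else:
        raw = n_A / total
    return raw, min(1.0, max(0.0, raw))


@dataclass
class PerSNPBurden:
    marker_id: str
    formula_id: int
    raw: float
    clamped: float
    donor_gt: Genotype
    recipient_gt: Genotype


@dataclass
class ChimerismResult:
    """Donor chimerism (%) with its per-SNP breakdown."""

    donor_chimerism: float
    n_informative: int
    per_snp: list[PerSNPBurden] = field(default_factory=list)
    sd_across_snps: float = 0.0
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (marker id, reason)

    def round_report(self) -> dict:
        return {
            "donor_chimerism": round(self.donor_chimerism, 2),
            "n_informative": self.n_informative,
            "sd_across_snps": round(self.sd_across_snps, 2),
        }


class NoInformativeMarkersError(RuntimeError):
    """Raised when a donor–recipient pair shares genotypes at every usable SNP."""


def compute_chimerism(
    donor_table: CountTable,
    recipient_table: CountTable,
    post_table: CountTable,
    panel: Sequence[SNPMarker],
    bands: GenotypeBands = DEFAULT_BANDS,
) -> ChimerismResult:
    """Full chimerism computation for one post-transplant sample.

    Genotypes are called on the donor and pre-transplant recipient
    tables; SNPs in an informative configuration contribute a burden
    computed from the post-transplant counts; donor chimerism is 100x the
    unweighted mean of the clamped burdens.

    Raises :class:`NoInformativeMarkersError` when no marker is
    informative — averaging over nothing would silently fabricate a
    result.
    """
    if not panel:
        raise ValueError("empty SNP panel")
    per_snp: list[PerSNPBurden] = []
    skipped: list[tuple[str, str]] = []
    for marker in panel:
        bc_d = donor_table.get(marker.locus)
        bc_r = recipient_table.get(marker.locus)
        bc_p = post_table.get(marker.locus)
        if bc_d is None or bc_r is None or bc_p is None:
            skipped.append((marker.id, "marker not covered in all three samples"))
            continue
        gt_d = call_genotype(bc_d, marker, bands)
        gt_r = call_genotype(bc_r, marker, bands)
        config = classify_informative(gt_d, gt_r, marker)
        if config is None:
            skipped.append((marker.id, f"non-informative ({gt_d.call.value}/{gt_r.call.value})"))
            continue
        if bc_p.counts[config.donor_allele] + bc_p.counts[config.other_allele] == 0:
            skipped.append((marker.id, "no post-transplant reads on panel alleles"))
            continue
        raw, clamped = donor_allele_burden(bc_p, config)
        per_snp.append(PerSNPBurden(marker.id, config.formula_id, raw, clamped, gt_d.call, gt_r.call))
    if not per_snp:
        raise NoInformativeMarkersError(
            "no informative markers for this donor-recipient pair"
        )
    burdens = [b.clamped for b in per_snp]
    mean = sum(burdens) / len(burdens)
    var = sum((b - mean) ** 2 for b in burdens) / len(burdens)
    return ChimerismResult(
        donor_chimerism=100.0 * mean,
        n_informative=len(per_snp),
        per_snp=per_snp,
        sd_across_snps=100.0 * math.sqrt(var),
        skipped=skipped,
    )
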