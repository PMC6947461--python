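"""Synthetic donor/recipient genotypes and mixed-chimerism base counts.

Generates everything the rest of the pipeline consumes, with known
ground truth: a SNP panel with population heterozygosity frequencies,
two diploid genotypes (unrelated by default, or full siblings sharing
parental haplotypes), base-count tables for the donor, the
pre-transplant recipient, and a post-transplant sample that is a
two-component cell mixture at donor fraction f, read-sampled at a
configurable depth with a uniform per-base substitution error.

Genotypes are drawn under Hardy–Weinberg equilibrium: a SNP with
population heterozygosity h has minor-allele frequency
p = (1 - sqrt(1 - 2h)) / 2 (the p <= 0.5 branch of 2p(1-p) = h), so h
may not exceed 0.5. Read counts at a locus are multinomial over the four
bases at the locus depth: the mixture allele fraction
f·(donor dosage)/2 + (1-f)·(recipient dosage)/2 sets the pre-error
base probabilities, and a read is miscalled with probability
``error_rate``, uniformly to the other three bases.

All outputs are reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_counts import BASES, BaseCount, CountTable, GenomicLocus, MutationMarker, SNPMarker


@dataclass(frozen=True)
class MutationSpec:
    """A mutation to spike into the post-transplant sample."""

    marker: MutationMarker
    true_mab: float  # percent

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_mab <= 100.0:
            raise ValueError(f"true_mab must be in [0,100] (got {self.true_mab})")


@dataclass
class SimConfig:
    """Study conditions for one simulated transplant.

    Defaults mirror the assay this emulates: a panel of SNPs with
    population heterozygosity 0.2-0.5, ~1400x mean depth, and a
    per-base error around 0.1% (panel-wide background error of a
    well-behaved hybrid-capture run).
    """

    n_snps: int = 121
    het_freqs: Optional[Sequence[float]] = None  # default: uniform over [0.2, 0.5]
    donor_fraction: float = 0.95
    depth: int = 1400
    error_rate: float = 0.001
    seed: int = 0
    related: bool = False    # full-sibling donor (shared parental haplotypes)
    mutations: list[MutationSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not 0.0 <= self.donor_fraction <= 1.0:
            raise ValueError("donor_fraction must be in [0,1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0,1]")
        if self.het_freqs is not None:
            hf = np.asarray(self.het_freqs, dtype=float)
            if hf.shape != (self.n_snps,):
                raise ValueError("het_freqs must have length n_snps")
            _check_het(hf)


def _check_het(h: np.ndarray) -> None:
    if np.any((h < 0) | (h > 0.5)):
        raise ValueError(
            "heterozygosity frequency must be in [0, 0.5] under Hardy-Weinberg "
            "(2p(1-p) <= 0.5 for any allele frequency p)"
        )


def het_to_allele_freq(het_freq) -> np.ndarray:
    """Minor-allele frequency implied by heterozygosity: the p <= 0.5
    solution of 2p(1-p) = h."""
    h = np.atleast_1d(np.asarray(het_freq, dtype=float))
    _check_het(h)
    return (1.0 - np.sqrt(1.0 - 2.0 * h)) / 2.0


def make_panel(config: SimConfig, rng: Optional[np.random.Generator] = None) -> list[SNPMarker]:
    """Synthesize a SNP panel: autosomal loci with distinct positions and
    random ref/alt base pairs."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if config.het_freqs is None:
        het = rng.uniform(0.2, 0.5, size=config.n_snps)
    else:
        het = np.asarray(config.het_freqs, dtype=float)
    chroms = rng.integers(1, 23, size=config.n_snps)
    positions = rng.choice(np.arange(10_000, 5_000_000), size=config.n_snps, replace=False)
    markers = []
    for i in range(config.n_snps):
        ref, alt = rng.choice(len(BASES), size=2, replace=False)
        markers.append(
            SNPMarker(
                locus=GenomicLocus(str(chroms[i]), int(positions[i])),
                ref_allele=BASES[ref],
                alt_allele=BASES[alt],
                het_freq=float(het[i]),
                id=f"snp{i:04d}",
            )
        )
    return markers


def _draw_genotype(p_alt: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Alt-allele dosage (0/1/2) per SNP under Hardy-Weinberg."""
    a1 = rng.random(p_alt.shape) < p_alt
    a2 = rng.random(p_alt.shape) < p_alt
    return a1.astype(int) + a2.astype(int)


def simulate_pair_genotypes(
    panel: Sequence[SNPMarker],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw donor and recipient alt-allele dosages at every panel SNP.

    Unrelated individuals are two independent Hardy-Weinberg draws. In
    ``related`` (full-sibling) mode, two parents are drawn and each
    individual inherits one allele from each parent — sharing parental
    haplotypes reduces the number of informative SNPs, as seen with
    sibling donors.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    p_alt = het_to_allele_freq([m.het_freq for m in panel])
    if not config.related:
        return _draw_genotype(p_alt, rng), _draw_genotype(p_alt, rng)
    n = len(panel)
    # parental allele pairs: shape (2 parents, 2 alleles, n SNPs)
    parents = rng.random((2, 2, n)) < p_alt
    def child() -> np.ndarray:
        pick = rng.integers(0, 2, size=(2, n))
        return sum(parents[i, pick[i], np.arange(n)].astype(int) for i in range(2))
    return child(), child()


def _expected_base_probs(
    marker: SNPMarker, alt_fraction: float, error_rate: float
) -> np.ndarray:
    """Observed base probabilities: panel-allele mixture perturbed by a
    uniform substitution error (each read miscalled with probability e,
    uniformly to the other three bases)."""
    p_true = np.zeros(4)
    p_true[BASES.index(marker.alt_allele)] = alt_fraction
    p_true[BASES.index(marker.ref_allele)] = 1.0 - alt_fraction
    e = error_rate
    return p_true * (1.0 - e) + (1.0 - p_true) * e / 3.0


def _counts_from_probs(
    probs: np.ndarray, depth: int, rng: Optional[np.random.Generator]
) -> dict[str, int]:
    if rng is None:  # analytic mode: expected counts, largest-remainder rounding
        exact = probs * depth
        floors = np.floor(exact).astype(int)
        rem = depth - floors.sum()
        order = np.argsort(-(exact - floors))
        floors[order[:rem]] += 1
        drawn = floors
    else:
        drawn = rng.multinomial(depth, probs)
    return {b: int(n) for b, n in zip(BASES, drawn)}


def simulate_counts(
    donor_gt: np.ndarray,
    recipient_gt: np.ndarray,
    panel: Sequence[SNPMarker],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    analytic: bool = False,
) -> tuple[CountTable, CountTable, CountTable]:
    """Base-count tables for donor, recipient, and the post-transplant
    mixture at donor fraction f.

    ``analytic=True`` replaces multinomial sampling with expected counts
    (largest-remainder rounding to integers at the configured depth),
    giving the error-free infinite-depth limit for closed-form checks.
    """
    if analytic:
        rng = None
    elif rng is None:
        rng = np.random.default_rng(config.seed)
    f = config.donor_fraction
    tables = {
        "donor": CountTable("donor"),
        "recipient": CountTable("recipient"),
        "post": CountTable("post"),
    }
    for i, marker in enumerate(panel):
        d_frac = donor_gt[i] / 2.0
        r_frac = recipient_gt[i] / 2.0
        fractions = {
            "donor": d_frac,
            "recipient": r_frac,
            "post": f * d_frac + (1.0 - f) * r_frac,
        }
        for name, alt_frac in fractions.items():
            probs = _expected_base_probs(marker, alt_frac, config.error_rate)
            counts = _counts_from_probs(probs, config.depth, rng)
            tables[name].add(BaseCount(marker.locus, marker.ref_allele, counts))
    return tables["donor"], tables["recipient"], tables["post"]


def spike_mutation(
    table: CountTable,
    locus: GenomicLocus,
    mut_base: str,
    target_mab: float,
    seed: int,
) -> CountTable:
    """Re-draw one locus so the mutant base carries ~target_mab % of reads.

    The mutant count is Binomial(depth, target_mab/100); the remaining
    reads are redistributed over the other bases in proportion to their
    original counts, preserving total depth.
    """
    bc = table.get(locus)
    if bc is None:
        raise KeyError(f"locus {locus} not in table {table.sample_id!r}")
    if not 0.0 <= target_mab <= 100.0:
        raise ValueError("target_mab must be in [0,100]")
    rng = np.random.default_rng(seed)
    depth = bc.depth
    n_mut = int(rng.binomial(depth, target_mab / 100.0))
    others = [b for b in BASES if b != mut_base.upper()]
    weights = np.array([bc.counts[b] for b in others], dtype=float)
    if weights.sum() == 0:
        weights = np.array([1.0 if b == bc.ref else 0.0 for b in others])
        if weights.sum() == 0:  # ref is the mutant base; spread uniformly
            weights = np.ones(len(others))
    drawn = rng.multinomial(depth - n_mut, weights / weights.sum())
    counts = {mut_base.upper(): n_mut, **{b: int(n) for b, n in zip(others, drawn)}}
    out = CountTable(table.sample_id, dict(table.records))
    out.records[locus] = BaseCount(locus, bc.ref, counts)
    return out


@dataclass
class SimulatedStudy:
    """One simulated transplant with its ground truth."""

    panel: list[SNPMarker]
    donor_gt: np.ndarray
    recipient_gt: np.ndarray
    donor: CountTable
    recipient: CountTable
    post: CountTable
    config: SimConfig

    def ground_truth(self) -> dict:
        return {
            "donor_fraction": self.config.donor_fraction,
            "depth": self.config.depth,
            "error_rate": self.config.error_rate,
            "seed": self.config.seed,
            "related": self.config.related,
            "donor_gt": self.donor_gt.tolist(),
            "recipient_gt": self.recipient_gt.tolist(),
            "mutations": [
                {"label": m.marker.label, "true_mab": m.true_mab} for m in self.config.mutations
            ],
        }


def simulate_study(config: SimConfig, analytic: bool = False) -> SimulatedStudy:
    """End-to-end generation: panel, genotype pair, three count tables,
    and any configured mutation spike-ins (applied to the post sample)."""
    rng = np.random.default_rng(config.seed)
    panel = make_panel(config, rng)
    donor_gt, recipient_gt = simulate_pair_genotypes(panel, config, rng)
    donor, recipient, post = simulate_counts(
        donor_gt, recipient_gt, panel, config, rng, analytic=analytic
    )
    for j, spec in enumerate(config.mutations):
        m = spec.marker
        probs = _expected_base_probs(
            SNPMarker(m.locus, m.ref, m.mut, 0.0, id=m.label), 0.0, config.error_rate
        )
        # error-only coverage at the mutation locus in every sample first
        for k, tbl in enumerate((donor, recipient, post)):
            if m.locus not in tbl:
                sub = np.random.default_rng(config.seed + 7919 * (j + 1) + 13 * k)
                counts = _counts_from_probs(probs, config.depth, None if analytic else sub)
                tbl.add(BaseCount(m.locus, m.ref, counts))
        post.records.update(
            spike_mutation(post, m.locus, m.mut, spec.true_mab, config.seed + 104729 * (j + 1)).records
        )
    return SimulatedStudy(panel, donor_gt, recipient_gt, donor, recipient, post, config)


def exact_mixture_counts(
    marker: SNPMarker, donor_dosage: int, recipient_dosage: int, f: float, depth: int
) -> BaseCount:
    """Error-free counts at the exact mixture fractions (no sampling, no
    rounding loss when f*depth is integral) — the closed-form oracle for
    the burden formulas."""
    alt_frac = f * donor_dosage / 2.0 + (1.0 - f) * recipient_dosage / 2.0
    n_alt = round(alt_frac * depth)
    counts = {b: 0 for b in BASES}
    counts[marker.alt_allele] = n_alt
    counts[marker.ref_allele] = depth - n_alt
    return BaseCount(marker.locus, marker.ref_allele, counts)
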