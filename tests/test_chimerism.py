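"""Genotype calling, informative-configuration classification, and the
four donor-allele-burden formulas."""

import itertools

import numpy as np
import pytest

from chimseq.chimerism import (
    Genotype,
    GenotypeCall,
    NoInformativeMarkersError,
    call_genotype,
    classify_informative,
    compute_chimerism,
    donor_allele_burden,
)
from chimseq.io_counts import BASES, BaseCount, CountTable, GenomicLocus, SNPMarker
from chimseq.simulate import SimConfig, exact_mixture_counts, make_panel, simulate_counts
from tests.conftest import make_bc


class TestCallGenotype:
    @pytest.mark.parametrize(
        "a,g,expected",
        [
            (950, 50, Genotype.HOM_REF),     # ref fraction 0.95 in the 90-100 band
            (50, 950, Genotype.HOM_ALT),
            (520, 480, Genotype.HET),        # 0.52/0.48 in the 45-60 band
            (750, 250, Genotype.NO_CALL),    # 0.75 in neither band
            (900, 100, Genotype.HOM_REF),    # boundary: 0.90 is homozygous
            (600, 400, Genotype.HET),        # boundary: 0.60/0.40 -> 0.40 < 0.45 fails
        ],
    )
    def test_band_assignment(self, ag_marker, a, g, expected):
        call = call_genotype(make_bc(A=a, G=g), ag_marker)
        if (a, g) == (600, 400):
            assert call.call is Genotype.NO_CALL
        else:
            assert call.call is expected

    def test_fractions_ignore_off_panel_bases(self, ag_marker):
        # C/T reads are background and do not dilute the panel-allele fraction
        call = call_genotype(make_bc(A=950, G=50, C=300, T=300), ag_marker)
        assert call.call is Genotype.HOM_REF

    def test_no_panel_coverage_gives_reasoned_no_call(self, ag_marker):
        call = call_genotype(make_bc(C=100), ag_marker)
        assert call.call is Genotype.NO_CALL
        assert "no coverage" in call.reason

    def test_major_fraction_bounds(self, ag_marker):
        call = call_genotype(make_bc(A=520, G=480), ag_marker)
        assert 0.5 <= call.major_fraction <= 1.0


def _gt(call: Genotype) -> GenotypeCall:
    return GenotypeCall("m", call, 0.95 if call is not Genotype.HET else 0.52)


def brute_force_classify(donor: Genotype, recipient: Genotype):
    """Independent enumeration of the four informative configurations."""
    table = {
        (Genotype.HOM_REF, Genotype.HOM_ALT): (1, "ref"),
        (Genotype.HOM_ALT, Genotype.HOM_REF): (2, "alt"),
        (Genotype.HOM_REF, Genotype.HET): (3, "ref"),
        (Genotype.HOM_ALT, Genotype.HET): (4, "alt"),
    }
    return table.get((donor, recipient))


class TestClassifyInformative:
    def test_all_genotype_pairs_match_brute_force(self, ag_marker):
        states = [Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT, Genotype.NO_CALL]
        for d, r in itertools.product(states, states):
            config = classify_informative(_gt(d), _gt(r), ag_marker)
            expected = None
            if d is not Genotype.NO_CALL and r is not Genotype.NO_CALL:
                expected = brute_force_classify(d, r)
            if expected is None:
                assert config is None, (d, r)
            else:
                fid, donor_allele = expected
                assert config.formula_id == fid
                assert config.donor_allele == getattr(ag_marker, f"{donor_allele}_allele")

    def test_donor_het_is_non_informative(self, ag_marker):
        assert classify_informative(_gt(Genotype.HET), _gt(Genotype.HOM_REF), ag_marker) is None

    def test_identical_homozygotes_carry_no_signal(self, ag_marker):
        assert classify_informative(_gt(Genotype.HOM_REF), _gt(Genotype.HOM_REF), ag_marker) is None


class TestDonorAlleleBurden:
    def test_hom_hom_is_donor_allele_fraction(self, ag_marker):
        config = classify_informative(_gt(Genotype.HOM_REF), _gt(Genotype.HOM_ALT), ag_marker)
        raw, clamped = donor_allele_burden(make_bc(A=800, G=200), config)
        assert raw == pytest.approx(0.8) and clamped == pytest.approx(0.8)

    def test_recipient_het_formula(self, ag_marker):
        config = classify_informative(_gt(Genotype.HOM_REF), _gt(Genotype.HET), ag_marker)
        raw, _ = donor_allele_burden(make_bc(A=750, G=250), config)
        assert raw == pytest.approx(1 - 2 * 0.25)

    def test_noise_below_zero_is_clamped(self, ag_marker):
        config = classify_informative(_gt(Genotype.HOM_REF), _gt(Genotype.HET), ag_marker)
        raw, clamped = donor_allele_burden(make_bc(A=450, G=550), config)
        assert raw == pytest.approx(-0.10)
        assert clamped == 0.0
        # clamping never moves a value by more than |raw| itself
        assert abs(clamped - raw) <= abs(raw)

    @pytest.mark.parametrize("f", [0.0, 0.1, 0.25, 0.5, 0.6431, 0.8, 0.95, 1.0])
    @pytest.mark.parametrize(
        "donor_dosage,recipient_dosage", [(0, 2), (2, 0), (0, 1), (2, 1)]
    )
    def test_all_four_formulas_exact_in_error_free_limit(
        self, ag_marker, f, donor_dosage, recipient_dosage
    ):
        """On analytically constructed counts every formula returns the
        mixture fraction to machine precision."""
        depth = 20_000  # f grid chosen so the expected counts are integral
        bc = exact_mixture_counts(ag_marker, donor_dosage, recipient_dosage, f, depth)
        d = _gt(Genotype.HOM_REF if donor_dosage == 0 else Genotype.HOM_ALT)
        r = _gt(
            Genotype.HET
            if recipient_dosage == 1
            else (Genotype.HOM_REF if recipient_dosage == 0 else Genotype.HOM_ALT)
        )
        config = classify_informative(d, r, ag_marker)
        raw, _ = donor_allele_burden(bc, config)
        assert raw == pytest.approx(f, abs=1e-12)


def _mirror_marker(marker: SNPMarker) -> SNPMarker:
    return SNPMarker(marker.locus, marker.alt_allele, marker.ref_allele,
                     marker.het_freq, id=marker.id)


def _mirror_table(table: CountTable) -> CountTable:
    return table  # counts are symmetric in the alleles; relabeling is panel-side


class TestComputeChimerism:
    @pytest.fixture
    def study(self):
        config = SimConfig(n_snps=40, donor_fraction=0.8, depth=1000,
                           error_rate=0.0, seed=3)
        rng = np.random.default_rng(3)
        panel = make_panel(config, rng)
        donor_gt = np.array([0, 2, 0, 2] * 10)
        recipient_gt = np.array([2, 0, 1, 1] * 10)
        return config, panel, donor_gt, recipient_gt

    def test_pure_donor_sample_reads_100(self, study):
        config, panel, dg, rg = study
        donor, recipient, _ = simulate_counts(dg, rg, panel, config, analytic=True)
        result = compute_chimerism(donor, recipient, donor, panel)
        assert result.donor_chimerism == pytest.approx(100.0, abs=1e-9)

    def test_pure_recipient_sample_reads_0(self, study):
        config, panel, dg, rg = study
        donor, recipient, _ = simulate_counts(dg, rg, panel, config, analytic=True)
        result = compute_chimerism(donor, recipient, recipient, panel)
        assert result.donor_chimerism == pytest.approx(0.0, abs=1e-9)

    def test_mixture_recovery_within_2_points(self, study):
        config, panel, dg, rg = study
        config.error_rate = 0.001
        donor, recipient, post = simulate_counts(
            dg, rg, panel, config, np.random.default_rng(17)
        )
        result = compute_chimerism(donor, recipient, post, panel)
        assert result.n_informative == 40
        assert abs(result.donor_chimerism - 80.0) < 2.0

    def test_mirror_symmetry(self, study):
        """Relabeling ref<->alt on every marker leaves chimerism unchanged."""
        config, panel, dg, rg = study
        donor, recipient, post = simulate_counts(
            dg, rg, panel, config, np.random.default_rng(9)
        )
        base = compute_chimerism(donor, recipient, post, panel)
        mirrored = compute_chimerism(
            donor, recipient, post, [_mirror_marker(m) for m in panel]
        )
        assert mirrored.donor_chimerism == pytest.approx(base.donor_chimerism)
        assert mirrored.n_informative == base.n_informative

    def test_depth_scaling_invariance(self, study):
        config, panel, dg, rg = study
        donor, recipient, post = simulate_counts(
            dg, rg, panel, config, np.random.default_rng(21)
        )

        def scale(table, k=10):
            out = CountTable(table.sample_id)
            for bc in table:
                out.add(BaseCount(bc.locus, bc.ref, {b: k * n for b, n in bc.counts.items()}))
            return out

        base = compute_chimerism(donor, recipient, post, panel)
        scaled = compute_chimerism(scale(donor), scale(recipient), scale(post), panel)
        assert scaled.donor_chimerism == pytest.approx(base.donor_chimerism)

    def test_formula_ids_match_reclassification(self, study):
        config, panel, dg, rg = study
        donor, recipient, post = simulate_counts(
            dg, rg, panel, config, np.random.default_rng(2)
        )
        result = compute_chimerism(donor, recipient, post, panel)
        assert result.n_informative <= len(panel)
        by_id = {m.id: m for m in panel}
        for entry in result.per_snp:
            expected = brute_force_classify(entry.donor_gt, entry.recipient_gt)
            assert expected is not None and expected[0] == entry.formula_id

    def test_no_informative_markers_is_hard_error(self, ag_marker):
        table = CountTable("s")
        table.add(make_bc(A=1000))  # both individuals hom-ref
        with pytest.raises(NoInformativeMarkersError):
            compute_chimerism(table, table, table, [ag_marker])

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            compute_chimerism(CountTable("d"), CountTable("r"), CountTable("p"), [])
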