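import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from panelmap import fixtures, panel_design
from panelmap.genomeio import GenomeSequence, VariantSite
from panelmap.panel_design import (
    CopyIndex,
    FlankContext,
    PanelConfig,
    classify_site,
    density_report,
    extract_flanks,
    filter_stats,
    find_copies,
    flank_filter,
    gc_fraction,
    select_panel,
    site_rejection_reason,
    site_stats,
)


def _site(genos, chrom="chr1", pos=500, ref="A", alt="G"):
    return VariantSite(chrom, pos, ref, alt, np.array(genos, dtype=np.int8))


class TestSiteStats:
    @pytest.mark.parametrize(
        "genos,maf,missing",
        [
            ([0] * 8 + [1] * 2, 0.10, 0.0),  # 2 hets among 10 -> alt freq 0.10
            ([-1] * 5 + [1] * 5, 0.5, 0.5),
            ([2] * 6, 0.0, 0.0),  # all hom-alt: maf 0 by symmetry
        ],
    )
    def test_counting_arithmetic(self, genos, maf, missing):
        s = site_stats(_site(genos))
        assert s.maf == pytest.approx(maf)
        assert s.missing_rate == pytest.approx(missing)

    def test_all_missing_flags_undefined_maf(self):
        s = site_stats(_site([-1, -1, -1]))
        assert s.missing_rate == 1.0
        assert not s.maf_defined


class TestFilterStats:
    def test_low_maf_rejected(self):
        sites = [_site([0] * 39 + [1])]  # maf 1/80 = 0.0125
        kept, tally = filter_stats(sites, maf_min=0.05)
        assert not kept and tally == {"maf": 1}

    def test_missing_rate_boundary_is_exclusive(self):
        sites = [_site([-1] * 5 + [1, 1, 1, 0, 0])]  # missing exactly 0.50
        kept, tally = filter_stats(sites, missing_max=0.50)
        assert not kept and tally == {"missing": 1}

    def test_maf_boundary_is_inclusive(self):
        # maf exactly 0.05 (1 alt allele among 20), missing 0 < 0.5 -> kept
        sites = [_site([0] * 9 + [1])]
        kept, tally = filter_stats(sites, maf_min=0.05, missing_max=0.50)
        assert len(kept) == 1 and not tally


class TestGcFraction:
    @pytest.mark.parametrize(
        "seq,gc", [("ATGC", 0.5), ("GGCC", 1.0), ("ANGC", 2 / 3), ("ATAT", 0.0)]
    )
    def test_known_values(self, seq, gc):
        assert gc_fraction(seq) == pytest.approx(gc)

    def test_all_n_is_nan(self):
        assert math.isnan(gc_fraction("NNN"))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            gc_fraction("")

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=50))
    def test_bounds_and_n_exclusion(self, seq):
        gc = gc_fraction(seq)
        if set(seq) <= {"N"}:
            assert math.isnan(gc)
        else:
            assert 0.0 <= gc <= 1.0
            assert gc == pytest.approx(gc_fraction(seq.replace("N", "")))


class TestExtractFlanks:
    def test_interior_position_complete(self, small_genome):
        ctx = extract_flanks(small_genome, _site([0, 1], pos=101))
        assert ctx.complete and len(ctx.up_seq) == 100 and len(ctx.down_seq) == 100
        assert ctx.up_seq == small_genome.fetch("chr1", 1, 100)

    def test_near_edge_incomplete(self, small_genome):
        ctx = extract_flanks(small_genome, _site([0, 1], pos=50))
        assert not ctx.complete
        assert len(ctx.up_seq) == 49

    def test_outside_chromosome_raises(self, small_genome):
        with pytest.raises(ValueError):
            extract_flanks(small_genome, _site([0], pos=50_000))

    def test_at_only_flanks_have_zero_gc(self):
        genome = GenomeSequence(["c"], {"c": "AT" * 50 + "G" + "AT" * 50})
        ctx = extract_flanks(genome, _site([0], chrom="c", pos=101))
        assert ctx.gc_up == 0.0 and ctx.gc_down == 0.0


class TestFlankFilter:
    def test_gc_out_of_bounds_fails(self):
        ctx = FlankContext("A", "A", 0.39, 0.50, False, True)
        ok, reason = flank_filter(ctx)
        assert not ok and reason == "gc"

    def test_n_in_flank_fails(self):
        ctx = FlankContext("A", "A", 0.5, 0.5, True, True)
        assert flank_filter(ctx) == (False, "n")

    def test_interior_gc_passes(self):
        ctx = FlankContext("A", "A", 0.41, 0.59, False, True)
        assert flank_filter(ctx) == (True, None)

    def test_incomplete_fails(self):
        ctx = FlankContext("", "A", float("nan"), 0.5, False, False)
        assert flank_filter(ctx) == (False, "incomplete")

    def test_bounds_are_strict(self):
        ctx = FlankContext("A", "A", 0.40, 0.50, False, True)
        assert not flank_filter(ctx)[0]
        ctx = FlankContext("A", "A", 0.50, 0.60, False, True)
        assert not flank_filter(ctx)[0]


def _brute_force_has_duplicate(genome, probe, self_locus, min_len):
    """Independent oracle: some min_len-substring of the probe occurs in the
    genome (either strand) outside the self locus."""
    from panelmap.genomeio import reverse_complement

    s_chrom, s_start, s_end = self_locus
    for strand_probe in (probe, reverse_complement(probe)):
        for j in range(len(probe) - min_len + 1):
            sub = strand_probe[j : j + min_len]
            for chrom in genome.chrom_names:
                start = 0
                seq = genome.sequences[chrom]
                while True:
                    i = seq.find(sub, start)
                    if i == -1:
                        break
                    hit = (chrom, i + 1, i + min_len)
                    if not (chrom == s_chrom and hit[1] <= s_end and hit[2] >= s_start):
                        return True
                    start = i + 1
    return False


@pytest.fixture(scope="module")
def dup_genome():
    dup = fixtures.Duplication("chr1", 5_001, 150, "chr2", 8_001)
    genome, _ = fixtures.make_genome(
        n_chrom=2, length=20_000, seed=42, duplications=[dup]
    )
    return genome


class TestFindCopies:

    def test_planted_150bp_duplicate_found(self, dup_genome):
        # probe centred on the duplicated block: its 150-bp core exists twice
        locus = ("chr1", 4_976, 5_176)
        probe = dup_genome.fetch(*locus)
        report = find_copies(dup_genome, probe, locus, min_copy_len=120)
        assert not report.is_single_copy
        non_self = [h for h in report.hits if not h.is_self]
        assert any(h.chrom == "chr2" and h.aligned_length >= 120 for h in non_self)

    def test_random_probe_single_copy_confirmed_by_brute_force(self, dup_genome):
        locus = ("chr1", 12_001, 12_201)
        probe = dup_genome.fetch(*locus)
        report = find_copies(dup_genome, probe, locus, min_copy_len=120)
        assert report.is_single_copy
        assert [h for h in report.hits if h.is_self]
        assert not _brute_force_has_duplicate(dup_genome, probe, locus, 120)

    def test_100bp_copy_is_below_threshold(self):
        dup = fixtures.Duplication("chr1", 5_001, 100, "chr2", 8_001)
        genome, _ = fixtures.make_genome(
            n_chrom=2, length=20_000, seed=43, duplications=[dup]
        )
        locus = ("chr1", 4_951, 5_151)
        probe = genome.fetch(*locus)
        report = find_copies(genome, probe, locus, min_copy_len=120)
        assert report.is_single_copy
        assert not _brute_force_has_duplicate(genome, probe, locus, 120)

    def test_short_probe_raises(self, dup_genome):
        with pytest.raises(ValueError):
            find_copies(dup_genome, "ACGT" * 10, ("chr1", 1, 40), min_copy_len=120)

    def test_reverse_complement_duplicate_found(self, small_genome):
        from panelmap.genomeio import reverse_complement

        locus = ("chr1", 1_001, 1_201)
        probe = small_genome.fetch(*locus)
        seq2 = small_genome.sequences["chr2"]
        planted = seq2[:5_000] + reverse_complement(probe) + seq2[5_201:]
        genome = GenomeSequence(
            ["chr1", "chr2"],
            {"chr1": small_genome.sequences["chr1"], "chr2": planted},
        )
        report = find_copies(genome, probe, locus, min_copy_len=120)
        assert not report.is_single_copy

    def test_exhaustive_agreement_with_brute_force(self):
        """Seeded search equals the all-windows scan on many random probes."""
        dup = fixtures.Duplication("chr1", 3_001, 130, "chr1", 9_001)
        genome, _ = fixtures.make_genome(
            n_chrom=1, length=30_000, seed=44, duplications=[dup]
        )
        index = CopyIndex(genome)
        rng = np.random.default_rng(0)
        for _ in range(25):
            pos = int(rng.integers(101, 30_000 - 101))
            locus = ("chr1", pos - 100, pos + 100)
            probe = genome.fetch(*locus)
            report = index.find(probe, locus, 120)
            assert (not report.is_single_copy) == _brute_force_has_duplicate(
                genome, probe, locus, 120
            )

    def test_external_hit_table_adapter(self):
        report = panel_design.copy_report_from_hits(
            [("chr1", 100, 201), ("chr2", 900, 150)],
            self_locus=("chr1", 100, 300),
            min_copy_len=120,
        )
        assert not report.is_single_copy
        report2 = panel_design.copy_report_from_hits(
            [("chr1", 100, 201), ("chr2", 900, 100)],
            self_locus=("chr1", 100, 300),
        )
        assert report2.is_single_copy


@pytest.fixture(scope="module")
def coding_genome():
    # chr: 10 bp pad + CDS ATG GCT TGG TAA + pad; gene at 11..22
    from panelmap.genomeio import GeneModel

    seq = "ATATATATAT" + "ATGGCTTGGTAA" + "ATATATATATATATATAT"
    genome = GenomeSequence(["c"], {"c": seq})
    gene = GeneModel("g1", "c", "+", [(11, 22)], (11, 22))
    return genome, [gene]


class TestClassifySite:

    def test_intergenic(self, coding_genome):
        genome, genes = coding_genome
        assert classify_site(_site([0], chrom="c", pos=5, ref="A", alt="G"), genes, genome) == "intergenic"

    def test_synonymous(self, coding_genome):
        genome, genes = coding_genome
        # codon 2 GCT -> GCC (Ala -> Ala)
        site = _site([0], chrom="c", pos=16, ref="T", alt="C")
        assert classify_site(site, genes, genome) == "synonymous"

    def test_nonsynonymous(self, coding_genome):
        genome, genes = coding_genome
        # codon 2 GCT -> GTT (Ala -> Val)
        site = _site([0], chrom="c", pos=15, ref="C", alt="T")
        assert classify_site(site, genes, genome) == "nonsynonymous"

    def test_stop_codon_change(self, coding_genome):
        genome, genes = coding_genome
        # codon 3 TGG -> TGA (Trp -> stop)
        site = _site([0], chrom="c", pos=19, ref="G", alt="A")
        assert classify_site(site, genes, genome) == "stop_codon_change"

    def test_start_codon_change(self, coding_genome):
        genome, genes = coding_genome
        site = _site([0], chrom="c", pos=11, ref="A", alt="G")
        assert classify_site(site, genes, genome) == "start_codon_change"

    def test_minus_strand_synonymous(self):
        # minus-strand CDS reads ATG GCT TGG TAA from the reverse complement
        from panelmap.genomeio import GeneModel, reverse_complement

        cds = "ATGGCTTGGTAA"
        seq = "ATATATATAT" + reverse_complement(cds) + "ATATATATAT"
        genome = GenomeSequence(["c"], {"c": seq})
        gene = GeneModel("g1", "c", "-", [(11, 22)], (11, 22))
        # plus-strand pos of the GCT third base (CDS offset 5): 22 - 5 = 17
        site = _site([0], chrom="c", pos=17, ref="A", alt="G")  # T->C on minus
        assert classify_site(site, [gene], genome) == "synonymous"

    def test_noncoding_genic(self, coding_genome):
        genome, _ = coding_genome
        from panelmap.genomeio import GeneModel

        gene = GeneModel("g1", "c", "+", [(11, 22)], (5, 30))
        site = _site([0], chrom="c", pos=25, ref="A", alt="G")
        assert classify_site(site, [gene], genome) == "noncoding_genic"

    def test_frame_inconsistency_falls_back(self, coding_genome):
        genome, _ = coding_genome
        from panelmap.genomeio import GeneModel

        gene = GeneModel("g1", "c", "+", [(11, 21)], (11, 21))  # 11 bp CDS
        site = _site([0], chrom="c", pos=15, ref="C", alt="T")
        with pytest.warns(UserWarning):
            assert classify_site(site, [gene], genome) == "noncoding_genic"


@pytest.fixture(scope="module")
def panel_fixture():
    return fixtures.make_panel_fixture(seed=11, n_clean=120)


class TestSelectPanel:

    def test_survivors_match_fixture_truth(self, panel_fixture):
        genome, _, variants, truth = panel_fixture
        result = select_panel(variants, genome)
        got = sorted((p.site.chrom, p.site.pos) for p in result.panel)
        assert got == truth.expected_survivors()

    def test_rejection_tallies_match_truth(self, panel_fixture):
        genome, _, variants, truth = panel_fixture
        result = select_panel(variants, genome)
        assert result.rejections == truth.expected_tally()

    def test_tallies_plus_survivors_conserve_inputs(self, panel_fixture):
        genome, _, variants, _ = panel_fixture
        result = select_panel(variants, genome)
        assert len(result.panel) + sum(result.rejections.values()) == len(variants.sites)
        assert len(result.rejected_sites) == sum(result.rejections.values())

    def test_all_passing_fixture_keeps_everything(self, small_genome):
        variants, truth = fixtures.make_population_vcf(
            small_genome, n_samples=30, n_sites=50, seed=3
        )
        result = select_panel(variants, small_genome)
        assert len(result.panel) == 50

    def test_cascade_is_order_invariant(self, panel_fixture):
        """Each filter is a pure per-site predicate, so the survivor set is
        the same whichever order the predicates are evaluated in."""
        genome, _, variants, _ = panel_fixture
        config = PanelConfig()
        index = CopyIndex(genome)

        def pred_stats(site):
            return panel_design.stats_filter_reason(
                site_stats(site), config.maf_min, config.missing_max
            ) is None

        def pred_flank(site):
            ctx = extract_flanks(genome, site, config.flank)
            return panel_design.flank_filter_reason(ctx, config.gc_lo, config.gc_hi) is None

        def pred_copy(site):
            ctx = extract_flanks(genome, site, config.flank)
            if not ctx.complete:
                return True  # probe undefined; rule vacuous on its own
            probe = ctx.up_seq + genome.base_at(site.chrom, site.pos) + ctx.down_seq
            locus = (site.chrom, site.pos - config.flank, site.pos + config.flank)
            return index.find(probe, locus, config.min_copy_len).is_single_copy

        baseline = {
            (p.site.chrom, p.site.pos)
            for p in select_panel(variants, genome, config=config).panel
        }
        sub = variants.sites[::5]  # spot-check a slice under every ordering
        for order in itertools.permutations([pred_stats, pred_flank, pred_copy]):
            surv = {
                (s.chrom, s.pos)
                for s in sub
                if all(pred(s) for pred in order)
            }
            assert surv == baseline & {(s.chrom, s.pos) for s in sub}

    def test_rejection_reason_helper_agrees_with_cascade(self, panel_fixture):
        genome, _, variants, _ = panel_fixture
        config = PanelConfig()
        index = CopyIndex(genome)
        result = select_panel(variants, genome, config=config)
        for site in variants.sites[::7]:
            reason = site_rejection_reason(site, genome, config, index)
            key = (site.chrom, site.pos)
            assert reason == result.rejected_sites.get(key)


class TestDensityReport:
    def test_counts_fall_in_expected_bins(self, small_genome):
        variants, _ = fixtures.make_population_vcf(
            small_genome, n_samples=20, n_sites=30, seed=5
        )
        result = select_panel(variants, small_genome, config=PanelConfig(check_copies=False))
        df = density_report(result.panel, small_genome, bin_size=5_000)
        assert df["count"].sum() == len(result.panel)
        for p in result.panel:
            row = df[
                (df["chrom"] == p.site.chrom)
                & (df["bin_start"] <= p.site.pos)
                & (df["bin_end"] >= p.site.pos)
            ]
            assert row["count"].iloc[0] >= 1

    def test_all_snps_in_first_bin(self, small_genome):
        variants, _ = fixtures.make_population_vcf(
            small_genome, n_samples=10, n_sites=5, seed=6
        )
        result = select_panel(variants, small_genome, config=PanelConfig(check_copies=False))
        df = density_report(result.panel, small_genome, bin_size=50_000)
        assert df.loc[df["chrom"] == "chr1", "count"].sum() == sum(
            1 for p in result.panel if p.site.chrom == "chr1"
        )

    def test_uniform_fixture_is_roughly_uniform(self):
        from scipy import stats as sps

        rng = np.random.default_rng(9)
        genome, _ = fixtures.make_genome(n_chrom=1, length=100_000, seed=9)
        positions = rng.integers(101, 99_900, size=400)
        sites = [
            panel_design.PanelSNP(
                _site([0, 1], pos=int(p)), None, None, "intergenic"
            )
            for p in np.unique(positions)
        ]
        df = density_report(sites, genome, bin_size=10_000)
        chi2, p_val = sps.chisquare(df["count"])
        assert p_val > 0.001

    def test_bad_bin_size_raises(self, small_genome):
        with pytest.raises(ValueError):
            density_report([], small_genome, bin_size=0)


class TestThinPanel:
    def test_greedy_spacing(self):
        panel = [
            panel_design.PanelSNP(_site([0, 1], pos=p), None, None, "intergenic")
            for p in (100, 150, 300, 320, 600)
        ]
        kept = panel_design.thin_panel(panel, min_spacing=200)
        assert [p.site.pos for p in kept] == [100, 300, 600]
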