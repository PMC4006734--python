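"""Meiosis, tetrads, phenotype assignment, cohorts, reads, artifacts."""

import numpy as np
import pytest

from roughmap.evaluate import expected_phenotype_frequency
from roughmap.genome import build_default_genome, make_snp_panel
from roughmap.simulate import (
    ORIGIN_A,
    ORIGIN_B,
    ArtifactSpec,
    CrossDesign,
    PhenotypeClause,
    PhenotypeModel,
    SegregantGenotype,
    assign_phenotype,
    default_causal_loci,
    default_phenotype_model,
    founder,
    inject_artifacts,
    rough_founder_segregant,
    simulate_backcross_cohort,
    simulate_meiosis,
    simulate_pooled_control,
    simulate_reads,
    simulate_tetrad,
)


class TestMeiosis:
    def test_identical_parents_give_identical_offspring(self, genome_small, panel_small):
        p = founder("BY", genome_small)
        child = simulate_meiosis(p, p, genome_small, seed=3)
        assert (child.origin_matrix_row(panel_small) == ORIGIN_A).all()
        assert child.causal_alleles == p.causal_alleles

    def test_crossover_count_poisson_mean(self):
        """Mean crossovers per chromosome over many meioses equals the
        chromosome's map length in Morgans (3 SE allowance)."""
        genome = build_default_genome(scale=0.2)
        by, s3 = founder("BY", genome), founder("3S", genome)
        rng = np.random.default_rng(5)
        n = 10_000
        counts = {c: 0 for c in genome.names}
        for _ in range(n):
            child = simulate_meiosis(by, s3, genome, rng)
            for chrom in genome.names:
                counts[chrom] += len(child.origin[chrom].breakpoints)
        for chrom in genome.names:
            lam = genome.map_length(chrom)
            se = np.sqrt(lam / n)
            assert abs(counts[chrom] / n - lam) < 3 * se + 1e-9

    def test_mendelian_marginal_one_half(self, genome_small, panel_small):
        by, s3 = founder("BY", genome_small), founder("3S", genome_small)
        rng = np.random.default_rng(8)
        n = 10_000
        site = len(panel_small) // 2
        tot = 0
        for _ in range(n):
            child = simulate_meiosis(by, s3, genome_small, rng)
            tot += int(child.origin_matrix_row(panel_small)[site])
        se = 0.5 / np.sqrt(n)
        assert abs(tot / n - 0.5) < 3 * se

    def test_genome_mismatch_raises(self, genome):
        from roughmap.genome import GenomeMap

        other = GenomeMap(chromosomes=(("plasmid", 5000),))
        p = SegregantGenotype(
            id="p",
            causal_alleles={},
            origin={"plasmid": founder("BY", genome).origin["chrI"]},
        )
        with pytest.raises(ValueError):
            simulate_meiosis(p, p, genome, seed=0, causal_loci={})


class TestTetrad:
    def test_two_to_two_segregation_everywhere(self, genome_small, panel_small):
        by, s3 = founder("BY", genome_small), founder("3S", genome_small)
        rng = np.random.default_rng(9)
        for _ in range(5):
            spores = simulate_tetrad(by, s3, genome_small, rng)
            mat = np.stack([sp.origin_matrix_row(panel_small) for sp in spores])
            assert (mat.sum(axis=0) == 2).all()

    def test_identical_parents(self, genome_small, panel_small):
        p = founder("3S", genome_small)
        spores = simulate_tetrad(p, p, genome_small, seed=1)
        for sp in spores:
            assert (sp.origin_matrix_row(panel_small) == ORIGIN_B).all()

    def test_pooled_tetrad_frequency_exactly_half(self, genome_small, panel_small):
        by, s3 = founder("BY", genome_small), founder("3S", genome_small)
        rng = np.random.default_rng(10)
        total = np.zeros(len(panel_small))
        n_tetrads = 250
        for _ in range(n_tetrads):
            for sp in simulate_tetrad(by, s3, genome_small, rng):
                total += sp.origin_matrix_row(panel_small)
        assert (total == 2 * n_tetrads).all()


class TestPhenotypeAssignment:
    def test_primary_clause_rough(self, rng, model):
        g = SegregantGenotype(
            id="x",
            causal_alleles={"END3": "A", "FLO8": "B", "IRA2": "mut", "MSS11": "A",
                            "TRR1": "B", "VII": "B", "XV2": "B"},
        )
        assert all(assign_phenotype(g, model, rng) == "rough" for _ in range(20))

    def test_alternate_clause_penetrance(self, rng):
        model = default_phenotype_model(pi_alt=0.2)
        g = SegregantGenotype(
            id="x",
            causal_alleles={"END3": "B", "VII": "A", "XV2": "A", "FLO8": "B",
                            "IRA2": "mut", "MSS11": "A", "TRR1": "B"},
        )
        n = 4000
        rough = sum(assign_phenotype(g, model, rng) == "rough" for _ in range(n))
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(rough / n - 0.2) < 3 * se

    def test_pure_3s_always_smooth(self, rng, model, genome):
        g = founder("3S", genome)
        assert all(assign_phenotype(g, model, rng) == "smooth" for _ in range(20))

    def test_bumpy_rule(self, rng):
        model = default_phenotype_model(include_bumpy=True)
        g = SegregantGenotype(
            id="x",
            causal_alleles={"END3": "A", "FLO8": "B", "IRA2": "mut", "MSS11": "A",
                            "TRR1": "A", "VII": "B", "XV2": "B"},
        )
        assert assign_phenotype(g, model, rng) == "bumpy"

    def test_missing_locus_raises(self, rng, model):
        g = SegregantGenotype(id="x", causal_alleles={"END3": "A"})
        with pytest.raises(KeyError):
            assign_phenotype(g, model, rng)

    def test_invalid_penetrance(self):
        with pytest.raises(ValueError):
            PhenotypeClause({"END3": "A"}, penetrance=1.5)
        with pytest.raises(ValueError):
            PhenotypeModel(clauses=())


class TestBackcrossCohort:
    def test_selection_contract(self, genome, model, rough_segregant, s3_founder):
        design = CrossDesign(parent1=rough_segregant, parent2=s3_founder,
                             n_offspring=30, selection="rough")
        cohort = simulate_backcross_cohort(design, model, genome, seed=42)
        assert len(cohort) == 30
        assert all(p == "rough" for p in cohort.phenotypes)
        assert cohort.n_attempted >= 30

    def test_unselected_frequency_matches_enumeration(
        self, genome, model, rough_segregant, by_founder
    ):
        design = CrossDesign(parent1=rough_segregant, parent2=by_founder,
                             n_offspring=20_000)
        cohort = simulate_backcross_cohort(design, model, genome, seed=7, track="causal")
        p = expected_phenotype_frequency(design, model, genome)
        obs = cohort.phenotype_frequency("rough")
        se = np.sqrt(p * (1 - p) / len(cohort))
        assert abs(obs - p) < 3 * se

    def test_impossible_selection_refused(self, genome, model, by_founder):
        design = CrossDesign(parent1=by_founder, parent2=by_founder,
                             n_offspring=5, selection="rough")
        with pytest.raises(ValueError, match="probability 0"):
            simulate_backcross_cohort(design, model, genome, seed=1)

    def test_causal_track_matches_full_track_distribution(
        self, genome, model, rough_segregant, s3_founder
    ):
        """The vectorised causal-loci sampler and full meiosis agree on
        the rough-phenotype frequency (two independent routes)."""
        design = CrossDesign(parent1=rough_segregant, parent2=s3_founder,
                             n_offspring=4000)
        full = simulate_backcross_cohort(design, model, genome, seed=3, track="full")
        causal = simulate_backcross_cohort(design, model, genome, seed=4, track="causal")
        p1, p2 = full.phenotype_frequency("rough"), causal.phenotype_frequency("rough")
        se = np.sqrt(0.13 * 0.87 * 2 / 4000)
        assert abs(p1 - p2) < 3 * se

    def test_recurrent_backcross_dilution(self, model):
        """After r selected backcross rounds the non-recurrent parent's
        genome fraction at unlinked neutral sites decays like 2^-r."""
        genome = build_default_genome(scale=0.25)
        panel = make_snp_panel(genome, 400, seed=6)
        rough = rough_founder_segregant(genome)
        by = founder("BY", genome)
        rounds = 6
        design = CrossDesign(parent1=rough, parent2=by, n_offspring=24,
                             selection="rough", rounds=rounds)
        cohort = simulate_backcross_cohort(design, model, genome, panel, seed=13)
        # neutral sites: donor (3S) origin in the founder and > 100 kb from
        # the selected donor loci
        rb = rough.origin_matrix_row(panel)
        loci = default_causal_loci(genome)
        far = np.ones(len(panel), bool)
        for name in ("FLO8", "TRR1", "IRA2"):
            c, p = loci[name]
            sl = panel.chrom_slice(c)
            far[sl] &= np.abs(panel.pos[sl] - p) > 100_000
        neutral = (rb == 1) & far
        frac_b = np.mean(
            [g.origin_matrix_row(panel)[neutral].mean() for g in cohort.genotypes]
        )
        expected = 0.5**rounds
        assert abs(frac_b - expected) < 0.03


@pytest.fixture(scope="module")
def small_cohort(genome_small, model):
    rough = rough_founder_segregant(genome_small)
    by = founder("BY", genome_small)
    design = CrossDesign(parent1=rough, parent2=by, n_offspring=30)
    return simulate_backcross_cohort(design, model, genome_small, seed=21)


@pytest.fixture(scope="module")
def cohort_and_reads(genome_small, panel_small, model):
    rough = rough_founder_segregant(genome_small)
    by = founder("BY", genome_small)
    design = CrossDesign(parent1=rough, parent2=by, n_offspring=10)
    cohort = simulate_backcross_cohort(design, model, genome_small, seed=31)
    reads = simulate_reads(cohort, panel_small, lam=4, eps=0.005, seed=32)
    return cohort, reads


class TestReads:
    def test_zero_error_reads_match_truth(self, small_cohort, panel_small):
        m = simulate_reads(small_cohort, panel_small, lam=20, eps=0.0, seed=1)
        for i, g in enumerate(small_cohort.genotypes):
            origin = g.origin_matrix_row(panel_small)
            assert (m.depth_b[i][origin == ORIGIN_A] == 0).all()
            assert (m.depth_a[i][origin == ORIGIN_B] == 0).all()

    def test_mean_depth(self, small_cohort, panel_small):
        lam = 4.0
        m = simulate_reads(small_cohort, panel_small, lam=lam, eps=0.005, seed=2)
        tot = m.total_depth()
        se = np.sqrt(lam / tot.size)
        assert abs(tot.mean() - lam) < 3 * se

    def test_error_fraction(self, small_cohort, panel_small):
        eps = 0.01
        m = simulate_reads(small_cohort, panel_small, lam=50, eps=eps, seed=3)
        wrong = 0
        for i, g in enumerate(small_cohort.genotypes):
            origin = g.origin_matrix_row(panel_small)
            wrong += m.depth_b[i][origin == ORIGIN_A].sum()
            wrong += m.depth_a[i][origin == ORIGIN_B].sum()
        total = m.total_depth().sum()
        se = np.sqrt(eps * (1 - eps) / total)
        assert abs(wrong / total - eps) < 3 * se

    def test_invalid_params(self, small_cohort, panel_small):
        with pytest.raises(ValueError):
            simulate_reads(small_cohort, panel_small, lam=0.0)
        with pytest.raises(ValueError):
            simulate_reads(small_cohort, panel_small, lam=4, eps=0.6)


class TestArtifacts:
    def test_aneuploidy_doubles_chromosome_depth(self, cohort_and_reads, panel_small):
        cohort, reads = cohort_and_reads
        spec = ArtifactSpec(aneuploidies=((0, "chrIV", 2.0),))
        out = inject_artifacts(reads, spec, cohort, panel_small, seed=1)
        sl = panel_small.chrom_slice("chrIV")
        lam = reads.mean_depth
        d4 = out.total_depth()[0, sl]
        n4 = sl.stop - sl.start
        assert abs(d4.mean() - 2 * lam) < 3 * np.sqrt(2 * lam / n4)
        other = np.ones(out.n_snps, dtype=bool)
        other[sl] = False
        d_other = out.total_depth()[0, other]
        assert abs(d_other.mean() - lam) < 3 * np.sqrt(lam / other.sum())

    def test_zero_mix_fraction_is_identity(self, cohort_and_reads, panel_small):
        cohort, reads = cohort_and_reads
        spec = ArtifactSpec(contaminations=((1, 0.0, None),))
        out = inject_artifacts(reads, spec, cohort, panel_small, seed=2)
        np.testing.assert_array_equal(out.depth_a, reads.depth_a)
        np.testing.assert_array_equal(out.depth_b, reads.depth_b)

    def test_half_mix_concentrates_allele_fractions(self, cohort_and_reads, panel_small):
        cohort, reads = cohort_and_reads
        spec = ArtifactSpec(contaminations=((2, 0.5, None),))
        out = inject_artifacts(reads, spec, cohort, panel_small, seed=3)
        tot = out.total_depth()[2]
        deep = tot >= 8
        frac_a = out.depth_a[2][deep] / tot[deep]
        # opposite-origin contaminant at 50% puts every site near 0.5
        assert abs(np.mean(frac_a) - 0.5) < 0.05
        assert (np.abs(frac_a - 0.5) < 0.4).mean() > 0.95

    def test_invalid_specs(self, cohort_and_reads, panel_small):
        cohort, reads = cohort_and_reads
        with pytest.raises(ValueError):
            inject_artifacts(reads, ArtifactSpec(aneuploidies=((0, "chrI", 0.0),)),
                             cohort, panel_small)
        with pytest.raises(ValueError):
            inject_artifacts(reads, ArtifactSpec(contaminations=((0, 1.5, None),)),
                             cohort, panel_small)


class TestPooledControl:
    def test_mendelian_pool_near_half_at_segregating_sites(
        self, genome_small, panel_small, model
    ):
        """Sites where the backcross segregates (the F1 parent carries the
        donor allele) pool near 0.5; monomorphic sites pool near 0."""
        rough = rough_founder_segregant(genome_small)
        by = founder("BY", genome_small)
        design = CrossDesign(parent1=rough, parent2=by, n_offspring=1)
        count_b, depth = simulate_pooled_control(
            design, genome_small, panel_small, lam_pool=200, seed=5, n_pool=400
        )
        rb = rough.origin_matrix_row(panel_small)
        frac_seg = count_b[rb == 1].sum() / depth[rb == 1].sum()
        frac_mono = count_b[rb == 0].sum() / depth[rb == 0].sum()
        assert abs(frac_seg - 0.5) < 0.03
        assert frac_mono < 0.01

    def test_selected_marker_fixed_and_decaying(self, genome_small, panel_small, model):
        """Pooled frequency of the selected allele is 1 at the marker and
        decays with map distance following the Haldane recombination
        fraction (marker placed on a donor-origin segment so the
        closed-form oracle freq_A(d) = 1 - r(d) applies)."""
        rough = rough_founder_segregant(genome_small)
        by = founder("BY", genome_small)
        design = CrossDesign(parent1=rough, parent2=by, n_offspring=1)
        rb_all = rough.origin_matrix_row(panel_small)
        chrom = max(
            ("chrI", "chrII", "chrVI", "chrVIII", "chrIX", "chrX"),
            key=lambda c: (rb_all[panel_small.chrom_slice(c)] == 1).sum(),
        )
        sl = panel_small.chrom_slice(chrom)
        pos = panel_small.pos[sl]
        rb = rb_all[sl]
        donor_sites = np.flatnonzero(rb == 1)
        marker_i = donor_sites[len(donor_sites) // 2]
        marker_pos = int(pos[marker_i])
        count_b, depth = simulate_pooled_control(
            design, genome_small, panel_small, lam_pool=300, seed=6,
            marker_loci=[(chrom, marker_pos, ORIGIN_A)], n_pool=300,
        )
        frac_a = 1.0 - count_b[sl] / np.maximum(depth[sl], 1)
        assert frac_a[marker_i] == 1.0
        c = genome_small.recomb_rate
        d = np.abs(pos[donor_sites] - marker_pos)
        oracle = 1.0 - 0.5 * (1.0 - np.exp(-2.0 * c * d))
        err = np.abs(frac_a[donor_sites] - oracle)
        assert err.mean() < 0.05

    def test_pool_depth_parameter(self, genome_small, panel_small, model):
        rough = rough_founder_segregant(genome_small)
        by = founder("BY", genome_small)
        design = CrossDesign(parent1=rough, parent2=by, n_offspring=1)
        count_b, depth = simulate_pooled_control(
            design, genome_small, panel_small, lam_pool=200, seed=7, n_pool=100
        )
        assert abs(depth.mean() - 200) < 3 * np.sqrt(200 / len(depth))


def test_seed_reproducibility(genome, model, rough_segregant, by_founder, panel):
    design = CrossDesign(parent1=rough_segregant, parent2=by_founder, n_offspring=25)
    c1 = simulate_backcross_cohort(design, model, genome, seed=99)
    c2 = simulate_backcross_cohort(design, model, genome, seed=99)
    assert c1.phenotypes == c2.phenotypes
    for g1, g2 in zip(c1.genotypes, c2.genotypes):
        assert g1.causal_alleles == g2.causal_alleles
        for chrom in genome.names:
            np.testing.assert_array_equal(
                g1.origin[chrom].breakpoints, g2.origin[chrom].breakpoints
            )
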