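import dataclasses

import numpy as np
import pytest

from crossblup.genome import build_genome, trait_architecture
from crossblup.simulate import (
    ConfigError,
    LociMap,
    PopulationBuilder,
    PopulationDesign,
    build_loci_map,
    meiosis,
    sample_qtl_effects,
    simulate_history,
    simulate_population,
)


def two_locus_map(length_cm=1.0):
    return LociMap(
        chrom=np.array([1, 1]),
        pos_cm=np.array([0.0, length_cm]),
        is_snp=np.array([True, True]),
        chrom_lengths=np.array([length_cm]),
    )


class TestMeiosis:
    def test_no_recombination_returns_intact_haplotype(self, rng):
        loci = LociMap(
            chrom=np.array([1] * 5),
            pos_cm=np.linspace(0, 0, 5),
            is_snp=np.ones(5, bool),
            chrom_lengths=np.array([0.0]),
        )
        haps = np.array([[0, 1, 0, 1, 1], [1, 0, 1, 0, 0]], dtype=np.uint8)
        for _ in range(20):
            g = meiosis(haps, loci, 0.0, rng)
            assert np.array_equal(g, haps[0]) or np.array_equal(g, haps[1])

    def test_homozygous_parent_transmits_identically(self, rng):
        loci = two_locus_map(50.0)
        haps = np.array([[1, 0], [1, 0]], dtype=np.uint8)
        for _ in range(10):
            assert np.array_equal(meiosis(haps, loci, 0.0, rng), haps[0])

    def test_recombination_fraction_matches_haldane(self):
        """Terminal loci 1 cM apart recombine with frequency ~ 0.01."""
        from crossblup.simulate import _make_gametes

        loci = two_locus_map(1.0)
        haps = np.array([[0, 0], [1, 1]], dtype=np.uint8)
        rng = np.random.default_rng(42)
        gam = _make_gametes(haps, np.zeros(100000, dtype=int), loci, 0.0, rng)
        rec = (gam[:, 0] != gam[:, 1]).mean()
        # Haldane: r = (1 - exp(-2d))/2 at d = 0.01 Morgan
        assert rec == pytest.approx(0.5 * (1 - np.exp(-0.02)), abs=0.0015)

    def test_mutation_flips_alleles_at_given_rate(self):
        from crossblup.simulate import _make_gametes

        loci = LociMap(
            chrom=np.ones(100, int),
            pos_cm=np.zeros(100),
            is_snp=np.ones(100, bool),
            chrom_lengths=np.array([0.0]),
        )
        haps = np.zeros((2, 100), dtype=np.uint8)
        rng = np.random.default_rng(0)
        gam = _make_gametes(haps, np.zeros(5000, dtype=int), loci, 1e-3, rng)
        assert gam.mean() == pytest.approx(1e-3, rel=0.3)


class TestHistory:
    def test_initial_frequencies_exactly_half(self):
        g = build_genome(1, 10.0, 50)
        loci, _ = build_loci_map(g, trait_architecture("SIM1", g), np.random.default_rng(0))
        pool = simulate_history(loci, ((40, 0),), 0.0, np.random.default_rng(1))
        assert np.allclose(pool.mean(axis=0), 0.5)

    def test_determinism(self):
        g = build_genome(1, 10.0, 50)
        loci, _ = build_loci_map(g, trait_architecture("SIM1", g), np.random.default_rng(0))
        a = simulate_history(loci, ((20, 2),), 1e-5, np.random.default_rng(7))
        b = simulate_history(loci, ((20, 2),), 1e-5, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_mean_frequency_unbiased_under_drift(self):
        g = build_genome(1, 10.0, 200)
        loci, _ = build_loci_map(g, trait_architecture("SIM1", g), np.random.default_rng(0))
        pool = simulate_history(loci, ((60, 30),), 0.0, np.random.default_rng(3))
        # loci drift independently; the cross-locus mean stays near 0.5
        assert pool.mean() == pytest.approx(0.5, abs=0.03)


class TestQtlEffects:
    def test_polygenic_trait_has_no_qtl_effects(self, rng):
        t = trait_architecture("SIM1")
        assert sample_qtl_effects(t, np.zeros((10, 0)), rng).size == 0

    def test_founder_qtl_variance_scaled_to_target(self, rng):
        t = dataclasses.replace(trait_architecture("SIM4"), n_qtl=20)
        dos = rng.integers(0, 3, (200, 20)).astype(float)
        eff = sample_qtl_effects(t, dos, rng)
        assert np.var(dos @ eff) == pytest.approx(0.33 * 0.13, rel=1e-9)

    def test_monomorphic_founders_degenerate(self, rng):
        t = dataclasses.replace(trait_architecture("SIM4"), n_qtl=5)
        with pytest.raises(ConfigError, match="monomorphic"):
            sample_qtl_effects(t, np.full((50, 5), 2.0), rng)


class TestFullSimulation:
    def test_determinism_bitwise(self, toy_genome):
        t = trait_architecture("SIM5", toy_genome)
        a = simulate_population(toy_genome, t, PopulationDesign.toy(), seed=9)
        b = simulate_population(toy_genome, t, PopulationDesign.toy(), seed=9)
        assert a.pedigree.equals(b.pedigree)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.phenotype, b.phenotype)

    def test_pedigree_acyclic_parents_precede(self, toy_pop_sim5):
        ped = toy_pop_sim5.pedigree
        ids = ped["id"].to_numpy()
        for col in ("sire", "dam"):
            parents = ped[col].to_numpy()
            known = parents > 0
            assert np.all(parents[known] < ids[known])

    def test_f1_parentage(self, toy_pop_sim5):
        pop = toy_pop_sim5
        ped = pop.pedigree.set_index("id")
        for k in range(1, 5):
            g1, g2 = pop.design.f1_parent_generations(k)
            for _, row in ped[ped["population"] == f"F1-{k}"].iterrows():
                assert ped.loc[row["dam"], "population"] == "Line1"
                assert ped.loc[row["dam"], "generation"] == g1
                assert ped.loc[row["sire"], "population"] == "Line2"
                assert ped.loc[row["sire"], "generation"] == g2

    def test_cohorts_disjoint(self, toy_pop_sim5):
        pop = toy_pop_sim5
        f1 = [pop.ids(population=f"F1-{k}") for k in range(1, 5)]
        allf1 = np.concatenate(f1)
        assert len(np.unique(allf1)) == len(allf1)

    def test_founder_variance_bookkeeping(self, toy_genome):
        """Var(TBV) ~ h2*vp and Var(QTL part) = h2_qtl*vp in founders."""
        t = trait_architecture("SIM5", toy_genome)
        pop = simulate_population(toy_genome, t, PopulationDesign.toy(), seed=21)
        founders = pop.cohorts["POP:g0"] - 1
        assert np.var(pop.tbv_qtl[founders]) == pytest.approx(0.33 * 0.13, rel=1e-6)
        assert np.var(pop.tbv[founders]) == pytest.approx(0.33 * 0.13, rel=1e-6)

    def test_phenotypic_variance_near_vp(self, toy_genome):
        reps = [
            simulate_population(
                toy_genome, trait_architecture("SIM5", toy_genome),
                PopulationDesign.toy(), seed=100 + s,
            )
            for s in range(3)
        ]
        v = np.mean([np.var(p.phenotype[p.cohorts["POP:g0"] - 1]) for p in reps])
        assert v == pytest.approx(0.13, rel=0.35)

    def test_downward_selection_reduces_means(self, toy_pop_sim5):
        pop = toy_pop_sim5
        d = pop.design
        base = pop.tbv[pop.cohorts["POP:g0"] - 1].mean()
        l2 = pop.tbv[pop.ids(population="Line2", generation=d.line2_gens) - 1].mean()
        assert l2 < base

    def test_line2_more_inbred_than_line1(self, toy_pop_sim5):
        pop = toy_pop_sim5
        d = pop.design
        f1 = pop.inbreeding[pop.ids(population="Line1", generation=d.line1_gens) - 1].mean()
        f2 = pop.inbreeding[pop.ids(population="Line2", generation=d.line2_gens) - 1].mean()
        assert f2 > f1


class TestMendelianForcing:
    def test_f1_heterozygous_when_parents_fixed_alternate(self, rng):
        loci = two_locus_map(10.0)
        sire_haps = np.zeros((2, 2), dtype=np.uint8)
        dam_haps = np.ones((2, 2), dtype=np.uint8)
        child = meiosis(sire_haps, loci, 0.0, rng) + meiosis(dam_haps, loci, 0.0, rng)
        assert np.all(child == 1)


class TestGeneDropAudit:
    def test_replay_reconstructs_every_haplotype(self, toy_genome):
        """Each transmitted haplotype equals the recorded strand gather of
        the parental haplotypes plus the logged mutations."""
        t = trait_architecture("SIM1", toy_genome)
        design = PopulationDesign.toy()
        pop = simulate_population(toy_genome, t, design, seed=5, track_origins=True)
        L = pop.loci.n_loci
        checked = 0
        for (popname, gen), rec in pop.origins.items():
            ids = rec["ids"]
            ped = pop.pedigree.set_index("id").loc[ids]
            for side, strands, muts in (
                ("sire", rec["pat_strands"], rec["pat_mut"]),
                ("dam", rec["mat_strands"], rec["mat_mut"]),
            ):
                parents = ped[side].to_numpy()
                expect = np.empty((len(ids), L), dtype=np.uint8)
                for r, par in enumerate(parents):
                    ph = pop.haplotypes[2 * (par - 1) : 2 * par]
                    expect[r] = ph[strands[r], np.arange(L)]
                if muts is not None:
                    expect[muts[0], muts[1]] ^= 1
                got = pop.haplotypes[2 * (ids - 1) + (0 if side == "sire" else 1)]
                assert np.array_equal(got, expect)
                checked += len(ids)
        assert checked > 100


class TestDesign:
    def test_scaled_design_sire_calibration(self):
        d = PopulationDesign.scaled(0.05)
        # Line2/F1 sires at full count (Ne-dominant); Line1 sires reduced to
        # match the full design's realized inbreeding under intense selection
        assert d.line1_sires == 128 and d.line2_sires == 64 and d.f1_sires == 60
        assert d.line1_dams == 1600 and d.line2_dams == 160
        assert d.expansion_target >= 2 * (d.line1_dams + d.line2_dams)

    def test_scale_males_option(self):
        d = PopulationDesign.scaled(0.05, scale_males=True)
        assert d.line1_sires == 32 and d.line2_sires == 3

    def test_f1_parent_generations_full_design(self):
        d = PopulationDesign.full()
        assert [d.f1_parent_generations(k) for k in (1, 2, 3, 4)] == [
            (7, 27), (8, 28), (9, 29), (10, 30)
        ]

    def test_insufficient_expansion_is_config_error(self, toy_genome):
        bad = dataclasses.replace(
            PopulationDesign.toy(), litter_size=1, expansion_target=10000
        )
        with pytest.raises(ConfigError, match="expansion"):
            PopulationBuilder(
                toy_genome, trait_architecture("SIM1", toy_genome), bad, seed=0
            )

    def test_founder_sampling_needs_large_enough_pool(self, toy_genome):
        bad = dataclasses.replace(
            PopulationDesign.toy(), hist_phases=((20, 2),), n_founder_males=50
        )
        b = PopulationBuilder(
            toy_genome, trait_architecture("SIM1", toy_genome), bad, seed=0
        )
        with pytest.raises(ConfigError, match="founders"):
            b.found_from_history()

    def test_zero_line_generations_is_identity(self, toy_genome):
        t = trait_architecture("SIM1", toy_genome)
        b = PopulationBuilder(toy_genome, t, PopulationDesign.toy(), seed=2)
        b.found_from_history()
        b.expand_population()
        b.sample_line_bases()
        before = b._line_parents["Line1"]
        n_before = b.n
        b.breed_line("Line1", n_generations=0)
        after = b._line_parents["Line1"]
        assert b.n == n_before
        assert np.array_equal(before[0], after[0]) and np.array_equal(before[1], after[1])
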