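"""Synthetic-data generator: populations, efficiencies, read sampling, artefacts."""

import numpy as np
import pytest

from ampliprofile import iupac, panels
from ampliprofile.primers import CONVENTIONAL, DegeneratePrimer, PCRAssay
from ampliprofile.simulate import (
    AmpliconReadSet,
    ArtefactModel,
    EfficiencyModel,
    IndividualGenotype,
    ReadOrigin,
    SimulatedAllele,
    allele_efficiency,
    default_flank_haplotypes,
    inject_artefacts,
    min_loci_for_profile,
    pcr_efficiency,
    sample_amplicon_reads,
    simulate_dataset,
    simulate_population,
)


def _allele(fwd="GCTCCCACTCCCTGAGGTAT", core="ACGT" * 10, rev=None):
    rev = rev or iupac.reverse_complement("GGACTCGCTCTGGTTGTAGT")
    return SimulatedAllele("A00", core, fwd, rev, "L0")


def _pair_assay(fwd_seq, rev_seq, fraction=1.0):
    f = DegeneratePrimer("F", "F", fwd_seq, "forward")
    r = DegeneratePrimer("R", "R", rev_seq, "reverse")
    return PCRAssay("pcr", ((f, 1.0),), ((r, 1.0),), fraction)


class TestPopulation:
    def test_deterministic_for_fixed_seed(self):
        a1, g1 = simulate_population(seed=7)
        a2, g2 = simulate_population(seed=7)
        assert a1 == a2 and g1 == g2

    def test_structure_matches_requested_sizes(self):
        alleles, genotypes = simulate_population(
            n_individuals=5, n_loci=7, allele_pool_size=13, seed=0
        )
        assert len(alleles) == 13
        assert len(genotypes) == 5
        assert len({a.locus_id for a in alleles.values()}) == 7
        # alleles only at their own locus, copy numbers diploid
        for g in genotypes:
            for locus, pair in g.loci:
                for aid in pair:
                    assert alleles[aid].locus_id == locus
            assert all(g.copy_number(a) in (1, 2) for a in g.allele_ids())

    def test_core_sequences_pairwise_distinct(self):
        alleles, _ = simulate_population(seed=3)
        cores = [a.core_sequence for a in alleles.values()]
        assert len(set(cores)) == len(cores)

    def test_flanks_drawn_from_supplied_haplotype_set(self):
        flanks = default_flank_haplotypes(13)
        alleles, _ = simulate_population(seed=0, flank_haplotypes=flanks)
        assert {(a.forward_flank, a.reverse_flank) for a in alleles.values()} <= set(flanks)

    def test_all_homozygous_single_individual(self):
        alleles, genotypes = simulate_population(
            n_individuals=1, n_loci=7, allele_pool_size=7, seed=0
        )
        g = genotypes[0]
        assert len(g.allele_ids()) <= 7
        homo = [a for a in g.allele_ids() if g.copy_number(a) == 2]
        hetero = [a for a in g.allele_ids() if g.copy_number(a) == 1]
        assert len(homo) * 2 + len(hetero) == 14  # 7 diploid loci

    def test_bad_frequency_vector_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            simulate_population(
                n_individuals=1, n_loci=1, allele_pool_size=2,
                allele_frequencies={"L0": [0.5, 0.4]}, seed=0,
            )

    def test_pool_smaller_than_loci_rejected(self):
        with pytest.raises(ValueError):
            simulate_population(n_loci=5, allele_pool_size=3)


def test_thirteen_alleles_need_at_least_seven_loci():
    assert min_loci_for_profile(13) == 7
    # diploid arithmetic: each locus contributes at most two distinct alleles
    for n in range(0, 20):
        assert 2 * min_loci_for_profile(n) >= n > 2 * (min_loci_for_profile(n) - 1)


class TestEfficiencyModel:
    def test_perfect_nondegenerate_pair_anchors_at_one(self):
        allele = _allele()
        assay = _pair_assay(allele.forward_flank, "GGACTCGCTCTGGTTGTAGT")
        model = EfficiencyModel()
        assert pcr_efficiency(allele, assay, model) == pytest.approx(1.0)

    def test_single_internal_mismatch_applies_lambda(self):
        allele = _allele(fwd="GCTCCCACTCCCTCAGGTAT")  # one internal difference
        assay = _pair_assay("GCTCCCACTCCCTGAGGTAT", "GGACTCGCTCTGGTTGTAGT")
        model = EfficiencyModel(lambda_internal=0.2)
        assert pcr_efficiency(allele, assay, model) == pytest.approx(0.2)

    def test_three_prime_window_mismatch_is_harsher(self):
        allele = _allele(fwd="GCTCCCACTCCCTGAGGTAA")  # terminal 3' mismatch
        assay = _pair_assay("GCTCCCACTCCCTGAGGTAT", "GGACTCGCTCTGGTTGTAGT")
        model = EfficiencyModel(lambda_internal=0.2, lambda_three_prime=0.02)
        assert pcr_efficiency(allele, assay, model) == pytest.approx(0.02)

    def test_effective_concentration_divides_by_degeneracy(self):
        allele = _allele()
        degenerate = _pair_assay("GCTCCCAYTCCYTGAKGTAT", "GGMYTCGCTCTGGTTGTAGT")
        with_conc = EfficiencyModel(effective_concentration=True)
        without = EfficiencyModel(effective_concentration=False)
        assert pcr_efficiency(allele, degenerate, with_conc) == pytest.approx(1 / (8 * 4))
        assert pcr_efficiency(allele, degenerate, without) == pytest.approx(1.0)

    def test_pooled_primers_flatter_than_conventional(self):
        """With one flank haplotype per non-degenerate primer, the weighted mix
        spans a much smaller efficiency range than the single degenerate pair."""
        model = EfficiencyModel()
        flanks = default_flank_haplotypes(13)
        alleles = [
            SimulatedAllele(f"A{i}", "ACGT" * 5, f, r, "L0")
            for i, (f, r) in enumerate(flanks)
        ]
        conv = panels.conventional_assay()
        pooled = panels.pooled_primers_assay()
        conv_eff = [pcr_efficiency(a, conv[0], model) for a in alleles]
        pool_eff = [pcr_efficiency(a, pooled[0], model) for a in alleles]
        assert max(pool_eff) / min(pool_eff) < max(conv_eff) / min(conv_eff)
        # every haplotype is perfectly matched by some primer of the mix: its
        # efficiency is the product of the best same-side pool proportions
        assert min(pool_eff) > 0

    def test_per_pcr_vector_for_multi_pcr_assays(self):
        allele = _allele()
        effs = allele_efficiency(allele, panels.pooled_pcrs_assay(), EfficiencyModel())
        assert effs.shape == (4,)
        assert (effs >= 0).all()


class TestReadSampling:
    @staticmethod
    def _two_allele_genotype():
        alleles = {
            "A": SimulatedAllele("A", "AAAA" * 10, "GCTC", "GGAC", "L0"),
            "B": SimulatedAllele("B", "CCCC" * 10, "GCTC", "GGAC", "L1"),
        }
        g = IndividualGenotype("ind0", (("L0", ("A", "A")), ("L1", ("B", "B"))))
        return alleles, g

    def test_equal_efficiencies_yield_balanced_fractions(self):
        alleles, g = self._two_allele_genotype()
        rs = sample_amplicon_reads(g, alleles, {"A": 1.0, "B": 1.0}, 10000, seed=0)
        frac = sum(r == alleles["A"].sequence for r in rs.reads) / 10000
        assert abs(frac - 0.5) < 3 * 0.005  # 3 sigma of a fair binomial

    def test_nine_to_one_efficiency_ratio(self):
        alleles, g = self._two_allele_genotype()
        rs = sample_amplicon_reads(g, alleles, {"A": 0.9, "B": 0.1}, 10000, seed=1)
        frac = sum(r == alleles["A"].sequence for r in rs.reads) / 10000
        assert abs(frac - 0.9) < 3 * np.sqrt(0.9 * 0.1 / 10000)

    def test_expected_fraction_ranking_follows_efficiency_times_copy(self):
        alleles = {
            f"A{i}": SimulatedAllele(f"A{i}", f"{'ACGT' * 10}{i}A", "GCTC", "GGAC", f"L{i}")
            for i in range(4)
        }
        g = IndividualGenotype(
            "ind0",
            tuple((f"L{i}", (f"A{i}", f"A{i}" if i % 2 else f"A{(i+1)%4}")) for i in range(4)),
        )
        effs = {f"A{i}": 0.1 * (i + 1) for i in range(4)}
        rs = sample_amplicon_reads(g, alleles, effs, 50000, seed=2)
        weights = {a: effs[a] * g.copy_number(a) for a in g.allele_ids()}
        counts = {a: sum(r == alleles[a].sequence for r in rs.reads) for a in weights}
        assert sorted(weights, key=weights.get) == sorted(counts, key=counts.get)

    def test_zero_depth_is_empty(self):
        alleles, g = self._two_allele_genotype()
        rs = sample_amplicon_reads(g, alleles, {"A": 1.0, "B": 1.0}, 0, seed=0)
        assert rs.reads == [] and rs.origins == []

    def test_all_zero_efficiencies_rejected(self):
        alleles, g = self._two_allele_genotype()
        with pytest.raises(ValueError, match="no amplifiable template"):
            sample_amplicon_reads(g, alleles, {"A": 0.0, "B": 0.0}, 10, seed=0)


class TestArtefacts:
    @staticmethod
    def _read_set(n_a=60, n_b=40, length=200):
        rng = np.random.default_rng(42)
        a = "".join(rng.choice(list("ACGT"), size=length))
        b = "".join(rng.choice(list("ACGT"), size=length))
        reads = [a] * n_a + [b] * n_b
        origins = [ReadOrigin(allele_id="A")] * n_a + [ReadOrigin(allele_id="B")] * n_b
        return AmpliconReadSet("ind0", CONVENTIONAL, "pcr1", reads, origins), a, b

    def test_zero_rates_are_a_no_op(self):
        rs, _, _ = self._read_set()
        out = inject_artefacts(rs, ArtefactModel(0.0, 0.0, 0.0), seed=0)
        assert out.reads == rs.reads
        assert out.origins == rs.origins

    def test_chimera_is_prefix_plus_suffix_of_parents(self):
        a, b = "A" * 50, "C" * 50
        rs = AmpliconReadSet(
            "i", CONVENTIONAL, "p",
            [a] * 10 + [b] * 10,
            [ReadOrigin(allele_id="A")] * 10 + [ReadOrigin(allele_id="B")] * 10,
        )
        out = inject_artefacts(rs, ArtefactModel(0.5, 0.0, 0.0), seed=5)
        chimeric = [
            (read, o) for read, o in zip(out.reads, out.origins) if o.kind == "chimera"
        ]
        assert chimeric
        for read, o in chimeric:
            k = o.breakpoint
            assert 1 <= k <= 49
            first, second = ("A", "C") if read[0] == "A" else ("C", "A")
            assert read == first * k + second * (50 - k)
            assert set(o.parents) == {"A", "B"}

    def test_chimera_requires_two_distinct_parents(self):
        a = "ACGT" * 25
        rs = AmpliconReadSet(
            "i", CONVENTIONAL, "p", [a] * 20, [ReadOrigin(allele_id="A")] * 20
        )
        out = inject_artefacts(rs, ArtefactModel(1.0, 0.0, 0.0), seed=0)
        assert all(o.kind != "chimera" for o in out.origins)

    def test_substitution_count_follows_poisson_expectation(self):
        # 500 reads x 200 bases = 1e5 bases at 1e-3 -> 100 +- 30 substitutions
        rs, a, b = self._read_set(n_a=300, n_b=200, length=200)
        out = inject_artefacts(rs, ArtefactModel(0.0, 1e-3, 0.0), seed=11)
        n_sub = 0
        for read, origin in zip(out.reads, rs.reads):
            n_sub += sum(x != y for x, y in zip(read, origin))
        assert 70 <= n_sub <= 130

    def test_homopolymer_indels_change_run_lengths_by_one(self):
        seq = "ACGT" * 10 + "AAAA" + "ACGT" * 10
        rs = AmpliconReadSet(
            "i", CONVENTIONAL, "p", [seq] * 200, [ReadOrigin(allele_id="A")] * 200
        )
        out = inject_artefacts(rs, ArtefactModel(0.0, 0.0, 0.5), seed=3)
        lengths = {len(r) for r in out.reads}
        assert lengths == {len(seq) - 1, len(seq), len(seq) + 1}
        errored = [o for o in out.origins if o.errored]
        assert len(errored) > 0

    def test_truth_table_covers_every_read(self):
        rs, _, _ = self._read_set()
        out = inject_artefacts(rs, ArtefactModel(), seed=0)
        assert len(out.reads) == len(out.origins)


class TestDataset:
    def test_dataset_deterministic(self):
        d1 = simulate_dataset(n_individuals=2, allele_pool_size=7, depth=200, seed=9)
        d2 = simulate_dataset(n_individuals=2, allele_pool_size=7, depth=200, seed=9)
        assert [rs.reads for rs in d1.read_sets] == [rs.reads for rs in d2.read_sets]
        assert d1.true_efficiencies == d2.true_efficiencies

    def test_amplicon_layout_per_strategy(self, study_dataset):
        keys = {rs.key for rs in study_dataset.read_sets}
        # per individual: 1 conventional + 4 pooled-PCRs + 1 pooled-primers
        assert len(keys) == 18 * 6
        per_strategy = {}
        for _, strategy, pcr in keys:
            per_strategy.setdefault(strategy, set()).add(pcr)
        assert len(per_strategy["pooled_pcrs"]) == 4
        assert len(per_strategy[CONVENTIONAL]) == 1

    def test_efficiency_spread_spans_two_orders_of_magnitude(self, study_dataset):
        conv = [
            v for (s, _), v in study_dataset.true_efficiencies.items()
            if s == CONVENTIONAL
        ]
        assert max(conv) / min(conv) > 100

    def test_unbiased_fractions_without_bias_or_artefacts(self):
        """Equal efficiencies, no artefacts: per-copy read fractions are unbiased
        (chi-squared goodness of fit against copy-number proportions)."""
        from scipy.stats import chisquare

        alleles, genotypes = simulate_population(
            n_individuals=1, n_loci=4, allele_pool_size=8, seed=21
        )
        g = genotypes[0]
        effs = {a: 1.0 for a in g.allele_ids()}
        rs = sample_amplicon_reads(g, alleles, effs, 10000, seed=21)
        ids = sorted(g.allele_ids())
        counts = [sum(r == alleles[a].sequence for r in rs.reads) for a in ids]
        copies = np.array([g.copy_number(a) for a in ids], dtype=float)
        expected = 10000 * copies / copies.sum()
        assert chisquare(counts, expected).pvalue > 1e-3
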