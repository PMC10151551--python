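"""Directional genotype containment, selfing-generation estimation and
phased-haplotype matching."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitikin.descent import (
    containment_test,
    descent_report,
    directionality,
    haplotype_containment,
    selfing_generations,
)
from vitikin.genotype import MISSING
from vitikin.simulate import (
    PedigreeEvent,
    PedigreeSpec,
    SimConfig,
    breed,
    degrade,
    simulate_founders,
)

# dosage encodings: AA=0, Aa=1, aa=2


class TestContainment:
    def test_error_rate_arithmetic(self):
        """45 violating alleles over 6,896 diploid sites -> 0.33%."""
        from vitikin.descent import ContainmentResult

        r = ContainmentResult("P", "O", n_sites_compared=6896,
                              n_violating_alleles=45, allowance=45, contained=True)
        assert round(100 * r.error_rate, 2) == 0.33

    def test_offspring_homozygous_at_parent_het_sites_ok(self):
        parent = np.array([1, 0, 2])
        offspring = np.array([2, 0, 2])
        r = containment_test(parent, offspring, allowance=0)
        assert r.n_violating_alleles == 0
        assert r.contained

    def test_double_violation_at_opposite_homozygote(self):
        parent = np.array([1, 0, 2])
        offspring = np.array([2, 2, 2])
        r = containment_test(parent, offspring, allowance=0)
        assert r.n_violating_alleles == 2
        assert not r.contained

    def test_missing_sites_skipped(self):
        parent = np.array([0, MISSING, 2])
        offspring = np.array([0, 2, MISSING])
        r = containment_test(parent, offspring, allowance=0)
        assert r.n_sites_compared == 1

    def test_rate_allowance_converts_to_count(self):
        parent = np.zeros(1000)
        offspring = np.zeros(1000)
        offspring[:4] = 1
        r = containment_test(parent, offspring, allowance=0.005)
        assert r.allowance == 10  # floor(0.005 * 2000)
        assert r.n_violating_alleles == 4
        assert r.contained

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=1, max_size=60))
    def test_reflexivity(self, g):
        r = containment_test(np.array(g), np.array(g), allowance=0)
        assert r.n_violating_alleles == 0
        assert r.contained


class TestDirectionality:
    @staticmethod
    def _selfed_pair(seed=51):
        G = simulate_founders(SimConfig(n_founders=2, n_loci=5000, seed=seed))
        ped = PedigreeSpec([PedigreeEvent("S1", "self", ("F000",))])
        return breed(G, ped, seed=seed + 1)

    def test_parent_contains_error_free_selfed_offspring_one_way(self):
        G = self._selfed_pair()
        gp = G.dosage[G.sample_index("F000")]
        go = G.dosage[G.sample_index("S1")]
        assert directionality(gp, go, allowance=0) == "a_contains_b"

    def test_clones_are_mutual(self, family_panel):
        ga = family_panel.dosage[family_panel.sample_index("F000")]
        gb = family_panel.dosage[family_panel.sample_index("CLONE")]
        assert directionality(ga, gb, allowance=0) == "mutual"

    def test_unrelated_founders_are_neither(self):
        G = simulate_founders(SimConfig(n_founders=2, n_loci=5000, seed=53))
        assert directionality(G.dosage[0], G.dosage[1], allowance=0.005) == "neither"


class TestSelfingGenerations:
    def test_reported_het_counts_give_one_generation(self):
        """1,976 vs 913 heterozygous sites: ratio 0.462, one selfing
        generation."""
        parent = np.concatenate([np.ones(1976), np.zeros(3024)])
        offspring = np.concatenate([np.ones(913), np.zeros(4087)])
        est = selfing_generations(parent, offspring)
        assert est.het_parent == 1976
        assert est.het_offspring == 913
        assert est.ratio == pytest.approx(0.462, abs=5e-4)
        assert est.g_hat == 1
        assert est.compatible

    def test_equal_het_counts_mean_clone(self):
        g = np.array([1, 1, 0, 2, 1])
        est = selfing_generations(g, g)
        assert est.g_hat == 0
        assert est.compatible

    def test_quarter_ratio_means_two_generations(self):
        parent = np.concatenate([np.ones(400), np.zeros(600)])
        offspring = np.concatenate([np.ones(100), np.zeros(900)])
        est = selfing_generations(parent, offspring)
        assert est.ratio == 0.25
        assert est.g_hat == 2

    def test_zero_parent_het_flagged(self):
        est = selfing_generations(np.zeros(10), np.zeros(10))
        assert est.g_hat is None
        assert not est.compatible

    def test_g_hat_recovery_over_selfing_chains(self):
        """g_hat equals the true number of selfing generations in >= 95%
        of replicates, for g in 0..3 at 10,000 loci."""
        n_reps = 50
        hits = 0
        total = 0
        for rep in range(n_reps):
            G = simulate_founders(SimConfig(n_founders=1, n_loci=10_000, seed=600 + rep))
            events = [PedigreeEvent("S1", "self", ("F000",))]
            events += [PedigreeEvent(f"S{g}", "self", (f"S{g-1}",)) for g in (2, 3)]
            G = breed(G, PedigreeSpec(events), seed=700 + rep)
            gp = G.dosage[0]
            for g, child in [(0, "F000"), (1, "S1"), (2, "S2"), (3, "S3")]:
                est = selfing_generations(gp, G.dosage[G.sample_index(child)])
                hits += est.g_hat == g
                total += 1
        assert hits / total >= 0.95


class TestHaplotypeContainment:
    def test_clone_matches_both_haplotypes_exactly(self, family_panel):
        table = haplotype_containment(family_panel, "F000", "CLONE")
        assert (table["mismatch_fraction"] == 0).all()
        assert set(zip(table["offspring_hap"], table["best_parent_hap"])) == {(1, 1), (2, 2)}

    def test_selfed_offspring_haplotypes_trace_to_parent(self):
        """With no recombination each offspring chromosome copy is one of
        the parent's two haplotypes verbatim."""
        G = simulate_founders(SimConfig(n_founders=1, n_loci=1000, n_chrom=4,
                                        crossover_rate=0.0, seed=55))
        ped = PedigreeSpec([PedigreeEvent("S1", "self", ("F000",))])
        G = breed(G, ped, seed=56, crossover_rate=0.0)
        table = haplotype_containment(G, "F000", "S1")
        assert (table["mismatch_fraction"] == 0).all()

    def test_unrelated_sample_mismatch_near_expectation(self):
        """For unrelated haplotypes the best-match mismatch fraction sits
        near the Hardy-Weinberg allele-sharing expectation, far from 0."""
        G = simulate_founders(SimConfig(n_founders=2, n_loci=5000, n_chrom=1, seed=57))
        table = haplotype_containment(G, "F000", "F001")
        # mean mismatch of two independent Bernoulli(p) draws, p ~ U(.05,.95)
        assert (table["mismatch_fraction"] > 0.15).all()

    def test_unphased_input_rejected(self, family_panel):
        G = family_panel.copy()
        G.haplotypes = None
        with pytest.raises(ValueError):
            haplotype_containment(G, "F000", "CLONE")


class TestDescentReport:
    def test_error_envelope_for_degraded_selfed_pair(self):
        """At a 0.33% per-allele error rate over ~7,000 sites a true
        parent/selfed-offspring pair shows tens of violating alleles."""
        config = SimConfig(n_founders=1, n_loci=6896, error_rate=0.0033,
                           missing_rate=0.0, seed=58)
        G = simulate_founders(config)
        G = breed(G, PedigreeSpec([PedigreeEvent("S1", "self", ("F000",))]), seed=59)
        noisy = degrade(G, config, seed=60)
        r = containment_test(noisy.dosage[0], noisy.dosage[1], allowance=0.01)
        assert 10 <= r.n_violating_alleles <= 120

    def test_report_structure_and_cross_check_with_kinship(self, family_panel):
        rep = descent_report(family_panel, "F001", "SELF1", allowance=0.005)
        assert rep["verdict"] == "a_contains_b"
        assert rep["selfing"]["g_hat"] == 1
        fwd = rep["containment"]["F001_contains_SELF1"]
        assert fwd["n_violating_alleles"] == 0
        from vitikin.kinship import kinship_pair

        assert kinship_pair(family_panel, "F001", "SELF1").ibs0 == 0.0
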