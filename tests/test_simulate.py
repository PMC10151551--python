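"""Simulator statistics: Hardy-Weinberg founders, Mendelian transmission,
selfing heterozygosity decay, degradation and colour phenotypes."""

import numpy as np
import pandas as pd
import pytest

from vitikin.colorscore import EffectTable
from vitikin.genotype import MISSING
from vitikin.simulate import (
    ConfigError,
    PedigreeEvent,
    PedigreeSpec,
    SimConfig,
    breed,
    degrade,
    simulate_color,
    simulate_founders,
)


def _config(**kw):
    base = dict(n_founders=4, n_loci=100, seed=1)
    base.update(kw)
    return SimConfig(**base)


class TestFounders:
    def test_hwe_heterozygosity_at_half_frequency(self):
        config = _config(n_founders=400, n_loci=50, seed=2)
        G = simulate_founders(config, freqs=np.full(50, 0.5))
        het = (G.dosage == 1).mean(axis=0)
        # binomial SE of observed het around 2pq = 0.5 at n = 400
        assert np.all(np.abs(het - 0.5) < 3 * np.sqrt(0.25 / 400))

    def test_fixed_allele_gives_homozygous_alternate(self):
        G = simulate_founders(_config(), freqs=np.ones(100))
        assert (G.dosage == 2).all()
        assert (G.dosage == 1).sum() == 0

    def test_same_seed_reproduces_bit_identical_matrices(self):
        a = simulate_founders(_config(seed=7))
        b = simulate_founders(_config(seed=7))
        assert (a.dosage == b.dosage).all()
        assert (a.haplotypes == b.haplotypes).all()
        assert a.loci.equals(b.loci)

    def test_allele_frequency_recovery(self):
        config = _config(n_founders=1000, n_loci=40, seed=3)
        expected = np.linspace(0.05, 0.95, 40)
        G = simulate_founders(config, freqs=expected)
        freq = G.alt_freq()
        se = np.sqrt(expected * (1 - expected) / (2 * 1000))
        assert np.all(np.abs(freq - expected) < 3 * np.maximum(se, 1e-3))

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigError):
            _config(error_rate=1.5)
        with pytest.raises(ConfigError):
            _config(freq_range=(0.9, 0.1))


class TestBreed:
    def test_cross_of_opposite_homozygotes_is_heterozygous(self):
        G = simulate_founders(_config(n_founders=2))
        G.haplotypes[0] = 0
        G.haplotypes[1] = 1
        G.dosage[0] = 0
        G.dosage[1] = 2
        ped = PedigreeSpec([PedigreeEvent("X", "cross", ("F000", "F001"))])
        out = breed(G, ped, seed=4)
        assert (out.dosage[out.sample_index("X")] == 1).all()

    def test_selfing_heterozygote_segregates_1_2_1(self):
        G = simulate_founders(_config(n_founders=1, n_loci=6000, seed=5),
                              freqs=np.full(6000, 0.5))
        G.haplotypes[0, :, 0] = 0
        G.haplotypes[0, :, 1] = 1
        G.dosage[0] = 1
        ped = PedigreeSpec([PedigreeEvent("S", "self", ("F000",))])
        out = breed(G, ped, seed=6)
        counts = np.bincount(out.dosage[out.sample_index("S")], minlength=3)
        frac = counts / 6000
        assert np.abs(frac[1] - 0.5) < 3 * np.sqrt(0.25 / 6000)
        assert np.abs(frac[0] - 0.25) < 3 * np.sqrt(0.1875 / 6000)

    def test_selfing_chain_halves_heterozygosity_each_generation(self):
        config = _config(n_founders=1, n_loci=10_000, seed=7)
        G = simulate_founders(config)
        events = [PedigreeEvent("S1", "self", ("F000",))]
        events += [PedigreeEvent(f"S{g}", "self", (f"S{g-1}",)) for g in (2, 3)]
        out = breed(G, PedigreeSpec(events), seed=8)
        h0 = out.het_counts()[0]
        for g in (1, 2, 3):
            hg = out.het_counts()[out.sample_index(f"S{g}")]
            expected = h0 * 0.5**g
            se = np.sqrt(h0 * 0.5**g * (1 - 0.5**g))
            assert abs(hg - expected) < 3 * se

    def test_clone_is_genotype_identical(self, family_panel):
        i = family_panel.sample_index("F000")
        j = family_panel.sample_index("CLONE")
        assert (family_panel.dosage[i] == family_panel.dosage[j]).all()

    def test_ancestry_tracing(self, family_panel):
        """Every offspring allele carries a founder-haplotype label, and a
        cross child has exactly one allele per parent per locus."""
        G = family_panel
        n_founders = 6
        assert G.ancestry.min() >= 0
        assert G.ancestry.max() < 2 * n_founders
        child = G.ancestry[G.sample_index("CHILD")] // 2  # founder index per allele
        p1, p2 = G.sample_index("F002"), G.sample_index("F003")
        assert set(np.unique(child[:, 0])) <= {p1, p2}
        from_p1 = (child == p1).sum(axis=1)
        from_p2 = (child == p2).sum(axis=1)
        assert ((from_p1 == 1) & (from_p2 == 1)).all()

    def test_unknown_parent_rejected(self):
        G = simulate_founders(_config())
        ped = PedigreeSpec([PedigreeEvent("X", "cross", ("F000", "NOPE"))])
        with pytest.raises(KeyError):
            breed(G, ped, seed=1)


class TestDegrade:
    def test_zero_noise_is_identity(self, family_panel):
        config = _config(error_rate=0.0, missing_rate=0.0)
        out = degrade(family_panel, config, seed=9)
        assert (out.dosage == family_panel.dosage).all()
        assert (out.haplotypes == family_panel.haplotypes).all()

    def test_expected_flip_count_matches_error_rate(self):
        """0.33% per-allele error over 2 x 6,896 allele copies flips ~45."""
        config = SimConfig(n_founders=1, n_loci=6896, error_rate=0.0033, seed=10)
        G = simulate_founders(config)
        n_alleles = 2 * 6896
        flips = []
        for s in range(20):
            out = degrade(G, config, seed=100 + s)
            flips.append(int((out.haplotypes != G.haplotypes).sum()))
        mean_expected = n_alleles * 0.0033  # = 45.5
        se = np.sqrt(mean_expected / 20)
        assert abs(np.mean(flips) - mean_expected) < 4 * se

    def test_full_missingness_blanks_the_sample(self, family_panel):
        config = _config(missing_rate={"F000": 1.0})
        out = degrade(family_panel, config, seed=11)
        assert (out.dosage[out.sample_index("F000")] == MISSING).all()
        assert (out.dosage[out.sample_index("F001")] != MISSING).all()

    def test_input_matrix_unmodified(self, family_panel):
        before = family_panel.dosage.copy()
        degrade(family_panel, _config(error_rate=0.1, missing_rate=0.5), seed=12)
        assert (family_panel.dosage == before).all()

    def test_depth_is_poisson_around_mean(self, family_panel):
        config = _config(mean_depth=12.0, missing_rate=0.0, error_rate=0.0)
        out = degrade(family_panel, config, seed=13)
        assert out.depth.shape == (family_panel.n_samples, family_panel.n_loci)
        assert abs(out.depth.mean() - 12.0) < 0.2


class TestColor:
    @staticmethod
    def _effects(G, betas):
        rows = [
            (G.loci["chrom"].iloc[j], G.loci["pos"].iloc[j], G.loci["alt"].iloc[j], b)
            for j, b in betas
        ]
        return EffectTable(pd.DataFrame(rows, columns=["chrom", "pos", "effect_allele", "beta"]))

    def test_zero_effects_give_white(self):
        G = simulate_founders(_config())
        df = simulate_color(G, self._effects(G, [(0, 0.0), (1, 0.0)]), noise_sd=0.0)
        assert (df["grade"] == 0).all()
        assert (df["color"] == "white").all()

    def test_single_strong_locus_saturates_to_black(self):
        G = simulate_founders(_config(n_founders=1), freqs=np.ones(100))
        df = simulate_color(G, self._effects(G, [(0, 2.0)]), noise_sd=0.0)
        assert df["grade"].iloc[0] == 4.0
        assert df["color"].iloc[0] == "black"

    def test_noiseless_category_is_deterministic_in_dosage(self):
        G = simulate_founders(_config(n_founders=30, seed=21))
        eff = self._effects(G, [(0, 1.0), (1, 0.7), (2, -0.4)])
        a = simulate_color(G, eff, noise_sd=0.0, seed=1)
        b = simulate_color(G, eff, noise_sd=0.0, seed=999)
        assert (a["category"] == b["category"]).all()
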