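"""Generator contracts: determinism, union structure, Mendelian frequencies."""

import numpy as np
import pytest

from plumhap.model import ConfigurationError, Region
from plumhap.simulate import (
    SimulationConfig,
    simulate_alignment,
    simulate_catalog,
    simulate_depth,
    simulate_families,
    simulate_family,
    simulate_panel,
)


class TestCatalog:
    def test_pinned_structure_matches_published_copy_counts(self, gene_map):
        cat, gmap = simulate_catalog(SimulationConfig(seed=0))
        counts = {
            h.id: sum(1 for b in h.bands if gmap.get(b) == "G1") for h in cat.haplotypes
        }
        assert counts == {"H1": 3, "H2": 1, "H3": 3, "H4": 2, "H5": 1, "H6": 1}

    def test_random_catalog_respects_cluster_constraints(self):
        cfg = SimulationConfig(seed=11, haplotype_compositions=None)
        cfg.haplotype_compositions = None  # force the random pathway
        cat, gmap = simulate_catalog(cfg)
        mono = cat.monomorphic_bands()
        assert len(mono) >= 1
        for h in cat.haplotypes:
            groups = [gmap[b] for b in h.bands]
            assert 1 <= groups.count("G1") <= 3
            assert groups.count("G2") == 1
            assert groups.count("G3") == 1

    def test_random_catalog_deterministic_and_seed_sensitive(self):
        def build(seed):
            cfg = SimulationConfig(seed=seed)
            cfg.haplotype_compositions = None
            cat, _ = simulate_catalog(cfg)
            return {h.id: h.bands for h in cat.haplotypes}

        assert build(3) == build(3)
        assert build(3) != build(4)

    def test_infeasible_band_count_rejected(self):
        cfg = SimulationConfig(seed=0, band_size_range=(243, 260), n_haplotypes=6)
        cfg.haplotype_compositions = None
        with pytest.raises(ConfigurationError, match="cannot place"):
            simulate_catalog(cfg)


class TestPanel:
    def test_noise_free_bands_are_union_of_truth_haplotypes(self):
        cfg = SimulationConfig(seed=2, penetrance=1.0)
        cat, _ = simulate_catalog(cfg)
        panel = simulate_panel(cfg, cat)
        haps = {h.id: h.bands for h in cat.haplotypes}
        from plumhap.simulate import rare_haplotype_definitions

        haps.update(rare_haplotype_definitions())
        for g in panel.genotypes:
            ha, hb = panel.truth_diplotypes[g.accession]
            assert g.bands == haps[ha] | haps[hb]

    def test_penetrance_one_means_color_iff_band_carrier(self):
        cfg = SimulationConfig(seed=2, penetrance=1.0)
        cat, _ = simulate_catalog(cfg)
        panel = simulate_panel(cfg, cat)
        pheno = {p.accession: p for p in panel.phenotypes}
        for g in panel.genotypes:
            assert pheno[g.accession].skin_binary == ("a356" in g.bands)

    def test_heterozygote_fraction_matches_hardy_weinberg(self):
        # two haplotypes at 50/50: expected heterozygote fraction 1/2
        cfg = SimulationConfig(
            seed=5,
            n_accessions=10_000,
            haplotype_frequencies={"H1": 0.5, "H2": 0.5},
            rare_accessions=[],
        )
        cat, _ = simulate_catalog(cfg)
        panel = simulate_panel(cfg, cat)
        het = sum(a != b for a, b in panel.truth_diplotypes.values())
        n = len(panel.truth_diplotypes)
        sd = np.sqrt(0.25 * n)
        assert abs(het - 0.5 * n) < 3 * sd

    def test_collision_hides_band_from_matrix(self):
        cfg = SimulationConfig(seed=3, collision_pairs=[("a473", "a470")])
        cat, _ = simulate_catalog(cfg)
        panel = simulate_panel(cfg, cat)
        assert not any("a473" in g.bands for g in panel.genotypes)

    def test_deterministic_under_seed(self):
        def run(seed):
            cfg = SimulationConfig(seed=seed)
            cat, _ = simulate_catalog(cfg)
            return [g.bands for g in simulate_panel(cfg, cat).genotypes]

        assert run(7) == run(7)
        assert run(7) != run(8)


class TestFamily:
    def test_noise_free_progeny_are_pairwise_unions(self):
        cfg = SimulationConfig(seed=1)
        cat, _ = simulate_catalog(cfg)
        haps = {h.id: h.bands for h in cat.haplotypes}
        fr = simulate_family("F", ("H3", "H4"), ("H1", "H2"), 60, cfg, cat)
        allowed = {
            haps[a] | haps[b] for a in ("H3", "H4") for b in ("H1", "H2")
        }
        for child in fr.family.progeny:
            assert child.bands in allowed

    def test_homozygous_parent_always_transmits(self):
        cfg = SimulationConfig(seed=1)
        cat, _ = simulate_catalog(cfg)
        fr = simulate_family("F", ("H1", "H5"), ("H3", "H3"), 40, cfg, cat)
        # every progeny carries the full H3 set from the homozygous parent
        h3 = cat.haplotype("H3").bands
        for child in fr.family.progeny:
            assert h3 <= child.bands

    def test_transmission_frequency_is_binomial_half(self):
        cfg = SimulationConfig(seed=9)
        cat, _ = simulate_catalog(cfg)
        n = 10_000
        fr = simulate_family("F", ("H3", "H4"), ("H1", "H2"), n, cfg, cat)
        k = sum(1 for hs, _ in fr.truth_transmissions if hs == "H3")
        assert abs(k - n / 2) < 3 * np.sqrt(n * 0.25)

    def test_unknown_haplotype_rejected(self):
        cfg = SimulationConfig(seed=1)
        cat, _ = simulate_catalog(cfg)
        with pytest.raises(ConfigurationError, match="H99"):
            simulate_family("F", ("H1", "H99"), ("H2", "H3"), 10, cfg, cat)

    def test_default_design_covers_all_six_haplotypes(self):
        cfg = SimulationConfig(seed=1)
        cat, _ = simulate_catalog(cfg)
        fams = simulate_families(cfg, cat, n_progeny=5)
        parents = {h for fr in fams for pair in fr.truth_parents for h in pair}
        assert parents == {"H1", "H2", "H3", "H4", "H5", "H6"}


class TestDepth:
    CLUSTER = Region("LG3", 50_000, 70_000)
    GENES = {
        "G1": Region("LG3", 52_000, 54_000),
        "G2": Region("LG3", 58_000, 60_000),
        "G3": Region("LG3", 64_000, 66_000),
    }

    def test_zero_noise_returns_exact_multipliers(self):
        cfg = SimulationConfig(seed=0, poisson_noise=False, mean_coverage=30)
        track = simulate_depth(cfg, self.CLUSTER, self.GENES, {"G1": 6, "G2": 2, "G3": 2})
        g1 = track.region_depths(self.GENES["G1"])
        assert np.allclose(g1, 90.0)  # 6 copies vs diploid baseline -> x3
        inter = track.region_depths(Region("LG3", 55_000, 56_000))
        assert np.allclose(inter, 30.0)

    def test_empty_layout_rejected(self):
        cfg = SimulationConfig(seed=0)
        with pytest.raises(ConfigurationError, match="empty"):
            simulate_depth(cfg, self.CLUSTER, {}, {})

    def test_poisson_mean_recovers_multiplier(self):
        cfg = SimulationConfig(seed=4, mean_coverage=30)
        track = simulate_depth(cfg, self.CLUSTER, self.GENES, {"G1": 6, "G2": 2, "G3": 2})
        g1 = track.region_depths(self.GENES["G1"])
        assert abs(g1.mean() / 30.0 - 3.0) < 0.05


class TestAlignment:
    def test_zero_rates_give_identical_sequences(self):
        cfg = SimulationConfig(
            seed=0, exon_sub_rate=0.0, intron_sub_rate=0.0, intron_indel_prob=0.0
        )
        recs, _ = simulate_alignment(cfg)
        assert len({s for _, s in recs}) == 1

    def test_exon_rate_zero_puts_all_diversity_in_intron(self):
        from plumhap.seqdiv import AlignedSet, nucleotide_diversity

        cfg = SimulationConfig(
            seed=1, exon_sub_rate=0.0, intron_sub_rate=0.05, intron_indel_prob=0.0
        )
        recs, mask = simulate_alignment(cfg)
        res = nucleotide_diversity(AlignedSet.from_records(recs), partition_mask=mask)
        assert res.partitions["exon"].pi == 0.0
        assert res.partitions["intron"].pi > 0.0

    def test_substitution_rate_recovers_target_diversity(self):
        # pairwise-diff probability for two independently mutated copies at
        # per-site rate r is 2r(1-r) + r^2 * 2/3
        from plumhap.seqdiv import AlignedSet, nucleotide_diversity

        r = 0.05
        expected = 2 * r * (1 - r) + r * r * 2 / 3
        pis = []
        for seed in range(30):
            cfg = SimulationConfig(
                seed=seed, exon_sub_rate=r, intron_sub_rate=r, intron_indel_prob=0.0
            )
            recs, _ = simulate_alignment(cfg)
            pis.append(nucleotide_diversity(AlignedSet.from_records(recs)).pi)
        assert abs(np.mean(pis) - expected) < 0.01
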