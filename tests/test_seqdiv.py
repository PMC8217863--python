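"""Diversity, Ka/Ks, TN93 and UPGMA against independent oracles."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from plumhap.model import ValidationError
from plumhap.seqdiv import (
    AlignedSet,
    bootstrap_supports,
    distance_matrix,
    ka_ks_pair,
    ka_ks_panel,
    nucleotide_diversity,
    tn93_distance,
    upgma,
)
from plumhap.simulate import SimulationConfig, simulate_alignment


def brute_force_pi(seqs, gap_mode):
    """Independent pairwise-counting oracle."""
    props = []
    for s1, s2 in combinations(seqs, 2):
        d = L = 0
        for x, y in zip(s1, s2):
            if "N" in (x, y):
                continue
            if gap_mode == "gap_as_state":
                if (x, y) == ("-", "-"):
                    continue
                L += 1
                d += x != y
            else:
                if "-" in (x, y):
                    continue
                L += 1
                d += x != y
        props.append(d / L)
    return sum(props) / len(props)


class TestNucleotideDiversity:
    TOY = ["ACGT-TAGGC", "ACGTATAGGC", "AC-TATCGGC", "ACGTTTCG-C"]

    def test_identical_sequences_zero_under_every_mode(self):
        aln = AlignedSet(["a", "b", "c"], ["ACGTACGT"] * 3)
        for mode in ("gap_as_state", "pairwise_deletion", "complete_deletion"):
            assert nucleotide_diversity(aln, gap_mode=mode).pi == 0.0

    def test_two_sequences_two_mismatches_over_ten_sites(self):
        aln = AlignedSet(["a", "b"], ["ACGTACGTAC", "ACGTACGTGG"])
        assert nucleotide_diversity(aln).pi == pytest.approx(0.2)

    @pytest.mark.parametrize("mode", ["gap_as_state", "pairwise_deletion"])
    def test_gapped_toy_matches_brute_force(self, mode):
        aln = AlignedSet([f"s{i}" for i in range(4)], self.TOY)
        assert nucleotide_diversity(aln, gap_mode=mode).pi == pytest.approx(
            brute_force_pi(self.TOY, mode)
        )

    def test_complete_deletion_equals_brute_force_on_shared_columns(self):
        aln = AlignedSet([f"s{i}" for i in range(4)], self.TOY)
        keep = [i for i in range(10) if all(s[i] != "-" for s in self.TOY)]
        stripped = ["".join(s[i] for i in keep) for s in self.TOY]
        assert nucleotide_diversity(aln, gap_mode="complete_deletion").pi == pytest.approx(
            brute_force_pi(stripped, "pairwise_deletion")
        )

    def test_invariant_under_sequence_reordering(self):
        aln1 = AlignedSet([f"s{i}" for i in range(4)], self.TOY)
        aln2 = AlignedSet([f"s{i}" for i in range(4)], list(reversed(self.TOY)))
        assert nucleotide_diversity(aln1).pi == nucleotide_diversity(aln2).pi

    def test_partition_pi_computed_on_masked_columns(self):
        aln = AlignedSet(["a", "b"], ["AAAACCCC", "AAAAGGGG"])
        mask = np.array([False] * 4 + [True] * 4)
        res = nucleotide_diversity(aln, partition_mask=mask)
        assert res.partitions["intron"].pi == 1.0
        assert res.partitions["exon"].pi == 0.0

    def test_single_sequence_rejected(self):
        with pytest.raises(ValidationError):
            nucleotide_diversity(AlignedSet(["a"], ["ACGT"]))

    def test_simulated_intron_exceeds_exon_diversity(self):
        cfg = SimulationConfig(seed=2)
        recs, mask = simulate_alignment(cfg)
        res = nucleotide_diversity(AlignedSet.from_records(recs), partition_mask=mask)
        assert res.partitions["intron"].pi > res.partitions["exon"].pi


class TestKaKs:
    def test_identical_sequences_undefined_ratio(self):
        r = ka_ks_pair("GATGAT", "GATGAT")
        assert r.ka == 0.0 and r.ks == 0.0 and r.ratio is None

    def test_single_synonymous_change_matches_hand_enumeration(self):
        # GAT->GAC (Asp, synonymous); GAT has 1/3 synonymous site (third
        # position), so S = 10/3 over ten codons and ps = 3/10
        r = ka_ks_pair("GAC" + "GAT" * 9, "GAT" * 10)
        ps = 1 / (10 / 3)
        assert r.ks == pytest.approx(-0.75 * math.log(1 - 4 * ps / 3))
        assert r.ka == 0.0
        assert r.ratio == 0.0

    def test_two_position_codon_averages_pathways(self):
        # TTT(F) vs CTA(L): both orders give one synonymous + one
        # nonsynonymous step, so Sd = Nd = 1.  Site counts by hand:
        # S = (1/3 + 4/3)/2 + 9 * 1/3 = 23/6, N = 30 - 23/6
        r = ka_ks_pair("TTT" + "GAT" * 9, "CTA" + "GAT" * 9)
        S, N = 23 / 6, 30 - 23 / 6
        assert r.ks == pytest.approx(-0.75 * math.log(1 - 4 * (1 / S) / 3))
        assert r.ka == pytest.approx(-0.75 * math.log(1 - 4 * (1 / N) / 3))

    def test_gapped_codons_excluded_pairwise(self):
        r = ka_ks_pair("GAT" + "G-T" + "GAT" * 4, "GAC" + "GGT" + "GAT" * 4)
        assert r.codons_used == 5

    def test_internal_stop_rejected(self):
        with pytest.raises(ValidationError, match="stop"):
            ka_ks_pair("TAAGAT", "TAAGAT")

    def test_twelve_alleles_give_66_pairs(self):
        # stop-free coding alleles: codons starting with G or C never mutate
        # into stop codons through third-position changes
        rng = np.random.default_rng(3)
        stems = ["GA", "GC", "GG", "CT", "CC", "CG"]
        base = [stems[i % len(stems)] + "T" for i in range(40)]
        seqs = []
        for _ in range(12):
            codons = [
                c[:2] + str(rng.choice(list("ACGT"))) if rng.random() < 0.1 else c
                for c in base
            ]
            seqs.append("".join(codons))
        panel = ka_ks_panel(AlignedSet([f"a{i}" for i in range(12)], seqs))
        assert panel.n_pairs == 66
        assert panel.n_undefined + sum(
            1 for r in panel.pairs.values() if r.ratio is not None
        ) == 66


class TestTN93:
    def test_identical_pair_zero(self):
        assert tn93_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_matches_independent_reference_value(self):
        # frozen oracle computed with an independent implementation of the
        # published TN93 formula (R ape dist.dna, model="TN93")
        s1 = "ACGTACGTGGCCATTAGCGTACGTTACGATCGATCGGATCCGTAGCTAGCTA"
        s2 = "ACGTACATGGCCATCAGCGTACGTTACGATCGATCGGATCCGCAGCTAACTA"
        assert tn93_distance(s1, s2) == pytest.approx(0.083549028359, abs=1e-10)

    def test_collapses_to_jukes_cantor_under_equal_rates(self):
        # equal base frequencies and equal substitution rates: TN93 ~ JC
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        s1 = rng.choice(bases, size=20000)
        s2 = s1.copy()
        flip = rng.random(s1.size) < 0.1
        for i in np.nonzero(flip)[0]:
            s2[i] = rng.choice(bases[bases != s1[i]])
        p = (s1 != s2).mean()
        jc = -0.75 * math.log(1 - 4 * p / 3)
        tn = tn93_distance("".join(s1), "".join(s2))
        assert tn == pytest.approx(jc, rel=0.02)

    def test_saturated_pair_flagged_infinite(self):
        assert math.isinf(tn93_distance("AAAAAAAA", "GGGGGGGG"))


class TestUPGMA:
    def test_three_taxa_known_tree(self):
        ids = ["A", "B", "C"]
        mat = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        tree = upgma(ids, mat).tree
        dists = tree.tip_tip_distances()
        assert dists[("A", "B")] == pytest.approx(2.0)
        assert dists[("A", "C")] == pytest.approx(4.0)
        a = tree.find("A")
        assert a.length == pytest.approx(1.0)

    def test_zero_matrix_no_crash(self):
        tree = upgma(["A", "B", "C"], np.zeros((3, 3))).tree
        assert {t.name for t in tree.tips()} == {"A", "B", "C"}

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            upgma(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_ultrametric_and_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = 8
            cond = rng.random(n * (n - 1) // 2) + 0.1
            mat = squareform(cond)
            ids = [f"t{i}" for i in range(n)]
            result = upgma(ids, mat)
            # ultrametric: all tips equidistant from root
            root = result.tree
            depths = {t.name: t.accumulate_to_ancestor(root) for t in root.tips()}
            assert max(depths.values()) - min(depths.values()) < 1e-9
            # cophenetic distances equal scipy's average-linkage cophenet
            ref = squareform(cophenet(linkage(cond, method="average")))
            tipdist = result.tree.tip_tip_distances(endpoints=ids)
            for i in range(n):
                for j in range(i + 1, n):
                    assert tipdist[(f"t{i}", f"t{j}")] == pytest.approx(ref[i, j])

    def test_deterministic_under_ties(self):
        ids = ["b", "a", "c", "d"]
        mat = squareform([1.0, 1.0, 2.0, 1.0, 2.0, 2.0])
        t1 = str(upgma(ids, mat).tree)
        t2 = str(upgma(ids, mat).tree)
        assert t1 == t2


class TestBootstrap:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=2, intron_indel_prob=0.0)
        recs, _ = simulate_alignment(cfg)
        aln = AlignedSet.from_records(recs)
        r1 = bootstrap_supports(aln, B=50, seed=9)
        r2 = bootstrap_supports(aln, B=50, seed=9)
        assert r1.supports == r2.supports
        assert str(r1.tree) == str(r2.tree)

    def test_three_ancestral_groups_recovered_monophyletic(self):
        cfg = SimulationConfig(
            seed=5, alignment_groups=3, intron_indel_prob=0.0,
            exon_sub_rate=0.02, intron_sub_rate=0.04,
        )
        recs, _ = simulate_alignment(cfg)
        aln = AlignedSet.from_records(recs)
        result = bootstrap_supports(aln, B=200, seed=1)
        groups = {}
        for name, _ in recs:
            groups.setdefault(name.split("_")[0], set()).add(name)
        for members in groups.values():
            clade = frozenset(members)
            assert clade in result.supports
            assert result.supports[clade] > 0.9

    def test_supports_converge_with_replicates(self):
        cfg = SimulationConfig(seed=4, alignment_groups=3, intron_indel_prob=0.0)
        recs, _ = simulate_alignment(cfg)
        aln = AlignedSet.from_records(recs)
        small = bootstrap_supports(aln, B=150, seed=3).supports
        big = bootstrap_supports(aln, B=600, seed=4).supports
        for clade, s in small.items():
            assert abs(s - big[clade]) < 0.1

    def test_newick_carries_support_labels(self):
        cfg = SimulationConfig(seed=2, alignment_groups=3, intron_indel_prob=0.0)
        recs, _ = simulate_alignment(cfg)
        result = bootstrap_supports(AlignedSet.from_records(recs), B=20, seed=0)
        nwk = result.newick()
        assert nwk.endswith(";\n") or nwk.endswith(";")
        assert any(f"){s:.2f}" in nwk or f"){s:0.2f}:" in nwk for s in result.supports.values())


def test_distance_matrix_symmetric_zero_diagonal():
    cfg = SimulationConfig(seed=1, intron_indel_prob=0.0)
    recs, _ = simulate_alignment(cfg)
    ids, mat = distance_matrix(AlignedSet.from_records(recs))
    assert np.allclose(mat, mat.T)
    assert np.allclose(np.diag(mat), 0.0)
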