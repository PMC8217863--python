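"""Chi-squared association, scan filtering, and the colour-prediction rule."""

import numpy as np
import pytest
from scipy import stats as st
from scipy.stats import chi2_contingency

from plumhap.assoc import (
    chisq_2x2,
    evaluate_predictions,
    predict_from_diplotype,
    scan_associations,
)
from plumhap.model import BandGenotype, PhenotypeRecord, PlumhapError
from plumhap.simulate import SimulationConfig, simulate_catalog, simulate_panel


class TestChisq2x2:
    def test_published_a356_table_reproduces_printed_p(self):
        chi2, p, deg = chisq_2x2(((52, 1), (0, 28)))
        assert not deg
        assert p == pytest.approx(1.96e-18, rel=5e-3)

    def test_perfect_independence(self):
        chi2, p, deg = chisq_2x2(((25, 25), (25, 25)))
        assert chi2 == 0.0 and p == 1.0

    def test_diagonal_table_matches_closed_form_and_tail_oracle(self):
        chi2, p, _ = chisq_2x2(((10, 0), (0, 10)))
        assert chi2 == pytest.approx(20.0)
        # independent 1-df upper-tail oracle via the erfc identity
        import math

        assert p == pytest.approx(math.erfc(math.sqrt(20.0 / 2)), rel=1e-12)

    def test_closed_form_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            t = rng.integers(1, 200, size=(2, 2))
            chi2, p, deg = chisq_2x2(((t[0, 0], t[0, 1]), (t[1, 0], t[1, 1])))
            ref = chi2_contingency(t, correction=False)
            assert chi2 == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-300)

    def test_invariant_under_transposition_and_row_column_swap(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 50, size=4)
            if (a + b) * (c + d) * (a + c) * (b + d) == 0:
                continue
            base = chisq_2x2(((a, b), (c, d)))[0]
            assert chisq_2x2(((a, c), (b, d)))[0] == pytest.approx(base)  # transpose
            assert chisq_2x2(((d, c), (b, a)))[0] == pytest.approx(base)  # both swaps

    def test_zero_margin_degenerate(self):
        chi2, p, deg = chisq_2x2(((5, 5), (0, 0)))
        assert deg and chi2 == 0.0 and p == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(PlumhapError):
            chisq_2x2(((-1, 2), (3, 4)))

    def test_yates_correction_shrinks_statistic(self):
        plain = chisq_2x2(((12, 3), (4, 11)))[0]
        corrected = chisq_2x2(((12, 3), (4, 11)), yates=True)[0]
        assert corrected < plain

    def test_type_one_error_under_permutation_null(self):
        # balanced margins at n=81, where the asymptotic level applies
        rng = np.random.default_rng(7)
        n = 81
        carrier = np.zeros(n, bool)
        carrier[:40] = True
        colored = np.zeros(n, bool)
        colored[:41] = True
        hits = 0
        B = 10_000
        for _ in range(B):
            y = rng.permutation(colored)
            a = int((carrier & y).sum())
            b, c = 40 - a, 41 - a
            d = n - 40 - c
            _, p, _ = chisq_2x2(((a, b), (c, d)))
            hits += p < 0.05
        assert 0.04 <= hits / B <= 0.06


class TestScan:
    def _panel(self, seed=2, **kw):
        cfg = SimulationConfig(seed=seed, **kw)
        cat, gmap = simulate_catalog(cfg)
        return simulate_panel(cfg, cat)

    def test_color_band_ranks_first_at_full_penetrance(self):
        panel = self._panel(penetrance=1.0)
        results = scan_associations(panel.genotypes, panel.phenotypes, tissue="skin")
        assert results[0].marker == "a356"
        assert results[0].p_value == min(r.p_value for r in results)

    def test_scan_agrees_with_per_marker_chisq(self):
        panel = self._panel()
        results = scan_associations(panel.genotypes, panel.phenotypes, tissue="skin")
        for r in results[:5]:
            assert chisq_2x2(r.table)[0] == pytest.approx(r.chi_squared)

    def test_frequency_filter_and_monomorphic_exclusion(self):
        # 16-band registry: 1 monomorphic (all carriers) and 4 rare bands
        # below 5% leave 11 testable markers
        rng = np.random.default_rng(3)
        common = [f"c{i}" for i in range(11)]
        rare = [f"r{i}" for i in range(4)]
        genotypes, phenos = [], []
        for i in range(81):
            bands = {"mono"} | {b for b in common if rng.random() < 0.5}
            if i < 3:
                bands.add(rare[i % 4])
            genotypes.append(BandGenotype(f"A{i}", frozenset(bands)))
            skin = "red" if rng.random() < 0.5 else "yellow"
            phenos.append(PhenotypeRecord(f"A{i}", skin, "white").recoded())
        results = scan_associations(genotypes, phenos, tissue="skin")
        assert len(results) == 11
        assert {r.marker for r in results} == set(common)

    def test_shuffled_phenotype_gives_uniformish_p(self):
        panel = self._panel(penetrance=1.0)
        rng = np.random.default_rng(11)
        recs = list(panel.phenotypes)
        hits = 0
        B = 300
        for _ in range(B):
            shuffled = rng.permutation(len(recs))
            phenos = [
                PhenotypeRecord(
                    recs[i].accession, recs[j].skin_color, recs[j].flesh_color
                ).recoded()
                for i, j in enumerate(shuffled)
            ]
            results = scan_associations(panel.genotypes, phenos, tissue="skin")
            a356 = next(r for r in results if r.marker == "a356")
            hits += a356.p_value < 0.05
        assert abs(hits / B - 0.05) < 3 * np.sqrt(0.05 * 0.95 / B) + 0.02

    def test_bonferroni_adjustment_on_flag(self):
        panel = self._panel()
        results = scan_associations(
            panel.genotypes, panel.phenotypes, tissue="skin", bonferroni=True
        )
        m = len(results)
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_value * m))


class TestPrediction:
    def test_validation_panel_full_penetrance_perfect_accuracy(self):
        cfg = SimulationConfig(seed=8, penetrance=1.0, n_accessions=31, rare_accessions=[])
        cat, _ = simulate_catalog(cfg)
        panel = simulate_panel(cfg, cat)
        cm = evaluate_predictions("a356", panel.genotypes, panel.phenotypes)
        assert cm.accuracy == 1.0 and cm.n == 31

    def test_colored_noncarrier_counted_false_negative(self, catalog):
        # the H2/H6 outlier pattern: coloured fruit without the colour band
        g = BandGenotype("X", catalog.haplotype("H2").bands | catalog.haplotype("H6").bands)
        rec = PhenotypeRecord("X", "red", "white").recoded()
        cm = evaluate_predictions("a356", [g], [rec], catalog=catalog)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (0, 0, 0, 1)

    def test_accuracy_tracks_penetrance(self):
        p = 0.9
        cfg = SimulationConfig(seed=5, penetrance=p, n_accessions=500, rare_accessions=[])
        cat, _ = simulate_catalog(cfg)
        panel = simulate_panel(cfg, cat)
        cm = evaluate_predictions("a356", panel.genotypes, panel.phenotypes)
        assert abs(cm.accuracy - p) < 3 * np.sqrt(p * (1 - p) / 500)

    def test_unknown_predictive_band_rejected(self, catalog):
        with pytest.raises(PlumhapError, match="registry"):
            predict_from_diplotype("a999", BandGenotype("X", frozenset({"a466"})), catalog=catalog)
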