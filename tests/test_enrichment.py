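import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from paleodup.dup_classifier import GeneModeCall
from paleodup.enrichment import (
    benjamini_hochberg,
    chi_square_2x2,
    duplication_mode_composition,
    group_mean_comparison,
    term_overrepresentation,
    wgd_pathway_enrichment,
)


def modes_from(spec: dict[str, str]) -> dict[str, GeneModeCall]:
    return {g: GeneModeCall(g, m) for g, m in spec.items()}


class TestChiSquare:
    def test_hand_computed_value(self):
        # expected counts 20/80/20/80 -> chi2 = 12.5
        chi2, p = chi_square_2x2([[30, 70], [10, 90]])
        assert chi2 == pytest.approx(12.5, abs=1e-12)
        assert p == pytest.approx(4.07e-4, rel=0.01)

    def test_no_difference_gives_zero(self):
        chi2, p = chi_square_2x2([[50, 50], [50, 50]])
        assert chi2 == 0 and p == 1

    def test_row_swap_invariance(self):
        a, _ = chi_square_2x2([[30, 70], [10, 90]])
        b, _ = chi_square_2x2([[10, 90], [30, 70]])
        assert a == pytest.approx(b)

    def test_zero_margin_is_undefined(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [10, 90]])


class TestWgdPathwayEnrichment:
    def test_counts_proportions_and_significance(self):
        genes = {}
        for i in range(100):  # pathway: 74% WGD
            genes[f"p{i}"] = "WGD" if i < 74 else "DSD"
        for i in range(900):  # rest: ~56% WGD -> genome 58%
            genes[f"g{i}"] = "WGD" if i < 507 else "TD"
        result = wgd_pathway_enrichment(
            modes_from(genes), {f"p{i}" for i in range(100)}
        )
        assert result.pathway_prop == pytest.approx(0.74)
        assert result.genome_prop == pytest.approx(0.581)
        assert result.p_value < 0.001

    def test_unknown_pathway_ids_dropped(self):
        genes = modes_from({"a": "WGD", "b": "DSD", "c": "WGD", "d": "DSD"})
        result = wgd_pathway_enrichment(genes, {"a", "b", "zz"})
        assert result.pathway_total == 2

    def test_empty_pathway_is_an_error(self):
        genes = modes_from({"a": "WGD", "b": "DSD"})
        with pytest.raises(ValueError):
            wgd_pathway_enrichment(genes, {"zz"})


class TestModeComposition:
    def test_proportions(self):
        genes = modes_from({"a": "WGD", "b": "WGD", "c": "WGD", "d": "TD"})
        comp = duplication_mode_composition(genes, {"a", "b", "c", "d"})
        assert comp.proportions["WGD"] == 0.75
        assert comp.proportions["TD"] == 0.25
        assert comp.proportions["PD"] == 0
        assert sum(comp.proportions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            duplication_mode_composition(modes_from({"a": "WGD"}), {"zz"})


class TestTermOverrepresentation:
    def universe(self, n=20):
        return {f"u{i}" for i in range(n)}

    def test_maximal_overlap_closed_form(self):
        # universe 20, term 5, target 5, overlap 5 -> p = 1/C(20,5)
        uni = self.universe()
        term_members = [f"u{i}" for i in range(5)]
        gt = pd.DataFrame({"gene_id": term_members, "term_id": "T1"})
        res = term_overrepresentation(gt, set(term_members), uni, min_genes=3)
        assert res.loc[0, "p_value"] == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    def test_term_covering_universe_is_never_enriched(self):
        uni = self.universe()
        gt = pd.DataFrame({"gene_id": sorted(uni), "term_id": "ALL"})
        res = term_overrepresentation(gt, {"u0", "u1", "u2"}, uni)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_target_outside_universe_rejected(self):
        gt = pd.DataFrame({"gene_id": ["u0"], "term_id": "T"})
        with pytest.raises(ValueError):
            term_overrepresentation(gt, {"zz"}, self.universe())

    def test_null_targets_rarely_significant(self):
        # one 50-gene term, random 40-gene targets from a 200-gene universe:
        # the hypergeometric tail p exceeds 0.05 in >= 95% of replicates
        rng = np.random.default_rng(23)
        uni = sorted(self.universe(200))
        gt = pd.DataFrame({"gene_id": uni[:50], "term_id": "T1"})
        non_sig = 0
        n_rep = 400
        for _ in range(n_rep):
            target = set(rng.choice(uni, size=40, replace=False))
            res = term_overrepresentation(gt, target, set(uni))
            if res.loc[0, "p_value"] > 0.05:
                non_sig += 1
        assert non_sig / n_rep >= 0.95

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_bh_monotone_in_rank_order(self, pvals):
        adj = benjamini_hochberg(np.array(pvals))
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0) and np.all(adj >= np.array(pvals) - 1e-12)


class TestGroupComparison:
    def test_hand_computed_t(self):
        # pooled t = 3 / sqrt(1*(1/3+1/3)) = 3.674, df = 4
        res = group_mean_comparison([1, 2, 3], [4, 5, 6])
        assert abs(res.t_statistic) == pytest.approx(3.674, abs=1e-3)
        assert res.degrees_of_freedom == 4
        assert res.p_value == pytest.approx(0.0214, abs=2e-3)

    def test_identical_groups(self):
        res = group_mean_comparison([1, 2, 3], [1, 2, 3])
        assert res.t_statistic == 0 and res.p_value == 1

    def test_degenerate_variance_limit(self):
        res = group_mean_comparison([1, 1], [1, 1])
        assert res.t_statistic == 0 and res.p_value == 1

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            group_mean_comparison([1], [2, 3])
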