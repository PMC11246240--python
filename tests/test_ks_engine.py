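import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paleodup.genome_io import HomologPair
from paleodup.ks_engine import (
    KsEstimate,
    align_and_estimate,
    assign_wgd_epochs,
    fit_ks_mixture,
    ng86_ka_ks,
)
from paleodup.synthetic_data import _random_cds

from _oracles import brute_force_ng86

CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
          if a + b + c not in ("TAA", "TAG", "TGA")]


class TestNg86:
    def test_identical_sequences_have_zero_rates(self):
        s = "ATGAAACCCGGGTTT" * 6
        est = ng86_ka_ks(s, s)
        assert est.ka == 0 and est.ks == 0 and not est.saturated

    def test_single_synonymous_difference_closed_form(self):
        # 10 Phe codons; TTT has exactly 1/3 synonymous site, so one
        # TTT->TTC difference gives ps = 1/(10/3) = 0.3 and
        # ks = -0.75*ln(1 - 0.4) = 0.3831...
        a = "TTT" * 10
        b = "TTT" * 9 + "TTC"
        est = ng86_ka_ks(a, b)
        assert est.s_sites == pytest.approx(10 / 3)
        assert est.ks == pytest.approx(-0.75 * math.log(0.6), abs=1e-12)
        assert est.ka == 0
        assert not est.saturated

    def test_saturation_when_ps_exceeds_jc_domain(self):
        # 3 of 10 synonymous third positions changed: ps = 3/(10/3) = 0.9
        a = "TTT" * 10
        b = "TTC" * 3 + "TTT" * 7
        est = ng86_ka_ks(a, b)
        assert est.saturated
        assert math.isnan(est.ks)

    def test_length_errors(self):
        with pytest.raises(ValueError):
            ng86_ka_ks("ATGAAA", "ATG")
        with pytest.raises(ValueError):
            ng86_ka_ks("ATGA", "ATGA")

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        a = "".join(CODONS[i] for i in rng.integers(0, len(CODONS), n))
        b = "".join(CODONS[i] for i in rng.integers(0, len(CODONS), n))
        e1, e2 = ng86_ka_ks(a, b), ng86_ka_ks(b, a)
        for attr in ("ka", "ks", "s_sites", "n_sites", "saturated"):
            v1, v2 = getattr(e1, attr), getattr(e2, attr)
            assert v1 == v2 or (
                isinstance(v1, float) and math.isnan(v1) and math.isnan(v2)
            )

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_site_conservation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        a = "".join(CODONS[i] for i in rng.integers(0, len(CODONS), n))
        b = "".join(CODONS[i] for i in rng.integers(0, len(CODONS), n))
        est = ng86_ka_ks(a, b)
        assert est.s_sites + est.n_sites == pytest.approx(3 * n, abs=1e-9)

    def test_adding_synonymous_differences_monotone_in_ks_only(self):
        base = list("TTT" * 30)
        prev_ks = 0.0
        for i in range(6):
            base[3 * i + 2] = "C"  # TTT -> TTC at successive codons
            est = ng86_ka_ks("TTT" * 30, "".join(base))
            assert est.ka == 0
            assert est.ks > prev_ks
            prev_ks = est.ks

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(10, 50))
            a = "".join(CODONS[i] for i in rng.integers(0, len(CODONS), n))
            b = "".join(CODONS[i] for i in rng.integers(0, len(CODONS), n))
            est = ng86_ka_ks(a, b)
            ka, ks, s_sites, n_sites, sat = brute_force_ng86(a, b)
            assert est.s_sites == pytest.approx(s_sites, abs=1e-9)
            assert est.n_sites == pytest.approx(n_sites, abs=1e-9)
            assert est.saturated == sat
            if not sat:
                assert est.ks == pytest.approx(ks, abs=1e-9)
                assert est.ka == pytest.approx(ka, abs=1e-9)

    def test_protein_guided_alignment_for_unequal_lengths(self):
        rng = np.random.default_rng(2)
        core = "".join(_random_cds(rng, 60))
        longer = core[:90] + "GCTGCA" + core[90:]  # 2-codon insertion
        est = align_and_estimate(core, longer)
        assert est.ks == pytest.approx(0.0, abs=1e-9)


class TestKsMixture:
    def test_single_lognormal_selects_one_component(self):
        rng = np.random.default_rng(11)
        ks = 10 ** rng.normal(-0.6, 0.1, size=1000)
        model = fit_ks_mixture(ks, k_max=4, seed=3)
        assert model.n_components == 1
        assert model.means[0] == pytest.approx(-0.6, abs=0.03)

    def test_two_component_recovery(self):
        rng = np.random.default_rng(13)
        ks = np.concatenate([
            10 ** rng.normal(-0.70, 0.08, size=500),
            10 ** rng.normal(-0.22, 0.08, size=500),
        ])
        model = fit_ks_mixture(ks, k_max=4, seed=5)
        assert model.n_components == 2
        assert model.means[0] == pytest.approx(-0.70, abs=0.05)
        assert model.means[1] == pytest.approx(-0.22, abs=0.05)
        assert model.weights.sum() == pytest.approx(1.0)

    def test_too_few_values_is_an_error(self):
        with pytest.raises(ValueError, match="more paralog pairs"):
            fit_ks_mixture(np.full(10, 0.3), seed=0)

    def test_window_filtering_excludes_allelic_and_saturated(self):
        rng = np.random.default_rng(7)
        good = 10 ** rng.normal(-0.5, 0.1, size=200)
        ks = np.concatenate([good, np.full(100, 0.001), np.full(100, 9.0)])
        model = fit_ks_mixture(ks, k_max=2, seed=1)
        assert model.n_components == 1
        assert model.means[0] == pytest.approx(-0.5, abs=0.05)


def _estimate(ks, a="x", b="y"):
    return KsEstimate(HomologPair.make(a, b, 100, 1e-30), 0.05, ks, 200.0, 700.0,
                      saturated=not np.isfinite(ks))


class TestEpochAssignment:
    @pytest.fixture
    def model(self):
        rng = np.random.default_rng(19)
        ks = np.concatenate([
            10 ** rng.normal(-0.7, 0.06, 400), 10 ** rng.normal(-0.2, 0.06, 400)
        ])
        return fit_ks_mixture(ks, k_max=3, seed=2)

    def test_pair_at_component_mean_gets_that_epoch(self, model):
        young = _estimate(10 ** model.means[0], "a", "b")
        old = _estimate(10 ** model.means[1], "c", "d")
        pairs, genes = assign_wgd_epochs(model, [young, old])
        by_key = {p.subject: p for p in pairs}
        assert by_key[("a", "b")].epoch == 1
        assert by_key[("a", "b")].posterior > 0.5
        assert by_key[("c", "d")].epoch == 2
        assert genes["a"].epoch == 1 and genes["d"].epoch == 2

    def test_saturated_pairs_stay_unassigned(self, model):
        sat = _estimate(float("nan"), "a", "b")
        pairs, genes = assign_wgd_epochs(model, [sat, _estimate(0.2, "c", "d")])
        by_key = {p.subject: p for p in pairs}
        assert by_key[("a", "b")].epoch is None
        assert "a" not in genes

    def test_empty_estimates_error(self, model):
        with pytest.raises(ValueError):
            assign_wgd_epochs(model, [])
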