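import filecmp

import numpy as np
import pytest

from paleodup.ks_engine import STOP_CODONS, ng86_ka_ks
from paleodup.synthetic_data import (
    SimulationParams,
    WgdEvent,
    _random_cds,
    apply_duplication_history,
    evolve_duplicate_sequences,
    simulate_ancestral_genome,
    simulate_genome,
    write_simulation,
)


def small_params(**kw):
    defaults = dict(
        n_chromosomes=2, genes_per_chromosome=50, pathway_size=10,
        cds_codons=120, seed=7,
    )
    defaults.update(kw)
    return SimulationParams(**defaults)


class TestAncestralGenome:
    def test_sizes_and_ranks(self):
        catalog, cds = simulate_ancestral_genome(small_params())
        assert len(catalog) == 100
        for chrom in catalog.chromosomes:
            assert [g.rank for g in catalog.genes_on(chrom)] == list(range(50))

    def test_cds_are_valid_orfs(self):
        _, cds = simulate_ancestral_genome(small_params())
        for seq in cds.values():
            assert len(seq) % 3 == 0
            assert seq.startswith("ATG")
            assert seq[-3:] in STOP_CODONS
            internal = [seq[i : i + 3] for i in range(0, len(seq) - 3, 3)]
            assert not any(c in STOP_CODONS for c in internal)

    def test_same_seed_reproduces_genome(self):
        c1, s1 = simulate_ancestral_genome(small_params())
        c2, s2 = simulate_ancestral_genome(small_params())
        assert s1 == s2
        assert c1.to_frame().equals(c2.to_frame())

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            simulate_ancestral_genome(small_params(n_chromosomes=0))


class TestDuplicationHistory:
    def test_full_retention_single_wgd_pairs_everything(self):
        sim = apply_duplication_history(
            small_params(
                wgd_events=[WgdEvent(0.3, 0.05, 1.0, 1.0)],
                td_rate=0, pd_rate=0, dsd_rate=0, trd_rate=0,
            ),
            evolve=False,
        )
        assert len(sim.catalog) == 200
        assert set(sim.truth_genes["mode"]) == {"WGD"}
        assert len(sim.pairs) == 100

    def test_zero_retention_leaves_singletons(self):
        sim = apply_duplication_history(
            small_params(
                wgd_events=[WgdEvent(0.3, 0.05, 0.0, 0.0)],
                td_rate=0, pd_rate=0, dsd_rate=0, trd_rate=0,
            ),
            evolve=False,
        )
        assert len(sim.catalog) == 100
        assert set(sim.truth_genes["mode"]) == {"singleton"}
        assert sim.pairs == []

    def test_retained_copy_count_is_binomial(self):
        sim = apply_duplication_history(
            SimulationParams(
                n_chromosomes=5, genes_per_chromosome=200, pathway_size=10,
                cds_codons=80,
                wgd_events=[WgdEvent(0.3, 0.05, 0.3, 0.3)],
                td_rate=0, pd_rate=0, dsd_rate=0, trd_rate=0, seed=11,
            ),
            evolve=False,
        )
        n_copies = (sim.truth_genes["parent"] != "").sum()
        sd = np.sqrt(1000 * 0.3 * 0.7)
        assert abs(n_copies - 300) <= 3 * sd

    def test_truth_closure_every_gene_appears_once(self, default_sim):
        truth_ids = list(default_sim.truth_genes["gene_id"])
        catalog_ids = [g.gene_id for g in default_sim.catalog]
        assert sorted(truth_ids) == sorted(catalog_ids)
        assert len(set(truth_ids)) == len(truth_ids)

    def test_growth_guard(self):
        with pytest.raises(ValueError, match="growth"):
            SimulationParams(
                wgd_events=[WgdEvent(3.0 - 0.1 * i, 0.05, 1.0, 1.0) for i in range(4)]
            ).validate()

    def test_pathway_membership_inherited_by_copies(self, default_sim):
        truth = default_sim.truth_genes.set_index("gene_id")
        for gid in default_sim.pathway_ids:
            row = truth.loc[gid]
            assert row["is_pathway"] == 1
            if row["parent"]:
                assert truth.loc[row["parent"], "is_pathway"] == 1


class TestSequenceDivergence:
    def test_zero_target_keeps_copies_identical(self):
        cds = "ATG" + "CCA" * 50 + "TAA"
        a, b = evolve_duplicate_sequences(cds, 0.0, 0.2, seed=1)
        assert a == b == cds

    def test_zero_omega_gives_zero_ka(self):
        rng = np.random.default_rng(3)
        cds = "".join(_random_cds(rng, 200))
        a, b = evolve_duplicate_sequences(cds, 0.4, 0.0, seed=2)
        est = ng86_ka_ks(a, b)
        assert est.ka == 0
        assert est.ks > 0.2

    def test_estimator_recovers_generator_target(self):
        rng = np.random.default_rng(5)
        values = []
        for i in range(60):
            cds = "".join(_random_cds(rng, 900))
            a, b = evolve_duplicate_sequences(cds, 0.30, 0.2, seed=100 + i)
            values.append(ng86_ka_ks(a, b).ks)
        assert 0.27 <= np.mean(values) <= 0.33

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError):
            evolve_duplicate_sequences("ATGTAA", -0.1)


class TestEmission:
    def test_identical_params_give_byte_identical_files(self, tmp_path):
        p1 = write_simulation(simulate_genome(small_params()), tmp_path / "a")
        p2 = write_simulation(simulate_genome(small_params()), tmp_path / "b")
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_emitted_files_are_pipeline_consumable(self, tmp_path):
        from paleodup.genome_io import (
            read_cds_sequences,
            read_gene_models,
            read_homolog_pairs,
        )

        sim = simulate_genome(small_params(), evolve=False)
        paths = write_simulation(sim, tmp_path)
        catalog = read_gene_models(paths["gff3"])
        assert len(catalog) == len(sim.catalog)
        cds, flags = read_cds_sequences(paths["cds"])
        assert not flags
        pairs, dropped = read_homolog_pairs(paths["pairs"], max_evalue=1e-5)
        assert dropped == 0
        assert {p.key for p in pairs} == {p.key for p in sim.pairs}
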