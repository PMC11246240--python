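import sys
from pathlib import Path
from types import SimpleNamespace

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from paleodup.collinearity import detect_syntenic_blocks
from paleodup.dup_classifier import assign_gene_modes, classify_pair_modes
from paleodup.ks_engine import align_and_estimate, assign_wgd_epochs, fit_ks_mixture
from paleodup.pipeline import outgroup_anchor_genes
from paleodup.synthetic_data import SimulationParams, simulate_genome


@pytest.fixture(scope="session")
def default_sim():
    """The default study-scale simulation: 5x400 genes, two nested WGDs
    (Ks 0.6 then 0.2), retention 0.3 background / 0.7 pathway."""
    return simulate_genome(SimulationParams(seed=42))


@pytest.fixture(scope="session")
def default_analysis(default_sim):
    """Full in-memory analysis of the default simulation."""
    sim = default_sim
    blocks, multiplicity = detect_syntenic_blocks(sim.catalog, None, sim.pairs)
    og_anchors = outgroup_anchor_genes(
        sim.catalog, sim.outgroup_catalog, sim.outgroup_pairs, 25, 5
    )
    pair_calls = classify_pair_modes(sim.pairs, blocks, sim.catalog, og_anchors)
    gene_modes = assign_gene_modes(pair_calls, sim.catalog)
    mode_of = {c.pair.key: c.mode for c in pair_calls}
    estimates = [
        align_and_estimate(sim.cds[p.gene_a], sim.cds[p.gene_b], p)
        for p in sim.pairs
    ]
    wgd_estimates = [e for e in estimates if mode_of[e.pair.key] == "WGD"]
    model = fit_ks_mixture(
        [e.ks for e in wgd_estimates if not e.saturated], k_max=4, seed=7
    )
    pair_epochs, gene_epochs = assign_wgd_epochs(model, wgd_estimates)
    return SimpleNamespace(
        sim=sim,
        blocks=blocks,
        multiplicity=multiplicity,
        outgroup_anchors=og_anchors,
        pair_calls=pair_calls,
        gene_modes=gene_modes,
        mode_of=mode_of,
        estimates=estimates,
        wgd_estimates=wgd_estimates,
        model=model,
        pair_epochs=pair_epochs,
        gene_epochs=gene_epochs,
    )
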