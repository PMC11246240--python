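#!/usr/bin/env python
"""Test whether WGD-derived duplicates are preferentially retained in the
pathway: the 2x2 chi-square of pathway vs rest-of-genome, the per-mode
composition of the pathway and the genome, and a cross-"species" group
comparison of pathway WGD-proportions (high-retention vs low-retention
regimes, emulating the oil-crop / non-oil contrast)."""

import sys

import pandas as pd

from paleodup.dup_classifier import GeneModeCall
from paleodup.enrichment import (
    duplication_mode_composition,
    group_mean_comparison,
    wgd_pathway_enrichment,
)
from paleodup.synthetic_data import (
    SimulationParams,
    WgdEvent,
    apply_duplication_history,
    truth_gene_mode_calls,
)


def main():
    try:
        table = pd.read_csv("results/gene_modes.tsv", sep="\t")
    except FileNotFoundError:
        sys.exit("run analysis/02_synteny_and_modes.py first")
    modes = {r.gene_id: GeneModeCall(r.gene_id, r.mode)
             for r in table.itertuples(index=False)}
    pathway = set(table.loc[table["is_pathway"] == 1, "gene_id"])

    enr = wgd_pathway_enrichment(modes, pathway)
    print(f"pathway: {enr.pathway_wgd}/{enr.pathway_total} WGD-derived "
          f"({enr.pathway_prop:.1%}); genome: {enr.genome_wgd}/{enr.genome_total} "
          f"({enr.genome_prop:.1%})")
    print(f"chi-square = {enr.chi2:.2f}, P = {enr.p_value:.3g} "
          "(pathway vs rest of genome, df=1)")
    enr.to_frame().to_csv("results/enrichment.tsv", sep="\t", index=False)

    comp_p = duplication_mode_composition(modes, pathway, "pathway")
    comp_g = duplication_mode_composition(modes, set(modes), "genome")
    pd.concat([comp_p.to_frame(), comp_g.to_frame()]).to_csv(
        "results/composition.tsv", sep="\t", index=False)
    print("pathway mode proportions:",
          {m: round(p, 3) for m, p in comp_p.proportions.items() if p})

    # emulate the oil-crop vs non-oil contrast: four "species" per regime,
    # high (0.7) vs low (0.35) pathway retention, summarised by their
    # pathway WGD-proportion
    groups = {}
    for label, retention in (("high", 0.7), ("low", 0.35)):
        values = []
        for i in range(4):
            sim = apply_duplication_history(
                SimulationParams(
                    wgd_events=[WgdEvent(0.6, 0.08, 0.3, retention),
                                WgdEvent(0.2, 0.08, 0.3, retention)],
                    seed=500 + 10 * i + (0 if label == "high" else 5),
                ),
                evolve=False,
            )
            truth_modes = truth_gene_mode_calls(sim)
            values.append(
                wgd_pathway_enrichment(truth_modes, sim.pathway_ids).pathway_prop
            )
        groups[label] = values
    res = group_mean_comparison(groups["high"], groups["low"])
    print(f"high-retention group {[round(v, 3) for v in groups['high']]} vs "
          f"low {[round(v, 3) for v in groups['low']]}: "
          f"t = {res.t_statistic:.2f} (df {res.degrees_of_freedom}), "
          f"P = {res.p_value:.2g}")
    pd.DataFrame(
        [(res.t_statistic, res.degrees_of_freedom, res.p_value,
          ";".join(f"{v:.4f}" for v in groups["high"]),
          ";".join(f"{v:.4f}" for v in groups["low"]))],
        columns=["t_statistic", "df", "p_value", "group_high", "group_low"],
    ).to_csv("results/group_test.tsv", sep="\t", index=False)
    print("wrote results/enrichment.tsv, results/composition.tsv, "
          "results/group_test.tsv")


if __name__ == "__main__":
    main()
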