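#!/usr/bin/env python
"""Detect intra-genomic syntenic blocks, anchor the genome against the
outgroup, and classify every paralog pair and gene into duplication modes
(WGD / tandem / proximal / transposed / dispersed / singleton).

Reads the files written by 01_simulate_genome.py through the ordinary
input readers — the same path real data would take — and reports the
classification against the simulation truth."""

import collections
import sys

import pandas as pd

from paleodup.collinearity import blocks_to_frame, detect_syntenic_blocks
from paleodup.dup_classifier import (
    assign_gene_modes,
    classify_pair_modes,
    gene_modes_to_frame,
    pair_modes_to_frame,
)
from paleodup.genome_io import read_gene_models, read_homolog_pairs
from paleodup.pipeline import outgroup_anchor_genes

SIM = "results/simulation"


def main():
    try:
        catalog = read_gene_models(f"{SIM}/genome.gff3")
    except FileNotFoundError:
        sys.exit("run analysis/01_simulate_genome.py first")
    pairs, _ = read_homolog_pairs(f"{SIM}/homolog_pairs.tsv")
    og_catalog = read_gene_models(f"{SIM}/outgroup.gff3")
    og_pairs, _ = read_homolog_pairs(f"{SIM}/outgroup_pairs.tsv")
    pathway = {l.strip() for l in open(f"{SIM}/pathway_genes.txt") if l.strip()}

    blocks, multiplicity = detect_syntenic_blocks(catalog, None, pairs)
    print(f"{len(blocks)} intra-genomic syntenic blocks "
          f"({sum(b.score for b in blocks)} anchor pairs)")
    depth = multiplicity["multiplicity"].value_counts().sort_index()
    print("regions by homologous-region depth:", dict(depth))

    anchors = outgroup_anchor_genes(catalog, og_catalog, og_pairs, 25, 5)
    print(f"{len(anchors)} genes at ancestral (outgroup-syntenic) loci")

    calls = classify_pair_modes(pairs, blocks, catalog, anchors)
    modes = assign_gene_modes(calls, catalog)
    counts = collections.Counter(c.mode for c in modes.values())
    print("gene modes:", dict(counts), f"(total {sum(counts.values())})")

    truth = pd.read_csv(f"{SIM}/truth_genes.tsv", sep="\t")
    truth_map = dict(zip(truth["gene_id"], truth["mode"]))
    acc = sum(modes[g].mode == m for g, m in truth_map.items()) / len(truth_map)
    print(f"gene-mode accuracy vs truth: {acc:.3f}")

    blocks_to_frame(blocks).to_csv("results/blocks.tsv", sep="\t", index=False)
    pair_modes_to_frame(calls).to_csv("results/pair_modes.tsv", sep="\t", index=False)
    gene_modes_to_frame(modes, pathway).to_csv(
        "results/gene_modes.tsv", sep="\t", index=False
    )
    print("wrote results/blocks.tsv, results/pair_modes.tsv, results/gene_modes.tsv")


if __name__ == "__main__":
    main()
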