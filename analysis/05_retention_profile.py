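#!/usr/bin/env python
"""Profile WGD retention around pathway loci: the retention ratio of the
pathway genes themselves (offset 0) versus the 20 genes to the left and
right, with a permutation test of the peak."""

import json
import sys

import numpy as np
import pandas as pd

from paleodup.dup_classifier import GeneModeCall
from paleodup.genome_io import read_gene_models
from paleodup.retention_profile import (
    compute_retention_profile,
    profile_permutation_test,
)

SIM = "results/simulation"
SEED = 17


def main():
    try:
        table = pd.read_csv("results/gene_modes.tsv", sep="\t")
    except FileNotFoundError:
        sys.exit("run analysis/02_synteny_and_modes.py first")
    catalog = read_gene_models(f"{SIM}/genome.gff3")
    modes = {r.gene_id: GeneModeCall(r.gene_id, r.mode)
             for r in table.itertuples(index=False)}
    focal = sorted(table.loc[table["is_pathway"] == 1, "gene_id"])

    profile = compute_retention_profile(catalog, modes, focal, window=20)
    ratio0 = profile.ratio[profile.window]
    flank = np.nanmean(profile.ratio[np.abs(profile.offsets) >= 10])
    print(f"retention ratio at pathway loci: {ratio0:.3f}; "
          f"flanking (|offset| >= 10): {flank:.3f}")

    perm = profile_permutation_test(catalog, modes, focal, window=20,
                                    n_perm=999, seed=SEED)
    print(f"permutation test of the peak: observed {perm.observed:.3f} vs "
          f"null {perm.null_mean:.3f} +/- {perm.null_sd:.3f}; "
          f"P = {perm.p_value:.3g} ({perm.n_perm} permutations)")

    profile.to_frame().to_csv("results/profile.tsv", sep="\t", index=False)
    with open("results/permutation.json", "wt") as fh:
        json.dump(perm.to_dict(), fh, indent=2)
    _plot(profile)
    print("wrote results/profile.tsv, results/permutation.json, "
          "results/figures/retention_profile.png")


def _plot(profile):
    import os

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs("results/figures", exist_ok=True)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(profile.offsets, profile.ratio, marker="o", ms=3)
    ax.axvline(0, color="red", ls="--", lw=1)
    ax.set_xlabel("gene-rank offset from pathway locus")
    ax.set_ylabel("WGD retention ratio")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig("results/figures/retention_profile.png", dpi=150)


if __name__ == "__main__":
    main()
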