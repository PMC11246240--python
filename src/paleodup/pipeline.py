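"""End-to-end orchestration: collinearity -> duplication-mode
classification -> Ka/Ks and Ks-mixture epochs -> retention enrichment ->
neighborhood retention profile, driven by a flat key=value config with a
single master seed.

Per-stage seeds are derived from the master seed by a fixed scheme, so
each stochastic stage is individually reproducible and two runs with the
same config produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .collinearity import blocks_to_frame, detect_syntenic_blocks
from .dup_classifier import (
    assign_gene_modes,
    classify_pair_modes,
    gene_modes_to_frame,
    pair_modes_to_frame,
)
from .enrichment import (
    duplication_mode_composition,
    term_overrepresentation,
    wgd_pathway_enrichment,
)
from .genome_io import (
    read_cds_sequences,
    read_gene_models,
    read_homolog_pairs,
    write_table,
    ENRICHMENT_COLUMNS,
    KS_PAIRS_COLUMNS,
    PROFILE_COLUMNS,
)
from .ks_engine import align_and_estimate, assign_wgd_epochs, fit_ks_mixture
from .retention_profile import compute_retention_profile, profile_permutation_test

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""


_PATH_KEYS = ("gff3", "cds", "pairs", "pathway", "outgroup_gff3",
              "outgroup_pairs", "gene_terms")


@dataclass
class PipelineConfig:
    # inputs
    gff3: str = ""
    cds: str = ""
    pairs: str = ""
    pathway: str = ""
    outgroup_gff3: str = ""  # optional: enables transposed-duplicate calls
    outgroup_pairs: str = ""
    gene_terms: str = ""  # optional: two-column gene_id<TAB>term_id
    feature_type: str = "gene"
    # homology thresholds
    max_evalue: float = 1e-10
    min_bitscore: float = 0.0
    # collinearity
    max_gap: int = 25
    min_anchors: int = 5
    # classification
    proximal_max: int = 10
    # Ks engine
    ks_min: float = 0.005
    ks_max: float = 5.0
    k_max: int = 4
    # retention profile
    window: int = 20
    n_perm: int = 999
    # reproducibility / output
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_file(cls, path: str, **overrides) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file; unknown keys rejected,
        keyword overrides win over file values."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        values: dict[str, object] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, raw = (s.strip() for s in line.split("=", 1))
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                ftype = fields[key].type
                if ftype in ("int", int):
                    values[key] = int(raw)
                elif ftype in ("float", float):
                    values[key] = float(raw)
                else:
                    values[key] = raw
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def stage_seed(self, stage: str) -> int:
        """Fixed per-stage seed derivation from the master seed."""
        ss = np.random.SeedSequence([self.seed, abs(hash_stable(stage))])
        return int(ss.generate_state(1)[0] % (2**31))


def hash_stable(text: str) -> int:
    """Deterministic small hash (process-independent, unlike ``hash``)."""
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc

        return wrapped

    return deco


def outgroup_anchor_genes(catalog, outgroup_catalog, outgroup_pairs,
                          max_gap: int, min_anchors: int) -> set[str]:
    """Genome genes sitting at ancestral loci: anchors of genome-vs-outgroup
    syntenic blocks (the genome is the 'a' side of every block)."""
    blocks, _ = detect_syntenic_blocks(
        catalog, outgroup_catalog, outgroup_pairs, max_gap, min_anchors
    )
    anchors: set[str] = set()
    for blk in blocks:
        for m in blk.anchors:
            g = catalog.gene_at(blk.chrom_a, m.rank_a)
            if g is not None:
                anchors.add(g.gene_id)
    return anchors


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all result tables under
    ``config.out_dir``. Returns the run report (manifest contents)."""
    load = _stage("read_inputs")(_read_inputs)
    catalog, cds, pairs, n_dropped, pathway_ids, gene_terms = load(config)

    blocks, multiplicity = _stage("collinearity")(detect_syntenic_blocks)(
        catalog, None, pairs, config.max_gap, config.min_anchors
    )

    outgroup_anchors = None
    if config.outgroup_gff3 and config.outgroup_pairs:
        def _outgroup():
            og_catalog = read_gene_models(config.outgroup_gff3, config.feature_type)
            og_pairs, _ = read_homolog_pairs(
                config.outgroup_pairs, config.max_evalue, config.min_bitscore
            )
            return outgroup_anchor_genes(
                catalog, og_catalog, og_pairs, config.max_gap, config.min_anchors
            )

        outgroup_anchors = _stage("outgroup_synteny")(_outgroup)()

    pair_calls = _stage("classify")(classify_pair_modes)(
        pairs, blocks, catalog, outgroup_anchors, config.proximal_max
    )
    gene_modes = assign_gene_modes(pair_calls, catalog)

    def _ks_stage():
        mode_of = {c.pair.key: c.mode for c in pair_calls}
        estimates = []
        for p in pairs:
            if p.gene_a not in cds or p.gene_b not in cds:
                raise ValueError(f"missing CDS for pair {p.key}")
            estimates.append(align_and_estimate(cds[p.gene_a], cds[p.gene_b], p))
        wgd_est = [e for e in estimates if mode_of[e.pair.key] == "WGD"]
        ks_values = [e.ks for e in wgd_est if not e.saturated]
        model = fit_ks_mixture(
            ks_values, config.k_max, config.stage_seed("mixture"),
            config.ks_min, config.ks_max,
        )
        pair_epochs, gene_epochs = assign_wgd_epochs(model, wgd_est)
        return estimates, mode_of, model, pair_epochs, gene_epochs

    estimates, mode_of, model, pair_epochs, gene_epochs = _stage("ks")(_ks_stage)()
    for gid, assign in gene_epochs.items():
        if gene_modes[gid].mode == "WGD":
            gene_modes[gid].epoch = assign.epoch

    enr = _stage("enrichment")(wgd_pathway_enrichment)(gene_modes, pathway_ids)
    comp_pathway = duplication_mode_composition(gene_modes, pathway_ids, "pathway")
    comp_genome = duplication_mode_composition(
        gene_modes, set(gene_modes), "genome"
    )
    ora = None
    if gene_terms is not None:
        wgd_set = {g for g, c in gene_modes.items() if c.mode == "WGD"}
        ora = _stage("ora")(term_overrepresentation)(
            gene_terms, wgd_set, set(gene_modes)
        )

    profile = _stage("profile")(compute_retention_profile)(
        catalog, gene_modes, pathway_ids, config.window
    )
    perm = _stage("profile")(profile_permutation_test)(
        catalog, gene_modes, pathway_ids, config.window, config.n_perm,
        config.stage_seed("permutation"),
    )

    report = _write_outputs(
        config, catalog, n_dropped, blocks, multiplicity, pair_calls,
        gene_modes, pathway_ids, estimates, mode_of, model, pair_epochs,
        enr, comp_pathway, comp_genome, ora, profile, perm,
    )
    return report


def _read_inputs(config: PipelineConfig):
    for key in ("gff3", "cds", "pairs", "pathway"):
        path = getattr(config, key)
        if not path:
            raise ValueError(f"config is missing required input {key!r}")
        if not os.path.exists(path):
            raise FileNotFoundError(f"{key} input not found: {path}")
    catalog = read_gene_models(config.gff3, config.feature_type)
    cds, flags = read_cds_sequences(config.cds)
    if flags:
        logger.warning("%d CDS flagged (frame/internal stop)", len(flags))
    pairs, n_dropped = read_homolog_pairs(
        config.pairs, config.max_evalue, config.min_bitscore
    )
    with open(config.pathway) as fh:
        pathway_ids = {line.strip() for line in fh if line.strip()}
    gene_terms = None
    if config.gene_terms:
        gene_terms = pd.read_csv(
            config.gene_terms, sep="\t", header=None, names=["gene_id", "term_id"]
        )
    return catalog, cds, pairs, n_dropped, pathway_ids, gene_terms


def _write_outputs(config, catalog, n_dropped, blocks, multiplicity,
                   pair_calls, gene_modes, pathway_ids, estimates, mode_of,
                   model, pair_epochs, enr, comp_pathway, comp_genome, ora,
                   profile, perm) -> dict:
    out = config.out_dir
    os.makedirs(out, exist_ok=True)

    epoch_of = {a.subject: a.epoch for a in pair_epochs}
    ks_rows = []
    for e in sorted(estimates, key=lambda e: e.pair.key):
        k = e.pair.key
        ks_rows.append((
            k[0], k[1],
            "" if not np.isfinite(e.ka) else round(e.ka, 6),
            "" if not np.isfinite(e.ks) else round(e.ks, 6),
            round(e.s_sites, 4), round(e.n_sites, 4),
            int(e.saturated), mode_of[k],
            "" if epoch_of.get(k) is None else epoch_of.get(k),
        ))
    ks_df = pd.DataFrame(ks_rows, columns=KS_PAIRS_COLUMNS)

    blocks_df = blocks_to_frame(blocks)
    write_table(blocks_df, os.path.join(out, "blocks.tsv"),
                blocks_df.columns.tolist())
    multiplicity.to_csv(os.path.join(out, "multiplicity.tsv"), sep="\t",
                        index=False, lineterminator="\n")
    pair_modes_to_frame(pair_calls).to_csv(
        os.path.join(out, "pair_modes.tsv"), sep="\t", index=False,
        lineterminator="\n")
    gene_modes_to_frame(gene_modes, pathway_ids).to_csv(
        os.path.join(out, "gene_modes.tsv"), sep="\t", index=False,
        lineterminator="\n")
    ks_df.to_csv(os.path.join(out, "ks_pairs.tsv"), sep="\t", index=False,
                 lineterminator="\n")
    write_table(enr.to_frame(), os.path.join(out, "enrichment.tsv"),
                ENRICHMENT_COLUMNS)
    pd.concat([comp_pathway.to_frame(), comp_genome.to_frame()]).to_csv(
        os.path.join(out, "composition.tsv"), sep="\t", index=False,
        lineterminator="\n")
    if ora is not None:
        ora.to_csv(os.path.join(out, "ora.tsv"), sep="\t", index=False,
                   lineterminator="\n")
    write_table(profile.to_frame(), os.path.join(out, "profile.tsv"),
                PROFILE_COLUMNS)

    with open(os.path.join(out, "mixture.json"), "wt") as fh:
        json.dump(
            {
                "n_components": model.n_components,
                "weights": model.weights.tolist(),
                "means_log10_ks": model.means.tolist(),
                "sds_log10_ks": model.sds.tolist(),
                "bic": model.bic,
                "bic_by_k": model.bic_by_k,
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    with open(os.path.join(out, "permutation.json"), "wt") as fh:
        json.dump(perm.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    mode_counts = {}
    for c in gene_modes.values():
        mode_counts[c.mode] = mode_counts.get(c.mode, 0) + 1
    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "counts": {
            "genes": len(catalog),
            "pairs": len({c.pair.key for c in pair_calls}),
            "pairs_dropped_on_read": n_dropped,
            "blocks": len(blocks),
            "modes": {m: mode_counts.get(m, 0) for m in sorted(mode_counts)},
            "pathway_genes": enr.pathway_total,
        },
        "enrichment": {
            "pathway_wgd_proportion": enr.pathway_prop,
            "genome_wgd_proportion": enr.genome_prop,
            "chi2": enr.chi2,
            "p_value": enr.p_value,
        },
        "mixture": {
            "n_components": model.n_components,
            "means_log10_ks": model.means.tolist(),
        },
        "profile": {"offset0_ratio": float(profile.ratio[profile.window]),
                    "permutation_p": perm.p_value},
    }
    assert sum(mode_counts.values()) == len(catalog)
    with open(os.path.join(out, "manifest.json"), "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
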