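"""Classify paralog pairs and genes into the five duplication modes:

WGD (whole-genome duplication, i.e. syntenic-anchor pairs), TD (tandem),
PD (proximal), TRD (transposed) and DSD (dispersed), with the fixed
priority WGD > TD > PD > TRD > DSD. Genes in no retained pair are
singletons.

The transposed call needs outgroup synteny: a pair is TRD when exactly one
gene sits at an ancestral locus (collinear with the outgroup) and the other
at a novel one. Without an outgroup anchor set, would-be TRD pairs fall
through to DSD rather than being guessed — a merged, honest category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .collinearity import SyntenicBlock, anchor_pair_keys
from .genome_io import GeneCatalog, HomologPair

logger = logging.getLogger(__name__)

MODES = ("WGD", "TD", "PD", "TRD", "DSD")
GENE_MODES = MODES + ("singleton",)
_PRIORITY = {m: i for i, m in enumerate(MODES)}

DEFAULT_PROXIMAL_MAX = 10


@dataclass(frozen=True)
class PairModeCall:
    pair: HomologPair
    mode: str


@dataclass
class GeneModeCall:
    gene_id: str
    mode: str
    epoch: int | None = None  # set later by the Ks engine, WGD genes only


def classify_pair_modes(
    pairs: list[HomologPair],
    blocks: list[SyntenicBlock],
    catalog: GeneCatalog,
    outgroup_anchors: set[str] | None = None,
    proximal_max: int = DEFAULT_PROXIMAL_MAX,
) -> list[PairModeCall]:
    """Assign each paralog pair its duplication mode by the priority rules.

    1. WGD — the pair is an anchor in an intra-genomic syntenic block;
    2. TD  — same chromosome, rank-adjacent (|Δrank| = 1);
    3. PD  — same chromosome, 1 < |Δrank| <= ``proximal_max``;
    4. TRD — exactly one gene in ``outgroup_anchors`` (skipped when no
       outgroup is provided);
    5. DSD — everything else.
    """
    if proximal_max < 2:
        raise ValueError("proximal_max must be >= 2")
    wgd_keys = anchor_pair_keys(blocks)
    pair_keys = {p.key for p in pairs}
    missing = wgd_keys - pair_keys
    if missing:
        raise ValueError(
            f"block anchors reference pairs absent from input: {sorted(missing)[:5]} ..."
        )
    if outgroup_anchors is None:
        logger.warning(
            "no outgroup anchor set given: transposed duplicates (TRD) cannot "
            "be distinguished and will be reported as dispersed (DSD)"
        )

    calls: list[PairModeCall] = []
    for p in pairs:
        ga, gb = catalog[p.gene_a], catalog[p.gene_b]
        if p.key in wgd_keys:
            mode = "WGD"
        elif ga.chromosome == gb.chromosome and abs(ga.rank - gb.rank) == 1:
            mode = "TD"
        elif ga.chromosome == gb.chromosome and 1 < abs(ga.rank - gb.rank) <= proximal_max:
            mode = "PD"
        elif outgroup_anchors is not None and (
            (p.gene_a in outgroup_anchors) != (p.gene_b in outgroup_anchors)
        ):
            mode = "TRD"
        else:
            mode = "DSD"
        calls.append(PairModeCall(p, mode))
    return calls


def assign_gene_modes(
    pair_calls: list[PairModeCall], catalog: GeneCatalog
) -> dict[str, GeneModeCall]:
    """Roll pair modes up to genes: each gene takes the highest-priority mode
    among its pairs; genes in no pair are singletons. Total over modes always
    equals the catalog size."""
    best: dict[str, str] = {}
    for call in pair_calls:
        for gid in (call.pair.gene_a, call.pair.gene_b):
            cur = best.get(gid)
            if cur is None or _PRIORITY[call.mode] < _PRIORITY[cur]:
                best[gid] = call.mode
    return {
        g.gene_id: GeneModeCall(g.gene_id, best.get(g.gene_id, "singleton"))
        for g in catalog
    }


def gene_modes_to_frame(
    gene_modes: dict[str, GeneModeCall], pathway_ids: set[str] | None = None
) -> pd.DataFrame:
    pathway_ids = pathway_ids or set()
    rows = [
        (gid, c.mode, "" if c.epoch is None else c.epoch, int(gid in pathway_ids))
        for gid, c in sorted(gene_modes.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "mode", "epoch", "is_pathway"])


def pair_modes_to_frame(pair_calls: list[PairModeCall]) -> pd.DataFrame:
    rows = sorted((c.pair.gene_a, c.pair.gene_b, c.mode) for c in pair_calls)
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "mode"])
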