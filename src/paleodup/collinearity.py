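"""Syntenic (collinear) block detection by chaining homologous gene-pair
anchors on gene-rank coordinates.

Blocks are found per chromosome pair with a dynamic program over anchors
sorted by rank: an anchor can extend a chain if both rank gaps are positive
and at most ``max_gap``, in the same direction on both axes (parallel) or
opposite directions (antiparallel). The highest-scoring chain (score =
anchor count) is extracted greedily, its anchors removed, and the DP
repeated, so no anchor belongs to two blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_io import GeneCatalog, HomologPair

DEFAULT_MAX_GAP = 25
DEFAULT_MIN_ANCHORS = 5


@dataclass(frozen=True)
class AnchorMatch:
    """A homolog pair placed on rank coordinates of two chromosomes."""

    rank_a: int
    rank_b: int
    pair: HomologPair


@dataclass
class SyntenicBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[AnchorMatch]
    orientation: str  # 'parallel' | 'antiparallel'

    @property
    def score(self) -> int:
        return len(self.anchors)


def chain_anchors_dp(
    matches: list[AnchorMatch],
    max_gap: int = DEFAULT_MAX_GAP,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    orientation: str = "parallel",
) -> list[list[AnchorMatch]]:
    """Greedy extraction of maximal collinear chains from one chromosome pair.

    Returns anchor chains (each sorted by ascending rank_a) with at least
    ``min_anchors`` anchors. Ties between equal-score chains break toward
    the smallest starting (rank_a, rank_b).
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    if min_anchors < 2:
        raise ValueError("min_anchors must be >= 2")
    if orientation not in ("parallel", "antiparallel"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sign = 1 if orientation == "parallel" else -1

    remaining = sorted(matches, key=lambda m: (m.rank_a, m.rank_b))
    chains: list[list[AnchorMatch]] = []
    while True:
        n = len(remaining)
        if n < min_anchors:
            break
        # longest-chain DP; best[i] = length of best chain ending at i
        best = [1] * n
        prev = [-1] * n
        for j in range(n):
            mj = remaining[j]
            for i in range(j):
                mi = remaining[i]
                da = mj.rank_a - mi.rank_a
                db = sign * (mj.rank_b - mi.rank_b)
                if 0 < da <= max_gap and 0 < db <= max_gap:
                    if best[i] + 1 > best[j]:
                        best[j] = best[i] + 1
                        prev[j] = i
        # best chain; tie-break: smallest starting (rank_a, rank_b), which the
        # sorted order delivers by preferring the earliest qualifying end
        end = max(range(n), key=lambda j: (best[j], -j))
        # among equal-length chains prefer the one whose START is smallest:
        top = best[end]
        candidates = [j for j in range(n) if best[j] == top]

        def chain_of(j: int) -> list[int]:
            idx = []
            while j != -1:
                idx.append(j)
                j = prev[j]
            return idx[::-1]

        chosen = min(
            (chain_of(j) for j in candidates),
            key=lambda idx: (remaining[idx[0]].rank_a, remaining[idx[0]].rank_b),
        )
        if len(chosen) < min_anchors:
            break
        chains.append([remaining[j] for j in chosen])
        used = set(chosen)
        remaining = [m for j, m in enumerate(remaining) if j not in used]
    return chains


def _anchor_matches(
    catalog_a: GeneCatalog,
    catalog_b: GeneCatalog,
    pairs: list[HomologPair],
    intra: bool,
) -> dict[tuple[str, str], list[AnchorMatch]]:
    """Place homolog pairs on rank coordinates, grouped by chromosome pair.

    In intra-genomic mode each pair is placed once with the lexicographically
    smaller (chromosome, rank) side as the 'a' axis, and self-diagonal
    matches are excluded.
    """
    unknown = [
        p.key
        for p in pairs
        if p.gene_a not in catalog_a and p.gene_a not in catalog_b
        or p.gene_b not in catalog_a and p.gene_b not in catalog_b
    ]
    if unknown:
        raise ValueError(f"pairs reference unknown gene ids: {unknown[:5]} ...")

    grouped: dict[tuple[str, str], list[AnchorMatch]] = {}
    for p in pairs:
        if intra:
            ga, gb = catalog_a[p.gene_a], catalog_a[p.gene_b]
            if (ga.chromosome, ga.rank) > (gb.chromosome, gb.rank):
                ga, gb = gb, ga
            if ga.chromosome == gb.chromosome and ga.rank == gb.rank:
                continue
        else:
            if p.gene_a in catalog_a and p.gene_b in catalog_b:
                ga, gb = catalog_a[p.gene_a], catalog_b[p.gene_b]
            elif p.gene_b in catalog_a and p.gene_a in catalog_b:
                ga, gb = catalog_a[p.gene_b], catalog_b[p.gene_a]
            else:
                continue
        grouped.setdefault((ga.chromosome, gb.chromosome), []).append(
            AnchorMatch(ga.rank, gb.rank, p)
        )
    return grouped


def detect_syntenic_blocks(
    catalog_a: GeneCatalog,
    catalog_b: GeneCatalog | None,
    pairs: list[HomologPair],
    max_gap: int = DEFAULT_MAX_GAP,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
) -> tuple[list[SyntenicBlock], pd.DataFrame]:
    """Detect syntenic blocks genome-wide and report per-region multiplicity.

    ``catalog_b=None`` (or the same catalog) selects intra-genomic mode.
    Returns ``(blocks, multiplicity)`` where multiplicity counts, per query
    gene, how many distinct blocks cover it through an anchor — the "depth"
    of homologous regions covering each locus.
    """
    intra = catalog_b is None or catalog_b is catalog_a
    cat_b = catalog_a if intra else catalog_b
    grouped = _anchor_matches(catalog_a, cat_b, pairs, intra)

    blocks: list[SyntenicBlock] = []
    for (ca, cb), matches in sorted(grouped.items()):
        if len(matches) < min_anchors:
            continue
        for orientation in ("parallel", "antiparallel"):
            for chain in chain_anchors_dp(matches, max_gap, min_anchors, orientation):
                blocks.append(SyntenicBlock(ca, cb, chain, orientation))
                taken = {id(m) for m in chain}
                matches = [m for m in matches if id(m) not in taken]

    cover: dict[str, set[int]] = {}
    for bi, blk in enumerate(blocks):
        for m in blk.anchors:
            ga = catalog_a.gene_at(blk.chrom_a, m.rank_a)
            gb = cat_b.gene_at(blk.chrom_b, m.rank_b)
            for g in (ga, gb) if intra else (ga,):
                if g is not None:
                    cover.setdefault(g.gene_id, set()).add(bi)
    mult = pd.DataFrame(
        sorted((gid, len(bis)) for gid, bis in cover.items()),
        columns=["gene_id", "multiplicity"],
    )
    return blocks, mult


def anchor_pair_keys(blocks: list[SyntenicBlock]) -> set[tuple[str, str]]:
    """Canonical gene-id keys of every anchor pair in the given blocks."""
    return {m.pair.key for blk in blocks for m in blk.anchors}


def blocks_to_frame(blocks: list[SyntenicBlock]) -> pd.DataFrame:
    rows = []
    for bi, blk in enumerate(blocks):
        anchors = ";".join(f"{m.pair.gene_a},{m.pair.gene_b}" for m in blk.anchors)
        rows.append((f"block{bi:05d}", blk.chrom_a, blk.chrom_b, blk.orientation,
                     blk.score, anchors))
    return pd.DataFrame(
        rows,
        columns=["block_id", "chrom_a", "chrom_b", "orientation", "n_anchors", "anchors"],
    )
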