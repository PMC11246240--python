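"""Simulate genomes with a known duplication history.

The generator emulates a diploid genome that went through nested
whole-genome duplications (WGDs) with biased duplicate retention in a
designated pathway, followed by small-scale duplications (tandem,
proximal, dispersed, transposed) and sequence divergence calibrated to
target synonymous distances (Ks). It emits exactly the inputs the
pipeline consumes — GFF3 gene models, CDS FASTA, 12-column tabular
homology, a pathway gene list, and an outgroup (the frozen pre-WGD
ancestor) for transposed-duplicate anchoring — plus per-gene and
per-pair truth tables for parameter-recovery tests.

Model sketch:

* an ancestral genome of ``n_chromosomes`` x ``genes_per_chromosome``
  random in-frame CDS (ATG ... stop, no internal stops);
* WGD events, oldest first; each duplicates every surviving gene onto a
  homeologous chromosome preserving order, then deletes each NEW copy
  with probability 1 - retention (pathway and background genes have
  separate retention probabilities) — biased retention in the pathway is
  the phenomenon the downstream statistics are built to detect;
* per-family event ages are jittered on the log10(Ks) scale so each WGD
  leaves a log-normal Ks peak; lineages accumulate synonymous and
  nonsynonymous substitutions between events (Ka = omega x Ks);
* after the WGDs, small-scale duplicates are inserted: tandem (adjacent
  rank), proximal (within ``proximal_max`` ranks), transposed (parent
  keeps its ancestral locus, copy lands at a random novel locus) and
  dispersed (both copies move to random loci, leaving no ancestral-locus
  signature).

Homolog pairs are emitted directly from truth parentage (every pair of
genes sharing an ancestral root), with pseudo-bitscores decreasing in
sequence divergence — the pipeline's input format is exercised without
running a similarity search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import (
    GeneCatalog,
    HomologPair,
    write_fasta,
    write_gff3,
)
from .ks_engine import STOP_CODONS, _CODON_TABLE

_BASES = "ACGT"
_NONSTOP_CODONS = sorted(set(_CODON_TABLE) - STOP_CODONS)


@dataclass(frozen=True)
class WgdEvent:
    """One whole-genome duplication: target Ks peak and retention regime."""

    ks_mean: float
    log10_sd: float = 0.08
    background_retention: float = 0.3
    pathway_retention: float = 0.7


@dataclass
class SimulationParams:
    n_chromosomes: int = 5
    genes_per_chromosome: int = 400
    cds_codons: int = 300  # mean CDS length in codons
    wgd_events: list[WgdEvent] = field(
        default_factory=lambda: [WgdEvent(0.6), WgdEvent(0.2)]
    )
    pathway_size: int = 120
    td_rate: float = 0.02  # per-gene probabilities of small-scale duplication
    pd_rate: float = 0.02
    dsd_rate: float = 0.02
    trd_rate: float = 0.02
    proximal_max: int = 10
    small_ks_range: tuple[float, float] = (0.05, 0.8)
    omega: float = 0.2  # Ka/Ks ratio of the divergence process
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes <= 0 or self.genes_per_chromosome <= 0:
            raise ValueError("genome sizes must be positive")
        if self.pathway_size > self.n_chromosomes * self.genes_per_chromosome:
            raise ValueError("pathway_size exceeds gene count")
        for e in self.wgd_events:
            for p in (e.background_retention, e.pathway_retention):
                if not 0 <= p <= 1:
                    raise ValueError("retention probabilities must be in [0,1]")
            if e.ks_mean <= 0:
                raise ValueError("Ks means must be positive")
        means = [e.ks_mean for e in self.wgd_events]
        if sorted(means, reverse=True) != means or len(set(means)) != len(means):
            raise ValueError("wgd_events must be ordered oldest (largest Ks) first")
        growth = math.prod(1 + max(e.background_retention, e.pathway_retention)
                           for e in self.wgd_events)
        growth *= 1 + self.td_rate + self.pd_rate + self.dsd_rate + self.trd_rate
        if growth > 10:
            raise ValueError("parameters imply > 10x genome growth")


class _SimGene:
    __slots__ = ("gene_id", "root", "parent", "birth_kind", "birth_epoch",
                 "birth_age", "pathway", "codons")

    def __init__(self, gene_id, root, parent, birth_kind, birth_epoch,
                 birth_age, pathway, codons):
        self.gene_id = gene_id
        self.root = root  # ancestral root gene id (family label)
        self.parent = parent  # _SimGene or None
        self.birth_kind = birth_kind  # None | WGD | TD | PD | DSD | TRD
        self.birth_epoch = birth_epoch  # epoch label (1 = youngest) for WGD births
        self.birth_age = birth_age  # divergence (Ks units) from parent at birth
        self.pathway = pathway
        self.codons = codons  # list of codon strings


# --------------------------------------------------------------------------
# sequence machinery

def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    body = [_NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS),
                                                     size=n_codons - 2)]
    return ["ATG"] + body + ["TAA"]


def _site_counts(codons: list[str]) -> tuple[float, float]:
    from .ks_engine import _sites_of

    s = n = 0.0
    for c in codons:
        if c in STOP_CODONS:
            continue
        cs, cn = _sites_of(c)
        s += cs
        n += cn
    return s, n


def _apply_mutations(codons: list[str], n_syn: int, n_non: int,
                     rng: np.random.Generator) -> None:
    """Apply counts of synonymous / nonsynonymous single-nucleotide changes
    in place, choosing uniformly among currently-valid changes by rejection
    sampling; stop codons are never created and the terminal stop is fixed."""
    n_codons = len(codons)
    for want_syn, remaining in ((True, n_syn), (False, n_non)):
        applied = 0
        guard = 0
        limit = 200 * (remaining + 1)
        while applied < remaining and guard < limit:
            guard += 1
            ci = int(rng.integers(0, n_codons))
            codon = codons[ci]
            if codon in STOP_CODONS:
                continue
            pos = int(rng.integers(0, 3))
            alt = _BASES[int(rng.integers(0, 4))]
            if alt == codon[pos]:
                continue
            new = codon[:pos] + alt + codon[pos + 1 :]
            if new in STOP_CODONS:
                continue
            if (_CODON_TABLE[new] == _CODON_TABLE[codon]) != want_syn:
                continue
            codons[ci] = new
            applied += 1


def _evolve(codons: list[str], ks_amount: float, ka_amount: float,
            rng: np.random.Generator) -> None:
    """Evolve one lineage by expected Ks/Ka amounts (substitutions drawn
    Poisson with means amount x sites)."""
    if ks_amount <= 0 and ka_amount <= 0:
        return
    s_sites, n_sites = _site_counts(codons)
    n_syn = int(rng.poisson(max(ks_amount, 0.0) * s_sites))
    n_non = int(rng.poisson(max(ka_amount, 0.0) * n_sites))
    _apply_mutations(codons, n_syn, n_non, rng)


def evolve_duplicate_sequences(
    cds: str, target_ks: float, omega: float = 0.2, seed: int = 0
) -> tuple[str, str]:
    """Duplicate a CDS and diverge the two copies to an expected Ks of
    ``target_ks`` (and Ka of ``omega * target_ks``), split evenly between
    the copies. Returns the diverged pair."""
    if target_ks < 0:
        raise ValueError("target_ks must be >= 0")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    if target_ks > 3:
        import logging

        logging.getLogger(__name__).warning(
            "target Ks %.2f is beyond practical saturation", target_ks
        )
    rng = np.random.default_rng(seed)
    a = [cds[i : i + 3].upper() for i in range(0, len(cds), 3)]
    b = list(a)
    _evolve(a, target_ks / 2, omega * target_ks / 2, rng)
    _evolve(b, target_ks / 2, omega * target_ks / 2, rng)
    return "".join(a), "".join(b)


# --------------------------------------------------------------------------
# genome assembly

@dataclass
class SimulatedGenome:
    """Everything the simulator knows about one replicate."""

    params: SimulationParams
    catalog: GeneCatalog
    cds: dict[str, str]
    pairs: list[HomologPair]
    pathway_ids: set[str]  # all pathway members (ancestral loci + copies)
    pathway_roots: set[str]  # the ancestral pathway loci only
    truth_genes: pd.DataFrame  # gene_id, mode, epoch, is_pathway, parent
    truth_pairs: pd.DataFrame  # gene_a, gene_b, mode, epoch, age
    outgroup_catalog: GeneCatalog
    outgroup_cds: dict[str, str]
    outgroup_pairs: list[HomologPair]


def simulate_ancestral_genome(
    params: SimulationParams,
) -> tuple[GeneCatalog, dict[str, str]]:
    """Ancestral genome only: ranked catalog plus in-frame CDS map."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    chroms, genes = _ancestral_state(params, rng)
    catalog = _emit_catalog(chroms, genes, rng)
    cds = {gid: "".join(g.codons) for gid, g in genes.items()}
    return catalog, cds


def _ancestral_state(params, rng):
    chroms: dict[str, list[str]] = {}
    genes: dict[str, _SimGene] = {}
    gid = 0
    for c in range(params.n_chromosomes):
        name = f"chr{c + 1:02d}"
        order = []
        for _ in range(params.genes_per_chromosome):
            gid += 1
            g = f"g{gid:05d}"
            n_codons = max(60, int(rng.poisson(params.cds_codons)))
            genes[g] = _SimGene(g, g, None, None, None, None, False,
                                _random_cds(rng, n_codons))
            order.append(g)
        chroms[name] = order
    return chroms, genes


def _emit_catalog(chroms, genes, rng) -> GeneCatalog:
    records = []
    for chrom in sorted(chroms):
        pos = 1
        for g in chroms[chrom]:
            length = len(genes[g].codons) * 3
            strand = "+" if rng.random() < 0.5 else "-"
            records.append((g, chrom, pos, pos + length - 1, strand))
            pos += length + 2000
    return GeneCatalog.from_unranked(records)


def apply_duplication_history(
    params: SimulationParams, evolve: bool = True
) -> SimulatedGenome:
    """Run the full history — ancestral genome, WGDs, small-scale events —
    and return the genome bundle with truth tables.

    ``evolve=False`` skips sequence divergence (histories only), which is
    orders of magnitude faster and sufficient for statistics that depend
    only on gene modes.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    chroms, genes = _ancestral_state(params, rng)
    roots = list(genes)

    pathway_roots = set(
        rng.choice(roots, size=params.pathway_size, replace=False).tolist()
    )
    for g in pathway_roots:
        genes[g].pathway = True

    # frozen pre-WGD ancestor = the outgroup
    outgroup_cds = {f"og.{g}": "".join(genes[g].codons) for g in roots}
    outgroup_chroms = {c: [f"og.{g}" for g in order] for c, order in chroms.items()}

    n_events = len(params.wgd_events)
    # per-family event ages, jittered on log10 scale, kept ordered oldest-first
    family_ages: dict[str, list[float]] = {}
    for r in roots:
        ages = [
            10 ** rng.normal(math.log10(e.ks_mean), e.log10_sd)
            for e in params.wgd_events
        ]
        family_ages[r] = sorted(ages, reverse=True)

    for ei, event in enumerate(params.wgd_events):
        epoch = n_events - ei  # 1 = youngest
        new_chroms: dict[str, list[str]] = {}
        for chrom in sorted(chroms):
            retained: list[str] = []
            for g in chroms[chrom]:
                parent = genes[g]
                keep_p = (
                    event.pathway_retention if parent.pathway
                    else event.background_retention
                )
                if rng.random() >= keep_p:
                    continue
                child_id = f"{g}.w{ei + 1}"
                child = _SimGene(
                    child_id, parent.root, parent, "WGD", epoch,
                    family_ages[parent.root][ei], parent.pathway,
                    list(parent.codons),
                )
                genes[child_id] = child
                retained.append(child_id)
            if retained:
                new_chroms[chrom + f"w{ei + 1}"] = retained
        chroms.update(new_chroms)
        if evolve:
            for g in genes.values():
                ages = family_ages[g.root]
                nxt = ages[ei + 1] if ei + 1 < n_events else 0.0
                delta = (ages[ei] - nxt) / 2.0
                _evolve(g.codons, delta, params.omega * delta, rng)

    _small_scale_events(params, chroms, genes, rng, evolve)

    catalog = _emit_catalog(chroms, genes, rng)
    truth_genes = _truth_gene_table(genes)
    truth_pairs = _truth_pair_table(genes)
    pairs = _emit_pairs(genes, evolve)
    outgroup_catalog = GeneCatalog.from_unranked(
        [
            (g, chrom, 1 + 3000 * i, 3000 * i + len(outgroup_cds[g]), "+")
            for chrom, order in sorted(outgroup_chroms.items())
            for i, g in enumerate(order)
        ]
    )
    outgroup_pairs = [
        HomologPair.make(g.gene_id, f"og.{g.root}", 500.0, 1e-100)
        for g in genes.values()
    ]
    pathway_ids = {g.gene_id for g in genes.values() if g.pathway}
    return SimulatedGenome(
        params=params,
        catalog=catalog,
        cds={gid: "".join(g.codons) for gid, g in genes.items()},
        pairs=pairs,
        pathway_ids=pathway_ids,
        pathway_roots=pathway_roots,
        truth_genes=truth_genes,
        truth_pairs=truth_pairs,
        outgroup_catalog=outgroup_catalog,
        outgroup_cds=outgroup_cds,
        outgroup_pairs=sorted(outgroup_pairs, key=lambda p: p.key),
    )


def _small_scale_events(params, chroms, genes, rng, evolve):
    """Insert TD/PD/DSD/TRD duplicates after the WGDs."""
    gene_list = sorted(genes)
    n = len(gene_list)
    counts = {
        kind: int(rng.binomial(n, rate))
        for kind, rate in (
            ("TD", params.td_rate), ("PD", params.pd_rate),
            ("DSD", params.dsd_rate), ("TRD", params.trd_rate),
        )
    }

    def position_of(g: str) -> tuple[str, int]:
        for chrom, order in chroms.items():
            try:
                return chrom, order.index(g)
            except ValueError:
                continue
        raise KeyError(g)

    # position index rebuilt lazily; insertions invalidate it
    def locate(g):
        return position_of(g)

    used: set[str] = set()
    wgd_families = {
        g.root for g in genes.values() if g.birth_kind == "WGD"
    }
    singleton_roots = [
        g for g in gene_list
        if genes[g].parent is None and genes[g].root not in wgd_families
    ]
    ancestral_locus = [
        g for g in gene_list  # roots and WGD copies sit in ancestral gene order
        if genes[g].birth_kind in (None, "WGD")
    ]

    def sample_pool(pool, k):
        pool = [g for g in pool if g not in used]
        k = min(k, len(pool))
        chosen = rng.choice(pool, size=k, replace=False).tolist() if k else []
        used.update(chosen)
        return chosen

    def make_child(src: str, kind: str) -> str:
        parent = genes[src]
        child_id = f"{src}.{kind.lower()}"
        age = float(rng.uniform(*params.small_ks_range))
        child = _SimGene(child_id, parent.root, parent, kind, None, age,
                         parent.pathway, list(parent.codons))
        if evolve:
            s_sites, n_sites = _site_counts(child.codons)
            _apply_mutations(
                child.codons,
                int(rng.poisson(age * s_sites)),
                int(rng.poisson(params.omega * age * n_sites)),
                rng,
            )
        genes[child_id] = child
        used.add(child_id)
        return child_id

    chrom_names = sorted(chroms)

    for src in sample_pool(singleton_roots, counts["DSD"]):
        child = make_child(src, "DSD")
        # both copies move to random loci: no ancestral-locus signature
        chrom, idx = locate(src)
        chroms[chrom].pop(idx)
        for g in (src, child):
            while True:
                tc = chrom_names[int(rng.integers(0, len(chrom_names)))]
                ti = int(rng.integers(0, len(chroms[tc]) + 1))
                other = child if g is src else src
                try:
                    oc, oi = locate(other)
                except KeyError:
                    oc, oi = None, None
                if oc == tc and oi is not None and abs(oi - ti) <= params.proximal_max:
                    continue  # avoid accidentally tandem/proximal placement
                chroms[tc].insert(ti, g)
                break

    for src in sample_pool(ancestral_locus, counts["TRD"]):
        child = make_child(src, "TRD")
        chrom, idx = locate(src)
        while True:
            tc = chrom_names[int(rng.integers(0, len(chrom_names)))]
            ti = int(rng.integers(0, len(chroms[tc]) + 1))
            if tc == chrom and abs(ti - idx) <= params.proximal_max + 1:
                continue
            chroms[tc].insert(ti, child)
            break

    for src in sample_pool(gene_list, counts["TD"]):
        child = make_child(src, "TD")
        chrom, idx = locate(src)
        chroms[chrom].insert(idx + 1, child)

    for src in sample_pool(gene_list, counts["PD"]):
        child = make_child(src, "PD")
        chrom, idx = locate(src)
        d = int(rng.integers(2, params.proximal_max + 1))
        chroms[chrom].insert(min(idx + d, len(chroms[chrom])), child)


def _ancestry_path(g: _SimGene) -> list[_SimGene]:
    path = [g]
    while path[-1].parent is not None:
        path.append(path[-1].parent)
    return path


def _pair_truth(x: _SimGene, y: _SimGene):
    """(mode, epoch, age) of the split separating two family members."""
    px, py = _ancestry_path(x), _ancestry_path(y)
    in_x = {g.gene_id: i for i, g in enumerate(px)}
    mrca_iy = next(i for i, g in enumerate(py) if g.gene_id in in_x)
    mrca_ix = in_x[py[mrca_iy].gene_id]
    below = []
    if mrca_ix > 0:
        below.append(px[mrca_ix - 1])
    if mrca_iy > 0:
        below.append(py[mrca_iy - 1])
    if not below:  # identical gene
        return None
    oldest = max(below, key=lambda g: g.birth_age)
    if all(g.birth_kind == "WGD" for g in below):
        return "WGD", oldest.birth_epoch, oldest.birth_age
    if len(below) == 1:
        return below[0].birth_kind, below[0].birth_epoch, below[0].birth_age
    kinds = {g.birth_kind for g in below}
    if kinds == {"WGD"}:
        return "WGD", oldest.birth_epoch, oldest.birth_age
    return "mixed", None, oldest.birth_age


def _truth_gene_table(genes: dict[str, _SimGene]) -> pd.DataFrame:
    families: dict[str, list[_SimGene]] = {}
    for g in genes.values():
        families.setdefault(g.root, []).append(g)
    priority = {"WGD": 0, "TD": 1, "PD": 2, "TRD": 3, "DSD": 4}
    rows = []
    for g in sorted(genes.values(), key=lambda x: x.gene_id):
        if g.birth_kind is not None:
            mode, epoch = g.birth_kind, g.birth_epoch
        else:
            children = [c for c in families[g.root] if c.parent is g]
            if children:
                best = min(children, key=lambda c: priority[c.birth_kind])
                mode = best.birth_kind
                wgd_children = [c for c in children if c.birth_kind == "WGD"]
                epoch = (min(c.birth_epoch for c in wgd_children)
                         if mode == "WGD" and wgd_children else None)
            else:
                mode, epoch = "singleton", None
        rows.append((g.gene_id, mode, "" if epoch is None else epoch,
                     int(g.pathway), g.parent.gene_id if g.parent else ""))
    return pd.DataFrame(rows, columns=["gene_id", "mode", "epoch",
                                       "is_pathway", "parent"])


def _truth_pair_table(genes: dict[str, _SimGene]) -> pd.DataFrame:
    families: dict[str, list[_SimGene]] = {}
    for g in genes.values():
        families.setdefault(g.root, []).append(g)
    rows = []
    for root in sorted(families):
        members = sorted(families[root], key=lambda g: g.gene_id)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                t = _pair_truth(members[i], members[j])
                if t is None:
                    continue
                mode, epoch, age = t
                a, b = sorted((members[i].gene_id, members[j].gene_id))
                rows.append((a, b, mode, "" if epoch is None else epoch, age))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "mode", "epoch", "age"])


def _emit_pairs(genes: dict[str, _SimGene], evolve: bool) -> list[HomologPair]:
    """All within-family gene pairs with identity-derived pseudo-bitscores."""
    families: dict[str, list[_SimGene]] = {}
    for g in genes.values():
        families.setdefault(g.root, []).append(g)
    pairs = []
    for root in sorted(families):
        members = sorted(families[root], key=lambda g: g.gene_id)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                x, y = members[i], members[j]
                if evolve:
                    n = min(len(x.codons), len(y.codons))
                    matches = sum(
                        1 for k in range(n) if x.codons[k] == y.codons[k]
                    )
                    identity = matches / n
                else:
                    identity = 0.9
                bit = round(1000.0 * identity, 1)
                pairs.append(HomologPair.make(x.gene_id, y.gene_id, bit, 1e-100))
    return sorted(pairs, key=lambda p: p.key)


def simulate_genome(params: SimulationParams | None = None,
                    evolve: bool = True) -> SimulatedGenome:
    """One-call simulation with default or supplied parameters."""
    return apply_duplication_history(params or SimulationParams(), evolve=evolve)


def truth_gene_mode_calls(sim: SimulatedGenome):
    """Truth table as GeneModeCall objects (for recovery comparisons and
    statistics that take gene modes as given)."""
    from .dup_classifier import GeneModeCall

    calls = {}
    for row in sim.truth_genes.itertuples(index=False):
        epoch = None if row.epoch in ("", None) else int(row.epoch)
        calls[row.gene_id] = GeneModeCall(row.gene_id, row.mode, epoch)
    return calls


def write_simulation(sim: SimulatedGenome, out_dir) -> dict[str, str]:
    """Write the bundle as pipeline-consumable files; returns path map."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "gff3": os.path.join(out_dir, "genome.gff3"),
        "cds": os.path.join(out_dir, "cds.fasta"),
        "pairs": os.path.join(out_dir, "homolog_pairs.tsv"),
        "pathway": os.path.join(out_dir, "pathway_genes.txt"),
        "outgroup_gff3": os.path.join(out_dir, "outgroup.gff3"),
        "outgroup_cds": os.path.join(out_dir, "outgroup_cds.fasta"),
        "outgroup_pairs": os.path.join(out_dir, "outgroup_pairs.tsv"),
        "truth_genes": os.path.join(out_dir, "truth_genes.tsv"),
        "truth_pairs": os.path.join(out_dir, "truth_pairs.tsv"),
    }
    write_gff3(sim.catalog, paths["gff3"])
    write_fasta(dict(sorted(sim.cds.items())), paths["cds"])
    _write_pair_tsv(sim.pairs, paths["pairs"])
    with open(paths["pathway"], "wt") as fh:
        for g in sorted(sim.pathway_ids):
            fh.write(g + "\n")
    write_gff3(sim.outgroup_catalog, paths["outgroup_gff3"])
    write_fasta(dict(sorted(sim.outgroup_cds.items())), paths["outgroup_cds"])
    _write_pair_tsv(sim.outgroup_pairs, paths["outgroup_pairs"])
    sim.truth_genes.to_csv(paths["truth_genes"], sep="\t", index=False,
                           lineterminator="\n")
    sim.truth_pairs.to_csv(paths["truth_pairs"], sep="\t", index=False,
                           lineterminator="\n")
    return paths


def _write_pair_tsv(pairs: list[HomologPair], path) -> None:
    """Emit pairs as 12-column tabular similarity rows."""
    with open(path, "wt") as fh:
        for p in pairs:
            fh.write(
                f"{p.gene_a}\t{p.gene_b}\t{p.bitscore / 10:.1f}\t900\t0\t0\t"
                f"1\t900\t1\t900\t{p.evalue:.3g}\t{p.bitscore:.1f}\n"
            )
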