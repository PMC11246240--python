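"""Readers and writers for the standard formats the pipeline touches.

Conventions established here and shared by every downstream module:

* coordinates are GFF3-style 1-based inclusive externally;
* gene order is expressed as a 0-based *rank* per chromosome, assigned by
  ascending start (ties broken by end, then gene id) — all window and
  offset arithmetic elsewhere uses ranks, never base pairs;
* homolog pairs are stored once, in canonical (lexicographic) order.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO


class ParseError(ValueError):
    """Raised for malformed input lines; carries the 1-based line number."""


@dataclass(frozen=True)
class GeneModel:
    """A gene feature with its positional rank along its chromosome."""

    gene_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'; stored but ignored for ranking
    rank: int  # 0-based order index along the chromosome


class GeneCatalog:
    """Ordered collection of gene models with per-chromosome rank indices."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._genes: dict[str, GeneModel] = {}
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self._genes[g.gene_id] = g
            self._by_chrom.setdefault(g.chromosome, []).append(g)
        for chrom, gs in self._by_chrom.items():
            gs.sort(key=lambda g: g.rank)
            ranks = [g.rank for g in gs]
            if ranks != list(range(len(gs))):
                raise ValueError(f"ranks on {chrom} are not 0..n-1 without gaps")

    @classmethod
    def from_unranked(
        cls, records: Iterable[tuple[str, str, int, int, str]]
    ) -> "GeneCatalog":
        """Build a catalog assigning ranks from (gene_id, chrom, start, end, strand)."""
        by_chrom: dict[str, list[tuple[str, str, int, int, str]]] = {}
        for rec in records:
            by_chrom.setdefault(rec[1], []).append(rec)
        genes: list[GeneModel] = []
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda r: (r[2], r[3], r[0]))
            for rank, (gid, _, start, end, strand) in enumerate(recs):
                if start > end:
                    raise ValueError(f"gene {gid!r}: start {start} > end {end}")
                genes.append(GeneModel(gid, chrom, start, end, strand, rank))
        return cls(genes)

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __iter__(self) -> Iterator[GeneModel]:
        for chrom in self.chromosomes:
            yield from self._by_chrom[chrom]

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def genes_on(self, chromosome: str) -> list[GeneModel]:
        """Genes on one chromosome in rank order."""
        return list(self._by_chrom.get(chromosome, []))

    def gene_at(self, chromosome: str, rank: int) -> GeneModel | None:
        gs = self._by_chrom.get(chromosome, [])
        if 0 <= rank < len(gs):
            return gs[rank]
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (g.gene_id, g.chromosome, g.start, g.end, g.strand, g.rank)
                for g in self
            ],
            columns=["gene_id", "chromosome", "start", "end", "strand", "rank"],
        )


@dataclass(frozen=True)
class HomologPair:
    """A canonical (lexicographically ordered) homologous gene pair."""

    gene_a: str
    gene_b: str
    bitscore: float
    evalue: float

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError(f"self pair {self.gene_a!r}")
        if self.gene_a > self.gene_b:
            raise ValueError("pair not in canonical (lexicographic) order")

    @staticmethod
    def make(gene_a: str, gene_b: str, bitscore: float, evalue: float) -> "HomologPair":
        a, b = sorted((gene_a, gene_b))
        return HomologPair(a, b, bitscore, evalue)

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def _open_text(source) -> IO[str]:
    if hasattr(source, "read"):
        return source
    if str(source).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(source, "rb"))
    return open(source, "rt")


def read_gene_models(gff3, feature_type: str = "gene") -> GeneCatalog:
    """Read one feature type from a GFF3 stream or path into a ranked catalog.

    The feature ID is taken from the ``ID=`` attribute (falling back to
    ``Name=``). Coordinates stay 1-based inclusive.
    """
    records = []
    seen: set[str] = set()
    with _open_text(gff3) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields[:9]
            if ftype != feature_type:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinates") from exc
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            gid = attr_map.get("ID") or attr_map.get("Name")
            if not gid:
                raise ParseError(f"line {lineno}: feature has no ID attribute")
            if gid in seen:
                raise ParseError(f"line {lineno}: duplicate gene_id {gid!r}")
            seen.add(gid)
            records.append((gid, seqid, start_i, end_i, strand if strand in "+-" else "+"))
    return GeneCatalog.from_unranked(records)


def read_cds_sequences(fasta) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Read CDS FASTA into an uppercased {gene_id: sequence} map.

    Returns ``(sequences, flags)`` where flags maps gene ids to quality
    issues among ``frame`` (length not divisible by 3) and ``internal_stop``.
    Flagged sequences are kept, not dropped.
    """
    seqs: dict[str, str] = {}
    flags: dict[str, list[str]] = {}
    with _open_text(fasta) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate FASTA id {rec.id!r}")
            seq = str(rec.seq).upper()
            seqs[rec.id] = seq
            issues = []
            if len(seq) % 3 != 0:
                issues.append("frame")
            else:
                codons = [seq[i : i + 3] for i in range(0, len(seq) - 3, 3)]
                if any(c in ("TAA", "TAG", "TGA") for c in codons):
                    issues.append("internal_stop")
            if issues:
                flags[rec.id] = issues
    if not seqs:
        raise ValueError("empty FASTA stream")
    return seqs, flags


def read_homolog_pairs(
    tabular,
    max_evalue: float = 1e-10,
    min_bitscore: float = 0.0,
) -> tuple[list[HomologPair], int]:
    """Read 12-column tabular similarity output into canonical homolog pairs.

    Self hits are removed, reciprocal rows collapse to one canonical pair
    keeping the best bitscore, and rows failing the e-value/bitscore
    thresholds are dropped. Returns ``(pairs, n_dropped)``.
    """
    best: dict[tuple[str, str], HomologPair] = {}
    dropped = 0
    with _open_text(tabular) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"line {lineno}: expected 12 tab-separated fields, got {len(fields)}"
                )
            query, subject = fields[0], fields[1]
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ParseError(
                    f"line {lineno}: non-numeric evalue/bitscore"
                ) from exc
            if query == subject:
                dropped += 1
                continue
            if evalue > max_evalue or bitscore < min_bitscore:
                dropped += 1
                continue
            pair = HomologPair.make(query, subject, bitscore, evalue)
            prev = best.get(pair.key)
            if prev is None or pair.bitscore > prev.bitscore:
                best[pair.key] = pair
    return [best[k] for k in sorted(best)], dropped


# ---------------------------------------------------------------------------
# deterministic TSV writers (fixed column orders; byte-identical on re-run)

GENE_MODES_COLUMNS = ["gene_id", "mode", "epoch", "is_pathway"]
PAIR_MODES_COLUMNS = ["gene_a", "gene_b", "mode"]
KS_PAIRS_COLUMNS = [
    "gene_a", "gene_b", "ka", "ks", "s_sites", "n_sites", "saturated", "mode", "epoch",
]
BLOCKS_COLUMNS = ["block_id", "chrom_a", "chrom_b", "orientation", "n_anchors", "anchors"]
ENRICHMENT_COLUMNS = [
    "pathway_wgd", "pathway_total", "genome_wgd", "genome_total",
    "pathway_prop", "genome_prop", "chi2", "p_value",
]
PROFILE_COLUMNS = ["offset", "retained", "total", "ratio"]


def write_table(df: pd.DataFrame, path: str | os.PathLike, columns: list[str]) -> None:
    """Write a TSV with a fixed column order; deterministic byte output."""
    out = df.reindex(columns=columns)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def write_results_tables(results: Mapping[str, pd.DataFrame], out_dir) -> list[str]:
    """Write every result table in ``results`` under ``out_dir``.

    Keys name the output files (without extension); known keys get their
    documented column order, unknown keys keep the frame's own columns.
    Returns the list of written paths.
    """
    known = {
        "gene_modes": GENE_MODES_COLUMNS,
        "pair_modes": PAIR_MODES_COLUMNS,
        "ks_pairs": KS_PAIRS_COLUMNS,
        "blocks": BLOCKS_COLUMNS,
        "enrichment": ENRICHMENT_COLUMNS,
        "profile": PROFILE_COLUMNS,
    }
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory {out_dir!s} is not writable")
    written = []
    for name, df in results.items():
        path = os.path.join(os.fspath(out_dir), f"{name}.tsv")
        write_table(df, path, known.get(name, list(df.columns)))
        written.append(path)
    return written


def write_gff3(catalog: GeneCatalog, path) -> None:
    """Emit the catalog as minimal GFF3 gene features (simulator output)."""
    with open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in catalog:
            fh.write(
                f"{g.chromosome}\tpaleodup\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "wt") as fh:
        for gid in seqs:
            fh.write(f">{gid}\n")
            s = seqs[gid]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
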