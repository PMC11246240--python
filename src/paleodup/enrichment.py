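"""Retention-enrichment statistics: pathway-vs-genome WGD enrichment
(Pearson chi-square), duplication-mode composition tables, generic term
over-representation (hypergeometric + Benjamini–Hochberg), and
cross-species group comparison (Student's pooled t-test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dup_classifier import GENE_MODES, GeneModeCall

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    pathway_wgd: int
    pathway_total: int
    genome_wgd: int
    genome_total: int
    pathway_prop: float
    genome_prop: float
    chi2: float
    p_value: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) for a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero row/column margin: chi-square undefined")
    expected = np.outer(row, col) / t.sum()
    chi2 = float(((t - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def wgd_pathway_enrichment(
    gene_modes: dict[str, GeneModeCall],
    pathway_ids: set[str],
) -> EnrichmentResult:
    """Test whether WGD-derived duplicates are over-retained in a pathway.

    Builds the 2x2 table (pathway vs rest-of-genome) x (WGD vs non-WGD)
    and applies the Pearson chi-square test without continuity correction.
    The reported ``genome_prop`` is the WGD proportion over *all* genes
    (pathway included), the figure a genome paper would quote as the
    background; the test itself contrasts pathway against the rest.
    """
    known = pathway_ids & gene_modes.keys()
    unknown = pathway_ids - known
    if unknown:
        logger.warning("%d pathway ids not in catalog; dropped: %s ...",
                       len(unknown), sorted(unknown)[:5])
    if not known:
        raise ValueError("no resolvable pathway genes")

    pathway_wgd = sum(1 for g in known if gene_modes[g].mode == "WGD")
    pathway_total = len(known)
    genome_wgd = sum(1 for c in gene_modes.values() if c.mode == "WGD")
    genome_total = len(gene_modes)
    rest_wgd = genome_wgd - pathway_wgd
    rest_total = genome_total - pathway_total
    table = np.array(
        [
            [pathway_wgd, pathway_total - pathway_wgd],
            [rest_wgd, rest_total - rest_wgd],
        ]
    )
    chi2, p = chi_square_2x2(table)
    return EnrichmentResult(
        pathway_wgd=pathway_wgd,
        pathway_total=pathway_total,
        genome_wgd=genome_wgd,
        genome_total=genome_total,
        pathway_prop=pathway_wgd / pathway_total,
        genome_prop=genome_wgd / genome_total,
        chi2=chi2,
        p_value=p,
    )


@dataclass
class ModeComposition:
    """Per-mode gene counts and proportions for one labelled gene set."""

    label: str
    counts: dict[str, int]
    proportions: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (self.label, m, self.counts[m], self.proportions[m])
                for m in GENE_MODES
            ],
            columns=["set_label", "mode", "count", "proportion"],
        )


def duplication_mode_composition(
    gene_modes: dict[str, GeneModeCall],
    gene_set: set[str],
    label: str = "set",
) -> ModeComposition:
    """Counts and proportions over the six gene-level modes for a gene set."""
    resolved = [gene_modes[g] for g in gene_set if g in gene_modes]
    if not resolved:
        raise ValueError("empty gene set after id resolution")
    counts = {m: 0 for m in GENE_MODES}
    for call in resolved:
        counts[call.mode] += 1
    n = len(resolved)
    return ModeComposition(label, counts, {m: c / n for m, c in counts.items()})


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(n)
    adj[order] = np.minimum(ranked, 1.0)
    return adj


def term_overrepresentation(
    gene_terms: pd.DataFrame,
    target_set: set[str],
    universe: set[str],
    min_genes: int = 3,
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a gene set.

    ``gene_terms`` has columns (gene_id, term_id), one association per row.
    For each term with at least ``min_genes`` members in the universe the
    upper-tail probability of the observed target overlap is computed and
    Benjamini–Hochberg adjusted. Sorted by adjusted value, ties by term id.
    """
    if not target_set <= universe:
        raise ValueError("target set is not a subset of the universe")
    gt = gene_terms[gene_terms.iloc[:, 0].isin(universe)]
    rows = []
    n_universe = len(universe)
    n_target = len(target_set)
    for term, group in gt.groupby(gt.columns[1]):
        members = set(group.iloc[:, 0])
        if len(members) < min_genes:
            continue
        overlap = len(members & target_set)
        # upper tail: P(X >= overlap), X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, len(members), n_target))
        rows.append((term, len(members), overlap, p))
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "term_size", "overlap", "p_value", "p_adjusted"]
        )
    df = pd.DataFrame(rows, columns=["term_id", "term_size", "overlap", "p_value"])
    df["p_adjusted"] = benjamini_hochberg(df["p_value"].to_numpy())
    df = df.sort_values(["p_adjusted", "term_id"], kind="stable").reset_index(drop=True)
    return df


@dataclass
class GroupComparison:
    values_a: list[float]
    values_b: list[float]
    t_statistic: float
    degrees_of_freedom: int
    p_value: float


def group_mean_comparison(values_a, values_b) -> GroupComparison:
    """Two-sided Student's (pooled-variance) t-test between two groups.

    Degenerate limit: when the pooled variance is zero and the means are
    equal, t = 0 and p = 1.
    """
    a = [float(v) for v in values_a]
    b = [float(v) for v in values_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    df = len(a) + len(b) - 2
    mean_a, mean_b = np.mean(a), np.mean(b)
    ss = np.sum((np.array(a) - mean_a) ** 2) + np.sum((np.array(b) - mean_b) ** 2)
    pooled_var = ss / df
    if pooled_var == 0:
        if mean_a == mean_b:
            return GroupComparison(a, b, 0.0, df, 1.0)
        raise ValueError("zero pooled variance with unequal means: t undefined")
    se = np.sqrt(pooled_var * (1 / len(a) + 1 / len(b)))
    t = float((mean_a - mean_b) / se)
    p = float(2 * stats.t.sf(abs(t), df))
    return GroupComparison(a, b, t, df, p)
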