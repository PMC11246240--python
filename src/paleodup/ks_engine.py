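"""Ka/Ks estimation (Nei–Gojobori 1986 counting with Jukes–Cantor
correction), Ks mixture modelling of paleopolyploidy peaks, and assignment
of WGD pairs to duplication epochs.

NG86 in brief: every codon carries 3 mutable sites, split into synonymous
and nonsynonymous fractions by enumerating all nine single-nucleotide
changes (changes producing stop codons are excluded from the denominator,
so the 3 sites are allocated proportionally among the remaining changes).
Site counts are averaged over the two sequences. Observed differences
between a codon pair differing at k positions are averaged over all k!
mutational pathways, skipping pathways that pass through a stop codon.
The proportions p_s, p_n are corrected for multiple hits with the
Jukes–Cantor formula d = -(3/4)·ln(1 - (4/3)·p); when the logarithm's
argument is non-positive the rate is saturated and reported undefined.

Ks peaks left by whole-genome duplications are modelled as a Gaussian
mixture on log10(Ks); the number of components is chosen by BIC and each
WGD pair is assigned to the epoch (component) with maximal posterior
membership, youngest epoch first.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .genome_io import HomologPair

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_BASES = "ACGT"

_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> None:
    from Bio.Data.CodonTable import standard_dna_table

    _CODON_TABLE.update(standard_dna_table.forward_table)
    for c in STOP_CODONS:
        _CODON_TABLE[c] = "*"


_build_codon_table()


@dataclass
class KsEstimate:
    """Per-pair NG86 estimate; rates are NaN when saturated/undefined."""

    pair: HomologPair | None
    ka: float
    ks: float
    s_sites: float
    n_sites: float
    saturated: bool


# --------------------------------------------------------------------------
# site counting

def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one codon.

    The codon's 3 sites are split proportionally to the synonymous fraction
    of its non-stop single-nucleotide neighbours.
    """
    aa = _CODON_TABLE[codon]
    syn = 0
    total = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            total += 1
            if _CODON_TABLE[alt] == aa:
                syn += 1
    if total == 0:  # cannot happen for non-stop codons of the standard code
        return 0.0, 3.0
    s = 3.0 * syn / total
    return s, 3.0 - s


_SITE_CACHE: dict[str, tuple[float, float]] = {}


def _sites_of(codon: str) -> tuple[float, float]:
    try:
        return _SITE_CACHE[codon]
    except KeyError:
        v = _codon_sites(codon)
        _SITE_CACHE[codon] = v
        return v


# --------------------------------------------------------------------------
# difference counting with pathway averaging

def _pathway_diffs(c1: str, c2: str) -> tuple[float, float] | None:
    """Average (synonymous, nonsynonymous) differences between two codons
    over all substitution pathways, skipping pathways through stop codons.

    Returns None when every pathway traverses a stop (the codon pair is
    then dropped from the difference counts).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = 0.0
    non_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = 0
        non = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            syn_total += syn
            non_total += non
            n_paths += 1
    if n_paths == 0:
        return None
    return syn_total / n_paths, non_total / n_paths


_DIFF_CACHE: dict[tuple[str, str], tuple[float, float] | None] = {}


def _diffs_of(c1: str, c2: str) -> tuple[float, float] | None:
    key = (c1, c2) if c1 <= c2 else (c2, c1)
    try:
        return _DIFF_CACHE[key]
    except KeyError:
        v = _pathway_diffs(key[0], key[1])
        _DIFF_CACHE[key] = v
        return v


def jukes_cantor(p: float) -> tuple[float, bool]:
    """JC69 multiple-hit correction; returns (distance, saturated)."""
    arg = 1.0 - (4.0 / 3.0) * p
    if arg <= 0.0:
        return math.nan, True
    return -0.75 * math.log(arg), False


def ng86_ka_ks(cds_a: str, cds_b: str, pair: HomologPair | None = None) -> KsEstimate:
    """NG86 Ka/Ks for an aligned, gap-free, in-frame CDS pair.

    Both sequences must have equal length divisible by 3; stop codons may
    terminate the sequences but codon columns containing a stop in either
    sequence are excluded from both site and difference counting.
    """
    a = cds_a.upper()
    b = cds_b.upper()
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) == 0 or len(a) % 3 != 0:
        raise ValueError(f"length {len(a)} not a positive multiple of 3")

    s_sites = 0.0
    n_sites = 0.0
    syn_diff = 0.0
    non_diff = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        if any(ch not in _BASES for ch in ca + cb):
            continue  # ambiguous columns removed from counting
        n_codons += 1
        sa, na = _sites_of(ca)
        sb, nb = _sites_of(cb)
        s_sites += 0.5 * (sa + sb)
        n_sites += 0.5 * (na + nb)
        d = _diffs_of(ca, cb)
        if d is None:
            logger.debug("codon pair %s/%s: all pathways hit stops; dropped", ca, cb)
            continue
        syn_diff += d[0]
        non_diff += d[1]
    if n_codons == 0:
        raise ValueError("no scorable codons in alignment")

    ps = syn_diff / s_sites if s_sites > 0 else 0.0
    pn = non_diff / n_sites if n_sites > 0 else 0.0
    ks, sat_s = jukes_cantor(ps)
    ka, sat_n = jukes_cantor(pn)
    return KsEstimate(pair, ka, ks, s_sites, n_sites, sat_s or sat_n)


def align_and_estimate(cds_a: str, cds_b: str, pair: HomologPair | None = None) -> KsEstimate:
    """Estimate Ka/Ks, building a codon alignment when lengths differ.

    Equal-length sequences are compared ungapped; otherwise a protein-guided
    global alignment is built (BLOSUM62, affine gaps) and gapped codon
    columns are removed before counting.
    """
    if len(cds_a) == len(cds_b):
        return ng86_ka_ks(cds_a, cds_b, pair)
    from Bio import Align
    from Bio.Align import substitution_matrices
    from Bio.Seq import Seq

    prot_a = str(Seq(cds_a[: len(cds_a) // 3 * 3]).translate()).rstrip("*")
    prot_b = str(Seq(cds_b[: len(cds_b) // 3 * 3]).translate()).rstrip("*")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    aln = aligner.align(prot_a.replace("*", "X"), prot_b.replace("*", "X"))[0]
    cols_a: list[str] = []
    cols_b: list[str] = []
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        for k in range(ea - sa):
            cols_a.append(cds_a[3 * (sa + k) : 3 * (sa + k) + 3])
            cols_b.append(cds_b[3 * (sb + k) : 3 * (sb + k) + 3])
    if not cols_a:
        raise ValueError("alignment left no ungapped codon columns")
    return ng86_ka_ks("".join(cols_a), "".join(cols_b), pair)


# --------------------------------------------------------------------------
# Ks mixture modelling

DEFAULT_KS_MIN = 0.005
DEFAULT_KS_MAX = 5.0
DEFAULT_K_MAX = 4
N_EM_RESTARTS = 10


@dataclass
class KsMixtureModel:
    """Gaussian mixture on log10(Ks); components sorted by ascending mean."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray  # log10(Ks) scale
    sds: np.ndarray
    bic: float
    bic_by_k: dict[int, float]

    def posterior(self, ks_values: np.ndarray) -> np.ndarray:
        """Posterior membership probabilities, shape (n, n_components)."""
        x = np.log10(np.asarray(ks_values, dtype=float))[:, None]
        log_dens = (
            -0.5 * ((x - self.means[None, :]) / self.sds[None, :]) ** 2
            - np.log(self.sds[None, :] * math.sqrt(2 * math.pi))
            + np.log(self.weights[None, :])
        )
        log_dens -= log_dens.max(axis=1, keepdims=True)
        dens = np.exp(log_dens)
        return dens / dens.sum(axis=1, keepdims=True)


def fit_ks_mixture(
    ks_values,
    k_max: int = DEFAULT_K_MAX,
    seed: int = 0,
    ks_min: float = DEFAULT_KS_MIN,
    ks_max: float = DEFAULT_KS_MAX,
) -> KsMixtureModel:
    """Fit Gaussian mixtures on log10(Ks) for K = 1..k_max and keep the
    BIC-optimal model (multiple seeded EM restarts per K)."""
    ks = np.asarray([k for k in np.ravel(ks_values) if np.isfinite(k)], dtype=float)
    ks = ks[(ks > ks_min) & (ks < ks_max)]
    if ks.size < 50:
        raise ValueError(
            f"only {ks.size} usable Ks values in ({ks_min}, {ks_max}); "
            "need >= 50 — supply more paralog pairs"
        )
    x = np.log10(ks)[:, None]
    rng = np.random.default_rng(seed)
    best: GaussianMixture | None = None
    best_bic = math.inf
    bic_by_k: dict[int, float] = {}
    for k in range(1, k_max + 1):
        k_best = None
        k_ll = -math.inf
        for _ in range(N_EM_RESTARTS):
            gm = GaussianMixture(
                n_components=k,
                covariance_type="diag",
                n_init=1,
                random_state=int(rng.integers(0, 2**31 - 1)),
                reg_covar=1e-6,
            ).fit(x)
            if gm.lower_bound_ > k_ll:
                k_ll = gm.lower_bound_
                k_best = gm
        means = np.sort(k_best.means_.ravel())
        sds = np.sqrt(k_best.covariances_.ravel())[np.argsort(k_best.means_.ravel())]
        if np.any(sds < 1e-4):
            logger.warning("K=%d fit ill-conditioned (component sd < 1e-4); skipped", k)
            continue
        # identifiability guard: adjacent components closer than one
        # component-sd are one peak fitted twice, not two resolvable epochs
        gaps = np.diff(means)
        widths = np.maximum(sds[:-1], sds[1:])
        if k > 1 and np.any(gaps < widths):
            logger.warning(
                "K=%d fit has unresolvable overlapping components; skipped", k
            )
            continue
        bic = k_best.bic(x)
        bic_by_k[k] = float(bic)
        if bic < best_bic:
            best_bic = bic
            best = k_best
    if best is None:
        raise RuntimeError("every mixture fit was ill-conditioned")
    order = np.argsort(best.means_.ravel())
    return KsMixtureModel(
        n_components=best.n_components,
        weights=best.weights_.ravel()[order],
        means=best.means_.ravel()[order],
        sds=np.sqrt(best.covariances_.ravel())[order],
        bic=float(best_bic),
        bic_by_k=bic_by_k,
    )


# --------------------------------------------------------------------------
# epoch assignment

@dataclass
class EpochAssignment:
    """Epoch (1 = youngest component) of one WGD pair or gene."""

    subject: tuple[str, str] | str  # pair key or gene_id
    epoch: int | None
    posterior: float


def assign_wgd_epochs(
    model: KsMixtureModel,
    wgd_estimates: list[KsEstimate],
) -> tuple[list[EpochAssignment], dict[str, EpochAssignment]]:
    """Assign WGD pairs (and their genes) to mixture components.

    Each pair goes to the component with maximal posterior membership
    (ties break toward the younger epoch); pairs with saturated or
    undefined Ks stay unassigned. A gene's epoch is that of its
    highest-posterior assigned pair.
    """
    if not wgd_estimates:
        raise ValueError("empty estimate list")
    pair_assignments: list[EpochAssignment] = []
    def is_usable(e: KsEstimate) -> bool:
        return not e.saturated and np.isfinite(e.ks) and e.ks > 0

    usable = [(e, e.ks) for e in wgd_estimates if is_usable(e)]
    unusable = [e for e in wgd_estimates if not is_usable(e)]
    if usable:
        post = model.posterior(np.array([ks for _, ks in usable]))
        for (est, _), probs in zip(usable, post):
            # argmax returns the first (youngest) component on exact ties
            comp = int(np.argmax(probs))
            pair_assignments.append(
                EpochAssignment(est.pair.key, comp + 1, float(probs[comp]))
            )
    for est in unusable:
        logger.debug("pair %s: saturated/undefined Ks, epoch unassigned", est.pair.key)
        pair_assignments.append(EpochAssignment(est.pair.key, None, 0.0))

    gene_assignments: dict[str, EpochAssignment] = {}
    for assign in pair_assignments:
        if assign.epoch is None:
            continue
        for gid in assign.subject:
            cur = gene_assignments.get(gid)
            if cur is None or assign.posterior > cur.posterior:
                gene_assignments[gid] = EpochAssignment(gid, assign.epoch, assign.posterior)
    return pair_assignments, gene_assignments
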