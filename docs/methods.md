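# Methods

## Problem and overall design

The package reconstructs the duplication history of a genome's paralogs
and asks whether whole-genome-duplication (WGD) derived duplicates were
preferentially retained in a designated pathway. It is organised as a
pipeline of independent stages — collinearity detection, duplication-mode
classification, Ka/Ks estimation, Ks-mixture epoch assignment, retention
statistics — each usable on its own, plus a genome simulator that
generates all inputs with known truth so that every stage can be tested
by parameter recovery.

All positional reasoning uses *gene ranks* (0-based order along a
chromosome by ascending start; ties broken by end, then gene id), never
base pairs: tandem/proximal distances, collinear chaining gaps and
neighborhood windows are statements about gene order. Strand is stored
but ignored for ranking. Coordinates are 1-based inclusive at the file
boundary (GFF3 convention).

## Collinearity

Homolog pairs are placed on rank coordinates per chromosome pair and
chained by dynamic programming: anchor *j* may extend anchor *i* when
both rank gaps are positive and at most `max_gap` (same direction on
both axes for parallel blocks, opposite for antiparallel). The chain
score is its anchor count; the best chain is extracted, its anchors
removed, and the DP repeated, so no anchor is in two blocks. Chains
shorter than `min_anchors` are discarded. Ties between equal-score
chains break toward the smallest starting `(rank_a, rank_b)`, which
together with the deterministic sort makes the output independent of
input order.

Defaults `max_gap = 25` genes and `min_anchors = 5` follow the common
practice of MCScanX-family tools. The score is a plain anchor count —
no gap penalty or bitscore weighting — because it is the simplest scheme
whose first extracted chain provably matches exhaustive search on small
instances (a tested invariant). Tandem arrays are not collapsed before
chaining; an adjacent tandem copy can occasionally be picked as the
anchor in place of its parent, which is visible in the recovery tests as
a ~1% tandem/WGD confusion and is mitigated by `min_anchors`.

Intra-genomic mode places each pair once (smaller `(chromosome, rank)`
side first) and excludes self-diagonal matches. The per-gene
multiplicity table counts how many distinct blocks cover each gene — the
"depth" of homologous regions, which is 2^n − 1 partners after n nested
WGDs without loss.

## Duplication-mode classification

Pairs are classified with a fixed priority, each pair receiving the
first matching mode:

1. **WGD** — the pair is an anchor of an intra-genomic syntenic block;
2. **TD** (tandem) — same chromosome, |Δrank| = 1;
3. **PD** (proximal) — same chromosome, 1 < |Δrank| ≤ `proximal_max`
   (default 10);
4. **TRD** (transposed) — exactly one gene of the pair lies at an
   ancestral locus, operationalised as "is an anchor of a genome-versus-
   outgroup syntenic block"; requires outgroup inputs;
5. **DSD** (dispersed) — everything else.

Genes take the highest-priority mode over all their pairs; genes in no
pair are singletons, so the mode counts always partition the catalog.
Without an outgroup the TRD test cannot be made, and would-be transposed
pairs are reported as dispersed rather than guessed — a merged, honest
category announced with a warning. A pair with *both* genes at ancestral
loci but not collinear with each other is dispersed, matching the
one-ancestral-one-novel definition of transposition.

## Ka/Ks (NG86 with Jukes–Cantor correction)

Synonymous and nonsynonymous *sites*: each codon carries 3 sites, split
proportionally to the synonymous fraction of its non-stop single-
nucleotide neighbours (changes producing stop codons are excluded from
the denominator). This allocation keeps `s_sites + n_sites = 3 ×
codons` exactly, a tested invariant. Site counts are averaged over the
two sequences.

*Differences*: codon pairs differing at k positions are scored by
averaging synonymous/nonsynonymous step counts over all k! substitution
orders, skipping orders that pass through a stop codon; if every order
does, the codon pair is dropped from the difference counts (logged).
Columns containing a stop or ambiguous base in either sequence are
excluded entirely.

The proportions p_s = syn diffs / s_sites and p_n are corrected for
multiple hits with Jukes–Cantor, d = −(3/4)·ln(1 − (4/3)p). When the
argument is non-positive the rate is reported NaN with `saturated=True`;
saturated pairs are never force-assigned downstream.

Counting (NG86) was chosen over maximum-likelihood codon models because
it is fully specifiable and oracle-checkable: the test suite contains an
independent brute-force pathway-enumeration implementation and requires
agreement to 1e-9. Note that implementations differ in stop-codon
conventions; Biopython's NG86 agrees exactly on stop-free neighbourhoods
but diverges by up to ~0.04 on sequences where stop-adjacent codons
occur, which is why the brute-force oracle, not a third-party library,
is the reference.

Unequal-length pairs are codon-aligned via a BLOSUM62 global protein
alignment (affine gaps −10/−0.5); gapped codon columns are removed
before counting. Equal-length pairs are compared ungapped.

## Ks mixture and epoch assignment

Ks values of WGD-classified pairs, restricted to the window
(0.005, 5.0) to drop near-identical allelic artifacts and the saturated
tail, are modelled on the log10 scale as a Gaussian mixture. For each
K = 1..`k_max` (default 4), EM runs with 10 seeded restarts and the best
likelihood is kept; K is then chosen by BIC. Only WGD (syntenic) pairs
enter the fit: small-scale duplications accumulate continuously and
contribute a broad background rather than peaks, and including them
degrades model selection.

Two guards reject a candidate K before BIC comparison:

* a component sd below 1e-4 (degenerate spike on repeated values);
* adjacent components whose means are closer than one component-sd
  (the larger of the two). Such a fit is one peak described twice — the
  components are not resolvable as distinct duplication epochs, and BIC
  alone will sometimes prefer this split to absorb the mild
  non-Gaussianity of real (and simulated) log-Ks peaks.

Each WGD pair is assigned to the component with maximal posterior
membership (ties break toward the younger epoch); epoch 1 is the
youngest (smallest mean). Gene-level epoch is the epoch of the gene's
highest-posterior pair. Mapping ordinal epochs to Greek-letter names
(α/β/γ) is left to presentation, since age order conventions vary.

## Retention statistics

**Pathway enrichment.** The 2×2 table is (pathway, rest of genome) ×
(WGD, non-WGD), tested with Pearson's chi-square, df = 1, *without*
Yates continuity correction — intended use is genome-scale tables with
expected counts far above 5. The reported `genome_prop` is the WGD
proportion over *all* genes including the pathway, the figure genome
papers quote as background; the test itself contrasts pathway against
the rest so the margins stay independent.

**Composition.** Counts and proportions over the six gene-level modes;
zero-count modes included.

**Term over-representation.** Hypergeometric upper tail per term
(terms with fewer than `min_genes = 3` members in the universe are
skipped), Benjamini–Hochberg adjusted across tested terms.

**Group comparison.** Two-sided Student's pooled-variance t-test (not
Welch's). The degenerate limit — zero pooled variance with equal means —
returns t = 0, p = 1.

**Neighborhood retention profile.** For each focal gene and offset d in
−W..+W (default W = 20), the gene at rank + d on the same chromosome
contributes to offset d's denominator, and to the numerator when its
gene-level mode is WGD. Offsets beyond a chromosome end contribute
nothing (the denominator shrinks; there is no wrap-around), so the
offset-0 total always equals the number of resolvable focal genes.
Focal genes that are neighbours of other focal genes count in both
roles. The permutation test redraws gene sets of the focal size
uniformly without replacement, compares offset-0 ratios one-sidedly,
and uses add-one smoothing: p = (1 + #{null ≥ observed})/(n_perm + 1),
so p is never below 1/(n_perm + 1).

## The simulator

The generator emulates the history the pipeline is built to detect:

* **Ancestral genome** — 5 chromosomes × 400 genes by default; CDS are
  random in-frame sequences (ATG … stop, no internal stops), length
  Poisson around 300 codons (min 60).
* **WGDs, oldest first** — defaults: two events with target Ks 0.6 and
  0.2. Every surviving gene duplicates onto a homeologous chromosome
  preserving order; each *new* copy is retained with probability 0.7
  (pathway members, 120 ancestral loci by default) or 0.3 (background),
  else deleted. Parents persist; lineage-specific parent loss is not
  modelled.
* **Ks structure** — per-family event ages are drawn log-normally
  around the event target (log10-sd 0.08, the spread used throughout
  the recovery tests) and kept ordered; between events every lineage
  accumulates Poisson numbers of synonymous and nonsynonymous
  substitutions (expected Δ·sites, with Ka = ω·Ks, ω = 0.2 by
  default), positions drawn uniformly among currently-synonymous
  (resp. nonsynonymous) stop-avoiding single-nucleotide changes. The
  estimator recovers generator targets to within a few percent (a
  tested property), the residual gap coming from multiple hits at
  two-state synonymous sites.
* **Small-scale duplications, after the WGDs** — per-gene rates 0.02
  each. Tandem copies insert rank-adjacent; proximal copies at 2..10
  ranks; transposed copies at a random novel locus with the source (a
  gene still in ancestral order) kept in place; dispersed events move
  *both* copies to random loci. Dispersed sources are drawn from
  families without WGD copies, and both copies move, because a
  stay-in-place parent at an ancestral locus would satisfy the
  transposed definition — the generator must not emit truth labels its
  own taxonomy contradicts. Small-scale pair divergence is uniform on
  Ks ∈ (0.05, 0.8).
* **Outgroup** — the frozen pre-WGD ancestor is emitted as a separate
  catalog with its own ids plus genome-versus-outgroup homolog pairs,
  exercising the transposed-duplicate branch end to end.
* **Homology input** — pairs are emitted from truth parentage (all
  genes sharing an ancestral root) with pseudo-bitscores decreasing in
  sequence divergence; no similarity search runs, but the 12-column
  format and its thresholds are exercised unchanged.

What the simulator does *not* emulate: intergenic sequence, introns,
transposable elements, rearrangements other than duplication placement,
rate variation along sequences, codon-usage bias, and lineage-specific
loss of parent copies. Recovery tests therefore demonstrate correctness
of the algorithms under the stated generative model, not performance on
real assemblies, where fractionation, tandem-array complexity and
annotation noise make classification harder.

Insertions shift ranks, so a tandem pair can later be separated by an
unrelated insertion landing between the copies (~8% of tandem events at
default rates); this is visible as a small, expected TD→PD confusion in
the recovery metrics.

## Reproducibility and numerics

Every stochastic stage takes a seed; the pipeline derives per-stage
seeds from the master seed with a fixed string-hash scheme, so stages
are individually reproducible and two runs with the same config are
byte-identical (tables are written with fixed column orders and `%.10g`
floats). EM restarts draw their seeds from the stage seed.

Problem sizes used by the test suite and the acceptance script — the
5×400-gene default simulation, 200 random pairs for the NG86 oracle,
500 chaining instances, 1000 resampled pathway sets for type-I
calibration, 300 history-only replicates for power, 999 permutations —
were chosen so each experiment's Monte-Carlo error is small relative to
the property being checked while the whole suite stays desk-scale.
Calibration experiments use truth gene modes (history-only simulation)
because they test the statistics given modes, not the classifier; the
classifier has its own recovery tests.

## Known limitations

* NG86 ignores transition/transversion bias and codon usage; Ks peaks
  are found reliably but absolute Ks is method-dependent. No absolute
  dating is attempted.
* Epoch assignment is marginal per pair; it does not enforce gene-tree
  consistency within a family (no phylogenetic reconciliation).
* The transposed call depends entirely on the supplied outgroup; with a
  poorly chosen outgroup, transposed and dispersed merge.
* Greedy chain extraction is optimal for the first chain only; later
  chains are conditionally greedy. Block significance is not modelled.
* The retention profile's per-offset denominator convention (each focal
  gene contributes at most one neighbour per offset) is one of several
  reasonable pooling choices; alternatives would shift flank levels
  slightly but not the focal peak.
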