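# paleodup

Comparative-genomics tooling for asking how a genome's duplicate genes
arose — whole-genome duplication (WGD), tandem, proximal, transposed or
dispersed duplication — and whether WGD-derived duplicates were
*preferentially retained* in a pathway of interest, the pattern repeatedly
seen for vegetable-oil (fatty-acid + triacylglycerol) biosynthesis genes
in oil crops. It is aimed at plant genome papers' "duplication history"
analyses: classify paralogs, date WGD epochs from Ks peaks, and test
pathway retention bias, all on standard inputs (GFF3, CDS FASTA,
12-column similarity tables, a pathway gene list).

Because real genome assemblies are large and external, the package ships
a first-class synthetic-genome simulator with known truth: nested WGDs
with log-normal Ks peaks, biased pathway retention, small-scale
duplications and gene loss. Every stage is tested by parameter recovery
against that truth.

## What it computes

* **Syntenic blocks** — collinear anchor chains on gene-rank coordinates
  (MCScanX-style dynamic programming with greedy extraction; defaults
  `max_gap=25` genes, `min_anchors=5`).
* **Duplication modes** — per pair and per gene, with the fixed priority
  WGD > TD > PD > TRD > DSD; TRD needs an outgroup anchor set (one gene
  at an ancestral, outgroup-syntenic locus, the other at a novel locus).
* **Ka/Ks** — Nei–Gojobori (1986) counting with equal-weight pathway
  averaging over multi-substitution codons, stop-excluded site
  allocation, and Jukes–Cantor correction
  `d = -3/4 · ln(1 - 4p/3)`; saturation is flagged, not guessed.
* **WGD epochs** — Gaussian mixture on log10(Ks) of syntenic (WGD)
  pairs, K chosen by BIC; each pair gets the maximum-posterior
  component, epoch 1 = youngest.
* **Retention statistics** — pathway-vs-genome 2×2 Pearson chi-square
  (no continuity correction), per-mode compositions, hypergeometric term
  over-representation with Benjamini–Hochberg adjustment, Student's
  pooled t-test for cross-species group contrasts, and the ±20-gene
  neighborhood retention profile with a permutation test of the peak.

## Worked example

```bash
python analysis/01_simulate_genome.py      # writes results/simulation/
python analysis/02_synteny_and_modes.py
python analysis/03_ks_epochs.py
python analysis/04_retention_enrichment.py
python analysis/05_retention_profile.py
```

The default simulation (seed 42; 5×400 ancestral genes, WGDs at Ks 0.6
and 0.2, pathway retention 0.7 vs background 0.3) prints:

```
44 intra-genomic syntenic blocks (2201 anchor pairs)
gene modes: {'singleton': 817, 'WGD': 2657, 'PD': 81, 'TRD': 92, 'TD': 52, 'DSD': 136} (total 3835)
gene-mode accuracy vs truth: 0.991
BIC selects 2 Ks peaks: Ks~0.20 (w=0.43), Ks~0.60 (w=0.57)
pathway: 345/373 WGD-derived (92.5%); genome: 2657/3835 (69.3%)
chi-square = 104.59, P = 1.5e-24 (pathway vs rest of genome, df=1)
retention ratio at pathway loci: 0.925; flanking (|offset| >= 10): 0.749
permutation test of the peak: observed 0.925 vs null 0.693 +/- 0.023; P = 0.001
```

Reading: the two simulated WGD epochs are recovered as Ks peaks at 0.20
and 0.60; 92.5% of pathway members are WGD-derived against a 69.3%
genome background, a strongly significant retention bias; and the
retention ratio spikes exactly at the pathway loci relative to their
chromosomal neighborhoods.

The same pipeline runs on real data through the CLI:

```bash
paleodup run-all --gff3 genome.gff3 --cds cds.fasta \
    --pairs blast.tsv --pathway oil_genes.txt \
    --outgroup-gff3 outgroup.gff3 --outgroup-pairs outgroup_blast.tsv \
    --seed 1 --out-dir results/run1
```

or from a flat `key = value` config file via `--config`. Outputs are
deterministic TSV/JSON tables (`gene_modes.tsv`, `ks_pairs.tsv`,
`blocks.tsv`, `enrichment.tsv`, `profile.tsv`, `mixture.json`,
`permutation.json`, plus a run manifest); two runs with the same config
are byte-identical.

## Layout

* `src/paleodup/` — the library: `genome_io`, `collinearity`,
  `dup_classifier`, `ks_engine`, `enrichment`, `retention_profile`,
  `synthetic_data`, `pipeline`, `cli`.
* `analysis/` — numbered narrative drivers over the library.
* `tests/` — pytest suite, including recovery/calibration tests against
  simulation truth and independent brute-force oracles.
* `docs/methods.md` — models, assumptions, parameter defaults and known
  limitations.
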