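# Methods

## The problem

Livestock GWAS hits for a given trait are scattered across studies with
poor reproducibility: array densities, phenotyping error and statistical
models differ, so single-study significance is weak evidence. Meanwhile,
QTL databases hold trait-associated *intervals*, and population
resequencing yields copy-number-variable regions (CNVRs) with per-sample
genotype calls. This package integrates the three evidence tracks: it
summarizes published GWAS SNPs into a windowed score, keeps the windows
whose score clears a threshold, and reports the genes overlapped by CNVRs
that fall inside both a high-confidence score window and a QTL — positional
candidates supported by all three data types.

## The windowed score

The genome is tiled into fixed, non-overlapping windows of `window_size` bp
(default 100 000, i.e. 0.1 Mb), anchored at position 1: window *k* covers
1-based positions `[kW+1, (k+1)W]`. For each occupied window,

    GWAScore = − n_gwas · Σᵢ log Pᵢ / (0.1 · n_snp)

where the sum runs over the association records in the window, `n_snp` is
their count, `n_gwas` the number of distinct contributing studies, and `Pᵢ`
the reported p-values. With log base 10 this equals
`10 · n_gwas · mean(−log₁₀ P)`: the mean evidence per SNP, amplified by
independent replication across studies. The statistic is

* **homogeneous in studies** — duplicating every record under a fresh study
  id exactly doubles it;
* **mean-invariant** — if all p-values are equal it does not depend on the
  SNP count;
* **monotone** — lowering any p-value never lowers it.

Windows with score strictly above `score_threshold` (default 0) are the
high-confidence regions. Each region is a single window — adjacent
qualifying windows are *not* merged — so K regions at 100 kb cover exactly
K × 0.1 Mb (190 regions ⇒ 19.0 Mb).

### Configuration choices

* `log_base` (default 10): the underlying formula is printed base-free;
  base 10 is the GWAS convention and natural log is selectable. Scores
  rescale by `ln 10 / ln b`.
* `normalization`: `as_printed` uses the `0.1 · n_snp` divisor above.
  `per_window_mean` drops the 0.1 factor (divides by `n_snp` only), giving
  scores 10× smaller; published score ranges in this family of analyses are
  consistent with either convention depending on the source, so both are
  exposed and neither is silently rescaled.
* `p_max` (default None): input tables are assumed to hold
  already-significant SNPs, so no filter is applied unless requested.
* A p-value of exactly 0 is rejected as invalid input rather than clamped:
  clamping would fabricate an arbitrary score.
* Threshold comparison is strict (`score > threshold`).
* Terminal windows are truncated only when a chromosome-length table is
  supplied; otherwise all windows have the full width.

## CNV genotype classing and breed specificity

CNVcaller-style genotype codes map totally onto three classes:
`dd, Ad → Loss`; `AA → Normal`; `AB, BB, BC, M → Gain`. Unknown codes are
errors naming the code and its region/sample context.

A region is **breed-specific** for breed B when every individual of B
carries the same genotype value and no individual of any other breed
carries that value. Decisions taken where the rule is underspecified:

* Comparison is at the Loss/Normal/Gain **class level by default**
  (`level="class"`), because the classing immediately precedes the
  specificity analysis; raw-code comparison is available (`level="code"`).
* A breed with **any missing call** at a region is ineligible for
  specificity there (conservative), and missing cells are excluded from all
  distributions.
* "Absent from other breeds" means no single non-missing sample elsewhere
  carries the value — one counter-example suffices.
* The **shared** count (Venn complement) is the number of regions where
  some genotype value is present in at least one sample of *every* breed.
* Per-breed class distributions are reported both as non-missing **cell
  counts** and as **region majority** counts; majority ties resolve in
  Loss, Normal, Gain order.

## Three-track integration and location labels

A CNVR survives when it overlaps (≥ 1 bp, no reciprocal-fraction
requirement) at least one high-confidence score window **and** at least one
QTL. It carries the maximum score over overlapping windows and the number
of distinct overlapping QTL ids. Surviving CNVRs are paired with every
gene they overlap or flank within `upstream_bp` (default 1000 bp, the
common variant-annotation convention; applied to both flanks, labelled
upstream/downstream by strand). Rows are ranked by score descending, ties
broken by (chromosome, start, gene symbol) for determinism.

Each pair gets one label with precedence

    exonic > UTR5 > UTR3 > intronic > upstream > downstream > intergenic.

**"Exonic" means the coding part of an exon.** In standard GFF3 the UTR
features lie inside exon features, so a literal exon-overlap test would
shadow the UTR labels entirely; the annotation layer therefore subtracts
UTR intervals from exons before the exonic test. A region confined to an
annotated UTR is labelled UTR5/UTR3; a region touching any coding exon
sequence is exonic regardless of what else it touches.

"Coding" genes are records with at least one exon whose biotype, when the
GFF3 provides one, is `protein_coding`; without a biotype attribute no
filtering is applied. Candidates overlapping no gene are reported as
intergenic rows with an empty gene field.

Coordinates: all TSV inputs and outputs are 1-based inclusive (matching
QTL-database exports and the candidate-table convention); internal
representation and BED exports are 0-based half-open.

## The synthetic-data generator

`simulate_all` emits a self-consistent bundle — GWAS TSV, QTL TSV, CNVR
genotype TSV, sample sheet, GFF3, truth JSON — from a single seeded NumPy
generator with a fixed generation order, so identical seeds give
byte-identical files.

Default conditions (chosen once as realistic for a desk-scale livestock
integration study): a 3-chromosome 8 Mb genome; 3 GWAS studies of 40
background SNPs each with p uniform on (10⁻⁴, 10⁻²]; 40 background QTLs of
50–250 kb; three breeds of 10/10/9 samples; 150 background CNVRs of
1.5–6.5 kb (≈ 4 kb mean) with class frequencies Loss 0.15 / Normal 0.70 /
Gain 0.15; ~50 background genes of 2–5 exons with 200/300 bp UTRs. The
`study_scale_config` preset scales the counts to the source study's
bookkeeping — 26 chromosomes, 440 GWAS markers across 10 studies, 729
QTLs, 4301 CNVRs, 29 samples in 3 breeds — for load testing; its genome
stays desk-sized (10 Mb per chromosome), so it is a workload preset, not a
reproduction claim.

Exactness of the truth set is by construction, not by measurement:

* Planted hot windows receive SNPs that all share one p-value `10⁻ᵐ`, so
  the expected score is closed-form (`n_studies · m / 0.1` for the default
  configuration) by mean invariance.
* Background features — SNPs, QTLs, CNVRs, genes — avoid the planted
  windows plus a 10 kb margin, and background p-values are bounded below
  by `p_background[0]`. No background window can therefore score above
  `n_studies · (−log₁₀ p_min) / 0.1`, and `recovery_threshold` places the
  cutoff midway between that analytic bound and the weakest planted window
  (refusing configurations where they do not separate).
* Planted candidates own their window: a fixed-layout plus-strand gene
  (200 bp UTR5, two 400 bp coding exons around a 2 kb intron, 300 bp UTR3)
  with the CNVR positioned to earn the requested label, plus a QTL spanning
  the window.
* Background genotype rows are rejection-sampled away from accidental
  breed-specific patterns (at both class and code level), so the planted
  specific regions are exactly the reported ones.

What the generator does **not** emulate: linkage disequilibrium among
markers, realistic gene density or chromosome-scale structure, correlated
genotypes within populations, overlapping or nested CNVRs, missing
genotype calls (cells are always called; missing handling is tested with
hand-built matrices), and realistic exon/intron length distributions.
Passing tests therefore demonstrate algorithmic correctness on known
ground truth, not statistical performance on real resequencing data. In
particular the synthetic exonic/intronic/intergenic split is dominated by
the (sparse) synthetic gene density and is not comparable to empirical
splits.

## Numerical and degenerate-input behaviour

Scores are plain double-precision sums of logs; the oracle comparisons in
the test suite hold to 1 × 10⁻⁹ relative tolerance. Empty inputs return
empty outputs (no errors): zero associations give zero windows, an empty
matrix gives zero counts, an empty score track gives zero candidates.
Chromosome names lacking the `chr` prefix are auto-prefixed with a logged
notice; chromosome names present in only some tracks produce a logged
warning listing the orphans, never a silent drop. Validation failures name
the record and, for files, the line number.

## Problem sizes used by the checks

The shipped checks run the generator at its default scale (tens of
windows, ~160 CNVRs, 29 samples) across 10–20 seeds, 1000-window oracle
sweeps for the formula, and 100 random track triples of up to 100
intervals each against an all-pairs scan; the study-scale preset is
exercised for counts and load. These sizes were chosen so the whole suite
runs in seconds while every code path and invariant is still covered.
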