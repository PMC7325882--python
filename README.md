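# gwascore

Integration of GWAS summary statistics, QTL intervals and copy-number
variation into ranked positional candidate genes, for livestock genomics.

Single-study GWAS hits reproduce poorly across array densities, phenotyping
protocols and statistical models. `gwascore` summarizes published
significant SNPs from *multiple* studies into a windowed score, then
cross-references the high-scoring windows with two independent evidence
tracks — database QTL intervals and population CNV regions — so that the
genes it reports are supported by all three data types. It is aimed at
animal-breeding researchers working from Animal QTLdb-style summary tables
and CNVcaller-style genotype matrices.

## The statistic

The genome is tiled into non-overlapping 100 kb windows anchored at
position 1. For every window containing at least one significant SNP,

```
GWAScore(w) = − n_gwas(w) · Σᵢ log₁₀ Pᵢ / (0.1 · n_snp(w))
```

where `n_snp(w)` counts association records in the window, `n_gwas(w)`
counts distinct contributing studies, and `Pᵢ` are the reported p-values.
Equivalently, `GWAScore = 10 · n_gwas · mean(−log₁₀ P)`: mean per-SNP
evidence amplified by independent replication. Windows with score > 0 (or
any stricter threshold) are the *high-confidence regions*, each a single
window, so K regions cover exactly K × 0.1 Mb.

A CNV region is a *positional candidate* when it overlaps (≥ 1 bp) both a
high-confidence window and a QTL; it is then paired with each gene it
overlaps or flanks (default 1 kb, strand-aware) and labelled by precedence
`exonic > UTR5 > UTR3 > intronic > upstream > downstream > intergenic`.

The package also classifies CNVcaller genotype codes
(`dd, Ad → Loss; AA → Normal; AB, BB, BC, M → Gain`) and finds
breed-specific CNV genotypes: a value fixed in every sample of one breed
and absent from all samples of the others.

## Worked example

`examples/score_windows.py` scores a seven-record association table:

```
chrom  start      end        n_gwas n_snp  GWAScore
chr1   1          100000     1      2      50.000
chr1   200001     300000     2      4      100.000
chr2   400001     500000     1      1      13.979

2 window(s) above GWAScore 40 -> high-confidence regions
```

The first window holds one study's SNPs at P = 10⁻⁴ and 10⁻⁶:
`−1 × (−4 − 6) / (0.1 × 2) = 50`. The second window contains the same two
loci reported by **two** independent studies, and scores exactly twice as
much — replication, not just significance, drives the score. The chr2
singleton at P = 0.04 scores `10 × 1.398 ≈ 14`.

The other examples each exercise one capability end to end:

* `examples/breed_specific_cnvs.py` — genotype classing, breed-specific
  detection, per-breed Loss/Normal/Gain composition;
* `examples/integrate_candidates.py` — simulate a dataset with planted
  triple-overlap genes, run the full integration, and print the candidate
  table (`Chromosome Start End GWAScore n_QTL Gene Location`) next to the
  planted truth it recovers;
* `examples/export_circos_tracks.py` — karyotype + QTL-tile /
  score-histogram / GWAS-scatter / CNV-tile track files for a CIRCOS
  figure.

## Command line

A thin CLI wraps the same functions:

```
gwascore simulate --seed 3 --out sim/
gwascore score --gwas sim/gwas.tsv --threshold 0 --out scored
gwascore cnv-summary --cnv sim/cnvr_genotypes.tsv --samples sim/samples.tsv --out cnv.json
gwascore integrate --cnv sim/cnvr_genotypes.tsv --qtl sim/qtl.tsv \
    --scores scored.regions.tsv --gff sim/genes.gff3 --out cand
gwascore run --gwas sim/gwas.tsv --qtl sim/qtl.tsv --cnv sim/cnvr_genotypes.tsv \
    --samples sim/samples.tsv --gff sim/genes.gff3 --out results/
```

Input dialects (tab-separated, 1-based inclusive coordinates) are
documented in `gwascore/io.py`; see `docs/methods.md` for the model,
parameter defaults and the design decisions behind the synthetic-data
generator.

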