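# qtlseq

A toolkit for **QTL-seq** — bulked-segregant analysis by whole-genome
sequencing — with everything needed to run and validate the method on
synthetic data: per-SNP SNP-index and Δ(SNP-index) statistics from two-bulk
allele counts, sliding-window genome scans, simulation-based null
confidence intervals, QTL interval calling against gene annotation, the
classical companion statistics (marker segregation filters, single-marker
association, replicated-trial phenotype summaries, θπ/θω nucleotide
diversity), and a first-class generator of synthetic F4 bulk-segregant
datasets.

It is written for plant geneticists mapping quantitative trait loci in
biparental populations (the motivating design is an intra-specific chickpea
F4 population segregating for 100-seed weight, with parents at 8.9 g and
30.1 g) and for methodologists who want a tested, reproducible QTL-seq
implementation to benchmark against.

## The statistics

Two DNA bulks are sequenced: pools of the *k* phenotypically lowest (LSB)
and highest (HSB) individuals from a segregating population (here an F4
advanced by single-seed descent, so an unselected locus segregates
LL : LH : HH = 7 : 2 : 7). After polarizing every site to the allele fixed
in the high parent, the **SNP-index** of a bulk at a SNP is

    SNP-index = (reads carrying the high-parent allele) / (read depth)

so 0 means every read derives from the low parent and 1 from the high
parent. The contrast

    Δ(SNP-index) = SNP-index(HSB) − SNP-index(LSB)

fluctuates around 0 genome-wide and is driven towards +1 at a locus that
controls the trait. Sites are filtered (depth ≥ 10 in both bulks, call
quality ≥ 20), averaged in 5 Mb windows slid by 10 kb, and judged against
**null confidence intervals**: for each read depth, the distribution of Δ
under "no QTL" is simulated by drawing k genotypes per bulk from the
mating design's neutral genotype law, forming the bulk allele frequency,
and binomially sampling reads (with sequencing error ε). Windows whose Δ
falls outside the simulated two-sided bounds — and whose bulk indices pass
the extreme-frequency criteria (HSB mean ≥ 0.9, LSB mean ≤ 0.1) — are
merged into candidate QTL intervals and intersected with GFF3 gene
annotation.

The validation-side statistics follow the classical single-marker
formulation: percent variance explained R² = 100·(1 − RSS₁/RSS₀) from the
regression of entry means on allele dosage, LOD = (n/2)·log₁₀(RSS₀/RSS₁),
additive effect a = (x̄(HH) − x̄(LL))/2; broad-sense heritability
H² = σ²G / (σ²G + σ²GE/e + σ²ε/(e·r)) from two-way ANOVA variance
components; and diversity per site θπ (mean pairwise difference rate) and
Watterson's θω = S/(a₁·L), a₁ = Σ_{i<n} 1/i.

## Worked example

Simulate a 10 Mb chromosome with 2,000 parent-differentiating SNPs, 221 F4
individuals, a major seed-weight QTL near 850 kb (H² = 0.85), bulks of
10 + 10 homozygous extremes, and reads at mean depth 30, then run the scan:

```sh
qtlseq simulate --n-sites 2000 --seed 1 --out demo
qtlseq qtlseq --counts demo/counts.tsv --seed 1 --out demo_scan
```

which logs, then prints:

```
causal QTL placed at Ca1:850717
sites: 2000 on 1 chromosome(s)
realized broad-sense H2: 0.858
bulk means (g): LSB 3.28, HSB 38.81

QTL-seq scan summary
================================================================
design: F4, bulk size k=10, error rate 0.005
window 5 Mb, step 10 kb, min 3 SNPs/window
site filters: depth >= 10 in both bulks, qual >= 20
----------------------------------------------------------------
input sites:               2000
parental fixed difference: 1998
passing depth/quality:     1997
windows scanned:           1000  (null reps 10000, seed 1)
----------------------------------------------------------------
candidate QTL intervals at 95% (merged windows):
  Ca1:1-6,120,000  (6,119,999 bp, 113 windows, level 99%)  peak Δ=0.847 @ 2,510,000  HSB=0.918 LSB=0.089
```

Reading the output: 1998 of 2000 simulated sites survive polarization (the
parents must be fixed for opposite alleles at ≥ 90 % of their reads) and
1997 pass the depth/quality screen. One interval is called; it contains the
true causal position (850,717 bp), its windows clear the 99 % null bound,
and the mean bulk indices inside it (HSB 0.918, LSB 0.089) satisfy the
≥ 0.9 / ≤ 0.1 extreme-frequency criteria. On a short, fully linked 10 Mb
chromosome the interval is necessarily wide; `qtlseq.call.refine_to_snps`
shrinks it to the outermost individually significant SNPs, mirroring
flanking-marker reporting.

The same run through the library:

```python
from qtlseq import QtlSeqScan, NullDesign

model = QtlSeqScan.from_tsv("demo/counts.tsv",
                            design=NullDesign("F4", k=10, error_rate=0.005))
result = model.fit(n_reps=10_000, seed=1)
print(result.summary())            # the table above
intervals = result.call_intervals(level=95)
fig = result.plot()                # bulk indices, Δ, and the CI band
```

Other entry points: `qtlseq scan` (single-marker R²/LOD/additive scan with
the 1:1 segregation filter), `qtlseq pheno` (CV, H², transgressive
segregants, normality), `qtlseq diversity` (per-group θπ/θω and
group-private SNPs from a TSV matrix or aligned FASTA), and
`qtlseq ci-table` (standalone null-CI tabulation). Every subcommand takes
`--config` (YAML; explicit flags win) and stamps outputs with the package
version, a configuration hash and the seed.

## File formats

Counts are exchanged as VCF 4.2 with per-sample `AD` fields (samples LSB,
HSB, LOW_PARENT, HIGH_PARENT) or as a TSV with a `#`-prefixed header and
columns `chrom pos ref alt qual` followed by ref/alt depth pairs per
sample in that order. All coordinates are 1-based inclusive (VCF/GFF
convention); interval BED exports convert to 0-based half-open at the
boundary. Genotypes are individuals × markers tables of LL/LH/HH codes;
phenotypes are tidy `individual environment replicate value` TSVs.

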