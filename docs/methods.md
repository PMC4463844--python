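# Methods

This note records the models implemented in `qtlseq`, the assumptions they
make, the defaults and why, and the numerical choices that a maintainer or
careful user would want spelled out. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The QTL-seq model

At a biallelic site polarized to the high-parent allele, a bulk's
SNP-index is the binomial fraction of reads carrying that allele, and
Δ(SNP-index) = HSB − LSB. Under the null hypothesis of no trait locus,
both bulks are random draws from the segregating population, so Δ is
symmetric about zero with a variance set by two nested sampling layers:

1. **Mendelian sampling of the bulk.** Each of the k bulked individuals
   contributes a high-allele frequency of 0, 1/2 or 1 according to the
   mating design's neutral genotype law — F2 1:2:1, RIL 1:0:1, and F4
   (three selfings from the F1 by single-seed descent) 7:2:7. A single F4
   individual's allele frequency therefore has mean 1/2 and variance
   p·q·(1+F)/2 = 7/32 with inbreeding coefficient F = 3/4; a bulk of k
   averages this to 7/(32k).
2. **Read sampling.** Given the bulk frequency p, high-allele reads are
   Binomial(d, p(1−ε) + (1−p)ε) at depth d with per-read error rate ε.

The null distribution has no convenient closed form once both layers and
the error rate are present, so confidence bounds are obtained by
simulation: 10,000 replicates per read depth by default, two-sided
empirical quantiles (order statistics with linear interpolation) at 95 %
and 99 %. The two bulks are simulated independently — shared family
structure between bulks is ignored, a deliberate approximation.

**Depth lookup is conservative.** Observed sites have unequal bulk depths;
bounds are tabulated with both bulks at the same depth and looked up at
min(LSB depth, HSB depth), which can only widen the interval relative to
the true mixed-depth null. A second source of conservatism is intrinsic:
Δ at depth d lives on a lattice with spacing ~1/d, and "strictly outside
an empirical quantile" then captures slightly less than α of the mass (up
to the local atom mass, ~tail density/d). Consequently the end-to-end
pipeline's realized outside-fraction sits a few parts per thousand *below*
the nominal α — never above it. The test suite checks exact-α calibration
on matched-depth draws at depths 75–100, where the lattice is fine
relative to the tail density, and separately asserts that the full
pipeline is never anticonservative and undershoots by at most 0.015.

**Windows.** Per-SNP values are averaged in rectangular windows (default
5 Mb, stepped 10 kb, 1-based inclusive, terminal window truncated) as
plain unweighted SNP means; depth weighting is available behind a flag but
is not the default, matching the plain reading of a windowed average.
Windows holding fewer than `min_snps = 3` SNPs are emitted with undefined
means so that sparse regions remain visible without being reported.
Window-level confidence bounds are the unweighted mean of the member SNPs'
per-depth bounds — the same averaging used for the index itself.

**Interval calling.** A window is significant when its Δ lies outside the
two-sided bound at the chosen level and, by default, its mean bulk indices
pass the extreme-frequency gates (HSB ≥ 0.9, LSB ≤ 0.1). Runs of at least
`min_run = 2` consecutive significant windows (a guard against
single-window noise; the choice is ours) are merged; boundaries are the
outermost window endpoints, and the attained level is 99 only if every
member window clears the 99 % bound. Physical interval length is reported
as end − start, the plain difference of the flanking coordinates. An
optional refinement step shrinks an interval to its outermost SNPs that
individually exceed their per-depth bound, mirroring flanking-marker
reporting. An optional absolute-Δ cutoff exists (off by default) for
workflows that additionally demand a fixed effect size. Gene overlap
against GFF3 uses ≥ 1 bp of overlap on 1-based inclusive coordinates,
strand ignored.

## The synthetic-data generator

The generator emulates the study design the analysis assumes, and only
that:

- **Map.** Sites scattered uniformly (sorted, deduplicated) along
  chromosomes; every site is a fixed difference between the parents, and
  the reference carries the high-parent allele at a random half of sites
  so that polarization is genuinely exercised. Default genetic scale
  1 cM/Mb, a chickpea-like genome-wide average (~845 cM over ~740 Mb);
  it is a constant per chromosome, not a recombination map.
- **Meiosis.** Crossovers per chromosome are Poisson with mean equal to
  the genetic length in Morgans, breakpoints uniform, no interference
  (Haldane). Breeding is strict single-seed descent from the F1 — one
  selfed offspring per line per generation, no selection.
- **Phenotypes.** value = midparent + a·(dosage−1) + d·[het] +
  environment shift + residual, with a = (high − low parental mean)/2
  (defaults 30.1 g and 8.9 g, so a = 10.6 g, dominance 0). The residual
  variance is solved so that broad-sense heritability on an entry-mean
  basis equals the requested H²: σ²ε = e·r·σ̂²G·(1/H² − 1), with σ̂²G the
  realized genetic variance of the simulated population. Environment
  shifts are additive common effects (sd 1 g); there is **no
  genotype-by-environment interaction** and no truncation of the Gaussian
  trait at zero, so extreme tails can be biologically implausible — the
  generator targets the statistical structure the scan consumes, not
  agronomic realism. Defaults: 221 individuals, 3 environments × 2
  replicates.
- **Bulks.** The k = 10 lowest and highest entry means, ties broken by
  individual id (stable); optionally, heterozygotes at a declared causal
  site are skipped while filling, emulating a marker-assisted
  homozygosity screen without reproducing a genome-wide one.
- **Reads.** Depth ~ Poisson(30) truncated at 1 (or constant, for exact
  worked examples), error rate 0.005; parents are sequenced under the
  same model with allele frequency fixed at 0 and 1. Read counts are
  generated directly — no FASTQ, alignment or base-quality simulation.

What passing tests therefore show: that the pipeline recovers a major QTL
and calibrates its null correctly **when the data satisfy these
assumptions**. They do not speak to alignment artefacts, reference bias,
structural variation, depth overdispersion beyond Poisson, or bulks
related through shared families.

## Classical companion statistics

- **Segregation filter.** Pearson chi-square against a Mendelian ratio,
  no continuity correction, df = classes − 1; heterozygotes are excluded
  so the 1:1 expectation applies to the two homozygous classes of an F4
  (which segregates 7:2:7 with heterozygotes included). The asymptotic
  test is anticonservative on small samples: enumeration against the
  exact binomial shows all decision mismatches up to total counts of 30
  are confined to asymptotic p-values within 0.025 of α = 0.05.
- **Single-marker scan.** Ordinary regression of entry means on allele
  dosage; R² = 100·(1 − RSS₁/RSS₀), LOD = (n/2)·log₁₀(RSS₀/RSS₁) (a
  strictly monotone transform of R² at fixed n), additive effect from the
  homozygote class means, dosage slope if a class is absent. Monomorphic
  markers are flagged, not scored. Interval mapping and composite interval
  mapping are out of scope; the single-marker scan is the validation
  surrogate.
- **Heritability.** Method-of-moments components from the balanced
  two-way ANOVA: σ²ε = MSE, σ²GE = (MS_GE − MSE)/r, σ²G =
  (MS_G − MS_GE)/(e·r), negative estimates clipped to zero, and
  H² = σ²G/(σ²G + σ²GE/e + σ²ε/(e·r)). Requires ≥ 2 environments, assumes
  balance (r is taken as the average replicate count otherwise).
- **Normality.** D'Agostino–Pearson skewness/kurtosis omnibus test on the
  entry means (undefined below n = 8).
- **Transgressive segregants.** Entry means beyond either parental mean,
  counted per tail.

## Diversity estimators

θπ is the average over unordered accession pairs of (differences /
pairwise-complete sites) — per *compared* site, so missing data shrink
the denominator pair by pair. θω = S/(a₁·L) counts S over sites with at
least two distinct non-missing calls while L stays the full region length;
the two estimators therefore scale differently under missingness, which
is documented rather than hidden. Heterozygous or ambiguous calls are set
to missing (selfing species; such calls are rare artefacts) and logged.
A SNP is private to a group when it is polymorphic within that group and
monomorphic (or uncalled) in every other group.

## Numerical and engineering choices

- All randomness flows through `numpy.random.Generator`; every stage is
  deterministic under a fixed seed, and the CLI derives stage seeds from
  one master seed via `SeedSequence`.
- Polarization requires each parent to carry one allele at ≥ 90 % of its
  reads with depth ≥ the bulk depth threshold — a read-level tolerance a
  genotype-based description does not need, configurable.
- Site filters are boundary-inclusive (depth ≥ 10 in *both* bulks —
  the conservative reading of a per-sample threshold — and QUAL ≥ 20;
  QUAL is the variant-call quality, per-read base quality being upstream
  of this tool).
- Depth lookups clamp to the nearest tabulated depth; quantiles use
  linear interpolation; ties in bulk selection break on individual id.
- Zero depth in `snp_index` is treated as a contract violation (such
  sites must have been filtered), not silently skipped.
- Problem sizes in the test suite are desk-scale by design: one 10 Mb
  chromosome with 2,000 SNPs, 221 individuals, 50 replicate simulations
  for recovery and 20 for parameter recovery; unlinked-site checks use a
  map density of several Morgans between adjacent sites so that
  binomial standard errors apply.

## Known limitations

- Bulks are simulated independently in the null model; real bulks share
  the population's family structure.
- The single simulated chromosome spans ~10 cM, so a fully penetrant QTL
  drags most of the chromosome with it; called intervals at this scale
  are wide, and recovery of the causal position under the default
  0.9/0.1 index gates sits near its design point rather than comfortably
  above it. SNP-level refinement narrows the report but the underlying
  linkage is real.
- No multiple-testing correction across windows (none is applied in the
  workflow this implements); no LOESS-type smoothing alternatives; no
  Tajima's D or other selection statistics; no linkage-map estimation.
- The phenotype model omits G×E variance and trait bounds, as noted
  above.
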