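# Methods

This note documents the statistical models, conventions and design choices
behind kdrkit, and what the synthetic-data generators do and do not emulate.

## Scope and data model

The package analyses diploid cohorts of *An. gambiae* s.l. (three taxa —
*An. coluzzii*, *An. gambiae* s.s., *An. arabiensis* — sampled across
villages/ecological zones) at a resistance gene region. Inputs are a VCF
(genotypes, optionally phased), tab-separated sample metadata, a GFF3
transcript model plus reference FASTA for codon-aware annotation, and a
samples × genes integer copy-number table produced upstream by
coverage-depth CNV callers. CNV *discovery* is out of scope; so are
alignment, variant calling and phasing.

Coordinates are 1-based inclusive throughout (VCF/GFF convention).
Multiallelic records are never split at ingest — decomposition into
per-allele rows happens only in the frequency and LD stages, so triallelic
resistance loci (codon 402: G>T and G>C, both Val→Leu; codon 995: L995F and
L995S modelled at one site) remain single sites. Missing genotypes
(allele index −1) are propagated, never imputed.

## Diversity statistics

A site is *segregating* when ≥ 2 distinct non-missing allele indices are
observed, *multiallelic* when ≥ 3; a multiallelic site counts once in S.
Sites where every call is missing are excluded (flagged by a warning).

* θ<sub>π</sub>: per site, the mean over all pairs of non-missing
  chromosomes of 1[alleles differ] (categorical mismatch — two distinct
  alleles count one difference regardless of which), summed over sites and
  divided by the analysed span. Per-site pair counts use the per-site
  non-missing chromosome number.
* θ<sub>w</sub> = S / (a₁ · span) with a₁ = Σ<sub>i=1</sub><sup>m−1</sup> 1/i
  and m the *modal* non-missing chromosome count across sites — a single
  harmonic correction rather than per-site corrections, adequate at the
  missingness levels targeted and simpler to reason about.
* Tajima's D uses the 1989 constants computed from the same m, with S
  counting multiallelic sites once and the numerator π<sub>total</sub> −
  S/a₁ (π<sub>total</sub> unnormalized by span). S = 0 yields NaN, a
  deliberate "not computable" sentinel distinct from 0. At m = 2 the
  variance constants vanish and D is defined as 0 (π = S identically).
* The denominator span is the analysed gene-region length by default; an
  accessibility-masked span can be passed instead where callable-site masks
  are available.

Finite-sample caveat: the numerator of D is exactly unbiased under
neutrality, but the normalized ratio is not — neutral coalescent
simulations at n = 10 give a mean D near −0.06 (confirmed against an
independent coalescent implementation). Calibration checks of the mean of D
at high replicate counts therefore resolve this intrinsic bias rather than
an estimator defect; the unbiased numerator is the quantity that centres on
zero exactly.

## Effect annotation and allele frequencies

Annotation requires a transcript model carrying its spliced CDS sequence
(assembled from GFF3 CDS features plus a reference FASTA; on the minus
strand the sequence is reverse-complemented and genomic alleles are
complemented before substitution). Every alternate allele of every coding
SNP receives its own record — the triallelic 402 site yields two
nonsynonymous records for the same amino-acid change. Codon numbering is
transcript-relative; legacy housefly numbering (e.g. L1014F for L995F) is a
display concern only. Indel alleles are skipped with a warning.

Frequencies are computed per group (taxon, site, or taxon×site) as focal
allele count over *non-missing* chromosomes in the group; groups with no
non-missing chromosomes at a site get NaN. Multiallelic named sites also
get a cumulative row (sum of alt-allele frequencies), the convention needed
to compare total 402L carriage against 1527T. The common-allele filter is
strict (frequency > threshold in ≥ 1 group; an allele at exactly 0.05 is
removed). The cluster-map matrix uses average-linkage hierarchical
clustering on Euclidean distances between frequency vectors, rows and
columns independently, with labels sorted before clustering so leaf orders
are reproducible.

## kdr allele configuration

Locus identities (positions, ref/alt nucleotides, label alphabet) are
supplied by a `KdrAlleleConfig`, never hard-coded: published coordinates
for these loci vary in format across sources, so defaults must be
user-verifiable. The shipped default is an internally consistent
*synthetic* configuration inside the Vgsc span (2L:2,358,158–2,431,617)
used by the generators and tests: 995 (triallelic; L→F, L→S) at 2,422,652,
402 (triallelic; V→L1 via g>t, V→L2 via g>c) at 2,391,228, 1527 (I→T) at
2,429,556. Real-data analyses should supply coordinates verified against
their reference annotation.

## Diplotype classification

A diplotype is the unordered pair of multi-locus haplotype labels, one
symbol per configured locus. Canonical pair order puts the label carrying
more mutant symbols first, ties broken lexicographically (hence
`FL1T/LVI`). Phased input is read directly off the two haplotype columns —
classification is then total and deterministic. For unphased input all
label pairs consistent with the per-locus genotypes are enumerated
(2^(h−1) pairs for h heterozygous loci); a unique pair is `unambiguous`,
otherwise the cohort's haplotype-label frequencies are estimated by the
standard genotype-to-haplotype EM over all samples and the pair maximizing
f(h₁)·f(h₂)·(2 if h₁≠h₂) is chosen (`em_resolved`), with the chosen
posterior and runner-up probability recorded. Samples missing a genotype at
any configured locus are excluded with a reason, outside all denominators.

Group frequencies are counts over classified samples; diplotype groups
rarer than a configurable cohort-wide count (default 3) pool into an
"other diplotypes" (OD) bucket. Hierarchical clustering of samples uses
Manhattan distance between alternate-allele dosage vectors over
biallelic-decomposed sites with average linkage (missing calls contribute
dosage 0); PCA mean-centres the dosage matrix and takes the SVD, with the
largest-magnitude loading of each component forced positive for a
reproducible sign convention.

## Allele-specific LD by EM

Each locus is collapsed to a focal-allele indicator (focal vs all other
alleles) — the device that makes a triallelic site analysable as two
separate focal alleles against a partner allele. From 3×3 two-locus
genotype counts on complete cases, the haplotype frequency p<sub>AB</sub>
is the only free parameter (allele-frequency marginals are fixed by the
data); EM splits double heterozygotes between coupling and repulsion by
p<sub>AB</sub>p<sub>ab</sub>/(p<sub>AB</sub>p<sub>ab</sub> +
p<sub>Ab</sub>p<sub>aB</sub>) and re-estimates until |Δp<sub>AB</sub>| <
10⁻¹⁰ (max 1000 iterations). The log-likelihood is asserted non-decreasing
at every step. Three starts — linkage equilibrium and the two feasibility
boundaries (full coupling, full repulsion) — guard against the interior
saddle point that a double-heterozygote-only sample produces; the highest
log-likelihood solution wins. A monomorphic focal allele leaves r²
undefined: it is reported as 0 for tabulation with `defined=False`
preserved in machine-readable output.

The per-group LD table adds a pooled `global` row that re-estimates from
the pooled genotypes rather than averaging per-group r². Pooling is the
deliberate choice: two strata with perfect but opposite-phase coupling
legitimately pool below 1 (and the EM estimate on pooled *genotypes* can
differ from the truth-phase pooled value, since phase is latent).

## Median-joining networks

Observed phased haplotypes are collapsed to unique nodes carrying counts
and label compositions. The network alternates (1) the ε-relaxed
minimum-spanning network under Hamming distance — edge weight classes
admitted in ascending order, an edge joining iff its endpoints were in
different components before its class opened, classes admitted until
connectivity plus ε further units; ties broken by lexicographic node key —
and (2) median addition: for every connected triplet (≥ 2 edges among the
three nodes) the site-wise majority vector is added if novel, for up to 20
rounds (non-convergence returns a flag). Medians not on any shortest path
between observed haplotypes are pruned, repeatedly until stable. ε defaults
to 0, the most parsimonious network. Median computation is the classical
majority rule on binary-coded sites; where a multiallelic site shows three
distinct values in a triplet, the value of the lexicographically smallest
vector is kept — a deterministic generalization. Haplotype sharing between
groups is reported as any observed node whose composition tallies ≥ 2
distinct labels.

## CNV summaries

Baseline ploidy is 2 for autosomal genes; X-linked genes use 2 in females
and 1 in males, with unknown-sex samples skipped unless a fallback baseline
is configured. copies > baseline is an amplification, < baseline a
deletion, 0 a complete deletion (flagged). Frequencies are
carriers/assayed, in percent to 2 decimals. Cohort-wide tallies count each
gene at most once per state but a gene with both amp and del carriers
appears in both state tallies — which is why per-state gene counts can sum
to more than the number of CNV-bearing genes.

## Synthetic-data generators

* **Coalescent**: Kingman genealogy (pairwise coalescence at rate k(k−1)/2,
  time in units of 2N generations) with infinite-sites mutation — Poisson
  (θ/2 · branch length) mutations per branch, each a new biallelic column.
  No recombination, constant population size, even haplotype counts (columns
  pair into pseudo-diploids). This suffices to calibrate the estimators
  against E[S] = θ·a<sub>n−1</sub> and E[π] = θ; it does not emulate
  demography, selection or sequencing error.
* **kdr cohorts**: each individual draws two haplotype labels i.i.d. from
  its (taxon, site) frequency table — Hardy–Weinberg at the haplotype
  level — expanded to allele indices at the configured loci. Background
  biallelic sites are independent per haplotype with per-site frequencies
  drawn once from a configurable range (default U(0.05, 0.5)): background
  sites are in linkage equilibrium *by construction*, so all LD structure
  lives in the haplotype table and the r² a table implies
  (D²/(p<sub>A</sub>q<sub>A</sub>p<sub>B</sub>q<sub>B</sub>), available as
  `table_r2`) is the generator-side truth for the LD estimator. The phased
  matrix is the ground truth; truth labels are retained for accuracy
  scoring. Defaults emulate the field-study shape — up to 3 taxa across 8
  villages, a triallelic 402 plus biallelic 995/1527 loci, cohorts of tens
  to hundreds of samples.
* **Copy numbers**: independent per-(sample, gene) draws from per-taxon
  distributions with support in 0..12 (the full amplification range
  observed in single mosquitoes, and complete deletions at 0).

One global integer seed feeds named substreams (one per replicate /
population / stage), so adding a population leaves the draws of the others
unchanged, and CLI reruns with the same config + seed are byte-identical.

What passing tests on these cohorts do *not* show: robustness to genotyping
error, to phasing switch errors, to background selection/linked selection
in the flanking region, or to missingness that is non-random with respect
to genotype. Real-data analyses should treat those as open validation
concerns.

## Problem sizes used in checks

Calibration and recovery checks run at sizes chosen to make Monte-Carlo
error small relative to the tolerances: 2000 coalescent replicates at
n = 10, θ = 5; LD recovery at n = 500 diploids (tolerance ±0.05, with
±0.1 at n = 100); diplotype and CNV recovery at cohorts of 150–500. The
printed-count worked examples (5121 sites, 368 triallelic, 675
non-synonymous, 73,460 bp span; 112/113 diplotype homozygotes; 1/240
chromosomes; 32 perfectly coupled diploids) are exact arithmetic
reproduced through the pipeline's own code paths.
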