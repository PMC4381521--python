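# Methods

## Scope and model

`xiscape` analyses the transcriptional and chromatin state of the inactive
X chromosome (Xi) at four levels: allele-level expression (array channels
and sequencing read counts at heterozygous SNPs), chromosome-scale
chromatin coverage, single-nucleus image intensities, and per-nucleus FISH
scoring across tumor cohorts. The unifying assumption is clonality: in a
clonal cell population every cell silences the same parental X, so a gene
subject to XCI appears monoallelic at its heterozygous SNPs, while
pseudoautosomal (PAR) genes, autosomal genes, and escapees appear
biallelic. Departures from this pattern in a cancer sample — relative to
normal clones and to reference XCI annotations — are the signal of
interest.

Upstream processing is out of scope by design: genotype calling,
copy-number/allelic-content segmentation, read alignment, allele counting
from BAMs, phasing, peak calling and image acquisition are consumed as
inputs (TSV/BED/bedGraph/TIFF).

## Allelic calling

**Array platform.** Each SNP receives three flags. *Expressed*: total
intensity (A+B) at or above a per-array quantile of all totals (default
median, `expr_quantile=0.5`; an absolute cutoff can be substituted). An
adaptive threshold survives array-to-array scale differences; ties pass
(`>=`). *Informative*: heterozygous, minor allele genomically retained
(minor copy number >= 1 when provided), outside every LOH segment (1-based
inclusive; overlapping segments unioned). *Allelic class*: among expressed
informative SNPs, biallelic iff the minor-channel fraction
min(A,B)/(A+B) >= `snp_minor_fraction` (default 0.20, deliberately the
same 20% minor-allele rule as the sequencing platform so one definition
serves both).

Window profiles cumulate SNP status over `window_size` (default 50)
consecutive *informative* SNPs, advancing by `window_step` (default 1) and
never crossing a chromosome; whether windows advance over informative or
all SNPs is configurable (`window_members`), informative being the default
since the profile counts expressed informative SNPs. Chromosomes with
fewer members than one window yield a single truncated, flagged window.

Gene calls require >= `min_informative_snps_per_gene` (default 1)
expressed informative SNPs; a gene is monoallelic when its biallelic-SNP
fraction is *strictly* below 2/3 — a gene with exactly 2/3 biallelic SNPs
is biallelic. Clonality is verified by the fraction of monoallelic X SNPs
whose expressed allele sits on the majority haplotype (clonal at >= 0.95).

**Sequencing platform.** Phase-consistent per-SNP haplotype counts are
summed per gene; the allelic expression ratio is
100 x minor / ((h1+h2)/2) = 200 x minor fraction, monoallelic iff
strictly < 40. The affine form is the unique map consistent with "ratio 40
== minor allele 20%"; the minor fraction is reported alongside for
transparency. Genes with < `min_gene_reads` (default 20) total reads are
uninformative. Per-SNP minor-allele summation of unphased data is not
offered, because taking the minor allele SNP-by-SNP biases genes toward
monoallelic; phasing is a precondition.

**Escape categories.** For each gene and cancer sample:
`cancer_specific_escapee` iff biallelic in the cancer sample AND
(monoallelic in every informative normal — at least one required — OR
annotated subject to XCI) AND not annotated escapee;
`constitutive_escapee` iff biallelic in the cancer sample AND (biallelic
in >= 1 normal OR annotated escapee), the normal-sample evidence taking
precedence over the annotated-subject branch; `subject` iff monoallelic in
the cancer sample; otherwise `uninformative` — including the case of a
biallelic call with no normal evidence and no annotation, which cannot be
attributed to cancer. Cross-platform overlap of cancer-specific sets is
reported as Jaccard x 100 (symmetric), with the two one-sided percentages
alongside, since the appropriate denominator is a matter of convention.
Cohort utilities retain tumors whose heterozygous-X SNP fraction is
>= `min_het_fraction` (default 0.10 — samples below it have likely lost
the Xi and are uninterpretable) and list genes biallelic in
>= `min_recurrent_samples` (default 2) tumors.

## Chromatin tracks

bedGraph coverage is averaged into fixed-width bins (default 1 Mb) by
length-weighted mean, uncovered bases counting 0 and the final partial bin
normalized by its true width; total signal is conserved on fully covered
chromosomes. Tracks on a shared grid are quantile-normalized classically:
values are replaced by the across-track mean of order statistics at the
same rank, ties receiving the mean of their tied ranks' reference values.
Multisets are identical across outputs for tie-free inputs; the tie rule
trades exact multiset identity for rank stability, the standard
compromise. Per-bin comparisons use log2((v+1)/(r+1)) (pseudocount
configurable; a raw-difference mode is available since either reading of
"variation relative to a reference" is defensible). TSS metaprofiles span
+/-1.5 kb at 50-bp steps (step is a resolution choice), strand-flipped so
+x is downstream; genes whose window crosses a chromosome edge become
all-NA rows excluded from means. Domain enrichment compares bins
overlapping a labeled domain set by >= 50% of their width (the overlap
rule is a choice; domains are consumed as BED) against bins overlapping no
domain; with no outside bins the ratio is flagged undefined. Haplotype-
split coverage can be analyzed by running the same functions on the two
tracks separately.

## Image quantification

The enrichment ratio is mean(channel | domain) / mean(channel | nucleus
minus domain): the "rest of the nucleus" excludes the domain, since
including it shrinks every ratio toward 1; depletion is a ratio < 1 with
the same estimator. No background subtraction is applied by default (an
optional constant can be supplied). Pearson colocalization is computed
over the whole nucleus mask by default, is invariant to positive-gain
affine rescaling, and is flagged NaN at zero variance. Line scans sample
along a segment at 1-px steps, average over a configurable perpendicular
width, and min-max normalize each channel to [0,1] (flat channels map to
0.5). Automated domain segmentation (for data without curated masks)
applies Otsu's threshold within the nucleus and keeps the expected number
of largest connected components above a 10-px minimum area. Population
summaries use 10/25/50/75/90th percentiles with linear interpolation.
Quantification is strictly 2D (single planes or projections): the ratio
and correlation estimators do not require 3D stacks.

## Tumor FISH scoring

A tumor is XIST-positive when the fraction of scored nuclei with >= 1
XIST RNA domain reaches 10% (inclusive by default; a strict > variant is
selectable because both readings of the rule appear in practice). Gene
reactivation is evaluated only in XIST-positive tumors: reactivated when
the fraction of nuclei with an in-domain nascent signal reaches 5%. The
denominator is all scored nuclei by default; a domain-bearing-nuclei
denominator is configurable, which matters when domain prevalence is low
(an in-domain signal rate p conditional on a domain of prevalence q
yields a marginal rate pq over all nuclei). Signals outside the domain
(presumed active-X expression) are recorded descriptively and trigger no
call. Cross-tabs count tumors and reactivations per molecular subtype
(Luminal / HER2 / BLC; unknown labels bucket to NA).

## Synthetic data: what it emulates and what it does not

The generator is a pure function of (config, seed) — identical inputs give
byte-identical outputs; all sub-generators derive child RNGs from the seed
plus a fixed label.

* **Annotation**: genes tiled without overlap (20-kb genes, 5-kb gaps) on
  chrX and one all-biallelic control autosome (chr2); PAR genes
  (`frac_par=0.05`) at the chrX extremities; constitutive escapees
  (default 15% of X genes) with stable per-gene Xi fractions drawn
  Uniform(0.15, 0.5) — strictly below 0.5, since escapees are expressed
  more weakly from the Xi than the Xa, and straddling the 20% calling
  threshold to exercise the boundary; 3–8 SNPs per gene at distinct
  positions, each with a fixed haplotype phase.
* **Clones**: subject genes carry Xi fraction `xi_leak_fraction` (default
  0.01 — well below the 0.2 threshold so noise-free recovery is exact;
  residual Xi expression of silenced genes is a free parameter, not a
  measured constant); PAR/autosomal genes 0.5; cancer samples plant
  exactly `n_cancer_reactivated_per_sample` (default 10) reactivated
  genes among expressed subject genes, with escapee-range Xi fractions.
  Opposite-Xi clones have mirrored monoallelic phase. LOH segments apply
  to cancer samples (genotypes forced homozygous, Xi allele lost).
* **Array channels**: per-gene expression lognormal (median 1000,
  sigma 0.5 across genes; silent genes — default 40% of genes, emulating
  SNPs in untranscribed regions — contribute background only); channel =
  expression x allele fraction x lognormal(0, 0.25) noise + a background
  floor of 50 with continuous upward jitter scaled by the same sigma
  (channels never fall below background, and background totals are
  tie-free so the adaptive expression threshold separates the modes). The
  silent fraction is kept below the default 0.5 expression quantile so
  the threshold lands above the background mode.
* **Allele counts**: depth per het SNP negative-binomial (mean 50,
  dispersion 0.2 — standard RNA-seq overdispersion; Poisson at 0), Xi
  counts Binomial(depth, Xi fraction), zero reads for silent genes.
* **Chromatin tracks**: 20-Mb chromosome in 100-kb bins, four domains with
  alternating H3K27me3/H3K9me3 labels at 3x contrast over baseline,
  lognormal(0, 0.1) noise; the perturbed track flattens domains in the
  distal half (epigenetic erosion) and zeroes the first 10% (regional
  genetic loss).
* **Nuclei**: 128x128 images, elliptical nucleus (48x40 px), one disk
  domain (12 px) at planted contrast 2.0 over background 100 with
  Gaussian noise sd 10 (10% of background), plus a structurally correlated
  second channel for colocalization; 2D only, no PSF or 3D stacks.
* **Tumor tables**: XIST-domain presence Bernoulli(0.3) per nucleus;
  in-domain signals Bernoulli(0.1) in domain-bearing nuclei; outside
  signals Bernoulli(0.2) anywhere; 40 tumors x 100 nuclei by default,
  genes HDAC8 / ATRX / TBL1X.

What the simulations do **not** model: genomic waves and GC effects on
array intensities, mapping bias and reference bias in allele counts,
correlated noise and segmentation error in images, tumor purity and
stromal contamination, subclonal heterogeneity, or real SNP density
variation. Passing the recovery tests therefore demonstrates correctness
of the estimators and calling logic under the stated statistical model,
not robustness to every artifact of real data.

## Recovery benchmarks and problem sizes

The end-to-end benchmark simulates 2 normal clones + 3 cancer samples at
the default study conditions (300 X genes, 15% escapees, 10 plants per
cancer sample, depth 50) and requires sensitivity >= 0.95 with FDR <= 0.05
on both platforms. Sensitivity is computed over planted genes that are
informative on the platform and whose true Xi fraction exceeds 0.25:
plants below the 20% operational threshold are not escapees under the
calling rule by construction, and informativeness conditioning mirrors how
such studies count (all rates are "of informative genes" — a median-based
expression threshold always leaves some genes below detection). FDR uses
all cancer-specific calls with no exclusions. Other benchmark sizes —
100 random 1,000-SNP window inputs, 50 nuclei for the imaging median,
10^5 pixels for the colocalization null, 200 tumors x 500 nuclei for FISH
calling — were chosen to make sampling error small relative to the margins
being tested while keeping the suite fast.

## Numerical conventions and degenerate inputs

TSV coordinates are 1-based inclusive; BED/bedGraph are 0-based half-open.
Quantiles and percentiles use linear interpolation; threshold comparisons
at boundaries are `>=` for expression, SNP biallelic fraction, XIST
positivity and reactivation, and strict `<` for the gene 2/3 rule and the
ratio-40 rule, following the published wording of each. Intensity ties
between channels break toward channel A for the major-channel label. An
all-zero array warns and calls nothing expressed; an empty window input
returns an empty profile; zero-variance colocalization, all-domain
chromosomes, and empty gene sets are flagged rather than raised where a
partial result is still meaningful, and raised where it is not (empty
masks, zero nuclei, degenerate line scans).
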