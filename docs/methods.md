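# Methods

`dtubench` is a self-contained benchmark of counting-bin strategies for
detecting differential transcript usage (DTU) from RNA-seq data.  It
simulates a two-condition experiment with known isoform switches,
represents the data under several counting-bin definitions, tests each
bin for differential usage with a bin-vs-rest negative-binomial GLM, and
scores gene-level calls against the simulated truth.  Everything runs on
synthetic annotation and synthetic fragments; no external data or
aligner is involved.

## Simulation model

**Annotation.** Genes are placed left to right on one synthetic
chromosome.  Each gene receives a primary transcript (exon count and
exon/intron lengths drawn from regime-specific log-normal and discrete
distributions) and additional isoforms derived by repeated structural
edits: skipping an internal exon, shifting a 5'/3' exon boundary inward
by at least 20 bp, or retaining an intron.  Duplicate structures within
a gene are rejected, so any two isoforms differ by at least one edit.
Two regime presets bracket the transcriptome-complexity axis:

| preset | isoforms/gene (weights) | exon length (median) | exons/transcript |
|---|---|---|---|
| `fruitfly_like` | 1:0.10, 2:0.50, 3:0.40 | ~350 bp | 3–6 |
| `human_like` | 3–10 (mean ≈ 5.3) | ~140 bp | 5–10 |

The presets are qualitative: simple transcriptomes have long exons and
few isoforms; complex ones short exons and many isoforms.  An optional
`gene_overlap_rate` places a fraction of genes so that their first exon
overlaps the previous gene's last exon on the same strand, exercising
the gene-aggregation path of flattening.

**Expression.** Per gene g, a baseline expected count μ_g is drawn
log-normal (σ_log = 0.7 by default) and scaled so Σ μ_g equals the
library size net of the background fraction.  The NB dispersion follows
the mean–dispersion curve φ = a₀ + a₁/μ with defaults (0.01, 3); the
coefficients are configurable and an optional log-scale jitter is
available.  Isoform proportions π_g are drawn once from a symmetric
Dirichlet with concentration 0.5 (< 1, so most genes have a dominant
isoform and some near-zero isoforms) and sorted descending; both
conditions share them initially.

**DTU.** `n_dtu` genes are drawn uniformly from the eligible set (at
least two isoforms with proportion above 0.10 and expected count above
500).  For each, the proportions of the two most abundant isoforms are
exchanged in condition 2.  Gene-level means are untouched, so the switch
carries no gene-level differential expression; the effect size is the
dominance difference |π₍₁₎ − π₍₂₎|, recorded in the truth table for
every gene.

**Samples and fragments.** Per sample, the gene count is
K ~ NB(μ, φ) (variance μ + φμ²); realized isoform fractions are
Dirichlet with concentration 100·π (isoforms with π = 0 are excluded
from the draw and stay at zero, since the Dirichlet is undefined at a
zero concentration); isoform RPK = gene RPK × fraction, where gene RPK
uses the expression-weighted mean of isoform effective lengths, and TPM
rescales RPK to 10⁶.  Paired-end fragments pick a transcript
multinomially with weight ∝ TPM × effective length, a length from a
normal (mean 250, sd 25) truncated to [read length, transcript length],
and a uniform start; effective length is max(1, L − 250 + 1).  Mates
are the genomic projections of the first and last 101 fragment bases,
split across exons as needed.  5 % of fragments are uniform single-block
background pairs anywhere on the chromosome.  Fragments are emitted as
exact coordinate blocks: there is no sequencing-error or base-quality
model and no aligner, so counting operates on true alignments.  The
default desk scale is 2×10⁵ fragments per sample with three replicates
per condition; all of these are configurable through `SimParams`.

The whole simulation is a pure function of `SimParams` (including its
seed); sub-streams for annotation, expression, and each sample are
derived with `numpy.random.SeedSequence`.

## Counting-bin representations

* **flat** (three overlap modes): exon unions are cut at every exon
  start/end, producing the maximal runs of bases covered by an
  identical transcript set within a feature.  `aggregate` merges genes
  whose exon unions overlap by ≥ 1 bp on the same strand into a
  complex whose identifier joins the member gene ids with "+";
  `exclude_same_strand` and `exclude_both_strands` instead drop the
  sub-intervals shared by two or more genes (on the same strand, or on
  either strand).  The aggregation trigger is exon-union overlap;
  purely intronic containment does not aggregate.
* **exon**: one bin per distinct exon per gene; bins may overlap and a
  fragment is assigned to every exon it touches.
* **junction**: one bin per distinct splice junction per gene; only
  fragments with a mate whose blocks split exactly at the junction
  count.
* **transcript**: the isoforms themselves.  Fragments are collapsed
  into equivalence classes of compatible transcripts (both mates inside
  the transcript's exons, every internal block boundary on one of its
  junctions) and expected per-transcript counts come from a
  uniform-read-model EM: responsibilities ∝ θ_t / effective length,
  M-step renormalizes, convergence when max|Δθ| < 10⁻⁸ or 1000
  iterations, uniform initialization for determinism.

Counting is fragment-level: one count at most per (fragment, bin), but
a fragment overlapping several bins counts in all of them, so flat/exon
column sums can exceed the number of fragments.

## The bin-vs-rest test

For each bin, the 2S observations are the bin's counts and the summed
counts of the feature's other (surviving) bins per sample.  The NB GLM
with log link and log-size-factor offsets has sample effects, a
bin-part effect, and a condition × bin-part interaction; the LRT
against the no-interaction model is referred to χ²₁ (two conditions).
Size factors are DESeq-style median-of-ratios rescaled to geometric
mean one, falling back to total-count ratios when no bin is positive
everywhere.

One dispersion per bin, shared by its 2S observations, is estimated by
maximizing the Cox–Reid adjusted profile likelihood (the NB
log-likelihood minus ½ log det XᵀWX at the IRLS fit) over
log φ ∈ [log 10⁻⁸, log 10] by bounded scalar minimization.  A trend
φ_tr(μ) = b₀ + b₁/μ is fitted across bins by iteratively reweighted
non-negative least squares with gamma-like weights (constant at the
median when fewer than 10 interior estimates exist).  Final dispersions
are MAP estimates under a log-normal prior centred at the trend, with
the prior sd taken from the MAD of log(φ̂/φ_tr) and floored at 0.25;
bins more than two prior sds above the trend keep their own estimate
(dispersion outliers).  IRLS converges on relative deviance change
< 10⁻⁸ or 100 iterations; EM counts are rounded to the nearest integer
before fitting.

Bins with mean normalized count below 5 (configurable) are removed
before testing; the complement sums are taken over surviving bins, so a
feature with a single surviving bin is untestable and yields no
q-value.  Per feature, the minimum bin p-value over its n tested bins
is Šidák-corrected (gene p = 1 − (1 − min p)ⁿ) and Benjamini–Hochberg
adjusted across features.  Šidák + BH is a deliberate, documented
stand-in for DEXSeq's `perGeneQValue`, whose exact empirical counting
rule is not reproduced here; agreement is qualitative, not numerical.

## Evaluation

Calls are q ≤ threshold (inclusive) at thresholds 0.01 / 0.05 / 0.1.
Feature identifiers that are not plain gene ids ("+"-joined complexes)
are excluded from the confusion counts; truly differential genes with
no q-value (filtered out or hidden in a complex) count as false
negatives, a behaviour that can be switched to the subset-style
evaluation (dropping them) with a flag.  TPR = TP/(TP+FN),
FDR = FP/(TP+FP), both 0 on empty denominators.  Stratification uses
left-closed right-open intervals: dominance breaks (0, ⅓, ⅔, 1],
isoform-count breaks (1, 2, 4, 8, ∞).

## Catalog-editing experiments

* **Isoform prefiltering** removes isoforms whose relative abundance is
  below the threshold in *both* conditions (true-abundance mode) or
  does not exceed it in *any* sample (estimated-abundance mode), then
  re-derives the bins.  Thresholds 0 / 0.05 / 0.10 / 0.15 / 0.25.
* **Annotation degradation** removes 20 % of transcripts, sampled
  without replacement separately within the swapped-pair stratum and
  the remainder (round-half-up per stratum), so the loss is
  proportionally distributed between differentially used and other
  isoforms.

## What the synthetic data does and does not emulate

The generator reproduces the structural features that drive the
benchmark's contrasts: the isoform-count/exon-length difference between
simple and complex transcriptomes, NB gene counts with a mean-dependent
dispersion, sparse isoform proportions with per-sample Dirichlet
wobble, the top-two switch with no gene-level differential expression,
uniform background fragments, and splice-aware paired-end alignments.
It does not model sequencing errors, base qualities, positional or GC
bias, alignment ambiguity, multi-chromosome genes, or correlated
expression between genes.  Passing tests therefore demonstrate the
behaviour of the counting/testing machinery under a faithful idealized
read model, not performance on real libraries, where alignment noise
and bias would add variance to every arm.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale problem sizes chosen as the
package's defaults: 120–300 genes and 1–2×10⁵ fragments per sample,
three replicates per condition, three seeds for replicated contrasts.
At these sizes the full pipeline runs in tens of seconds per arm.
Degenerate inputs are handled explicitly: empty annotations write empty
GTFs; genes losing all isoforms during editing are dropped; equivalence
classes with no compatible transcript are tallied and discarded;
features whose bins are all filtered vanish from the result table;
ties in the top-two proportions make the switch a no-op with dominance
difference 0.  Tie-breaks are deterministic everywhere (stable sorts by
identifier).

## Known limitations

* The per-gene aggregation (Šidák + BH) and the dispersion-outlier rule
  (2 prior sds) are principled stand-ins for the corresponding DEXSeq /
  DESeq2 internals, not re-implementations of their exact code paths.
* The independent filter uses a fixed mean-count threshold rather than
  a rejection-maximizing quantile search; the threshold is exposed.
* The equivalence-class EM ignores fragment-length bias within a
  transcript (uniform read model) and performs no bootstrap or bias
  correction.
* With only three replicates per condition, per-bin dispersion
  estimates are noisy; shrinkage toward the trend is what keeps the
  null calibrated, and the LRT's χ² reference is asymptotic (the
  count-scaling invariance of p-values holds only in the large-count
  limit).
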