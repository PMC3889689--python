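# Methods

`tfdirect` implements the genomic definition of a transcription factor's
*direct target genes* in a mucociliary model system: a gene is a direct
target when it (i) changes expression after knockdown of the factor and
(ii) carries a binding site of the factor near its gene body.  Around that
core, the package maps target evidence from a duplicated (allotetraploid)
frog genome into human-ortholog space and prioritizes uncharacterized
targets by their company in a weighted functional gene network.  This note
records the models, the parameters that matter, and the choices made where
the design was genuinely open.

## Annotation model and scaffold filter

The draft genome is a set of scaffolds; a gene is represented by the
genomic interval of its *longest transcript*, and the transcript's summed
exon length is the length used for expression normalization.  All
in-memory coordinates are 0-based half-open; GFF3's 1-based closed
convention is converted at the I/O boundary only, so no other module does
coordinate arithmetic for a format.

Scaffolds must be *strictly longer* than `scaffold_min_length`
(default 10,000 bases) to be retained; genes and peaks on removed
scaffolds are excluded downstream.  Strand is stored but ignored in all
distance computations; no strand rule is part of the assignment model.

## Differential expression

Counts are modelled as negative binomial with a common dispersion phi
(variance mu + phi mu^2).  Normalization is total-count: a library's size
is the total reads mapped onto gene models.  RPKM
(`1e9 * count / (transcript_length * library_size)`) is used for reporting
and replicate QC (Pearson r of log2(RPKM+1) between replicates), not for
testing.

**Dispersion** is estimated by a median-of-moments rule: after scaling all
samples to the geometric-mean library size, the within-group sample
variance s^2 (pooled across the two groups, d degrees of freedom)
estimates mu + phi mu^2 per gene.  Because the *median* of s^2 sits at
median(chi2_d)/d of the true variance (0.693 at the default 2+2 design's
d = 2), the pooled s^2 is divided by that factor before applying
max(0, (s^2 - m)/m^2); the median of the corrected per-gene estimates over
genes with mean above `mean_floor` (default 5 scaled counts) is then
approximately median-unbiased.  Simulation at phi = 0.1 with 2,000 genes
recovers phi in [0.08, 0.12]; Poisson data yield phi <= 0.01.

**Testing** conditions on the per-gene total after equalizing library
sizes to their geometric mean (rounding half-to-even, so the test is
deterministic).  Group sums of NB counts with common phi are NB with sizes
n_group/phi, so the conditional law of the split given the total is
negative hypergeometric; at phi = 0 it degenerates to
Binomial(total, n_kd/(n_kd + n_ctrl)).  The two-sided p-value is the
summed probability of all splits at most as probable as the observed one
(ties included), computed in log space.  Genes with total 0 are untestable
and report p = 1.

**Calling**: a gene is differentially expressed iff
|log2 fold-change| > log2(`fold_threshold`) *strictly* and BH-adjusted
FDR < `de_fdr` *strictly* (defaults: twofold, 5%).  The fold-change
estimator is the ratio of library-equalized group means with a 0.5
pseudocount on each mean; a boundary gene at exactly twofold or exactly
FDR 0.05 is excluded, following the strict inequalities of the calling
rule.

Library-size equalization by rescaling is approximate: scaling a shallow
library up multiplies its Poisson variance component beyond what the NB
model at the scaled mean assumes.  With the default 30/72 depth imbalance
the measured type-I error at alpha = 0.05 on 10^4 null genes is ~0.049,
and the tail (p < 1e-3) is within ~1.3x of nominal; the cost of the
approximation is negligible at this imbalance but would grow with more
extreme depth ratios.

## Peak selection and gene assignment

A peak is retained iff FDR < 5% (strict) **or** fold-enrichment > 20
(strict).  Retained peaks are assigned to every gene on the same scaffold
whose longest-transcript interval lies within `window` (default 10,000
bases, inclusive) of the peak interval; the distance is the interval gap
(0 when they overlap), not summit-to-TSS, since the assignment model is
defined on whole intervals.  Assignment is many-to-many — no nearest-gene
tie-breaking — so both "peaks assigned" and "genes bound" are meaningful
counts and both are reported.  A per-scaffold interval tree makes the
query near-linear; an all-pairs scan is kept in the test suite as the
oracle.

## Integration and enrichment

The tested universe is the set of genes tested for differential
expression: genes on retained scaffolds with an unambiguous human
ortholog.  Direct targets are DE ∩ bound within that universe; bound genes
outside the universe are dropped (with a logged count), not added.
Overlap significance is the exact hypergeometric upper tail
P(X >= k | N, K, n), summed in log space so genome-scale tails do not
underflow.  Reference-set overlap reports count, percent of targets
(integer, rounding half away from zero) and the same tail p.  Term
enrichment tests only terms with >= 1 target hit and corrects across the
tested terms (the multiplicity universe is logged); term sets are taken as
flat, pre-propagated lists.

## Ortholog collapse and network modules

Evidence transfers from either homeolog (alloallele) to the single human
ortholog by OR: a human gene is bound/differential if any of its frog
copies is, and is a direct target if some single copy is itself both.
Frog genes without an ortholog are dropped — the network namespace is
human-only.  The evidence set for subnetwork extraction defaults to
bound ∪ differential (config switch to direct targets only), and the
induced subgraph of the weighted network on those genes is what gets
clustered.

Module detection is greedy cohesiveness growth.  A module M scores

    f(M) = w_in / (w_in + w_bound + penalty * |M|)

with w_in the total internal edge weight, w_bound the weight crossing the
boundary, and `penalty` (default 2.0) modelling unobserved false-negative
links per member.  Growth starts from seeds in decreasing weighted-degree
order (lexicographic tie break), skipping seeds inside an already-retained
module, and repeatedly applies the best single add/remove until no move
increases f; ties break to the lexicographically smallest gene, making
detection deterministic.  Modules below `min_size` (3) or with weighted
density w_in/C(|M|,2) below `min_density` (0.3) are discarded; pairs with
omega overlap |A∩B|^2/(|A||B|) >= `merge_overlap` (0.8) are merged until
stable.  Modules may overlap.

On graphs whose background weights are nearly uniform, greedy growth can
run away: once the module absorbs most of a component the boundary term
vanishes and f keeps rising until the whole component is swallowed.  Such
growths are never genuine modules (their density is the background
density), so detection bounds each growth at `module_growth_cap` (default
50) nodes; a capped growth fails the density filter and is discarded.  The
cap changes runtime, not results, for any module denser than background.
`grow_module` called directly is uncapped and returns a verified local
optimum.

**Guilt by association**: for each (module, function set) pair with at
least `min_known` (default 2 — one annotated gene must not drive a
prediction) annotated members, every unannotated member becomes a
candidate with score = known-in-module / (module size − 1), the fraction
of its module partners carrying the annotation, ranked by score then
module cohesiveness.

## Synthetic data: what it emulates, what it does not

The generator produces every input with known ground truth, one RNG per
stage derived from a master seed, so identical seeds give byte-identical
files and any stage can be regenerated alone.

- **Annotation**: ~10^4 genes placed without overlap on long scaffolds;
  at least 10% of scaffolds are gene-free and shorter than 10 kb so the
  scaffold filter has work.  A `homeolog_fraction` (default 0.5) of human
  orthologs receive two frog copies (.L/.S).  The default intergenic gap
  (15.5–20 kb) exceeds window + window/2 + peak width, so a peak planted
  near one gene can never fall in a neighbour's window and binding truth
  is exactly recoverable.  Real draft genomes have no such guarantee;
  passing truth-recovery tests therefore says nothing about assignment
  ambiguity in real, gene-dense loci.
- **Counts**: NB with dispersion 0.1, baselines log-normal
  (median 100), 2 control + 2 knockdown libraries with the last knockdown
  at 30/72 relative depth (one shallow replicate).  10% of genes carry
  fold-changes of magnitude 4–8, strictly outside the twofold ambiguity
  band (a flag allows borderline effects for power studies).  Directions
  are assigned by greedy balancing so planted effects conserve expected
  total output: total-count normalization cannot correct a net
  composition shift, and an unbalanced plant would bleed a spurious fold
  into every null gene.  Real knockdowns need not be balanced — this is
  exactly the regime where total-count normalization underperforms TMM-
  style references, and the tests do not probe it.
- **Peaks**: every truly bound gene gets >= 1 peak centred within
  window/2 of its 5' end with attributes passing the selection rule (most
  via the FDR branch, ~30% only via fold-enrichment); noise peaks either
  pass attributes but sit on gene-free scaffolds or fail both branches.
- **Network**: planted modules of 6–9 genes with within-module edge
  probability 0.9 and weights 0.8–1.0, background probability 0.02 with
  weights 0.05–0.2.  Real log-likelihood-score networks are scale-free
  and weight-heterogeneous; the uniform background here is *harder* for
  the growth-cap heuristic (runaway growth) but easier for recovery.
- **Gene sets**: one reference-proteome-like set holding an exact
  fraction (default 20%) of the true targets plus background; GO-like
  terms, one enriched among targets by construction; per-module function
  sets of the planted "known" members for guilt-by-association.

## Problem sizes and determinism

Default end-to-end runs use 10,000 genes on 150 scaffolds (~6,700
orthologs, ~450k network edges) and finish in about a minute; the
statistical suites use 2,000-gene matrices over 20 seeds and 10^4-gene
null matrices, sizes at which Monte-Carlo bands (3 SE) are narrow enough
to be meaningful.  All tabular outputs are sorted by primary key before
writing, reports carry no timestamps, and the pipeline is a pure function
of (inputs, config): rerunning any stage with the same seed reproduces
files byte for byte.

## Known limitations

- The DE module handles exactly two groups with a common dispersion; no
  tagwise/trended dispersion, covariates, or multi-group designs.
- Total-count normalization is a modelling commitment, not a default to
  tune; composition-shifted designs will inflate the false-discovery
  proportion (see above).
- Peak-to-gene distance uses whole intervals only; summit-to-interval
  distance is not implemented, because the peak model carries no summit
  and the assignment rule is defined on intervals.
- Term enrichment does not propagate an ontology DAG.
- The growth cap is a heuristic guard; a genuine cohesive module larger
  than `module_growth_cap` would be truncated and likely discarded.
  Raise the cap if such modules are plausible in your network.
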