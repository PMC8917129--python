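# Methods

`beegut` analyses a two-factor honey bee cage experiment: newly emerged
workers either colonized with a conventional gut microbiota (CL) or left
microbiota-depleted (MD), crossed with five chronic pesticide feeding
treatments (Control, Insecticide, Herbicide, Fungicide, and their ternary
Mix), four cages of 30 bees per combination. Per combination 16 guts (4 per
cage) are profiled by 16S rRNA gene amplicon sequencing and qPCR; five
enzymatic markers (GST, G6PDH, LDH in head/abdomen/midgut, ALP and POx in
the midgut) are assayed on 7 pooled samples per treatment; survival and
feeder mass are logged daily over a 5-day exposure.

## Absolute quantification (qPCR)

Total bacterial load is estimated from universal 16S qPCR against plasmid
standard curves. For each gene the curve `Cq = intercept + slope *
log10(copies)` is fit by least squares; amplification efficiency is
`E = 10^(-1/slope)` (E = 2 is perfect doubling). Raw copies per µL are
recovered by the inverse relation `n = E^(intercept - Cq)`; technical
triplicates enter as their arithmetic mean (replicate spread above one
cycle warns but does not exclude — exclusion would silently discard
samples on a quality signal the analyst should see). Copies per gut are
raw copies times the elution volume (default 50 µL). 16S copies are then
normalized against the host actin gene — divide by the sample's actin
copies, multiply by the across-sample median of actin copies — which
cancels gut-size and extraction-efficiency variation (any common rescaling
of actin values leaves the result unchanged). Cells per gut are normalized
copies divided by 4, the approximate mean number of 16S loci per genome
across bee gut symbionts; the constant is exposed in configuration.

The multiplication by elution volume before actin normalization follows
the stated processing order; because the normalization is a ratio, the
order does not affect the result.

## Filtering

ASVs whose lineage contains *mitochondria*, *chloroplast* or *Eukaryota*
(case-insensitive, any rank) are removed first. Reagent contaminants are
then called from the 16 blank extractions with two signals, combined as
"either" at threshold 0.1 (strict inequality):

* **prevalence** — one-sided Fisher exact test on the 2×2 presence/absence
  table (blanks vs true samples), alternative: over-representation in
  blanks;
* **frequency** — one-sided Spearman test for *negative* correlation
  between an ASV's relative abundance and log10 total load, computed over
  the true samples in which the ASV occurs (at least 5, else the score is
  neutral 0.5). A contaminant enters at a constant absolute level, so its
  relative share must fall as input DNA rises.

This is a deliberate re-implementation of the prevalence/frequency logic,
not a port of any existing tool. One important addition: in the pipeline
the frequency score is computed **within each colonization stratum** and
the largest (least significant) within-stratum p is kept. Pooling CL and
MD samples confounds load with composition — taxa typical of the low-load
MD stratum have high relative abundance exactly where load is low and
would be falsely flagged. Requiring the load anticorrelation to hold in
every stratum removes that artifact while leaving genuine constant-level
contaminants (which anticorrelate within every stratum) detectable.

## Absolute-abundance table and community statistics

Per-sample ASV proportions from the count table are multiplied by the
sample's actin-normalized 16S copy number, giving a samples × ASVs matrix
of estimated absolute copy numbers whose rows sum to the measured loads.
ASV-level statistics use normalized 16S copies; cell numbers (copies / 4)
are used for load-level summaries.

Community structure is assessed on three dissimilarities, implemented from
their definitions: Bray-Curtis `Σ|x−y| / Σ(x+y)`; unweighted UniFrac
(branch length unique to either sample's leaf set over the length of their
union); and weighted UniFrac `Σ_b len_b |p_A(b) − p_B(b)|` over branches
with subtree relative abundances `p`, normalized by default by
`Σ_b len_b (p_A + p_B)` so values lie in [0, 1]. Trees are read from
Newick via dendropy; every table ASV must be a leaf.

PCoA applies Gower double-centering to −½D² and an eigendecomposition;
coordinates are built from positive eigenvalues and negative eigenvalues
are reported, not hidden. PERMANOVA computes the one-way pseudo-F directly
from the distance matrix through the Gower identity
(SS = Σ pairwise d²/n within groups); R² = SS_between/SS_total. ANOSIM
ranks all n(n−1)/2 distances (midranks on ties) and uses
R = (r̄_between − r̄_within)/(M/2). PERMDISP embeds samples in the full
principal-coordinate space, measures each sample's distance to its group
centroid with negative-eigenvalue axes *subtracting* (the standard
correction for non-Euclidean dissimilarities; negative squared distances
are clipped at zero with a warning), and applies a one-way F to those
distances. We verified exact agreement of this statistic with the
reference betadisper (centroid) implementation.

All three tests draw p-values from seeded label permutations. The observed
arrangement counts as one of the permutations, so the sampled p is
`(1 + #{F* ≥ F}) / (N + 1)` with N = 999 by default; an exhaustive mode
enumerates every distinct label arrangement for small designs and then
p is the exact fraction `#{F* ≥ F}/total`. Permutations are unrestricted
across samples; cage-restricted schemes are out of scope. Pesticide
effects are tested within each colonization stratum as one-way five-level
tests; the overall colonization effect uses the full 160-sample matrix.

## Per-ASV permutation ANOVA

For each ASV present in at least 25% of a stratum's samples (the
prevalence floor avoids testing all-zero groups), abundances are
randomized across samples 10,000 times (2,000 in the scaled-down test and
acceptance runs). The omnibus p is the proportion of randomized datasets
whose one-way F is ≥ the observed F — the raw ≥-proportion rule, which can
return exactly 0; a plus-one variant is available. Because a five-level
factor has no single t value, treatment-level detail comes from the
per-treatment t statistics against the Control reference level of the same
linear model, compared two-sided (`|t*| ≥ |t|`) by default with the
one-sided ≥ rule available as a faithful mode. Comparisons use a 1e-9
relative tolerance so randomizations that merely reorder values within
groups count as ties rather than falling on one side by float noise.
Per-ASV seeds are derived from the master seed and the ASV/stratum label
(CRC32), and samples are processed in a canonical sorted order, so results
are independent of column and row order. Tukey HSD over all treatment
pairs with Bonferroni adjustment across the 10 pairs provides the post hoc
table; adjustment is within-ASV, with cross-ASV multiplicity reported but
not adjusted. Significant sets from CL and MD are reported as a Venn
partition (only-CL / only-MD / shared).

## Physiology

Activities are analysed per (tissue, marker, stratum) across the five
treatments with n = 7 replicates. The route is chosen by a Shapiro-Wilk
test (α = 0.05) on the residuals after removing group means: parametric →
one-way ANOVA + Tukey HSD; otherwise Kruskal-Wallis (midranks, tie
correction) + Dunn's test with Benjamini-Hochberg adjustment. CL-vs-MD
contrasts per (tissue, marker, pesticide) use the same routing: a
pooled-variance t (via the k = 2 ANOVA identity) or the Wilcoxon rank-sum
test, whose exact p is computed by full enumeration up to a combined
n = 20 and by tie-corrected normal approximation with continuity
correction beyond.

For the integrative view, treatment means of the 11 (tissue, marker)
combinations are normalized to the colonized control column as a rate of
variation `(t − c)/c` — CL.Control maps to zero for every marker, and the
MD rows are normalized to CL.Control as well (a `ratio` mode `t/c` is
available). Rows and columns are clustered by UPGMA on Euclidean
distances: average-linkage agglomeration with deterministic lexicographic
tie-breaks; node heights are half the average inter-cluster distance at
each merge, giving an ultrametric dendrogram serialized to Newick. The
heatmap uses a green–black–red diverging scale centred at zero.

## Survival and consumption

Survival uses the product-limit (Kaplan-Meier) estimator on integer death
days with administrative censoring at the 5-day horizon; dead bees are
counted once per day, so days are treated as integer event times. Group
comparisons use the k-sample log-rank statistic `(O−E)ᵀ V⁻ (O−E)` with the
hypergeometric covariance and a chi-square reference (k−1 df), followed by
pairwise log-rank post hocs with Benjamini-Hochberg adjustment.

Consumption treats the cage as the experimental unit (bees share a
feeder). Daily per-bee intake is `max(0, feeder mass change − evaporation
control)/bees alive`, with negative corrected values clipped to zero with
a warning; cumulative per-bee intake over the exposure is compared across
treatments by Kruskal-Wallis on cage-level values.

## Synthetic experiment

The generator is the package's test bed and emulates the full design. Its
defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| guts per treatment | 16 (4 cages × 4) | 160 gut samples total |
| blanks | 16 | reagent-only extractions |
| mean MD load | 5×10⁶ cells/gut | lognormal, CV 0.5 |
| CL/MD load ratio | 3.0 | fold difference of means |
| Dirichlet concentration | 50 | individual compositional variability |
| sequencing depth | Poisson(20,000) | reads per sample (a free parameter; no depth is reported for the study, so a depth typical of MiSeq V4 runs after filtering was fixed once) |
| Cq noise | 0.15 cycles/replicate | triplicates emitted |
| enzyme CV | 0.10 | Gaussian activities |
| daily hazard | 0.02, all treatments | null survival by design |
| physiology replicates | 7 | pooled samples per treatment/tissue |

Base compositions are deterministic geometric profiles: CL is 92% core
phylotype ASVs (Lactobacillus-, Gilliamella-, Snodgrassella-,
Bifidobacterium-, Frischella-like labels), MD is 98% hive-environment
opportunists, a handful common and the rest at about 1% each. Treatment
effects multiply the *expected absolute abundance* of target ASVs, leaving
other ASVs' absolute abundances untouched (total load therefore shifts by
the small mass of the targets — which is why default targets are
low-abundance opportunists, keeping the configured load ratio essentially
intact). The default effect map plants ten-fold shifts (one a ten-fold
decrease) on five rare MD opportunists, roughly five within-group standard
deviations on the log scale at the default CVs; the enzyme effect map
raises head LDH under the Fungicide in both strata and head LDH / midgut
GST under Herbicide and Mix in MD, with a CL > MD midgut-GST baseline.

Reads are Dirichlet-multinomial for the gut community; contaminants and
host organellar ASVs enter at constant absolute levels independent of the
bacterial load (half of the contaminants "sporadically", hitting ~40% of
true-sample extractions but ~90% of blanks, so prevalence and frequency
evidence are both exercised). Blanks contain only contaminants at a tenth
of the sample depth. Cq values invert the true standard curves with
replicate noise; a shared lognormal extraction-efficiency factor scales
both genes and is cancelled by actin normalization. The tree is a random
binary merge tree with exponential height increments — only its topology
and branch lengths matter for UniFrac.

What the generator does *not* emulate: sequencing error and chimeras
(counts are drawn from the true composition, not from reads), batch
effects across extraction or PCR plates, phylogenetic signal in the
composition (the tree is independent of the abundance profiles),
overdispersed mortality, or day-structure in consumption. Passing
recovery tests therefore demonstrate that the analysis chain is correct
and calibrated under the declared noise model — not that it is robust to
artifacts the model omits.

## Numerical choices and conventions

* Permutation p-values: sampled tests include the observed arrangement
  (`(1+c)/(N+1)`); the per-ASV test follows the raw ≥-proportion rule
  (`c/N`, can be 0) to match the published procedure, with plus-one
  available.
* Exact Wilcoxon enumeration is switched off above combined n = 20
  (C(20,10) ≈ 1.8×10⁵ assignments).
* Degenerate inputs (zero variance anywhere it matters) return p = 1 with
  a `degenerate` flag instead of NaN.
* UPGMA ties break lexicographically on cluster labels, making the
  dendrogram invariant to input row order.
* Seeds: every stochastic routine takes an explicit seed; the pipeline
  derives stage and per-ASV seeds deterministically (CRC32 of the stage or
  ASV name mixed with the master seed, kept below 2³¹).
* Scaled-down problem sizes in tests and the acceptance script (2,000
  permutations, 2,000–4,000 null simulations) were chosen as the smallest
  sizes at which the calibration bands (5% ± 1%) are statistically
  meaningful.

## Known limitations

* One-way analyses only: no interaction term between colonization and
  pesticide, no mixed models, and no cage-restricted permutation schemes
  (cage is recorded and available).
* The frequency-based contaminant score assumes loads are measured without
  systematic bias; strongly load-correlated taxa in a *single-stratum*
  design would still confound it.
* PERMDISP permutes distances-to-centroid rather than recomputing
  centroids per permutation; this is the standard residual-permutation
  approximation.
* Compositional caveat: absolute estimates inherit any error in the qPCR
  load multiplicatively and whole-row-wise; dropping ASVs and
  re-normalizing changes remaining estimates.
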