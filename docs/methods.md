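# Methods

This note documents the statistical procedures implemented in `supersilac`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real data.

## Quantification model

A super-SILAC experiment spikes the same amount of a heavy-labeled protein
mixture into every sample, so each protein's heavy/light ratio measures
standard/sample. All internal arithmetic is on
x = log2(sample/standard) = −log2(H/L) (heavy standard), which makes two
conventions structural rather than incidental: between-sample comparisons
are subtractions of x, and the group difference Δ = mean(group 2) −
mean(group 1) is positive when a protein is higher in the second group.

Processing order: log2 transform → per-sample median centering →
median over technical replicates per biological replicate → minimum-valid
filter. The median (not mean) over technical replicates damps single
outlier runs; median centering equalizes overall protein load between runs
and is applied before aggregation, per sample column, because load
differences are a run-level, not replicate-level, artifact. When both raw
and search-engine-normalized ratio columns exist, the normalized ones are
preferred; both paths are supported since either may have been used
upstream.

The minimum-valid filter keeps proteins quantified in ≥ 2 biological
replicates. Its scope is deliberately configurable: "each group" is the
appropriate reading when testing without imputation (both group means must
be estimable), while "at least one group" is appropriate with imputation,
because a protein absent from one group — a candidate on/off event — is
exactly what the label-free exclusive-detection operation and the imputed
*t*-test are meant to catch. The defaults switch accordingly.

Zero label-free intensities are parsed as *missing*, never as measurements:
in search-engine output they are placeholders for non-detection, and
treating them as zeros would fabricate infinite fold changes.

## Label arithmetic

Heavy-label mass shifts are computed from the NIST monoisotopic mass table
(via pyteomics): Lys8 (six ¹³C, two ¹⁵N) shifts peptides by 8.0142 Da and
Arg10 (six ¹³C, four ¹⁵N) by 10.00827 Da. Incorporation efficiency is the
median over peptides of heavy/(heavy+light) intensity; the median keeps a
few aberrant peptides (e.g. arginine-to-proline conversion products, which
are otherwise out of scope) from dominating, and the estimate is invariant
to global intensity rescaling.

## Imputation

Missing spike-in ratios are missing-not-at-random: low-abundance proteins
drop below the identification limit preferentially. Missing cells are
therefore drawn from a Gaussian *downshifted* below the observed
distribution — mean μ − 1.5σ and SD 0.5σ, with μ and σ taken from **all
observed values of the matrix** (not per column or per protein). The 1.5/0.5
defaults are the standard Perseus-style values for this data type. Draws are
deterministic given the seed; observed cells are never touched; the imputed
mask is carried through to the output table.

The imputed matrix feeds the *t*-statistics only. The reported effect size
Δ is computed from observed values, with imputed draws standing in only
when a group has no observation at all: imputation exists to let the test
assign a finite p-value in the presence of missingness, and letting the
downshifted draws shrink or fabricate effect estimates would bias exactly
the quantity users read off the table.

## Testing and the permutation background

Per protein, a two-sided equal-variance Student *t*-test compares the two
groups of biological replicates (equal-variance, not Welch, matching the
method this pipeline re-implements; an optional s0 denominator constant is
exposed but defaults to 0). P-values are corrected by an empirical
background built from random reassignment of the group labels, pooled
across proteins (the SAM idea): a 3-vs-3 design has only C(6,3) = 20
assignments (10 up to group swap), far too few for a per-protein null, but
pooling statistics across thousands of proteins gives the null fine
resolution. All assignments are enumerated exactly whenever their count is
≤ 10,000; otherwise 250 random assignments are sampled (configurable). A
protein is flagged when the fraction of pooled null |t| values at least as
extreme as its own is below α = 0.05.

The headline differential-expression call is |Δ| ≥ 0.58 (i.e. 1.5-fold,
inclusive) **and** p < 0.05 (strict); the stricter flag additionally
requires the permutation criterion. Both the imputed and unimputed test
arms are emitted so either reading of a dataset can be inspected.

Known limitation: the per-fit "estimated FDR at threshold" diagnostic
(median permutation call count / observed call count, identity assignment
excluded) is conservative when many proteins carry real effects, because
with only six samples every permuted assignment shares two-thirds of its
labels with the truth and retains part of the signal; no π₀ correction is
attempted. Ground-truth simulations show the realized FDR of the calls is
well below this diagnostic.

## Enrichment

Annotation terms are scored on the per-protein Δ values by a two-sample
Mann–Whitney U of members vs non-members, reported as the rank-biserial
score 2U/(n_in·n_out) − 1 — a bounded effect size, 0 in expectation under
exchangeability, positive when the term's proteins rank high (up in
group 2). Exact p-values are used for small tie-free instances
(n_in·n_out ≤ 400), the tie-corrected normal approximation otherwise;
Benjamini–Hochberg correction is applied across the tested terms. The
in-term median of Δ is reported alongside, matching how such results are
usually quoted ("median log2 ≈ 0.6"). Terms need ≥ 10 members with values
by default; the background is all scored proteins, and restricting the
input series to a significant subset switches the analysis to that
background. Compartment fractions divide by the number of DE proteins
carrying *any* compartment annotation; multi-localized proteins count once
per compartment, so fractions can sum to more than 1.

## Replicate QC

Pairwise-complete Pearson correlations between normalized ratio columns
(pairs sharing < 200 proteins by default are masked as unreliable rather
than reported), average-linkage hierarchical clustering on d = 1 − r
(heights in [0, 2]; labels sorted lexicographically first so ties resolve
deterministically), and a co-clustering score: the fraction of replicate
groups whose members form a complete subtree of the dendrogram before any
merge with an outside sample. 1.0 reproduces the tight replicate blocks
expected of a reproducible experiment; shuffled labels score near 0.
d = 1 − r (not 1 − |r|) is used because anti-correlated replicates are a
failure, not a similarity. The linkage method is configurable; average
linkage is the default for correlation heat maps of this kind.

## Synthetic data: what it emulates and what it does not

The generator mirrors the study design: two groups × 3 biological
replicates × 2 technical replicates of log2 ratios centered on zero
(baseline SD 1.0), a 10% fraction of true effects of ±1.0 log2 units
(direction split 50/50 by default; a `fraction_down` knob set to 0.64
mimics the down-regulation excess the motivating dataset showed), shared
per-biological-replicate noise (SD 0.3) plus per-run technical noise
(SD 0.15), logistic intensity-dependent dropout
P(missing) = expit(slope·(value − location)) with slope −1.0 and location
−2.0 (≈ 8–15% of cells, concentrated in low-abundance proteins), optional
annotation terms with a planted mean shift, and heavy-label incorporation
0.95 applied to the standard channel when back-transforming to H/L ratios.
Output is serialized through the same protein-groups dialect the real data
arrives in, so the production readers are exercised end to end.

Not emulated: peptide-level structure, retention-time or batch effects,
correlated protein modules, heteroscedastic per-protein variances, and
ratio compression beyond the incorporation term. Passing recovery tests on
this generator therefore demonstrates correctness of the statistical
machinery under its stated model, not performance on arbitrary real
matrices — in particular, real missingness mechanisms are harsher, and the
downshift imputation is known to cost power on proteins with several
missing cells (visible in the generator too: sensitivity drops from ≈ 0.85
with complete data to ≈ 0.70 at the generator's full default
noise-and-dropout settings).

## Problem sizes and numerical conventions

The test-suite and the reproduction script run on generated data sized for
a laptop-class single core: 300-protein × 20-seed null batteries for
type-I calibration, 2000-protein × 3-seed batteries for effect recovery
(metrics averaged across seeds to damp binomial noise), 5000 × 6 matrices
for imputation moments, and 50-protein instances for the exact
permutation-oracle comparison. All randomness flows through
`numpy.random.default_rng` seeds; a single pipeline seed is expanded into
per-stage seeds via `SeedSequence`, so every table is bit-reproducible.
Degenerate inputs fail loudly rather than silently: zero pooled variance,
zero matrix SD, empty columns, all-zero peptide pairs, singleton replicate
partitions and incomplete correlation matrices all raise errors naming the
problem.
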