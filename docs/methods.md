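# Methods

`exomir` reimplements the statistical workflow of a small-cohort exosomal
miRNA study: 312 miRNAs assayed by a multiplexed bead array in prefrontal
cortex (Brodmann area 9) from three clinical groups — 6 controls (C), 6
bipolar disorder (BD) and 8 schizophrenia (SZ) cases.  The raw expression
matrix and qPCR traces of that cohort were never deposited, so the package
pairs each analysis stage with a synthetic-cohort generator and with
transcriptions of the cohort's printed summary tables, which are internally
checkable by exact arithmetic.

## Moderated multi-group scores

For miRNA *i* with samples in K groups of sizes n_k (N = Σ n_k):

    s_i  = sqrt( SSW_i / (N − K) / N )
    z_ik = (x̄_ik − x̄_i) / (s_i + s0)
    D_i  = max_k |z_ik|

where SSW_i is the within-group sum of squares, x̄_ik the group mean and
x̄_i the grand mean.  Because group deviations are taken around the grand
mean, Σ_k n_k z_ik = 0 identically — the package checks this identity both
on everything it computes (≤ 1e−6·N) and on the transcribed 198-row score
table (≤ 0.05, the printed 5–6 significant digits).  The published table
does not state its scale formula; this pooled-standard-error form was
chosen because it preserves the weighted-sum identity visible in the
printed rows and keeps scores on the printed scale.  The ranking scalar
D_i = max_k |z_ik| is likewise an inference from the printed row order
(the top row's largest |z| is 3.55).

The exchangeability constant s0 guards against weakly expressed miRNAs
being promoted by tiny standard errors.  It is selected from the
percentiles (0, 5, …, 100) of {s_i} by minimizing the coefficient of
variation of the per-bin median absolute score across s_i-quantile bins —
the classic criterion making the score scale independent of s_i.

## Permutation q-values and local FDR

The null preserves group sizes: B label permutations (default 1000;
exhaustive enumeration when ≤ 500 distinct labelings exist), recomputing
all of x̄_ik, s_i and D_i per permutation with s0 held at its
observed-data value.  For the feature of rank r with threshold t = D_(r):

    q(r) = 100 · median_b( #{ null scores of permutation b ≥ t } ) / r

forced non-decreasing along the ranking (running maximum) and clipped to
[0, 100].  Local FDR evaluates each feature with its neighbors: for the
window of ranks around r (default 50, clipped at the ends), it is 100 ×
(mean permutation count inside the window's score interval) / (observed
count), clipped to [0, 100].

A calibration caveat, measured and documented rather than hidden: with the
median-count definition, a pure-null panel still awards q = 0% to its
top-ranked feature in roughly a third of datasets — q(1) = 0 exactly when
the observed maximum beats the whole null in more than half the
permutations, an event of appreciable probability under exchangeability of
the observed labeling.  The mean-count (expected-false-count) variant
suppresses these calls entirely but also destroys the power to assign
q = 0% to genuinely spiked features, because a single wild null score in
any permutation then blocks the call.  The median form is kept: it is what
gives a usable zero-q candidate list at n = 20, and its false zero-q calls
are limited to one to three borderline features.  Two-sided permutation
p-values use add-one smoothing, p = (1 + #{|null| ≥ |z|})/(B + 1); the
printed p-values of the source tables match no standard distribution and
are not emulated.

Holm's step-down correction follows the printed formula: sort p ascending
and reject while p_(r) ≤ α/(m_total − r + 1), stopping at the first
failure (α = 0.05, m_total = 312 gives the rank-1 threshold 1.603e−4).
The Wilcoxon rank-sum supplement uses exact mid-rank enumeration of all
C(n1+n2, n1) assignments for the cohort's group sizes.

## Clustering and nearest shrunken centroids

Samples are agglomerated greedily on the distance 2·(1 − cc), where cc is
the Pearson correlation between cube-rooted average cluster profiles,
clamped below at 0 so the dendrogram lives on the stated 0–2 scale (raw
correlation can be negative, which would exceed 2).  Linkage is
average-profile (centroid-correlation), ties break on the
lexicographically smallest member pair, and merge heights take a running
maximum because centroid-style linkage can invert.  Note that correlation
distance is insensitive to pure level shifts: a signature in which every
spiked miRNA moves the same direction in one group separates that group
only marginally, whereas a mixed signature (subsets up in different
groups, as in the study's zero-q list) separates it reliably.

Classification uses nearest shrunken centroids: standardized differences
d_ik = (x̄_ik − x̄_i)/(m_k (s_i + s0)) with m_k = sqrt(1/n_k − 1/N),
soft-thresholded by Δ, with s0 the median of the pooled within-class
scales and uniform class priors (the 6/6/8 groups are near-equal;
configurable).  Cross-validation is leave-one-out, the natural choice at
N = 20.  At full shrinkage the classifier degenerates to the
prior-majority rule, so the misclassification curve ends exactly at the
majority-class error (0.6 here).  Under permuted labels the curve start
(Δ = 0) averages ≈ 0.76 — leave-one-out nearest centroids on noise are
slightly worse than chance because the held-out sample drags its own
class centroid away — while the curve average over a Δ grid spanning no
shrinkage to full shrinkage is ≈ 0.70.

## Medication-covariate adjustment

Seven drug classes (A–G) flag which case subjects took at least one
medication of the class; controls take none.  A class is evaluable only
with ≥ 3 takers and ≥ 3 non-takers, counted within the diagnostic groups
that actually contain takers of that class: a class used in one diagnosis
only (e.g. mood stabilizers, class D, in BD) cannot borrow non-takers from
the other diagnosis — with cohort-wide counting class D (4 takers, 10
non-taker cases) would pass the 3-and-3 rule, contradicting the study's
A/B/C-only outcome, while group-scoped counting (4 vs 2 within BD)
reproduces it.

The effect of an eligible class is the taker-group standardized score of
the two-group taker vs non-taker contrast (same s0 convention), and the
adjusted score is z_adj = z − Σ effects of the classes adjusted for; blank
effects contribute zero.  The subtraction is exact arithmetic, verified
cell-by-cell against the printed effect/adjusted tables at 1e−4.  On
synthetic confounds the subtraction removes a medication effect well when
takers concentrate in one diagnostic group (the effect and the confound's
contribution to that group's z-score then share the same numerator; mean
|z_adj| of affected miRNAs drops to ≈ 0.4 of unadjusted).  When takers
split across both disease groups the grand mean absorbs much of the shift
and the full-strength taker contrast over-corrects — a structural limit of
score subtraction, not an implementation artifact.

## qPCR delta-CT validation

Within every plate, replicate CTs are averaged per (sample, target) and
the reference miRNA's (miR-423) average CT on the same plate is
subtracted; per-plate ΔCTs are averaged unweighted across plates (plates
lacking the reference are dropped with a warning).  Group contrasts use
the classical equal-variance two-sample t-test (Welch available by flag)
on sample ΔCTs, and the fold change is the standard relation
2^(−ΔΔCT) with ΔΔCT = case − control, so one cycle earlier in cases is a
two-fold increase and ΔΔCT = −1.47 is the 2.77-fold benchmark.  No
amplification-efficiency correction is applied.  Per-plate CT offsets
cancel exactly in ΔCT, which the tests exercise with random offsets.

## Synthetic cohort generator

Log2-scale signal per miRNA: a log-normal baseline (log2 abundance
~ N(6, 2), spanning the ~4 decades a bead array covers), additive group
effects for spiked subsets, additive medication effects in takers, and
within-group Gaussian noise of SD 0.5 log2 units (a typical biological +
technical spread for bead arrays).  Raw readings are 2^signal minus a
background constant (30 raw units), so weak miRNAs emerge negative exactly
as the instrument reports below-background values; the preprocessing floor
maps them to 0.  Defaults mirror the study design: 312 miRNAs, groups
C:6/BD:6/SZ:8, spiked subsets of 14 (up in SZ) and 7 (up in BD) echoing
the 21 and 7 zero-q calls, effect 2.0 log2 units, and the published
per-case medication flags as the default covariate assignment.  A single
seed drives everything; metadata and qPCR wells use fixed offsets (+1, +2)
from it, making outputs byte-identical under a fixed seed.

The generator emulates the statistical structure the analysis assumes —
group shifts, heteroscedastic abundance, below-background censoring,
taker-linked confounds, plate offsets — and not the instrument physics:
no bead-count variation, probe cross-hybridization, or amplification bias.
Passing tests therefore demonstrate that the pipeline recovers the
structure it models, not that the model captures everything in real
bead-array data.

## Problem sizes and numerics

Tests and the acceptance script use the study-scale design throughout
(312 × 20, B = 1000 permutations, leave-one-out CV, 50-seed qPCR
batches) — each SAM fit is vectorized across permutations and runs in
well under a second.  Degenerate inputs are defined, not fatal: features
constant everywhere score 0 (0/0 → 0), zero-variance profiles correlate
as 0 (distance 2, warned), all-zero samples raise a named normalization
error, and q-values/local FDR are clipped to [0, 100].  Ties break
deterministically everywhere: descending statistic then lexicographic id
in rankings, smallest member pair in merges, larger prior then larger
class then label order in classification.

## Known limitations

* The 312 → 198 informative-miRNA reduction rule of the source study is
  unknown ("a linear regression model"); the filter here (expressed in ≥ 3
  samples, nonzero variance) is an explicit, parameterized stand-in.
* The bead-array intra-normalization protocol is not public;
  median-of-positives column scaling is used, switchable off, with a fixed
  target available for exact scale invariance.
* Printed p-values in the source's adjusted-score tables match neither a
  normal nor a small-df t distribution; permutation p-values are provided
  instead and no attempt is made to reproduce those columns.
* The BD adjusted-score transcription interleaves columns inconsistently
  in its lower rows and is packaged for inspection only.
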