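# Methods

## Model and procedure

A protein complex is modelled as the ego network of a hub: the hub protein
plus its direct interaction partners in an undirected protein–protein
interaction network.  A node qualifies as a hub when it has at least
`min_degree` partners (default 5; pass 6 for a strict "more than five"
reading).  The same protein may appear as an interactor in many complexes;
interactors are sorted lexicographically so all downstream averages are
order-independent.

For complex *C* = (H, I₁…Iₙ) and tissue *t* with *nₜ* replicate samples,
coordination is the mean hub–interactor Pearson correlation

    ρ̄(C, t) = (1/n_used) Σᵢ r(e_H, e_Iᵢ)   over tissue-t samples,

where pairs with an undefined correlation (a constant profile) are dropped
from the mean and `n_used` records how many contributed.  A hub missing
from the expression matrix voids the whole row: the hub profile anchors
every term, so no partial substitute is meaningful.  Correlations require
at least 3 samples.

Replicate counts vary strongly between tissues, which biases raw
correlations: with few samples, |r| is noisy and extreme values are easy to
hit.  The averaged score is therefore Fisher-transformed, z = atanh(ρ̄),
whose sampling standard error for a correlation estimated from nₜ samples
is approximately 1/√(nₜ − 3), and standardized.  Two standardizations are
implemented because the exact published form is ambiguous:

- **analytic** (default): z(C,t) = atanh(ρ̄) · √(nₜ − 3).  This directly
  divides by the Fisher standard error and is the reading most consistent
  with correcting for unequal sample counts; it requires nₜ ≥ 4.
- **empirical**: per-tissue column z-score over complexes (sample sd,
  ddof = 1), which instead normalizes each tissue's score distribution.

With equal nₜ everywhere, analytic standardization is a strictly
increasing transform of ρ̄ and cannot change within-complex tissue order;
with unequal nₜ, raw and standardized rankings legitimately differ (the
test suite carries a constructed counterexample).  The Fisher transform is
applied to the averaged ρ̄ by default; `fisher_before_average` averages
atanh-transformed pair correlations instead.  |r| is clamped at 1 − 10⁻⁶
before atanh so perfect correlations stay finite.

Tissues are ranked per complex by decreasing score; missing scores sort
last and ties break lexicographically by tissue label, so rankings are
deterministic and diffable.

## Benchmarking

Tissue-level rankings are collapsed to coarse categories (e.g. "heart"
covering atrial myocardium and cardiac ventricle) with a user-supplied
tissue → category map; a category scores the maximum over its member
tissues, since a category is hit as soon as any member is.  Against a gold
standard of (gene, disease) → positive categories, every
(association, category) pair contributes a binary label and the score
−rank; pooling all pairs and sweeping the rank threshold gives the ROC
curve, and its trapezoidal area with midpoint tie handling equals the
Mann–Whitney statistic.  All listed gold categories count as positive for
ROC labels; the gold list's internal order matters only for top-k overlap
(default k = 3).  Per-category and per-complex AUCs restrict the same
construction.  The pooled curve weights associations with many gold
categories proportionally; a macro average over categories can be formed
from the per-category table.

The single-protein baseline ranks tissues by the Welch (unequal-variance)
two-sample t statistic of the gene's expression in one tissue against all
other tissues pooled — Welch because the tissue-vs-rest group sizes are
severely unbalanced.  When both groups are constant the statistic is
undefined and the tissue ranks last; constant groups with unequal means
give ±∞ with the sign deciding the direction.

The randomization null permutes, independently within each tissue, which
gene owns which expression row (preserving sample-level structure,
destroying gene identity), then recomputes the full coordination matrix,
rankings and pooled AUC.  One master seed spawns per-replicate child
seeds via `numpy.random.SeedSequence`, so runs are reproducible and
replicates independent.  Default 100 replicates; analyses here use 25,
which bounds the Monte Carlo standard error of the null mean near 0.02
while keeping runs fast.

## Tissue distance trees

Each tissue is summarized by the arithmetic mean of its samples'
genome-wide profiles (median available); the distance between tissues is
1 − PCC of these profiles, in [0, 2].  Trees are built with classic
neighbor joining (Q-criterion, standard branch-length and reduction
formulas).  Ties in Q break on the lexicographically smallest pair of
canonical labels (the smallest leaf label under each node), making the
topology deterministic.  Negative branch lengths are reported as computed
with a warning — they are information about non-additivity — with an
option to clamp at zero for display.  On exactly additive distances NJ
recovers the generating topology and path lengths to numerical precision.
Newick serialization follows scikit-bio's dialect (spaces as underscores,
literal underscores quoted); reading inverts it, so labels round-trip.

## Synthetic data

The generator emulates the statistical structure the method assumes, not
microarray physics.  It plants, per hub, a shared latent factor in one
tissue: hub and interactor values there are β·f_j + ε with f_j ~ N(0,1)
per sample and ε ~ N(0, noise_sd²), giving population correlation
β²/(β² + noise_sd²); everywhere else values are independent
N(0, baseline_sd²).  Crucially all tissue means are zero, so a mean-based
single-protein test is blind to the planting by construction — this is
what lets the complex-ranking > single-protein > random ordering be a
designed property of the fixture rather than an accident.  Defaults:
8 hubs × 6 interactors among 120 genes, 60 random background edges,
6 tissues with 12–17 samples (unequal on purpose, to exercise the
sample-size correction), β = 3, noise_sd = baseline_sd = 1 (planted
correlation 0.9).  These sizes keep a full benchmark with null replicates
in seconds while leaving the planted signal strong but not degenerate.

What passing tests on this fixture do **not** show: robustness to
non-Gaussian noise, probe effects, batch structure, correlated background
genes, or gold standards with wrong/partial labels.  Real compendia also
require a curated tissue exclusion list and category map, which are
user-supplied inputs here.

## Numerical choices and limitations

- Correlation denominators of exactly zero yield a missing value, never 0:
  constant expression carries no co-expression evidence.
- Minimum 3 samples per correlation; analytic standardization needs ≥ 4
  (the Fisher variance 1/(n−3) is undefined otherwise).
- Expression values are consumed as provided; normalization and
  probe-to-gene collapsing are out of scope.
- Identifiers are opaque strings; no ID mapping is attempted.
- ROC requires at least one positive and one negative pair after pooling;
  degenerate per-category or per-complex label sets raise instead of
  returning a vacuous AUC.
- Confidence-weighted edges, clustering-based complex detection, partial
  correlations and bootstrap support values are deliberately out of scope.
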