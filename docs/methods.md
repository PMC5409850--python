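# Methods

## The problem

A probabilistic surface atlas summarizes, for each vertex of a common
triangulated cortical template, the fraction of subjects whose region of
interest (ROI) covers that vertex after cortex-based alignment.  Two
questions drive the package:

1. **Predictability.** How well does the group map predict an unseen
   subject's ROI, and how does the choice of alignment template — which
   changes residual inter-subject misalignment — affect that?
2. **Correspondence.** How strongly does the atlas line up with a second,
   independently derived parcellation of the same cortex, relative to chance?

Real postmortem or in-vivo label data are not required: a synthetic cohort
generator reproduces the statistical structure the analysis assumes, so the
full pipeline is testable end to end.

## Predictability: LOOCV dice with a threshold sweep

For each ROI, each subject is left out once; the group probabilistic map is
built from the remaining n subjects (per-vertex counts / n) and thresholded
at every level of the grid {0, 1/n, …, 1}.  Agreement between the
thresholded group set G and the held-out ROI I is the dice coefficient

    dc = 2 |I ∩ G| / (|I| + |G|),

0 for disjoint sets, 1 for identity, undefined (an error, never a silent 0)
when both are empty.  Per threshold we report the mean and the standard
error across folds (sample SD with n−1 denominator over sqrt(folds); the
denominator convention is stated here because field usage varies).

Numerical choices:

- **Inclusive thresholding.** G(t) = {v : counts[v]/n ≥ t}.  This is forced
  by the usual field gloss that, with n = 8, t = .375 keeps vertices shared
  by *three or more* subjects.  A guard of 1e−12 absorbs float rounding so
  j/n compares inclusively at level j.
- **t = 0 means the support** (counts ≥ 1), not the whole mesh; otherwise
  the unthresholded map would degenerate to the template sphere.  Published
  descriptions do not pin this down; support is the only reading under which
  the unthresholded dice is informative.
- **Threshold for condition contrasts** defaults to .375.  Reports in this
  literature are inconsistent about the exact evaluation threshold (a figure
  caption citing "no threshold and .33" against body text citing ".375" with
  n = 8, where .33 is not even on the 1/8 grid); we surface rather than
  resolve this and evaluate at the grid level nearest the requested value,
  recording the level actually used.
- **Subjects missing an ROI** are first-class absences: they are excluded
  from that ROI's folds, group maps and chance pools, and the per-cell
  subject count is recorded.
- Dice is unweighted vertex counting by default; a per-vertex-area weighted
  mode exists (`vertex_weights=`) but is an extension, off by default.

The condition contrast uses a **paired sign-flip permutation test** on the
per-fold dice differences: folds are the exchangeable units paired across
conditions; each of 10,000 permutations flips each pair's sign independently
with probability 1/2 (sampling sign assignments with replacement) and the
two-sided p gets add-one smoothing, (1 + #{|T*| ≥ |T|}) / (1 + n_perm), so
p is never 0.  An exact enumeration mode over all 2^n sign patterns exists
for n ≤ 20 pairs.  The verbal protocol this implements ("permutation testing
with replacement, alignments randomly shuffled") is ambiguous; paired
sign-flipping of fold differences is the closest standard procedure, chosen
because folds are what the two conditions share.  Per-ROI testing with
Bonferroni over the ROI count is the default; a pooled test is a caller-side
one-liner on the concatenated fold differences.

## Maximum probability map

Each vertex with any support is assigned to the ROI whose probabilistic map
value is highest, subject to an optional `min_prob` floor (default 0: every
supported vertex is assigned; the rest carry an explicit background code).
Ties break to the lowest ROI id in the canonical (sorted) ROI ordering, so
the assignment is invariant to input order.  No smoothing or gap-filling is
applied.

## Correspondence with a second parcellation

For a group-level region m of the other parcellation and each ROI c, the
**directional overlap proportion** |m ∩ c| / |m| is computed against each
individual brain's c and averaged over the brains possessing it (SE across
brains).  Chance for region m is the distribution of its overlap with a
uniformly drawn (brain, ROI) label from the same hemisphere's full pool,
resampled with replacement (default 1000 draws): the chance level is the
null mean, the 95% CI the 2.5/97.5 percentiles of the draws, and the
one-sided exceedance p is (1 + #{null ≥ observed}) / (1 + n_iter),
Bonferroni-corrected over the ROI count.  The "average" chance overlap is
read as the mean of single-draw overlaps, not means of batches — the draw
distribution is the null.

A known consequence in one-to-one synthetic designs: the pool contains each
region's own source ROI, so roughly (match rate)/2 of the draws tie or beat
the observed mean and the exceedance p is bounded below near 1/(2·K) for K
pooled ROIs.  With K = 8 that bound is ≈ .06 before correction, so diagonal
cells in a clean one-to-one design are *not* flagged significant — the
machinery is conservative by construction there, and the reports state the
per-cell chance level so this is visible.  Hemispheres are processed
independently throughout (separate pools, separate rows); a hemisphere main
effect can be tested afterwards with the built-in Friedman test over the
(region × ROI) overlap table, which — unlike the scipy implementation —
accepts k = 2 treatments and applies the standard midrank tie correction.

## Synthetic cohorts

ROI templates are geodesic patches (spherical caps) on a unit icosphere:
subdivision s gives 10·4^s + 2 vertices.  A subject's ROI is the template
with its center displaced by a tangent-plane Gaussian (renormalized to the
sphere; a small-angle stand-in for exact von Mises–Fisher sampling, chosen
for transparency) and its radius perturbed by a Gaussian truncated to
(0, π) by bounded resampling.  Conditions share everything except the center
jitter SD — this encodes "template choice changes alignment precision"
without modeling registration.

Defaults (per-parameter rationale):

| parameter | default | why |
|---|---|---|
| subdivision | 4 (2,562 vertices) | orders of magnitude below a real average-surface mesh but past the resolution where every statistical property of the pipeline has converged; desk-scale runtime |
| subjects | 9 | the canonical complete-design size for this kind of postmortem atlas |
| ROIs | 8, radii 0.30 → 0.15 rad | mixes large early-visual-like and small higher-order-like patches |
| center jitter | 0.05 / 0.10 rad | no published inter-subject variability exists for such ROIs; these values produce rise-then-fall dice-vs-threshold curves of realistic magnitude (~0.6–0.85 at the evaluation threshold) and a clearly resolvable condition difference |
| radius jitter | 0.02 rad | mild size variability, secondary to position |

Randomness is split per (subject, ROI, condition) from the root seed by a
counter-based scheme (SeedSequence spawn keys from CRC32 of the ids), so
adding a subject or reordering ROIs never changes anyone else's labels, and
every artifact is a pure function of the config.

The derived second parcellation displaces each template center by a fixed
angle along a deterministic tangent direction and optionally splits the
first `round(split_fraction · K)` regions along the great circle through the
displaced center perpendicular to the displacement — so ground-truth overlap
is available in closed form: the intersection of two caps of radii α, β at
separation γ has area (Gauss–Bonnet over the lens)

    A = 2π − 2·φ_a·cos α − 2·φ_b·cos β − 2·C,

with φ_a = arccos[(cos β − cos α cos γ)/(sin α sin γ)], φ_b symmetric, and C
the spherical-triangle angle at a crossing point.  Tests verify this against
numeric quadrature and use it as the oracle for displaced-region overlaps.

**What the generator does not emulate:** cortical folding and curvature-
driven registration error structure (jitter is isotropic; real misalignment
is anisotropic along sulci), spatially correlated boundary noise, ROI shape
irregularity, and volume-to-surface projection artifacts.  Passing tests
therefore certify the *evaluation machinery* — not that any particular real
atlas is precise.

## Degenerate inputs and tie-breaks

- dice of two empty sets: error.  Empty thresholded G against non-empty I: 0.
- A probabilistic map must have non-empty support; counts outside
  [0, n] are rejected at construction.
- MPM ties: lowest ROI id wins (documented canonical ordering).
- Monte-Carlo p-values: add-one smoothing everywhere; exceedance
  comparisons use a 1e−12 tie guard so equality counts as exceedance.
- Friedman with every block fully tied: statistic 0, p 1 (the tie-correction
  factor would otherwise divide by zero).

## Problem sizes used in tests and reports

The default suite runs on subdivision-3/4 icospheres with 3–10 subjects and
1–8 ROIs; resampling calibrations use 500 simulations at 2,000 permutations.
The acceptance report uses the full reference design (subdivision 4, 9
subjects, 8 ROIs, 10,000 permutations, 1,000 chance draws) — all sizes are
the package's own desk-scale choices, stated here so results are read at the
right scale.

## Known limitations

- The permutation reading of the condition contrast is one defensible
  interpretation of an ambiguous verbal protocol (see above).
- Chance exceedance is conservative whenever the tested region's best match
  dominates the pool (bounded p; see correspondence section).
- Label values (probabilities) round-trip through text at 10 significant
  digits; vertex indices and connectivity round-trip exactly.
- Only FreeSurfer ASCII labels and OFF / FreeSurfer ASCII surfaces are
  supported; binary surface formats and annot files are out of scope.
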