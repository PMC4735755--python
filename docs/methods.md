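# Methods

`facespace` asks a representational question with a linear model: when a
face space is organized to discriminate one facial property, how well
does it already support the *other* properties?  The package implements
the full computational protocol — synthetic face-image generation,
Eigenface/Fisherface subspace construction, cross-property
relabel-and-test evaluation with a delayed-match-to-sample (DMS) score,
and within/between-class distance statistics — as a reproducible,
seeded pipeline.

## The model

Images (90 × 90 grayscale, intensities in [0, 1]) are vectorized
row-major, centered on the global mean face, and reduced by PCA to
`k` components (the "Eigenfaces"; default `k = 10`, swept over a grid in
the protocol).  In PCA coordinates, a multi-class Linear Fisher
Discriminant is fitted for a chosen labeling (identity, sex, race or
expression): with between-class scatter `S_B` (class means weighted by
class size) and pooled within-class scatter `S_W`, the discriminant
directions solve the symmetric-definite generalized eigenproblem

    S_B v = λ S_W v,

keeping at most `C − 1` directions for `C` classes.  Directions retain
the generalized-eigenvector normalization `vᵀ S_W v = 1`.  This choice
is deliberate and load-bearing: the projection then *whitens*
within-class scatter, so Euclidean distance in the projected space
measures separation in units of within-class variability.  A subspace
trained on identity therefore compresses exactly the directions along
which images of one person vary — which is where expression lives — and
amplifies the directions that distinguish people, which is where sex
and race live.  That asymmetry, not the choice of axes per se, is what
produces the invariant/variant transfer dissociation.  (A
Euclidean-orthonormal variant of the same directions was evaluated and
rejected: whenever `C − 1 ≥ k` — always true for identity training —
the orthonormalized map is an isometry of PCA space, every trained
space induces the same distances, and all transfer effects vanish.)

Because discriminant counts differ across labelings (1 for sex, 5 for
six expressions, up to `k` for identity), performance comparisons pad
every model of a comparison group to the group's maximum dimension with
random directions drawn orthonormal *in the `S_W` metric* (the stacked
map `W` satisfies `W S_W Wᵀ = I`).  Padded axes thus carry within-class
scale ≈ 1, commensurate with the discriminant axes; with
Euclidean-orthonormal random padding the padded axes would inherit raw
data variance and drown the discriminants.  Distance summaries, KS
statistics and the component scatter figures are computed in each
condition's own *unpadded* discriminant space: they characterize that
space's geometry ("the first components"), whereas padding exists only
to make percent-correct scores comparable across class counts.

`S_W` is ridge-regularized (`1e-8 · tr(S_W)/k` on the diagonal) because
pooled scatter is singular whenever samples-per-class are few.
Eigenvector signs are fixed (largest-magnitude entry positive) so runs
are bit-reproducible across platforms.

## Transfer evaluation

For a train:test condition (e.g. ID:SE), samples are projected into the
subspace trained on the first property, the evaluation labels are
replaced by the second property's labels (coordinates untouched), and
classification is scored with a two-alternative DMS rule: for every
pair of references from different classes and every distinct probe from
one of the two classes, the trial is correct iff the probe lies
strictly nearer (Euclidean) to its own class's reference.  Exact ties
count as incorrect (measure-zero for continuous data; deterministic and
conservative).  All valid (pair, probe) triples are enumerated
exhaustively when their number is at most `max_trials` (default
100 000); otherwise triples are sampled uniformly with a seeded
generator, stratified exactly by their enumeration weights.  Chance
level is 50 %.

Evaluation classes with fewer than two samples cannot supply a
(probe, same-class reference) pair and are excluded with a logged
warning; this happens routinely when an expression-trained condition is
relabeled to identity.

## Distance statistics

For each projected sample, the mean Euclidean distance to all same-class
samples ("within") and to all different-class samples ("between") is
computed; samples in singleton classes contribute to "between" only.
The two per-sample-average distributions are compared with a one-sided
two-sample Kolmogorov–Smirnov test of the alternative "between
stochastically larger than within",
`D = max_x [ECDF_within(x) − ECDF_between(x)]`, with the standard
one-sided asymptotic p-value (`exp(−2 n_eff D²)` with Hodges'
finite-sample correction), as provided by `scipy.stats.ks_2samp`.
Percent-correct samples are compared across conditions with pooled
(Student) two-sample t-tests, `df = n₁ + n₂ − 2`, matching the df
convention of the printed statistics this protocol family reports.
Note that the KS test on per-sample *averages* is extremely sensitive:
averages over ~100 samples concentrate, so even a 1 % systematic
within/between difference is detectable.  Cross-condition KS results
should be read with that in mind.

## The synthetic collections

The original stimuli (a 3-D-reconstruction database balanced over sex
and race with five viewpoints, and a frontal photograph collection of
six expressions) are private; the generator emulates their *statistical*
structure, not their appearance.  Each image is a linear rendering of a
26-dimensional latent code through a fixed, seeded basis of
orthonormalized 2-D Gaussian-bump components (smooth, full column
rank), plus i.i.d. pixel noise (sd 0.02), clipped to [0, 1] and
quantized to 8-bit levels so disk round-trips are lossless.

Latent layout: 16 morphology dims (14 free identity dims, i.i.d.
standard normal per identity, with geometrically decaying render gains
so a few directions dominate, as in real face sets; 1 sex dim and 1
race dim holding ±2.0 offsets — two within-cell standard deviations),
8 expression dims, 2 viewpoint dims.

**Invariant collection** (default 120 identities balanced over
sex × race, viewpoints −10…30°): one image per identity per viewpoint.
A viewpoint change shifts the 2 viewpoint dims deterministically and,
crucially, perturbs the *whole morphology block* along a face-specific
pose axis (a deterministic draw keyed on the renderer seed and the
face's own morphology), scaled by angle/30 — by 4.0 on the free dims
and 3.0 on the sex/race dims.  This emulates how rotating a 3-D head
changes every shape cue, including how male/female or Asian/Caucasian
a face looks.  These two scales control the whole invariant-side
phenomenology: within-identity variance on the offset dims moderates
the SE:SE/RA:RA baselines (otherwise they saturate at 100 % and no
cross condition can match them), while the free-dim scale sets how
strongly identity structure competes with the sex/race structure inside
an identity-trained space.  The defaults were calibrated once, jointly
against the qualitative transfer pattern, on the *mean* over several
base seeds, and then frozen.

**Expression collection** (default 50 identities, half female, one
race, frontal): one image per identity per expression.  Expressions are
prototype deformations in the expression block (six fixed unit
directions scaled to norm 3.0, flat spectrum) plus isotropic per-image
jitter with per-dim sd 0.25 × the prototype norm — large enough that
expression discrimination is clearly harder than the invariant tasks.
A small fraction (0.15) of each expression dim also renders through the
free-morphology surface components (mouth and eye regions carry
identity too); the mixing map is global, so at coupling `kappa = 0` the
expression component carries no identity, sex or race information (a
permutation test on generated latents verifies this).  The flat
expression spectrum keeps a clean eigengap between expression and
identity variances, which stops finite-sample PCA from rotating
identity variance into the expression discriminants.  The collection's
identity render gain is 1.25× the invariant collection's (photographs
that include outer features carry more identity-specific variance than
normalized 3-D renders).

**Identity–expression coupling.** With `kappa > 0`, the deformation for
identity *i* and expression *x* becomes
`s_x (√(1−κ) u_x + √κ u_i)` where `u_i` is a fixed identity-dependent
unit direction in the expression block.  At `kappa = 1` each identity
deforms along its own direction: expression-trained spaces then carry
identity information, and EX:ID transfer rises monotonically with
`kappa` — the package's probe for graded dependence between the variant
and invariant systems.

What the generator does *not* emulate: photorealistic appearance,
lighting, occlusion, hairline variation as such, non-linear pose
geometry, heavy-tailed identity distributions.  Passing tests show that
the pipeline recovers the qualitative transfer pattern from data with
the assumed *linear-Gaussian* structure; they do not certify behavior
on real photographs.

## Protocol, sweeps and omission rules

Each condition at grid point (`k` components, `f` faces) subsamples `f`
faces stratified over the training property: as many classes as
possible with at least 4 samples each (`min(C, f // 4)` classes, filled
evenly); identity classes are drawn round-robin over the sex × race
cells to mirror the balanced composition.  Samples are split 50/50
within each training class; PCA is fitted on the full subsample (it
uses no labels), the discriminant on the training half only, and all
scores are computed on the held-out half.

Rows are omitted (flagged, not errored) when `f < k` (the stated
omission rule), when `f = k` (PCA of `n` samples has at most `n − 1`
components), and when the training half leaves the within-class scatter
rank-deficient (`n_train − C < k`): ridge-dominated whitening produced
erratic outlier scores with no interpretable geometry.

The full protocol runs the five invariant-collection conditions
(ID:ID, SE:SE, RA:RA, ID:SE, ID:RA) and the seven expression-collection
conditions (EX:EX, ID:EX, SE:EX, ID:ID, EX:ID, SE:SE, EX:SE) over the
grids components [6:2:42] and faces [20:10:120] / [20:10:160], computes
the eight cross-condition t-tests, and produces figure-scale runs
(120 / 160 faces, 10 components) for distance histograms, KS statistics
and 2-D/3-D component scatters.  All row seeds derive deterministically
from the base seed and grid coordinates; two runs with the same
configuration produce bit-identical CSVs.  The acceptance script and
test suite use reduced grids (components {6, 10, 14}, faces
{40, 80, 120}) — the package's documented demonstration size; the
default CLI configuration runs the full grids.

## Known limitations

* The DMS procedure with random single references cannot reproduce
  sub-chance transfer scores; under label independence its expectation
  is ≥ ~50 %.  Cross-property conditions here land near chance rather
  than far below it.
* With two equally strong binary attributes (sex, race), DMS trials in
  an identity-trained space face a structural confound: a same-sex
  reference of the other race competes against an other-sex reference
  of the same race, and the comparison is zero-sum between the two
  attributes.  Summed over both cross conditions this costs up to ~25 %
  of confounded trials in any fixed metric; the calibrated defaults
  operate in the regime where these comparisons split evenly and the
  same-class baselines are moderated to meet the cross conditions.
  Residual seed-to-seed variation of the grid means is a few points.
* Generalization to real face databases is untested by construction;
  the package's claims are about the method and its behavior on the
  stated latent structure.
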