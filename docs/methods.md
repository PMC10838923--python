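# Methods

`connid` implements a family of network-similarity statistics for deciding
whether two index-aligned sets of functional connectomes — here, 13 biological
parents and their 13 children scanned during a story-listening task — carry a
shared "fingerprint" that identifies which parent belongs to which child.
This note records the model, its assumptions, the defaults, and the numerical
and design choices, in the order the pipeline runs them.

## FC profiles and edges

A subject's profile is the r × r matrix of Pearson correlations between ROI
time courses (defaults r = 264 regions, T = 150 volumes at TR = 1 s). The
diagonal is identically 1 and the matrix is symmetric, so all statistics act
on the strict-upper-triangle *edge vector* of length r(r−1)/2 in a fixed
row-major order (`EdgeIndex`). Correlating the deduplicated vector is exactly
equivalent to correlating the full off-diagonal matrix — uniform duplication
leaves Pearson invariant, which the test suite asserts — so one convention is
used everywhere. No Fisher z-transform is applied by default.

## Fingerprint identification

Each target profile is matched to the database profile with the highest
Pearson correlation between edge vectors; a hit is a match landing on the
target's own dyad index, and the rate is the hit fraction. Both directions
(parents as targets, children as targets) are reported. Ties in the argmax
break to the lowest index (deterministic) with a logged warning. The
permutation null shuffles database identities uniformly; the p-value is the
fraction of shuffles whose rate reaches the observed one.

## CBI: cross-group feature selection and sub-models

For every edge, the n parent values are Spearman-correlated with the n child
values across dyads. Edges with p < α (default 0.05) split by the sign of ρ
into a positive and a negative feature set; each subject is then represented
by its own FC values at those edges. Couples are matched per parent by

* positive sub-model: minimum Euclidean distance / maximum Spearman
  coefficient to a child's vector;
* negative sub-model: maximum distance / minimum coefficient.

Spearman p-values use the two-sided t approximation with n − 2 degrees of
freedom (the dominant convention at n = 13); ranks average over ties. Edges
constant across dyads have undefined rank correlation and are excluded from
both masks with a counted warning. No multiple-comparison correction is
applied to the r(r−1)/2 edgewise tests: the permutation tests below are the
statistical control, and an inflated false-edge set is meant to surface there
rather than be filtered upstream.

Two permutation tests (default 5,000 iterations each):

1. **Label shuffling.** Couple assignments are shuffled with the feature
   masks held fixed. Shuffling the child order alone induces the same
   distribution over diagonal pairings as shuffling both sets independently
   (the composition of two independent uniform permutations is uniform), so
   the simpler scheme is used; the per-permutation rate reduces to the
   fraction of rows whose extremal column is a fixed point of the draw, and
   its expectation is exactly 1/n for any data with distinct row extrema.
2. **Feature re-selection.** Each iteration re-pairs the dyads, reruns the
   edgewise screen on the shuffled pairing, represents the *original* sets by
   the resulting masks, and scores identification against the true diagonal.
   Reported per sub-model × metric: mean rate, maximum rate, and how often
   the maximum recurred. Iterations yielding an empty mask score rate 0 and
   are counted rather than dropped, which would bias the null.

Empirical p-values are reported without the (+1)/(N+1) small-sample
correction by default so that a never-exceeded observation reads exactly 0; a
`conservative_p` option adds it.

### A caution on in-sample selection

Because features are selected on the very pairing being evaluated, the
unshuffled identification rate is biased upward: on cohorts with *no*
parent–child coupling at all, the ~α·r(r−1)/2 edges that pass the screen by
chance still encode the pairing used to select them, and the sub-models
identify 60–100% of couples in-sample, with both permutation tests returning
p ≈ 0. The permutation machinery therefore certifies that the observed
pairing is consistently recoverable, not that the features would generalize
to held-out dyads. Synthetic experiments with the bundled generator make this
circularity easy to reproduce and quantify, and the acceptance suite includes
deliberately failing checks documenting where chance-level behavior would be
expected of a selection-free procedure but is not attained by this one.

## Network-node accounting

With ROIs labeled by network (e.g. the 14 networks of the 264-ROI
parcellation), each selected edge increments the (network, network) block it
joins. Masks live on the deduplicated triangle, so no symmetric double
counting can occur. Counts are normalized two ways: by the sub-model's total
selected-feature count (fractions over unique blocks sum to 1), and by node
size — n_A·n_B possible edges for an off-diagonal block, n_A(n_A−1)/2 for a
within-network block. ROI self-correlations are constant 1 and can never be
selected, so they are excluded from node sizes; a single-ROI network's
diagonal value is defined as 0 with a warning. The "uncertain" network is an
ordinary label.

## Diffusion maps

All 2n profiles (whole-brain matrices or feature vectors) become nodes with
Gaussian affinities K(i, j) = exp(−d(i, j)²/ε). Metrics:

* Euclidean for feature vectors;
* affine-invariant Riemannian for whole-brain profiles,
  d(A, B) = ‖log(A^{−1/2} B A^{−1/2})‖_F, computed via symmetric
  eigendecompositions (log-Euclidean available as a cheaper option).

Correlation matrices estimated from T < r volumes are rank deficient, so
profiles pass through linear shrinkage (1−γ)M + γI first; the pipeline raises
γ from its 10⁻³ floor to the smallest value putting every profile's minimum
eigenvalue above 10⁻³ (synthetic direct-edge profiles can be strongly
indefinite and need more than real rank-deficient estimates).

ε defaults to the median squared off-diagonal distance (scale knob
`epsilon_scale`), a scale-free choice that keeps every kernel entry strictly
positive and the graph connected. The kernel is row-normalized into a Markov
matrix P whose leading eigenvalue is exactly 1 with a constant right
eigenvector; that trivial pair is discarded and the next l = 2 eigenpairs
(computed through the symmetric conjugate D^{1/2} P D^{−1/2} for stability,
right eigenvectors unit-normalized, signs fixed so the first
maximal-magnitude component is positive) give coordinates
X_i → (λ₁φ₁(i), λ₂φ₂(i)).

Dyad separation compares the n embedded same-dyad parent–child distances with
all n² − n cross-dyad parent–child distances: means, standard errors
(sd/√m; the unrelated observations are dependent, which the procedure
ignores by construction), and a two-sided Mann–Whitney U with normal
approximation and tie correction (no continuity correction). On coupled
cohorts the positive-feature embedding pulls dyads together
(mean_bio < mean_unrel) and the negative-feature embedding pushes them apart.

## Synthetic cohorts

The generator emulates the study's statistical skeleton, not BOLD physics: no
hemodynamics, motion, physiological noise, or spatial autocorrelation, so
passing tests demonstrate the statistics' behavior under the planted model,
not performance on real fMRI. Per edge e and dyad d, with latent
u ~ N(0, 1) shared within the dyad:

    parent = tanh(μ_e + c·u + s_f·v + noise),   noise ~ N(0, σ²)
    child  = tanh(μ_e + sign_e·c·u + s_f·v + noise′)

where sign_e is +1 on planted positive edges, −1 on planted negative edges,
0 elsewhere; μ_e is a per-cohort baseline ~ N(0.1, 0.2²) truncated to
(−0.8, 0.8); v is a second dyad-shared latent on *every* edge with strength
s_f (`individual_strength`), the component a whole-connectome fingerprint can
detect. tanh keeps entries in (−1, 1) without clipping artifacts. Defaults:
13 dyads, r = 264, T = 150, 5% of edges planted per sign, coupling 1.0,
noise 0.3, s_f = 0. Equal planted positive and negative counts make the
coupling cancel in whole-brain Pearson similarity, so the fingerprint model
stays at chance unless s_f > 0 — separating what the CBI sub-models detect
from what whole-connectome correlation detects.

A `timeseries` mode builds each subject's target correlation the same way,
floors its eigenvalues at 10⁻³ (planted structure can break positive
semi-definiteness), samples a T × r Gaussian series, and re-estimates the
profile through the Pearson pipeline.

Test and acceptance runs use n = 13 dyads with r = 50 ROIs (1,225 edges) —
large enough for ~60 planted edges per sign and a stable α·m false-positive
count, small enough that the full suite including two 5,000-iteration
permutation tests finishes in seconds. The "strong coupling" regime is
c = 1.5, σ = 0.1 (planted cross-dyad correlation ≈ 0.99, selection
near-certain); the null regime is c = 0, σ = 0.3.

## Known limitations

* All inference is in-sample over one small cohort (see the circularity
  caution above); there is no out-of-sample extension or cross-validation.
* The anisotropic (density-normalized) diffusion-map family and Nyström
  out-of-sample mapping are not implemented.
* The Mann–Whitney samples are dependent by construction; p-values are
  descriptive.
* Only plain-text time series and profiles are read; volumetric formats and
  preprocessing are out of scope.
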