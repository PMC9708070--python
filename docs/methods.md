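# Methods

This note documents the model and procedure implemented by `fcsubtypes`, the
assumptions behind them, the synthetic-data design used to exercise the
pipeline, and the numerical choices that were genuinely open.

## Seed-FC maps and quality control

The unit of analysis is a seed-FC map: for one seed network, the vector of
Pearson correlations between the network's mean time course and the time
course of every spatial feature (parcel or gray-matter voxel), computed over
the frames that survive motion censoring. Censoring removes every frame whose
framewise displacement (FD) exceeds `fd_threshold` (default 0.4 mm) together
with the one preceding and two following frames; a session is usable only if
at least `qc_min_frames` (50) frames remain and mean FD over all frames is at
most `qc_max_mean_fd` (0.3 mm). Zero-variance target signals produce missing
(NaN) correlations, which propagate as missing features and are excluded
pairwise from spatial correlations downstream rather than poisoning them.

For test-retest analyses that average M sessions at a fixed data budget of K
session-equivalents, each session is truncated to `round(K/M · n_frame_min)`
frames (round-half-to-even; this reproduces both 79 = 238/3 and
159 = 2·238/3 at the reference session length of 238 frames) and per-session
maps are averaged elementwise. Truncation takes the *first* frames of each
session — deterministic and order-preserving; the alternative (random frame
selection) would inject avoidable run-to-run variance. Censoring is applied
before truncation by default and is configurable, since the ordering is a
genuine protocol choice.

## Residualization

Within each sample separately, maps are centered feature-wise to the sample
mean and linear effects of covariates of non-interest are removed by
per-feature OLS. Site is deviation-coded (sum-to-zero), so the intercept is
the grand mean and "centering to the sample mean" and "regressing site" are
one coherent model; the choice of coding affects only the intercept, not the
residuals. The optional whole-brain-FC covariate is the per-individual mean
FC over all features of all seed networks — the simplest scalar capturing
global FC shifts; a per-network variant is available. Residualization of a
new sample (replication, or a held-out scan session) always re-fits within
that sample: transporting discovery coefficients would leave the new sample
un-centered. Features missing in more than 5% of individuals are dropped and
logged; sparser missingness is handled by per-feature row exclusion.

## Subtype extraction

Dissimilarity between residual maps is `D = 1 − r` (spatial Pearson), with
range [0, 2] and `D = 2` attained at perfect anti-correlation. The N×N matrix
is clustered with UPGMA (unweighted-average) linkage. Communities are read
off the dendrogram top-down: starting at the root, a node is accepted iff the
average pairwise dissimilarity among its leaves is strictly below θ,
otherwise its two children are visited; accepted nodes with at least `n_min`
leaves become subtypes, numbered by decreasing size (ties by smallest member
index, for stable reporting). Everyone else — members of accepted-but-small
candidates and leaves under never-accepted subtrees — is unassigned. The
strictness of the inequality (`<` vs `≤`) is configurable; strict is the
default. Tie handling inside the linkage is scipy's deterministic order.

Two properties of this acceptance rule are worth knowing:

- **It is permissive.** The average-pairwise criterion rejects a node only
  when roughly half of its member pairs are dissimilar. A single outlier in
  an otherwise tight community (even at `D ≈ 2` from everyone) barely moves
  the average, so isolated individuals are typically *absorbed*, not
  unassigned. Unassignment arises from coherent small groups (below `n_min`)
  and from genuinely fragmented subtrees.
- **θ = 1 cannot split balanced, clean mixtures.** For column-centered data,
  the union of two equal, internally homogeneous communities has average
  dissimilarity ≈ (D_within + D_between)/2 < 2, which is below 1 unless the
  two community maps are nearly perfectly anti-correlated. With well-separated
  synthetic clusters (k ≥ 3), sibling communities therefore merge at θ = 1;
  recovery of planted structure needs θ between D_within and the merged-node
  average. The desk-scale synthetic protocols in the tests use θ = 0.5
  (cross-sectional, k = 3 orthogonal prototypes) and θ = 0.8 (longitudinal).
  On weakly separated real data the same rule with θ = 1 yields a handful of
  subtypes per network; the `threshold_sweep` operation exposes the whole
  θ-dependence, and the assigned proportion is non-decreasing in θ by
  construction of the cut.

Subtype maps are member means of residual maps; continuous assignments are
spatial correlations with subtype maps and are defined for any individual
with compatible features, including out-of-sample transfer.

## Stability analyses

**Split-half.** Half-subsamples of size ⌊N/2⌋ are drawn without replacement,
stratified to preserve the diagnosis ratio within one individual; unordered
pairs of distinct subsamples are drawn uniformly without repetition. Within
each subsample the *full* procedure is repeated (residualization included).
Map stability is the directional best-match statistic: for each subtype map
in A, the maximum spatial correlation over B's maps (with replacement),
averaged. Discrete stability is the Dice coefficient
`2|X∩Y| / (|X| + |Y|)` of an individual's community *neighbour* sets
(communities restricted to A∩B, the individual itself excluded — otherwise a
Dice of 0 would be unattainable). Individuals unassigned in either model are
excluded from the mean by default (counted and reported); scoring them 0 is
available by flag. Dice is symmetric in A/B and invariant to subtype
renumbering.

**Test-retest.** Reliability of continuous assignments across two scan
sessions is ICC(1,1), the one-way random-effects single-measurement form:
`(MS_between − MS_within) / (MS_between + (k−1)·MS_within)`. Sessions of a
resting-state protocol are exchangeable replicates, which is exactly the
one-way model; ICC(2,1) is available by flag for designs with a systematic
session effect. Negative estimates are reported as computed. Subtypes come
either from session 1 of the same sample (within-sample) or from an
independent discovery model (out-of-sample); each test session is centered
and residualized independently before scoring.

## Association, FDR, and replication

Continuous assignments are compared between groups with a pooled-variance
two-sample t-test (the cohorts are constructed with equal group sizes, where
the pooled test is exact; no unequal-variance correction is applied).
P-values are BH-FDR corrected at q = 0.05 *pooled across all subtypes of all
networks*; symptom correlations (ADOS restricted to diagnosed individuals,
SRS on everyone with scores) form a separate BH family. Cohen's
`d = (mean_ASD − mean_NTC)/SD_pooled`, so d < 0 marks subtypes with stronger
neurotypical affinity (negASD) and d > 0 stronger ASD affinity (posASD). CIs
use the normal approximation `d ± z·√((n1+n2)/(n1·n2) + d²/(2(n1+n2)))`.

Replication transfers the discovery subtype maps to a replication cohort that
was residualized within itself, restricts testing (and its FDR correction) to
the discovery-significant subtypes, and grades each on four independent
rungs: FDR-significant, p < 0.05, replication d within the discovery d's CI,
same direction. The CI rung uses a 90% interval by default while plotted
error bars use 95% — the two conventions serve different purposes and both
levels are configurable. Effect-size concordance (Pearson r of the d vectors)
is reported both over discovery-significant subtypes and over all common
subtypes.

## Synthetic cohorts

The generator is the package's test bed; its defaults are fixed study
conditions, not tuning knobs.

**Cross-sectional.** Per network, k prototypes are random smooth patterns
(linear combinations of a 10-function cosine basis, mutually orthogonalized,
per-feature SD = `prototype_scale`) — smoothness makes spatial correlations
between maps well behaved, as in real FC topographies. An individual's map is
grand-mean pattern + loading·prototype(own subtype) + site offset +
age·slope + motion·slope + iid Gaussian noise, with the loading jittered
around 1 (`loading_sd`). Ages are uniform on [8, 40] years; per-subject mean
FD is lognormal with median 0.15 mm; sites and diagnoses are balanced.
Setting every noise scale to zero collapses each map to its (centered)
prototype exactly.

**Diagnosis effect.** The planted effect is a shift of ASD individuals' maps
along the centered target prototype, with magnitude solved numerically
(bisection) so that the standardized group difference of true-map continuous
assignments — computed after group-mean centering, the scale the analysis
works on — equals `diag_effect_d` exactly. A naive shift of the prototype
*loading* does not survive the analysis: correlation-based assignments
saturate near 1 for subtype members, so loading shifts reach the estimated d
only ~35% attenuated. Planting on the assignment scale makes the generator's
d directly comparable with the d the association stage estimates; the
pipeline recovers planted d = 0.5 at ≈ 0.50 (N = 200/arm).

**Longitudinal.** Each subject has a stable latent map on the Fisher-z scale
(`0.25 ×` the prototype pattern), squashed through tanh so true FC values lie
in (−1, 1). Each session adds a fresh smooth perturbation of amplitude
`session_noise_sd` (default 1.5, relative to the prototype scale) — session
effects in fMRI are spatially structured, and iid feature noise would average
out of spatial correlations entirely, leaving test-retest reliability
unrealistically at ≈ 1. Frames follow
`y_t = ρ x_t + √(1−ρ²) ε_t`, so the sample seed correlation converges to ρ
with Fisher-z variance ≈ 1/(T−3); 95% of the target-noise variance is carried
by ten shared smooth spatial profiles (variance-normalized per feature, so
the limiting FC is untouched). With unstructured noise instead, the number of
frames would have no measurable effect on assignment reliability; with this
structure, mean ICC rises from ≈ 0.52 (single short session) to ≈ 0.78 (four
sessions, full frame budget), increasing monotonically in both the number of
sessions averaged and the total frame budget.

**What the generator does not emulate:** realistic fMRI artifacts (spikes,
drifts, physiological cycles), spatial autocorrelation beyond the smooth
basis, site-by-age interactions, diagnosis effects on discrete cluster
existence (the effect modulates assignment strength only), and volumetric 4D
data. Passing tests therefore demonstrate the correctness and calibration of
the *procedure* under its stated statistical assumptions, not performance on
clinical data.

## Problem sizes and numerical choices

Test protocols use cohorts of 200–400 individuals with 150–200 features and
1–2 networks (cross-sectional), and 30 subjects × 9 sessions × 60 frames × 60
features (longitudinal) — large enough for stable Monte-Carlo behavior over
20–50 seeds while keeping the full suite in the tens of seconds. All
randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical seed + configuration is bit-identical.
Degenerate inputs fail loudly: zero-variance maps name the offending row,
rank-deficient confound designs name the collinear columns, and empty
dissimilarity structures yield all-unassigned labellings rather than errors.
Pearson correlations are clipped to [−1, 1] against floating-point overshoot;
dissimilarities to [0, 2].

## Known limitations

- The top-down average-dissimilarity cut is one of several reasonable
  readings of a threshold-plus-minimum-size acceptance rule; it is the
  maximal-community variant and is validated against a brute-force
  enumeration of dendrogram cuts in the tests.
- ICC is computed per subtype on two measurements; no pooling or variance
  shrinkage across subtypes is attempted.
- The symptom-association stage models linear relationships only.
- NIfTI support is parcel-level; voxel-level maps are handled as flattened
  masked vectors outside this package.
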