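# Methods

## The model

`tensorgsvd` decomposes two third-order tensors that share two "column"
dimensions but not their "row" dimension.  The motivating data are paired
DNA copy-number datasets: a tumor tensor `D1` of `K1` probes × `L` patients ×
`M` platforms and a normal tensor `D2` of `K2` probes × `L` patients × `M`
platforms, where the patient and platform axes are matched one-to-one but the
probe sets differ.  The tensor generalized singular value decomposition
(tensor GSVD) factors both simultaneously and exactly:

    D_i = R_i ×_a U_i ×_b Vx ×_c Vy ,    i = 1, 2

- `U_i` (K_i × LM, orthonormal columns) holds the *arraylets*: dataset-specific
  copy-number patterns across probes.
- `Vx` (L × L) and `Vy` (M × M) are invertible with unit-norm rows of `Vxᵀ`
  and `Vyᵀ`: the *x-probelets* (patterns across patients) and *y-probelets*
  (patterns across platforms), identical for both datasets.
- `R_i` (LM × L × M) are the core tensors of real (not necessarily positive)
  *tensor generalized singular values*.

The construction is by three matrix GSVDs of the paired unfoldings: the
row-mode unfolding (K_i × LM, column index `l·M + m`, platform fastest)
supplies `U_i`; the x-mode ((K_i·M) × L) and y-mode ((K_i·L) × M) unfoldings
supply `Vx` and `Vy`.  The cores follow by contracting each tensor with
`U_iᵀ`, `Vx⁻¹`, `Vy⁻¹`, implemented as one probe-mode product followed by two
small triangular solves — the LM × LM Kronecker matrix `Vxᵀ ⊗ Vyᵀ` is never
materialized, giving O(K·L·M·(L+M)) cost instead of O(K·L²M²).

### The matrix GSVD

The two-matrix GSVD `D_i = U_i Σ_i Vᵀ` (shared invertible `V`, orthonormal
`U_i`, positive `Σ_i`) is computed by a QR factorization of the stacked
matrix `[D1; D2]` followed by a cosine–sine decomposition of the partitioned
orthonormal factor: the SVD of the top block supplies the cosines and `U1`;
the sines are the column norms of the rotated bottom block, which normalizes
to `U2`.  Internally `Σ1² + Σ2² = I` before the rows of `Vᵀ` are rescaled to
unit norm, with the scale absorbed equally into both `Σ` factors (ratios and
angles unaffected).  This route avoids forming `DᵀD` and is stable for the
well-conditioned inputs the decomposition requires: both matrices must have
full column rank, checked numerically (SVD rank with tolerance
`max(K, N)·eps·σ_max`); deficiency raises an error naming the deficient
input rather than silently truncating.

Sign convention: basis vectors are unique only up to ±1 phases, so each row
of `Vᵀ` is flipped to make its largest-magnitude entry positive, with the
compensating flip absorbed by the corresponding `U_i` columns.  Within blocks
of exactly tied ratios the factors are unique only up to rotation; a stable
sort preserves their pre-sort order.

### Angular distances and significance

The relative significance of the `a`-th paired basis direction is the ratio
`σ_{1,a}/σ_{2,a}`, re-expressed as the angular distance

    θ_a = arctan(σ_{1,a}/σ_{2,a}) − π/4  ∈  [−π/4, +π/4],

antisymmetric in the two datasets: `+π/4` marks a direction exclusive to
dataset 1, `−π/4` exclusive to dataset 2, `0` equally present in both.
Factors are ordered by decreasing ratio, so the most dataset-1-exclusive
arraylet is always first (`a = 1`).

Each subtensor `(a, b, c)` carries a significance fraction
`P_{i,abc} = R_{i,abc}² / ΣR_i²` and an angular distance
`Θ_abc = arctan(R_{1,abc}/R_{2,abc}) − π/4`.  Because the row-mode unfolding
of the core is `Σ_i Vᵀ (Vx⁻ᵀ ⊗ Vy⁻ᵀ)` with a factor shared between the two
datasets, the element-wise core ratio collapses to the row-mode σ-ratio and
`Θ_abc = θ_a` at every defined entry — verified to 1e−10 in the tests.
Entries where both cores vanish have an undefined ratio and are reported as
NaN with an explicit `defined` mask, not as zero.

### Special cases

- `M = 1` (matrices): the factorization reduces to the matrix GSVD exactly.
- `D1` whose row unfolding is the identity: the decomposition of `D2`
  reduces to its higher-order SVD (HOSVD); `hosvd` implements that
  single-tensor special case directly and serves as the oracle in tests.
  Note the GSVD's ratio ordering then *reverses* the HOSVD's singular-value
  ordering, so comparisons match factors pairwise after sorting.

### Identifiability of common patterns

A pattern planted with equal weight in both tensors has a σ-ratio ≈ 1 —
inside the ratio band of the i.i.d. noise background, whose pencil
eigenvalues spread roughly as `1 ± 2√(LM/K)`.  Within such a near-degenerate
ratio block the arraylets are determined only up to rotation, so no single
factorization index isolates an equal-weight pattern, *regardless of its
amplitude*.  This is a property of the decomposition, not of the
implementation: GSVD separates by relative, not absolute, significance.
`pattern_angular_distance` therefore evaluates a *specified* patient ×
platform direction by the ratio of the two tensors' projections onto it;
for a direction coinciding with a probelet pair this equals the subtensor's
`Θ`, and it remains well defined in the degenerate case.  Dataset-exclusive
patterns have extreme ratios, sit outside the noise band, and are recovered
as the `a = 1` subtensor with arraylet cosine ≈ 1.

## Patient classification

Discovery-set patients are split on an x-probelet coefficient at
`median + k·sMAD`, `k = 0.5` by default, where sMAD is the standardized
median absolute deviation `1.4826·median|v − median v|` (the constant makes
it estimate a normal standard deviation; "standardized" is interpreted this
way and the constant is configurable).  The threshold is one-sided: "high"
is strictly above the cutoff on the signed deviation; a per-arm `direction`
flag records which label is hypothesized favorable.  Validation-set
patients, profiled on possibly different probes, are scored by the Spearman
rank correlation of their profile with the first arraylet over the shared
probes (≥ 10 required) and thresholded by the same rule — the exact
validation cutoff is an open choice and is exposed as configuration.

A split is *robust* when the two groups differ at log-rank p < 0.05 at every
cutoff in `k ± 0.1` sMAD (step 0.02); a cutoff leaving fewer than two
patients in either group is non-evaluable and fails the scan.  With ~30%
carriers this rule has an intrinsic accuracy ceiling of about 0.93: the
cutoff settles ≈ 1.3 noise-SD above the non-carrier bulk, so ≈ 8–10% of
non-carriers always land in the high group however small the noise.

A y-probelet is *platform-consistent* when its entries are approximately
equal across platforms: maximal pairwise relative difference
`|y_i − y_j| / max(|y_i|, |y_j|) ≤ 0.15` (the tolerance is a package
default, configurable).  Three binomial classifications combine into
prognostic groups by Hamming distance from a user-declared favorable triple:
A (distance 0, 1 triple), B (distance 1, 3 triples), C (distance ≥ 2,
4 triples).

## Survival statistics

Kaplan–Meier curves and the k-sample log-rank test are delegated to
lifelines; the median survival time is the earliest time the curve reaches
≤ 0.5 and is flagged undefined when it never does.  Cox proportional-hazards
regression is implemented directly: Newton–Raphson maximization of the
Breslow partial likelihood (risk-set sums as suffix sums over tie blocks),
step-halving on likelihood decreases, at most 100 iterations, with Wald
standard errors from the observed information.  Coefficients beyond ±15
(hazard ratios beyond e¹⁵) are treated as the monotone-likelihood signature
of complete separation and raise an error.  On tie-free data the fit matches
lifelines' Efron fit to ~1e−5, which serves as the independent cross-check.

Two predictors are judged *independent* when their jointly fitted log hazard
ratios stay within 25% (relative, configurable) of the separately fitted
ones.  Hazard ratios are non-collapsible, so a small systematic attenuation
of the univariate fits is expected even under exact independence; the 25%
band absorbs it at the planted effect sizes used here.

## Segmentation

An arraylet in genomic order is partitioned by recursive binary splitting:
the candidate breakpoint maximizes the two-sample t-statistic, and a split
is accepted when its permutation p-value (1000 within-segment shuffles,
seeded, so results are reproducible) is below α = 0.01, recursing on both
sides.  This is a deliberately simplified stand-in for circular binary
segmentation with the same interface.  A noiseless level change has zero
pooled variance, infinite t, and is always split exactly.  Segments are
called amplified/deleted when their mean exceeds the baseline by `delta`
(default: one sMAD of the arraylet), *focal* when a called segment spans
strictly fewer than 125 probes, and *frequent* when strictly more than 23%
of patients are altered over the segment — a patient counts as altered when
their mean copy number over the segment's probes exceeds the threshold in
the call's direction (the per-patient rule is a package definition).

## Synthetic cohorts

The generator emulates the structure of paired tumor/normal copy-number
datasets.  Defaults, fixed once as the reference study conditions: K1 = 500
tumor and K2 = 480 normal probes, L = 60 patients, M = 2 platforms, one
tumor-exclusive pattern (amplification block at level +0.5 over 40% of the
arm, deletion at −0.4 over 20% — typical log-ratio magnitudes), 30%
carriers, equal platform weights, i.i.d. Gaussian noise with sd 0.1.
Survival: exponential baseline with 40-month median (realistic for
high-grade serous ovarian carcinoma), carrier hazard multiplied by a planted
ratio of 2, independent Uniform(0, τ) censoring with τ solved to achieve a
20% censoring fraction.  Carrier subsets for distinct patterns are drawn
disjointly while patients remain, so each planted pattern excites its own
patient direction and remains identifiable.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: probe-density differences between platforms,
batch and GC-wave artifacts, heavy-tailed or spatially correlated noise,
overlapping carrier populations, and non-proportional hazards.  Probe shapes
are piecewise constant so that segmentation has recoverable truth.

## Numerical choices

- Reconstruction tolerances: 1e−8 relative Frobenius error (achieved:
  ~1e−15); `Θ = θ` identity to 1e−10; orthonormality to 1e−10.
- Rank tolerance `max(K, N)·eps·σ_max`; rank deficiency is an error.
- Undefined `Θ` entries (both cores below 1e−12 of the core scale) are NaN.
- Near-ties in subtensor significance (within 1e−9 relative) select the
  lexicographically smallest index, with a warning.
- Problem sizes in tests and the acceptance script (tensor pairs up to
  60×6×2, cohorts of 60–200 patients, 20–50 seed replicates, 300–500
  calibration replicates) were chosen to give stable Monte-Carlo estimates
  at desk scale.

## Known limitations

- Only order-3 tensors, two datasets, complete data, real values.
- Equal-weight (common) patterns are identified by direction, not by
  factorization index (see above) — an intrinsic GSVD property.
- The segmentation stand-in lacks CBS's circular statistic and pruning, and
  undersplits relative to it on multi-change signals with unequal variances.
- Cox regression covers time-fixed covariates and Breslow ties only; no
  competing risks.
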