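# Methods

This note records the statistical procedures implemented in wingmorph,
the defaults chosen where several conventions exist, and what the
synthetic data generator does and does not emulate.

## Superimposition

Shapes are k = 19 two-dimensional landmark configurations (any k ≥ 3 is
supported). Size is centroid size, CS = sqrt(Σᵢ ‖xᵢ − x̄‖²), in the raw
coordinate units; a `SCALE=` factor present in TPS records is applied
only when `apply_scale` is enabled, since every downstream shape
statistic is scale-invariant but raw size comparability across images
requires a consistent choice.

The generalized Procrustes fit is the *full* fit: each configuration is
centred, scaled to unit centroid size, and rotated onto the running
consensus; the consensus is the renormalised mean, iterated until its
maximum coordinate change falls below 1e-10 (cap 1000 iterations — the
fit converges in a handful of iterations on wing-like data, and the cap
only matters for near-degenerate stress inputs). Rotations are proper
(det +1) only: all wings come from the same body side, and permitting a
reflection would silently absorb digitization side errors. In 2-D the
optimal rotation is computed in closed form as the phase of the complex
inner product between configurations, which is exactly the singular-value
solution specialised to the plane. Because the consensus is defined only
up to rotation, each new consensus is re-anchored to the orientation of
the previous one during iteration, and the converged solution is rotated
so landmark 1 of the consensus lies on the +x half-axis; this makes
results invariant (not merely equivariant) under common similarity
transforms of the input.

Aligned rows are projected orthogonally onto the tangent space at the
consensus. For k 2-D landmarks that space has dimension at most 2k − 4
(34 here). Replicate digitizations are superimposed jointly and then
averaged per specimen — tangent coordinates and centroid sizes both —
which halves the digitization-error variance for two replicates. We
project to tangent space before averaging; the difference from the
reverse order is far below any reported precision.

The Procrustes distance between two shapes is the partial Procrustes
distance: both centred and scaled to unit size, one rotated optimally
onto the other, distance = root of the residual sum of squares.

## Discrimination in shape space

Tangent data are rank-deficient and small groups make covariance
estimates singular, so all discriminant computations run in a *retained
subspace*: the principal-component basis of the analysed dataset,
keeping components with eigenvalue > 1e-12 × the largest, capped at
n − g components when g group labels are in play. Residual rank
deficiencies (tiny groups in pairwise comparisons) are handled by an
eigenvalue-truncated pseudo-inverse with the same 1e-12 relative cut,
applied identically to observed and permuted statistics so permutation
p-values remain exact. Pairwise-pooled covariances for very small groups
overfit and inflate Mahalanobis distances; this mirrors the behaviour of
standard morphometric software, and a `covariance="global"` option is
available to hold the all-groups pooled covariance fixed instead.

CVA solves the between- vs pooled-within-group eigenproblem by whitening
with W^(−1/2) and diagonalising the whitened between-group covariance;
axes are scaled so the pooled within-group covariance of the scores is
the identity, and axis percentages are eigenvalue shares. With g groups
there are at most g − 1 non-trivial axes, so three groups always yield
two axes summing to 100%.

Permutation tests on pairwise Mahalanobis (pairwise-pooled covariance by
default) and Procrustes distances relabel specimens preserving group
sizes; p = (b + 1)/(rounds + 1), never exactly zero; default 10,000
rounds. Each pair draws its RNG stream deterministically from
(seed, pair index), so any single pair can be reproduced in isolation
and observed distances are identical across seeds. Statistics are
compared on the squared scale with a 1e-12 absolute slack so that
permutations equal to the observed value up to float jitter count as
"at least as extreme".

Classification is leave-one-out nearest-group Mahalanobis: for each
held-out specimen, group means and the pooled within-group covariance
are recomputed without it. The multi-group table uses a single
nearest-group rule in the common retained subspace (the pairwise-DFA
literature leaves the multi-group aggregation unspecified; this rule is
a documented choice). Ties break by declared group order and are logged.
A held-out member of a singleton group cannot be assigned to its own
group and counts as incorrect. Note that under the null (identical
groups) leave-one-out nearest-centroid is pessimistically biased below
50%: removing a specimen pushes its own group mean away from it. Sex
discrimination is the two-group specialisation run per species; species
lacking two specimens of each sex are skipped and logged.

## Size statistics

Kruskal–Wallis H (tie-corrected, chi-squared approximation, df = g − 1)
across species, then pairwise Mann–Whitney U tests with the Bonferroni
threshold α / C(g, 2) over the species-pair family (0.05/66 ≈ 0.00076
for 12 species). U is reported as min(U₁, U₂); the p-value is exact by
enumeration when n₁·n₂ ≤ 400 and the data are tie-free, otherwise the
normal approximation with tie and continuity corrections. Per-species
sex differences are two-sided at α = 0.05, uncorrected — the sex-test
family is interpreted per species, not jointly. Boxplot summaries use
type-7 (linear interpolation) quartiles with min/max whiskers.

## Allometry

Shape is regressed on centroid size (natural scale by default; a
`log_size` flag switches to the log-size convention some reference
software uses). Percent predicted = 100 × SS(predicted)/SS(total) on the
(sub)group-centred data; the permutation test permutes sizes against
shapes within each pooling subgroup, statistic = percent predicted.
"Pooling" within species (or sex within species) centres both shapes
and sizes on subgroup means so that group mean differences cannot
masquerade as allometry; subgroups with fewer than two members are
dropped with a warning. The phrase "regression of Procrustes distance on
centroid size" found in parts of the morphometric literature is read
here, as in the reference software, as the multivariate regression of
the Procrustes *coordinates* on centroid size.

Allometry-free shapes are defined as xᵢ − b·(sᵢ − s̄), removing the
estimated common allometric component evaluated at the grand mean size.
In the unpooled case this equals the regression residuals re-centred on
the grand mean shape; under pooling it deliberately retains group mean
differences (re-centring pooled residuals on one grand mean would erase
the very group structure the corrected reruns are meant to analyse).
The overall cross-species regression is reported both pooled within
species (the default headline number) and unpooled, since either
convention appears in practice. When several groups genuinely share one
allometric trajectory, the unpooled regression is the more precise
estimator of it — its slope uses the full size range — and is the right
basis for testing whether groups are separated by allometry alone.

## UPGMA phenogram

Average-linkage agglomeration of the species Mahalanobis matrix; merge
heights are half the inter-cluster average distance, so the tree is
ultrametric and leaf-pair path lengths in the exported Newick equal the
cophenetic distances. Ties in the minimum distance break by
lexicographic label order and are logged.

## Synthetic data generator

The generator emulates the sampling design of a multi-site blow-fly
survey: 12 species in 3 genera with the strongly unbalanced per-species
male/female counts of the emulated study (372 specimens total, including
a 3-specimen all-female species and two conspicuously smaller-bodied
species), 19 landmarks, two digitization replicates.

Per specimen, the tangent-space shape is
template + genus offset + species offset (+ sex vector for males)
+ a·(s − s₀) + isotropic N(0, σ_w²) noise, where s is the log-normally
drawn centroid size. The configuration is then scaled to s, randomly
rotated and translated, and each replicate receives independent
N(0, σ_e²) landmark noise in image units — where a digitizer's pointing
error actually enters. Offset, sex and allometry directions are drawn
once per species (and once per genus) from a seeded isotropic Gaussian
orthogonal to the template's similarity-nuisance directions, then frozen
into the ground truth; orthogonality makes their norms survive
superimposition essentially unchanged, which is what makes calibrated
parameter-recovery tests possible. An optional `common_allometry`
component shared across species around the study-wide reference size
creates species that differ in mean shape through allometry alone.

Perturbations are added directly to the unit-size template coordinates —
a small-deformation assumption, valid for the sub-0.1 tangent norms used
throughout.

Default magnitudes were chosen once to resemble a real wing study:
within-species tangent sd σ_w = 0.004 per coordinate, species offsets
0.02 on top of genus offsets 0.035 (pairwise Procrustes distances
between species mean shapes then fall in the 0.02–0.1 range typical of
congeneric flies), log-normal sizes around 4.4–6.3 units with log-sd
0.07, males 5% smaller in four species, per-species allometric
magnitude 0.03 per size unit (within-species percent-predicted in the
10–30% range), digitization sd 0.01 image units. The helper
`allometry_magnitude_for_fraction` inverts
f = ‖a‖²·var(s) / (‖a‖²·var(s) + (2k − 4)·σ_w²) to produce a dataset in
which size explains a prescribed share of shape variance.

What the generator does *not* emulate: correlated (non-isotropic)
within-species covariance, biomechanical constraints on vein positions,
landmark-specific digitization error, curved allometric trajectories,
and site effects. Tests passing on these data therefore demonstrate the
correctness and calibration of the statistical machinery, not the
biological discriminability of any real species pair.

## Problem sizes in tests and the acceptance script

The acceptance script runs the full 372-specimen study at 999
permutation rounds per family — enough to resolve p ≈ 0.001 while
keeping a run to about half a minute. The test suite's calibration
checks use 500 simulated null datasets at 999 rounds (two groups of 8,
k = 6) for the attained level of the permutation tests, and 200
replicates of n = 120 for allometry recovery; these sizes give Monte
Carlo error comfortably inside the asserted bands.
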