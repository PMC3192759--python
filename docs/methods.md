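# Methods

`admri` reimplements a multi-feature structural-MRI classification analysis
for Alzheimer's disease staging as a fully synthetic, testable pipeline.
Four feature families are extracted from 3D T1-like volumes — hippocampal
volume (HV), cortical thickness (CTH), tensor-based morphometry (TBM) and
manifold-based learning (MBL) — harmonized for age and sex, pruned by
stepwise selection, and fed to LDA or RBF-SVM classifiers under
leakage-audited cross-validation protocols. Because the original clinical
images are access-restricted, every stage is validated against a synthetic
phantom cohort with analytic ground truth.

## The phantom and its stated world

The phantom is geometric, not anatomical: nested ellipsoidal CSF / GM / WM
compartments with a cortical ribbon of known thickness, two
hippocampus-like ellipsoids with an adjacent amygdala region, a deep
"atrophy nucleus" carrying planted regional volume change, and a
deterministic k-means parcellation of brain tissue (default 84 parcels,
matching the TBM feature count). Tissue classes have distinct mean
intensities (CSF 40, GM 100, hippocampus 105, amygdala 130, WM 160,
nucleus 70) with smooth transitions, a multiplicative bias field (±5%) and
additive Gaussian noise (sd 5, ~5% of GM).

Planted effects follow the disease-severity gradient HC → S-MCI → P-MCI →
AD and are monotone by construction:

| quantity | HC | S-MCI | P-MCI | AD |
|---|---|---|---|---|
| hippocampal volume factor | 1.00 | 0.93 | 0.88 | 0.85 |
| ribbon thickness offset (mm) | 0 | −0.15 | −0.30 | −0.50 |
| nucleus log-volume shift | 0 | −0.08 | −0.15 | −0.22 |

The AD hippocampal factor (0.85) and thickness offset (−0.5 mm) anchor the
plant-and-recover tests; the AD nucleus shift corresponds to a regional
volume factor of 0.80. Normal covariate effects are applied to **all**
groups with identical coefficients (hippocampal volume −0.3%/year and +5%
in males; thickness −0.01 mm/year, +0.05 mm in males), so control-trained
residualization has exactly the "normal, not disease-related" variation to
remove. Small volume factors are realized exactly (±half a voxel) by
thresholding the ellipsoid field at the k-th smallest normalized radius
rather than by analytic axis scaling, which would quantize away at coarse
grids. A fraction of subjects (default 13%, echoing the missing-data rate
of the motivating study) is flagged CTH-missing with the deterministic
count floor(n·f + 0.5).

The atrophy nucleus occupies ~3% of brain volume (semi-axes 0.16/0.12/0.12
of the image extent). This size is part of the stated world: with a much
smaller region, the α/2 false-positive floor of voxelwise testing alone
caps the achievable selection Dice below the 0.5 the localization
criterion demands of a *correct* implementation, i.e. the criterion itself
constrains the geometry.

Each subject additionally receives a random smooth B-spline deformation
(control spacing 8 voxels, amplitude 0.8 mm, clipped at 3 amplitudes) —
identity effects plus zero noise therefore reproduce the warped template
exactly, and all planted values are recorded in a per-subject
`GroundTruth` that is recoverable without running any pipeline stage.

What the phantom does **not** emulate: MR physics (no k-space artifacts,
Gaussian rather than Rician noise), anatomical shape variability beyond
smooth warps, multi-site scanner effects, and partial-volume mixtures. A
green test therefore establishes algorithmic correctness and
plant-and-recover fidelity, not clinical performance.

## Registration

Affine plus cubic B-spline free-form deformation (FFD), both optimized by
multi-resolution gradient descent with step halving on analytic gradients.
The transform convention is fixed → moving (pull-back): `T(x) = A(x +
u(x))`, so a Jacobian determinant below 1 reads as local shrinkage of the
subject relative to the fixed template — the "atrophic voxel" reading used
by TBM. The similarity metric defaults to negative normalized
cross-correlation (robust to the phantom's bias field; SSD available); the
original study does not name its metric, so this is a package decision. A
bending-energy penalty (squared second differences on the control grid,
weight 1e-3) regularizes the FFD. Jacobians are evaluated in closed form
from the B-spline derivative basis; a finite-difference oracle checks them
to 1e-3 and the change-of-variables identity to 2%. Registration is
validated purely by recovery properties (translation to 0.25 voxel, a
2-voxel-max smooth warp to <0.5 voxel mean residual), never against a
reference implementation's output.

## Feature families

**HV.** Multi-atlas segmentation: atlases ranked by NCC with the affinely
aligned query, the top k (default 3–5) FFD-registered to the query, warped
binary hippocampus masks averaged into a spatial prior, and a two-class
Gaussian-mixture EM refinement with voxelwise class prior `α·prior +
(1−α)·uniform` (α = 0.9, preventing zero-probability lock-in). The atlas
pool mixes all four groups, so similarity-based selection can match
disease stage — without this the HC-sized prior biases patient volumes
upward and flattens the planted group ratio. The feature is bilateral
voxel count × voxel volume. The EM class count (2) is the minimal choice
supporting a volume feature; class structure and k are config.

**CTH.** The deformable-mesh surface machinery of the original pipeline is
replaced by a voxel-domain construction that preserves the *t-link
definition* of thickness: Laplace's equation is solved over the GM ribbon
(inner boundary 0, outer 1), every inner-boundary node is traced along the
gradient to the outer boundary, and thickness is the Euclidean distance
between the linked endpoints, in native space. Endpoints are localized at
sub-voxel precision on the 0.5-level of smoothed tissue indicators;
without this the half-voxel start/stop bias is ~0.2 mm. Node values are
smoothed by explicit heat diffusion on the node adjacency graph (edge
weights 1/ℓ², symmetric, hence exactly mean-preserving); diffusion time is
set from the requested FWHM after normalizing the graph's measured mean
squared step per unit time, which makes a smoothed point source Gaussian
with the requested width to within a few percent. Group analysis happens
on the template node set via nearest-inner-node resampling (the phantom
cohort is coarsely aligned by construction); per parcel, the feature is
the mean thickness over nodes significant at α and thinner in the
more-affected group — the feature count is contrast-dependent by design.

**TBM.** A stratified template library (default 10 HC / 10 MCI / 10 AD
when the cohort permits) is co-aligned affinely, averaged, then refined
once by FFD re-registration to the mean; the refinement transforms are
stored. Each template is FFD-registered to the study subject, the analytic
Jacobian map taken on the template grid, and pulled back into reference
space. Voxelwise Welch t-tests between contrast groups (computed from
held-out subjects only) define per-parcel statistical ROIs: member voxels
have p < α (default 0.05) and a mean difference in the atrophy direction;
the feature is Σ w·J / Σ w with w = −log₁₀ p, computed per template and
averaged. The weighting scheme is the most standard monotone choice for
"weighted based on voxel-wise p-values" (the original supplementary
definition is unavailable); both w and α are config. Empty parcels fall
back to the unweighted parcel mean, flagged.

**MBL.** Subjects are compared through z-scored intensity patches of a
template-space ROI (hippocampus + amygdala labels dilated 4 voxels,
margin config) after coarse alignment (10 mm B-spline control spacing).
Euclidean patch distances define a symmetrized k-NN graph with Gaussian
kernel (σ = median k-NN distance); the generalized eigenproblem
L y = λ D y of the graph Laplacian yields the embedding, and the first d =
20 nontrivial coordinates are the features. Eigenvectors are renormalized
by total degree so a uniform rescaling of W leaves coordinates unchanged,
and signs are fixed by the largest-magnitude entry. The graph is built
transductively over all subjects (the construction reads no labels; the
method has no native out-of-sample map); if disconnected, k is increased
with a log, never silently embedding components separately.

## Harmonization and selection

Per-feature OLS of feature on [1, age, sex], fitted on healthy controls
only, subtracted from everyone — patients' corrected values use
control-fitted coefficients exclusively. Missing cells are excluded from
fits and stay missing through correction; the default completion is
train-mean imputation (keeping full n for the combined feature set), with
drop-subject/drop-feature modes for sensitivity analysis. Stepwise
selection is classical forward/backward regression on a linear model of
the binary label with partial-F p-values, p_enter = 0.05 and p_remove =
0.10 (the textbook defaults; the study cites the method without
parameters), deterministic name tie-breaks, and termination guaranteed by
p_enter ≤ p_remove plus an iteration cap. When no candidate reaches
p_enter, the single best-correlated feature is used (a classifier needs at
least one input); this fallback is logged in the selection record.

## Classification and evaluation

LDA is implemented directly (class means, pooled covariance, fixed
uninformative priors 0.5/0.5 even for unbalanced groups, ridge
ε·trace(Σ)/dim when n ≤ dim, exact ties to the positive class); the test
suite checks it against a brute-force discriminant evaluation and the
closed-form Gaussian Bayes rate 100·Φ(d/2). The SVM is scikit-learn's
libsvm-based SVC behind the package's surface, with the standard default
γ = 1/(n_features·var(X)) and C = 1; a two-point closed-form dual and the
XOR instance serve as oracles. Metrics are CCR/SEN/SPE in percent, with
sensitivity on the disease-ward class (AD or P-MCI). The 95% CI is the
empirical 2.5/97.5 percentile of the run-CCR distribution (normal
approximation available); run distributions are compared by
unequal-variance t-tests at p < 1e-4 after a Kolmogorov–Smirnov normality
check, mirroring the study's reporting.

## Protocols

Dataset 1: the contrast cohort splits into three stratified parts; each
part in turn supplies the CTH/TBM statistical-ROI subjects while the other
two thirds are evaluated by 100 repetitions of stratified random 5%-test /
95%-train splits (300 runs total, averaged). Within each repetition the
correction is refit on the training controls (the study's order of
operations is ambiguous; refit-per-repetition is the leak-free reading) —
if a small control draw cannot identify a covariate term (e.g. all one
sex), the protocol driver drops that term rather than aborting the run —
imputation uses training statistics only, and selection runs inside the
training fold (a `global` mode reproducing the selection-before-CV reading
exists). For the S-MCI vs P-MCI contrast the correction trains on cohort
controls outside the evaluation set. Dataset 2 is a single fixed split
with ROIs from held-out subjects. Repetition randomness is counter-based
((seed, part, rep) → generator), so runs are reproducible and order-free.
A `RunLedger` records the ids every fitted object touched and `audit()`
asserts ROI ∩ evaluation = ∅, train ∩ test = ∅, and that no fit touched a
test subject — the audit runs in the test suite on every protocol test.

## Numerical choices and degenerate inputs

Variance floors in EM (1e-3, logged); p-values clipped to the smallest
positive float; zero-variance voxels flagged and excluded, never
zero-filled; empty test-set classes resampled (cap 100); registration
divergence raises with the iteration index; ribbon holes flag nodes
missing and only >50% failure is an error. All randomness flows from
explicit integer seeds; identical seeds give bit-identical cohorts.

## Known limitations

Registration is a simple gradient-descent FFD — adequate for the phantom's
smooth warps, not tuned for real anatomy. The CTH stage assumes coarse
pre-alignment when matching nodes to the template surface. The k-means
parcellation is spatially compact but arbitrary, standing in for an
anatomical parcellation the original study does not specify. Multi-atlas
fusion at easy phantom scales is dominated by the single best-selected
atlas, so fusion gains appear only against the average member, not the
selected best. Clinical accuracy figures of the motivating study are out
of reach by design; the acceptance suite validates properties, not those
numbers.
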