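# Methods

## The experiment the package encodes

Radiomic software platforms disagree because they make different choices for
user-configurable calculation settings, not (mostly) because they implement
different formulas. `radharm` makes that mechanism testable by running *one*
feature engine under several **settings profiles** and treating the profiles
as interchangeable raters: profile-vs-profile comparisons emulate
platform-vs-platform comparisons, and a profile versus a deliberately
perturbed clone emulates a version change. All conclusions drawn this way
concern the settings mechanism only; real platforms additionally differ in
implementation details (meshing algorithms, matrix aggregation, rounding)
that a shared engine cannot expose.

## Settings profiles

A profile fixes, per matrix family (histogram, GLCM, NGTDM):

- the discretisation dialect and its parameters — fixed bin number over the
  ROI range (FBN), fixed bin number over a fixed intensity window, or fixed
  bin width (FBS) from a lower bound; bounds may be numeric (HU) or symbolic
  `roi_min`/`roi_max`, resolved against the masked voxels at extraction
  time;
- the GLCM displacement set (direction vectors × integer offsets) and
  symmetry flag;
- the NGTDM Chebyshev neighbourhood distance;
- an ε guard (default 1e-12) for divide-by-zero conventions, stored in the
  profile so degeneracy handling is itself a setting.

The shipped platform-default profiles encode the published defaults of
LIFEx (400 levels over [−1000, 3000] HU), IBEX (256 levels over [0, 4096]
for histogram/NGTDM but 100 levels over [0, 2100] for GLCM; GLCM offsets
{1, 4, 7}; NGTDM distance 2), PyRadiomics (bin width 25 from the ROI
minimum), CERR (bin width 25 on [0, 500]; 4 in-plane GLCM directions) and
the harmonised profile (64 levels over the ROI range, 13 directions, offset
1, distance 1). Two choices the platform documentation leaves open are made
here explicitly: IBEX's three offsets are merged into a single
co-occurrence matrix (keeping one matrix per subject, so the downstream
feature contract is uniform), and CERR's four directions are taken as the
four canonical 2D in-plane directions applied slice-wise and merged (four
directions only exist in 2D).

## Discretisation

FBN: `g = floor(Ng·(x − lo)/(hi − lo)) + 1`, with levels clamped to `Ng`
(this both closes the top edge, so the maximum maps to bin Ng, and guards
float round-up for interior values whose ratio rounds to 1). Fixed-range
FBN clamps out-of-range intensities to the end bins rather than dropping
them, conserving the voxel count. FBS: `g = floor((x − lo)/w) + 1`; with a
numeric window, the exact upper edge joins the last bin. Bins are half-open
`[lo + (k−1)Δ, lo + kΔ)` with a closed top edge. A flat ROI (max = min) maps
every voxel to level 1 and sets a degeneracy flag; downstream features then
take their homogeneous-ROI conventions instead of crashing.

FBN-over-ROI-range is invariant under positive affine rescaling of the ROI
intensities; FBS is covariant under translation by whole bins. Both
properties are enforced by tests and are the root cause of every
settings-dependence phenomenon the package demonstrates.

## Shape features

The mask is padded, anti-aliased with a fixed Gaussian (σ = 0.8 voxels) and
triangulated by marching cubes at level 0.5, with vertices in physical mm.
The anti-aliasing is a deliberate choice: on a raw binary mask the
marching-cubes surface is a staircase whose area exceeds the smooth boundary
by ~8% *independently of resolution*, so the sphericity of a digital ball
would plateau near 0.92 rather than converging to 1. With anti-aliasing,
ball sphericity reaches ≈0.993 at radius 20 voxels and the mesh volume is
within 1% of the analytic value; the price is extra rounding of genuinely
sharp corners (a 10-voxel cube loses ~14% of its analytic area, decaying as
O(1/a)). ROIs thinner than the smoothing kernel fall back to meshing the
raw indicator so single-voxel masks still produce a closed mesh.

Mesh volume (divergence-theorem sum of signed tetrahedra, orientation
normalised by taking the absolute value) is the canonical volume used in
sphericity; the voxel-count volume is computed alongside. The mesh-volume
routine rejects meshes whose edges are not all shared by exactly two faces.

## First-order and histogram features

Minimum, maximum, mean and standard deviation are computed on raw masked
intensities with population (1/N) moments, following the convention of the
standardisation initiative the profiles emulate; they are independent of
every profile setting. Skewness is computed on discretised levels
(`m3/m2^{3/2}`, population moments), so it inherits the histogram-family
discretisation; a single-level ROI returns 0 with a warning.

## Texture features

GLCM: pairs of levels at each profile displacement are counted over voxel
pairs that are both masked, accumulated into one merged symmetric matrix per
subject, and normalised to probabilities. Features: correlation (1 by
convention when a marginal variance vanishes — a flat region is perfectly
self-correlated), contrast Σ(i−j)²P, angular second moment ΣP², joint
entropy −ΣP log₂P with 0·log 0 = 0, difference average Σk·p_diff(k), and
inverse difference ΣP/(1+|i−j|). No distance weighting is applied.

NGTDM: for each voxel with at least one masked neighbour within Chebyshev
distance d, the absolute difference between its level and its neighbours'
mean level accumulates into s_i; voxels with no masked neighbour are
excluded from N_v. Coarseness = 1/Σp_i s_i, capped at 10⁶ when the sum falls
below ε; busyness = Σp_i s_i / Σ|i·p_i − j·p_j| over present levels, 0 when
the denominator vanishes; contrast = [Σp_i p_j(i−j)²/(N_gp(N_gp−1))]·
[Σs_i/N_v], 0 when a single level is present. The neighbourhood means are
computed by convolution; enumeration oracles in the test suite verify both
matrices exhaustively on small grids.

## Reliability (ICC)

Per feature, the n-subjects × k-profiles matrix enters a two-way ANOVA and
the absolute-agreement single-measure ICC, with the F-based 95% CI using
Satterthwaite degrees of freedom (the same variant and CI method as the
standard R reliability packages; the mixed- and random-effects forms share
this point estimate). Negative estimates and CI bounds are truncated at
zero, the upper bound capped at one. An all-equal matrix is reported as
ICC 1 with a flag. Subjects with any missing rater value are dropped
listwise (complete blocks are required by the ANOVA), with the dropped count
retained.

Categories use the conventional 0.5/0.75/0.9 thresholds. Because a CI can
span several bands, the primary category is taken conservatively from the CI
*lower bound*, with the point-estimate category and a straddle flag reported
alongside; boundary values fall into the lower band. Features constant
across all subjects and raters are excluded from category counts and
flagged.

## Survival screen

Each feature column is standardised to mean 0, sample-SD 1 (the SD = 1
contract holds under either SD convention; sample SD matches the default of
the usual statistical environments) and fitted alone in a Cox
proportional-hazards model via lifelines with Efron tie handling. Wald p
values are reported, binned at 0.05/0.1 for the heat-map output; constant
features, non-convergent (monotone-likelihood) fits and under-powered
cohorts become flagged cells rather than exceptions. No multiple-testing
correction is applied across the 17 features, matching the univariable
screening design the package emulates; a Benjamini–Hochberg column can be
added by the caller from the raw p values.

## Synthetic data

**Phantoms.** Ellipsoidal masks (optionally lobulated by a low-order
angular modulation of the radius) on anisotropic CT-like grids (default
0.97 × 0.97 mm in-plane, 3 mm slices), filled with base intensity +
spatially correlated Gaussian texture (Gaussian-filtered white noise,
rescaled to a target SD) + independent voxel noise, all in HU-scale units.
The two texture knobs act on features as intended: the correlation length
raises NGTDM coarseness and GLCM correlation; the amplitude sets the ROI
intensity range and therefore everything discretised over fixed windows.
What the phantoms do *not* emulate: CT reconstruction physics, partial
volume effects at boundaries, contour variability, and inter-scanner
protocol differences — so passing tests show the settings mechanism, not
fidelity to any clinical distribution.

**Cohorts.** Event times are exponential with hazard h₀·exp(β·z) and
administrative censoring at the follow-up horizon; h₀ is calibrated by root
finding so the *expected* event count hits the target fraction. The default
calibration (108 subjects, 28/108 events, 2.2-year horizon) is the scale of
a single-centre head-and-neck radiotherapy cohort and sizes every survival
demonstration; it is a configuration default, not a claim of distributional
fidelity.

**Ratings.** `value(s, r) = subject + rater + noise`, all Gaussian with
stated SDs, giving a known theoretical absolute-agreement ICC
σ²_s/(σ²_s+σ²_r+σ²_e) for estimator calibration and CI-coverage checks.

All generators are pure functions of spec + seed.

## The inversion demonstration

`demo_inversion` plants the hazard on a single latent: texture amplitude
(β = 1.2 per SD, sized so the feature-level hazard ratios land at the
magnitudes typical of a strong prognostic radiomic feature), with
correlation length fixed at 3 voxels and a 15 HU noise floor. Joint entropy
over a fixed window tracks amplitude positively (more occupied bins); over
the ROI range it tracks amplitude negatively (the noise floor shrinks
relative to the range, so the discretised field is smoother). An earlier
two-driver design that also planted risk on correlation length was
abandoned: the length → ROI-range entropy coupling is non-monotonic
(smoothing first lowers entropy, then hands dominance to the noise floor,
which raises it), making the direction unstable.

## Problem sizes and numerical conventions

Default grids are 40 × 48 × 48 voxels (~2.5–4 k ROI voxels per phantom);
demonstration cohorts use 10–15 phantoms for reliability studies and 108
for survival, which the package processes in seconds per profile — chosen
as the smallest sizes at which every mechanism is stable across seeds.
Degenerate inputs (flat ROIs, isolated voxels, constant features, cohorts
with fewer than two events) resolve to flagged conventions rather than
errors throughout. Ties in category thresholds go to the lower band; the
coarseness cap is 10⁶; ε guards default to 1e-12 and live in the profile.

## Known limitations

- One engine under many profiles cannot reproduce implementation-level
  divergence between real platforms (e.g. closed-source sphericity
  differences); it isolates the settings mechanism only.
- The merged (rather than per-direction averaged) GLCM aggregation is a
  convention; platforms are not explicit about theirs, and no ground truth
  exists here to prefer one.
- Mesh anti-aliasing trades corner fidelity for convergence on smooth
  shapes; masks with genuinely sharp ridges lose a resolution-dependent
  fraction of surface area.
- Survival generation is exponential with administrative censoring only; no
  competing risks, no covariate-dependent censoring.
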