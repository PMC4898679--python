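# Methods

`gyriconn` implements a multimodal surface + diffusion analysis that asks
whether local cortical folding (gray matter) and the diffusivity of the
white-matter tracts attached to the folded cortex are coupled, and whether
a group difference in diffusivity is better explained by diagnosis or by
folding. Because no real imaging data ship with the package, every stage is
exercised on synthetic cohorts with planted, known effects; this note
records the models, the defaults, and what the synthetic world does and
does not establish.

## Local gyrification index

The lGI at a vertex is the ratio of buried pial surface to visible outer
surface inside a geodesic disc:

    lGI(v) = area( pial patch corresponding to disc(v, r) ) / area( disc(v, r) on hull )

The outer hull is the morphological closing of the pial solid with a
spherical element (default diameter 15 mm — the convention of the standard
lGI implementation; the geodesic radius default is 25 mm, likewise the
cited convention). Implementation: the pial interior is voxelized (flood
fill of the exterior against a sealed surface crust), converted to a
signed-distance field that is exact within a thin band around the surface,
closed via Euclidean distance transforms, and re-meshed with marching
cubes on the (lightly smoothed) distance field followed by a few Taubin
iterations. Marching on a signed-distance field rather than a binary mask
keeps the hull sub-voxel accurate on convex regions: a radius-50 mm sphere
re-meshes with < 0.5 % area error at 1 mm pitch, and per-vertex lGI on
that sphere stays within 0.02 of 1.

Geodesic discs use Dijkstra graph distances on hull edges (adequate at the
target mesh resolutions; an exact polyhedral geodesic would be an
upgrade). Pial-to-hull correspondence is nearest-point projection. Patch
membership near the disc boundary is graded linearly over one vertex-cell
width on both surfaces — a partial-coverage correction that removes the
cell-quantization noise that otherwise dominates the estimate at coarse
mesh resolution. Cluster summaries are area-weighted vertex means.

Sulcal depth is the signed pial-to-hull closest-point distance, thickness
the symmetric white/pial closest-point distance, and curvature the
cotangent Laplace–Beltrami mean curvature.

## Surface smoothing and vertex statistics

Scalar maps are smoothed by explicit heat-equation iterations of the
clamped cotangent Laplacian with lumped (barycentric) masses, with the
total diffusion time matched to the requested Gaussian FWHM
(t = FWHM²/16 ln 2). The step size respects the positivity bound, so the
operation conserves the lumped surface integral exactly and preserves
positivity.

The vertex model is `Y = b0 + b1 Group + b2 Center + b3 Age + b4 FSIQ + e`,
with the group effect tested as t = b1/SE(b1). Cluster-level familywise
control uses nonisotropic random-field theory: the t map is thresholded at
a cluster-forming quantile (default vertex-wise p = 0.001, two-tailed —
the common convention in surface-statistics toolboxes; configurable),
connected components are measured in resel units using locally estimated
residual smoothness, and cluster p-values come from the expected-Euler-
characteristic / exponential-extent approximation evaluated for the
Gaussianized field. Two implementation choices matter for calibration and
were validated on null simulations:

- The per-vertex smoothness map (squared gradients of unit-normalized
  residuals along edges) is noisy at realistic df, and its noise is
  correlated with threshold exceedances; using it raw makes the test
  anticonservative (FWER ≈ 0.12 at nominal 0.05 in our null study). The
  map is therefore regularized by surface smoothing at the globally
  estimated FWHM before warping cluster areas.
- Euler-characteristic densities use the Gaussianized threshold rather
  than the t-field densities, and two-tailed cluster p-values take the
  Poisson union over the two tails' expected cluster counts (doubling is
  an upper bound that visibly over-corrects against the permutation
  oracle). With the regularized resels this puts the familywise error at
  0.043–0.053 over 1000 smooth null simulations (n = 32, FWHM ≈ 3.6 edge
  lengths, subdivision-4 sphere).

A within-centre permutation test (max cluster mass or resel extent) is the
distribution-free oracle; RFT and permutation p-values agree within 0.03
in the p ∈ [0.01, 0.2] range on the simulation fixtures. Cluster ROIs are
mirrored through the exact symmetry of the icosphere to produce
contralateral control ROIs.

## Tractography

Deterministic tensor-line tracking: one seed per voxel with FA ≥ 0.2,
bidirectional Euler integration with 1 mm steps along the principal
eigenvector of the component-wise cubic-spline-interpolated tensor, sign
continuity by dot product with the previous direction, termination on
voxel-wise FA < 0.2 at the candidate point, turning angle > 35°, or
leaving the volume, and a 20 mm minimum length. The stopping rule reads
the voxel-wise FA map (not the interpolated FA): interpolation smears the
sharp bundle boundary over ~2 voxels, which would otherwise let
streamlines overshoot planted bundle ends by 4–6 mm; with the voxel-wise
rule a planted 60 mm bundle is recovered at 59 ± 1 mm.

Surface ROIs are voxelized with a configurable band (default 1–1.5
voxels) to absorb surface/volume discretization gaps. Dissection keeps
streamlines with at least one endpoint in the ROI mask (pass-through
streamlines excluded); subject-level tract metrics (FA/MD/AD/RD from the
interpolated tensor eigenvalues; AD = λ1, RD = (λ2+λ3)/2) are unweighted
means over streamlines of along-streamline means.

## Length mixture classification

Pooled streamline lengths are tested for multimodality with Hartigan's
dip, computed from greatest-convex-minorant / least-concave-majorant fits
on either side of every candidate modal point (floored at 1/2n, the
classic convention; validated against an independent qhull-based brute
force). The dip is location-scale invariant but — contrary to an
occasionally repeated claim — not invariant under general monotone
transformations. The p-value is Monte Carlo against the uniform null.

Mixtures are 1-D Gaussian, fitted by EM with quantile-seeded k-means
initialization, restarts, a per-iteration non-decreasing-likelihood
assertion, and a small variance regularization that guards against
collapse onto repeated values (streamline lengths are step-quantized; the
pipeline additionally dithers lengths by ±half a step before modeling).
The component count is chosen by split-half cross-validation: the
smallest k whose held-out log-likelihood gain from k+1 falls below a
relative threshold (default 1% — an explicit operationalization of "no
considerable increase"). Class cut-offs are the weighted-density crossings
between adjacent components (closed-form quadratic, grid fallback when no
crossing lies between the means); short = [min, cutoff), long =
[cutoff, 150 mm], longer streamlines excluded and counted.

## Coupling statistics

Per-metric group GLMs (group + centre + age + FSIQ) report F(df = 1) for
the group effect over the 8 tract-class × metric family with Bonferroni
control (0.05/8 = 0.00625). Moderation models
`DTI ~ Group + lGI + Group×lGI + Center` (and the reverse) standardize
both continuous variables before forming the interaction. SURE is
feasible GLS on the stacked two-equation system with the cross-equation
residual covariance estimated from per-equation OLS; the cross-equation
equality test is the Wald chi-square (df = 1) on the joint GLS covariance,
asymptotically equivalent to the constrained-vs-free system comparison.
lGI and diffusivity are z-scored before SURE so cross-equation
coefficients share a scale (required for "effect A exceeds effect B" to
be meaningful; type-I error of the test is 0.05–0.06 in null
calibration). Partial correlations residualize both variables on the
covariates, with p from the t transform at n − k − 2 df.

## The synthetic world

Surfaces are icospheres with concentric sinusoidal ripples confined to a
patch (`r(θ) = R + A·w(θ)·cos(2πfθ)`, θ the angle from the patch centre,
w a cosine-squared taper): the simplest folding proxy whose area admits an
exact 1-D quadrature oracle, with an independent rolling-ball oracle for
the hull profile. Defaults: R = 50 mm, f = 3 cycles/radian (ripple
wavelength ≈ 17 mm, resolvable at subdivision 4 and bridgeable by the
15 mm closing element), A = 5 mm at the mean lGI. The white surface is a
curvature-limited inward offset (2.5 mm, capped below the local radius of
curvature at fold crests and troughs — where real cortex also thins);
note this makes measured thickness strongly folding-coupled, so the
CT-partialled lGI–diffusivity correlation is attenuated in the synthetic
world relative to real data.

Tensor phantoms plant tube-shaped bundles (straight segments and circular
U-arcs bounded by their endpoint planes) with the principal axis along the
centerline tangent in a sub-threshold isotropic background
(0.7×10⁻³ mm²/s). The cohort phantom attaches ~10 U-fibers (lengths
21–29 mm, golden-angle spread under the patch) and three long bundles
(55–70 mm) per hemisphere; the mirrored control hemisphere carries the
same architecture without planted effects. Bundle λ1 carries the
subject's axial diffusivity; λ2 = λ3 = 0.55×10⁻³ puts FA ≈ 0.4 and MD in
the observed case-control range.

Cohorts are 51 cases / 48 controls over two centres with matched age
(18–43) and FSIQ. The case-control effects: a latent lGI offset of 0.135
(≈ 1.1 SD; mapped to fold amplitude at 5 mm per lGI unit), and a
short-tract AD difference of 0.023×10⁻³ mm²/s against a within-group SD
of 0.04×10⁻³ — the effect size jointly implied by the published group
means (1.10 vs 1.08 ×10⁻³, SD 0.04) and group F (≈ 8) for short-tract
axial diffusivity. Most of the AD difference (0.018×10⁻³) is routed
through the lGI coupling, with a small direct group term (0.005×10⁻³),
matching the finding that diffusivity differences are primarily related
to gyrification rather than diagnosis. Note this effect size implies only
~50 % power at the Bonferroni-corrected threshold with n = 99 — a single
simulated cohort reproduces the corrected-level AD significance only
about half the time, which is a property of the published effect size,
not of the implementation.

Problem sizes for the shipped studies were chosen for single-CPU desk
scale: subdivision-4 meshes (2562 vertices), 2 mm phantom voxels on a
64³ grid, 12 mm smoothing (≈ 3.6 edge lengths, mirroring the ratio of the
study's 5 mm kernel to its far finer meshes), dip/mixture modeling on a
2000-length subsample, and 500–2000 replicates for the calibration
studies.

## What passing tests do and do not show

The synthetic cohorts have exactly Gaussian noise, shared mesh topology
across subjects (no registration error), a rotation-free affine (no
cross-modal registration), single-fiber tensors (no crossing fibers, no
CSF partial volume beyond bundle-boundary blending), and fixed bundle
geometry across subjects. Passing the acceptance studies therefore
demonstrates the correctness and calibration of the algorithms under
their stated assumptions — not robustness to registration error,
scanner noise, crossing fibers, or anatomical variability, which the
source analyses must additionally contend with.
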