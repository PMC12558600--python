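# Methods

This note documents the models and numerical choices behind `doseforge`:
what each degradation technique computes, the parameters that matter, what
the synthetic phantoms do and do not emulate, and the design decisions taken
where more than one reading was defensible.

## Geometric feature fields

All spatial control flows through a feature field λ ∈ [0, 1] congruent with
the dose grid. Conventions:

* Arrays are (z, y, x); spacing is mm per axis; distances are computed in
  physical millimetres with anisotropic voxel spacing (`scipy.ndimage`
  Euclidean distance transform with per-axis sampling).
* Normalization is min–max over voxels inside the body only; every voxel
  outside the body is then set to λ = 1, i.e. excluded from modification. A
  constant raw field inside the body is degenerate and maps to 0 (logged).
* The sigmoid-like remap is `f(λ) = u^β / (u^β + (1 − u)^β)` with gain
  `u = λ^(−ln 2 / ln fwhm)`. It fixes f(0) = 0 and f(1) = 1 and crosses 0.5
  exactly at λ = fwhm (the gain maps fwhm ↦ ½); β sets the steepness. This
  is the only parameterization under which the `fwhm` parameter names the
  half-max point, which is why it was adopted.
* Angular components are 2D, evaluated per axial slice against slice-wise
  structure centroids (robust to cross-sections that drift with z): each
  voxel's value is the planar angle at the target centroid between the voxel
  direction and the ray toward the OAR centroid, normalized by π. Slices
  beyond the structures' z-extent plus a 3-slice margin are set to 1 (no
  angular effect). Technique 1 uses the z-extent of either structure
  ("union"); technique 2 only slices containing both ("intersection").
  Within the extent, slices missing a structure inherit the nearest
  populated slice's centroid; coincident centroids on a slice define the
  angle as 0 there (both logged).
* Weighted component sums are clipped to [0, 1] before kernel construction.
  Unclipped values above 1 would make the off-centre kernel entries 1 − λ
  negative and the weight normalization ill-defined; the directional clamp
  (below) makes the clip behaviorally safe.

## The position-dependent convolution

At each voxel the kernel has centre weight 1 and off-centre weights 1 − λ,
normalized to sum to 1, so λ = 1 is the identity and λ = 0 a uniform box
blur; the result is multiplied by s(λ, a) = (1 − a)λ + a. Both published
footprints are in-plane: (1×5×5) for the OAR boost, (1×3×3) for
conformality erosion.

Implementation: since all off-centre weights are equal, the per-voxel kernel
sum reduces to a closed form over the plain neighborhood box sum, computed
with `uniform_filter` — algebraically identical to realizing the kernel at
every voxel, and verified against a naive triple-loop oracle to 1e-10 in the
tests. Edges use replicate padding; among the standard paddings it is the
one that does not dilute dose at the body edge with artificial zeros.
Arithmetic is double precision throughout; dose is never quantized.

Post-processing:

* Directional clamp — voxel-wise maximum against the original for the boost
  (dose may never decrease), minimum for the erosion (never increase). This
  removes the small opposite-direction updates the blur would otherwise
  introduce near structure boundaries.
* Hotspot suppression (boost only) — a single pass resetting every voxel
  above 104% of the prescription to 98% of its value. With multiple
  prescription levels the highest one is used. The pass is deliberately not
  iterated to a fixed point; inputs between 104% and ~106.1% of Rx land
  back under the threshold after one pass, and the technique's own scaling
  bound keeps outputs out of the regime where a second pass would matter.
  Applied to all voxels; in-target doses do not trigger it in practice
  because the target protection (below) caps in-target scaling at
  s(0.98, 1.7) ≈ 1.014.

## Technique 1 — OAR-dose boost

Per OAR in the chosen group: ρ = sigmoid(normalized distance outside the
OAR; fwhm 0.05, β 5) and φ = sigmoid(normalized angular distance; fwhm 0.05,
β 5); the member's feature is clip(ρ + 0.3·φ, 0, 1). Members merge by
voxel-wise minimum (any member may open the map). The target union
contributes protection: sigmoid of its normalized interior depth (fwhm 0.09,
β 5) rescaled to [0, 0.98], defined as 0 outside the targets (no protection
there). The final λ is the voxel-wise maximum of the merged OAR feature and
the target protection — the stronger constraint wins — and the scaling
parameter a ranges over 1.1–1.7 (1.7 is excluded from the single-target
pelvic default range, where it produces unrealistically hot plans). Values
outside the validated range are allowed with a warning.

The 0.98 ceiling, rather than 1.0, deliberately lets the target pick up a
small (≲1.4%) dose increase so that the boosted region blends into the
target dose rather than abutting it with a seam.

## Technique 2 — conformality erosion

Three components around the high-risk target (the target with the highest
prescription): (1) the unsigned distance to the target border evaluated on
both sides, remapped with fwhm 0.01, β 15 — a narrow open band hugging the
border where the high-dose conformality is uniformly reduced; (2) the
outside-only distance, fwhm 0.05, β 10; (3) the angular distance toward the
over-spared OAR group, fwhm 0.2, β 10, restricted to slices containing both
structures ±3. Components 2 and 3 combine per member as clip(c2 + 0.3·c3)
(the same 0.3 angular weight as technique 1, which the source material
implies but does not restate) and merge by minimum; the final map is
clip(0.4·c1 + merged, 0, 1). Scaling a ranges over 0.95–0.99, bounding the
voxel-wise decrease at 1–5%.

Note the a → 1 limit: the scaling vanishes but the kernel smoothing does
not, so the technique at a ≈ 1 converges to the (clamped) smoothing
operator, not to the identity. This is inherent to the construction — the
blur is itself part of the intended conformality loss.

## Technique 3 — target hotspots

1–4 hotspots (uniform draw when unspecified); each is a biased random walk
inside the high-risk target with ⌊75 / n_hotspots⌋ steps ("walk size" counts
steps; revisits mean the visited set can be smaller). Steps move one voxel
±y/±x with probability 0.9 (split evenly over the four in-plane moves) or
±z otherwise; steps that would leave the mask are resampled, keeping the
walk in-target (spillover through dilation/smoothing is accepted). Each
walk's visited voxels get a scale drawn uniformly from [1.07, 1.13]
(overlapping walks keep the larger scale); the multiplier map is then
grey-dilated with a (1×3×3) footprint and box-mean smoothed with a (1×5×5)
footprint, and multiplied into the dose. The smoothing is applied to the
excess over 1 so that the multiplier is exactly 1 away from the walks and
never below 1 anywhere (a box mean of values ≥ 1 cannot undershoot; doing
it this way also keeps the filter's float round-off out of the far field).

## DVH metrics and statistics

ΔDmean, ΔDmax, ΔV99% and ΔV95% are relative changes ((new − old) / old);
ΔV107% is absolute in cm³ because high-quality baselines have (near-)zero
V107%, making a relative delta undefined. DVH quantities are voxel-count
based with no sub-voxel interpolation — mask-level granularity; Dmax is the
single-voxel maximum (no D0.03cc smoothing). Zero-baseline relative metrics
are reported as NaN and flagged, never silently zeroed. No multiple-testing
correction is applied.

The working significance test is the one-sample, one-sided Wilcoxon
signed-rank test of the per-case deltas against zero (exact p-values where
the sample size permits), with Shapiro–Wilk normality reported alongside but
never used as a gate. The named two-sample rank-sum test is also provided
(`ranksum_compare`) for comparing the original and degraded metric
populations directly, but the stated hypotheses are about paired deltas, so
the signed-rank form is the default; every report records which was run.
Cohort-level checks pool one delta per case for a fixed technique and
scaling parameter.

## Synthetic phantoms

No clinical data ships with the package; phantoms stand in for predicted
VMAT dose distributions. A phantom is an ellipsoidal body (default semi-axes
70×85×85 mm on a 64×96×96 grid at 2.5×2×2 mm spacing) containing spherical
or concentric-shell targets and ellipsoidal OARs. The dose model: inside a
target, Rx·(1 + ε) with multiplicative Gaussian noise ε (σ = 0.5% of
prescription — large enough to avoid degenerate DVH steps, small enough to
keep the plan under the 104% ceiling); outside, each target contributes
Rx·max(bath, exp(−d/ℓ)·(1 + ε)) with decay length ℓ = 15 mm and a low-dose
bath at 15% of prescription, the voxel taking the maximum contribution;
clipped at 104% of the highest prescription and zero outside the body. The
defaults mimic VMAT-like gradients: fresh phantoms have essentially complete
V95% target coverage and a compliant global maximum.

Two default layouts are provided: a head-and-neck-like phantom with three
concentric shell targets at 7000/6300/5600 cGy (high/mid/low risk) and
eight OARs in five groups (esophagus+larynx, brainstem, optics, parotids,
cochleae), and a pelvic-like phantom with a single 4500 cGy target and
bladder, rectum and femoral-head OARs. Geometry, not anatomy, is what the
techniques consume — the named ellipsoids only fix plausible distances and
angles. Cohorts jitter target radii (×0.92–1.08, one factor per case so
shells stay nested), shift structures by a few mm, and draw independent
noise; cohort generation is a pure function of (n, spec, seed). The standard
experiment cohort is 20 single-target phantoms with the bladder adjacent to
the target — sized so the full significance reproduction runs in well under
a minute on one CPU.

What the phantoms do **not** emulate: CT anatomy, beam/fluence structure and
deliverability, the dose texture of real optimizers, and in particular the
low-dose-region artifacts of model-predicted dose distributions. Passing
tests therefore demonstrate the correctness and controllability of the
degradation operators on smooth, well-behaved inputs — not visual realism on
clinical plans, which requires expert review.

## Degenerate inputs and tie-breaks

* Empty masks are rejected everywhere with a clear error naming the mask.
* A mask too small for a random walk to move leaves the walker in place
  (flagged in the log).
* Multi-target plans use the prescription-maximizing target as "high-risk";
  the hotspot-suppression threshold uses the highest prescription.
* All-zero delta samples make the signed-rank test degenerate; the result
  carries p = 1 and a degenerate flag rather than an exception.

## Known limitations

* Degradations are applied directly to the dose grid; the cascading effects
  a real replan would have on other structures are not modeled.
* An OAR partly inside the target receives a reduced boost (the target
  protection wins there) — accepted behavior, no compensation.
* The conformality erosion also lowers the target's interior dose by up to
  ~3% (the narrow-band weight saturates at 0.4 + angular contribution deep
  inside the target); on noisy-but-flat synthetic target doses this shifts
  V99% strongly, more so than the near-border effect alone would.
* The convolution is correctness-first: no separable/FFT optimization is
  attempted beyond the closed-form box-sum reduction.
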