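# Methods

## Forward model

A coherently illuminated, dynamically scattering surface produces a speckle
field whose temporal autocorrelation decays with correlation time `τ_c`,
assumed inversely proportional to mean scatterer (blood) speed. A camera
integrating over exposure `T` blurs the speckle, reducing the local contrast
`K = σ/⟨I⟩`. For a Lorentzian field spectrum (`g₁(τ) = e^{−τ/τ_c}`) and
fully developed speckle, triangular-weighted time averaging of `|g₁|²` gives

    K²(x; β) = β { x + (x²/2)(e^{−2/x} − 1) },   x = τ_c/T,

with `β ∈ (0, 1]` the instrumental decorrelation factor (detector-to-speckle
size ratio, polarization). `K²` rises monotonically from `βx` (fast flow,
x → 0) to `β(1 − 2/(3x))` (static, x → ∞); both limits are used as numerical
series where the direct expression loses precision (x > 10⁶ switches to the
asymptotic series; `expm1` keeps the small-x branch exact). Monotonicity
guarantees a unique inverse; the scalar inverse brackets the root and solves
with Brent's method to 1e-12 relative, the map-level inverse seeds Newton
iterations from a precomputed monotone grid (both agree to <1e-8; round-trip
identity over five decades of `τ_c/T` is tested to 1e-6).

Relative flow is reported as `1/τ_c` in arbitrary units. Only ratios to the
pre-stroke baseline are meaningful; absolute velocity calibration is out of
scope. Pixels with `K² ≥ β` cannot arise from finite `τ_c` and are flagged
clipped (flow 0) rather than silently saturated; `K ≤ 0` is flagged invalid.
For real data `β` can be estimated as the `K²` plateau over a
user-designated static region (`estimate_beta`); simulated detectors use
β = 1.

## Contrast estimation

The spatial estimator computes sd/mean over an odd sliding window per frame
and averages the per-frame maps over an analysis bin; the temporal estimator
(per-pixel sd/mean across ≥8 frames) serves as an internal cross-check. The
window default is 7 px, the common compromise at 640-px resolution between
variance stability and boundary resolution. Two conventions matter:

- the border of width `(window−1)/2` and any pixel with nonpositive window
  mean are flagged invalid and excluded from all downstream area sums;
- a windowed sd over correlated speckle (grain ≈ 2 px) is shrunk by the
  within-window sample correlation: ≈8% low at window 7, ≈2% at window 15.
  The shrinkage acts as a nearly constant factor on `K` (an effective β), so
  it cancels in baseline-normalized flow ratios; quantitative
  contrast-vs-theory checks therefore use whole-frame contrast on uniform
  regions or a 15-px window.

The default analysis bin is one minute of frames per time point, matching
the per-minute axis of intraoperative monitoring; the scaled-down test
scenarios use 8–16 frames per bin, which the CBF₅₀ error budget below
accounts for.

## Synthetic dynamic speckle

The generator is the physical realization of the forward model. Each
sub-exposure field is a spatially band-limited complex circular Gaussian
field: i.i.d. complex normal Fourier coefficients inside a circular low-pass
(cutoff `1/(2·speckle_size)` cycles/px, speckle grain default 2 px =
Nyquist-sampled), normalized to unit mean intensity. Across the `M`
sub-steps spanning one exposure the field evolves as AR(1) with per-pixel
coefficient `exp(−Δt/τ_c)`, and the frame is the mean of `|E|²`. The
discrete sum reproduces the closed-form `K²` with O(1/M) bias (<1% in `K²`
at the default M = 64 for `T/τ_c ≤ 16`); exposures covering more than `M/4`
correlation times are rejected as undersampled, so the fastest-flow sweep
point (`τ_c/T = 0.05`) is rendered with M = 128. β < 1 is emulated exactly
by mixing the dynamic intensity with a constant pedestal at amplitude √β.
Frames are seeded individually from `(scenario seed, frame index)`:
identical configurations are bit-reproducible, and disjoint renders of a
static phantom coincide.

Consecutive frames are *independent* speckle realizations (the frame
interval exceeds `τ_c` by orders of magnitude at 50 fps and millisecond
correlation times), which is faithful for contrast statistics but leaves
nothing for image registration to lock onto. Real frames share static
anatomical reflectance; the generator emulates this with an optional smooth
multiplicative pattern (`anatomy_contrast`, default off; 0.4 with 4-px
correlation length is realistic). Because sd/mean is invariant to locally
constant scaling, a smooth pattern is nearly invisible to windowed contrast;
the 4-px pattern used for motion scenarios does inflate windowed `K` by a
few percent and biases recovered areas by ~5–10% — as real vasculature does
— so quantitative recovery scenarios leave it off and motion scenarios
compare aligned against motion-free results under identical settings.

## Occlusion scenario

The hypoperfused territory is a disc (real territories are vascular; the
geometry is irrelevant to pipeline correctness) rasterized to exactly the
pixel count nearest `area/pitch²` (order statistics of pixel distance from a
tie-broken fractional center), growing linearly to the configured target at
15 min of illumination and plateauing after. Flow inside the territory drops
to `occlusion_flow_fraction` (default 0.3, a 70% reduction); an inner core
of half the territory radius — the illuminated vessel focus — drops to
`core_flow_fraction` (default 0.03, near-complete occlusion), so the >50%
territory statistic and the strictly->85% regional occlusion check are both
realizable, and the occlusion check passes reliably even at reduced image
sizes where the contrast window dilutes the small core. τ_c is
`baseline_tau / flow` pixelwise (default baseline 1 ms at 5-ms exposure,
x = 0.2). The ipsilateral hemisphere defaults to the left half-image; pixel
pitch defaults to 0.0109 mm/px (640 px across a 7-mm window) and scales
inversely when images are rendered smaller.

### CBF₅₀ error budget

With 0.3/1.0 flow contrast across the boundary, the 50% threshold falls
almost exactly at the mixing midpoint of the two contrast populations inside
a boundary-straddling window, so the systematic boundary shift is <0.1 px.
Remaining error is stochastic: with 16 frames per bin and a 7-px window,
per-pixel normalized flow carries ~15–20% noise, giving false-positive and
false-negative rates that largely cancel. Measured end-to-end recovery of
planted 19.5 and 12.4 mm² territories at 256 px is −2%; the acceptance
tolerance is 5%. At 64 px (pipeline smoke tests) a single boundary pixel is
~20% of the disc area, so only coarse agreement is asserted there.

## Motion and registration

Jitter is injected as per-frame Fourier-domain translation (exact for the
periodic band-limited synthetic frames) with the schedule stored as ground
truth. Registration is rigid translation only — the cranial window is fixed
to the skull — via frequency-domain cross-correlation of mean-removed,
variance-normalized frames, integer peak plus separable 3-point quadratic
refinement, with confidence reported as the ratio of the main peak to the
strongest peak outside a 5-px exclusion zone. Inputs are pre-smoothed
(Gaussian σ = 2 px by default in `align_stack`) to suppress the
decorrelating speckle component; the recommended reference is the temporal
mean of a pre-ischemic baseline interval, which averages the speckle away.
On 256-px scenarios with 0.4-contrast anatomy, planted ≤5-px jitter is
removed to <0.3 px per frame and the aligned CBF₅₀ matches the motion-free
value to <1%.

## Lesion and infarct volumetry

Each slice is smoothed with a 3 × 3 Gaussian kernel (σ = 1 px, unit sum,
reflective borders) and thresholded at 75% of its own maximum — the lesion
(T2 hyperintensity) and infarct (TTC pallor) are the bright class of the
analyzed channel. Volume is `Σ slice area × thickness` exactly. Two
conventions:

- the per-image threshold presupposes a lesion-bearing image; a slice
  participates only if its smoothed maximum reaches 75% of the volume-wide
  maximum, otherwise a lesion-free slice would threshold on its own
  background. A stack with no lesion anywhere and a bright uniform
  background is still misclassified — an inherent limit of the relative
  threshold, shared with the original procedure;
- TTC analysis reuses the same 75% rule on the pallor channel; manual
  planimetric outlining is not reproducible, so this is a deliberate
  substitution.

The lesion phantom plants an ellipsoid (axis ratios 0.9/1.0/1.2) rasterized
by order statistics to exactly the voxel count nearest `volume/voxel` with
tie-breaking center offsets, intensity 100 over background 60 with Gaussian
noise (sd ≤ 5% of lesion intensity, the separability precondition of the
75% rule). Recovery of planted volumes {10…63.7} mm³ at 5% noise is within
10%; the residual bias is the smoothed-edge crossing sitting slightly
outside the true boundary (~0.3 px of perimeter per slice).

## Scores and statistics

NSS cohorts draw a latent per-rat severity from N(group mean, group sd),
add examiner/trial noise (default sd 0.5, 3 examiners × 3 trials), round to
the integer scoring grid, clip to [0, 18], and decompose totals into
category scores proportionally to the category maxima (6/2/6/4) with
deterministic largest-remainder tie-breaks. Per-rat scores are means over
records. Group summaries are mean ± SEM (n−1 sd over √n); comparisons use
the Welch t-test by default (the pooled-variance variant is available), with
a p = 1 convention for two zero-variance groups with equal means. Time-series
comparisons run one t-test per bin with no multiple-testing correction by
default (a Bonferroni toggle is provided). Relative group differences are
`100·(conscious − anesthetic)/anesthetic`, rounded to one decimal — the
convention that reproduces all three published percentages (58.9, 28.3,
46.9) from the published group means. Simulated per-animal spread is set
from the published SEMs (sd = SEM·√11), with volumes clipped at small
positive floors; clipping slightly biases group means upward when the sd is
large relative to the mean (TTC volumes), which matters for realism, not
correctness, of the group pipeline.

## Study pipeline

`run_simulation` writes a complete two-group dataset (default 11 + 11 rats;
per-rat speckle stacks for a pre-onset baseline bin and bins at 1–25 min —
recording is capped at 25 min post occlusion — plus T2-like NIfTI, TTC-like
TIFF, NSS CSV, and ground-truth JSON). Default image size is 128 px (scaled
down from the 640-px acquisition; pitch scales to keep areas in mm²) so a
full study simulates in minutes. `run_analysis` is fully deterministic given
a dataset: per rat it (optionally) aligns stacks to the baseline-mean
reference, computes per-bin flow maps, CBF₅₀/CBF₊ series, the occlusion flag
over a small ROI at the (dataset-recorded) illumination focus, volumetry and
NSS totals; rats failing the occlusion criterion are excluded with a logged
reason. The report echoes every threshold and parameter for provenance and
round-trips through JSON bit-identically.

## Known limitations

- Disc-shaped territories, intensity-only "MRI/TTC" contrast, and
  category-level NSS are stand-ins: the generator validates the analysis
  pipeline, not biological variability in lesion shape or item-level
  scoring rubrics.
- Independent frames understate temporal correlations of real 50-fps data;
  temporal-contrast estimators on real data see correlated samples.
- The relative 75% threshold misclassifies lesion-free volumes (see above).
- Registration handles rigid translation only; rotation and out-of-plane
  motion are out of scope.
- The windowed contrast shrinkage (an effective β) is documented rather
  than corrected; it cancels in normalized ratios but biases absolute
  `τ_c` estimates at small windows.
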