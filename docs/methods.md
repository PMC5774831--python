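# Methods

## Model and assumptions

A wound-healing assay images a cell-free region ("wound") in a confluent
monolayer closing over time. The package's central quantity is the
concerted cell velocity

    v(t) = -(d/dt) Â(t) / P̂(t),

the rate of area loss normalized by the length of the advancing front. If
every point of the front advances at the same normal speed v, then
dA/dt = -v·P exactly, for any wound shape; v is therefore comparable across
wounds of different geometry, whereas the raw area slope scales with the
perimeter. The estimate assumes: one wound per field; cells brighter than
the wound (natively or after the gradient transform); the front advances
inward (a transiently retreating front gives negative v, which is reported,
not clipped).

## Detection

Per frame, in order: Gaussian smoothing (scale σ, reflective boundaries,
kernel truncated at 4σ — results are insensitive to the truncation radius
at the default σ); confluency intensity I_c = Σp²/Σp computed on the
smoothed frame (a config switch allows the raw frame; the smoothed variant
keeps threshold and compared pixels on one intensity scale); binarization
at p < β·I_c; 4-connected component labelling; spatial gating — components
whose centroid lies farther than r from the reference point are discarded,
where the reference is the midpoint of the wound centroids of the first two
frames (those two frames themselves are gated only by size); largest
surviving component; hole filling (simply connected topology, so bright
drifting cells inside the wound do not perforate it). Area is the pixel
count. Strict inequality puts ties in the cell phase; pixel coordinates are
0-based (row, col); areas convert to μm² via pixel_scale².

Detection variance: the full detection is replicated at n_thresholds = 5
values evenly spaced over β ± Δβ (odd count, so β itself is sampled), and
the per-frame mean and ddof=1 variance of area and perimeter are taken
across the replicates in which a wound was found. A frame with no wound at
any threshold is flagged closed. Replicates that lose the wound while
others keep it simply drop out of the statistics (n_found is recorded);
this leaves the mean unbiased at the cost of understating variance in the
frames straddling closure, which the closure filter then mostly removes.

Closure: from the first time point whose area falls below
closure_fraction = 0.005 of the image area, all remaining points are
excluded from model training (re-opening never re-admits points).

### Parameter guidance

σ encodes the length scale of intensity texture to suppress. The defaults
(σ = 18 px, β = 0.3, Δβ = 0.08, r = 100 px at 1.3 μm/px) are tuned for real
fluorescent high-content-screening images, where cell texture is strong and
I_c sits well above the smoothed wound–cell midpoint. The synthetic
fixtures deliberately omit cell texture (see below), so their edges are
ideal steps; `DetectionParams.for_synthetic()` (σ = 2, β = 0.5) places the
threshold at the midpoint of that step, where the detected boundary
coincides with the true one. With a flat two-level image and β = 0.3 the
threshold sits ~0.5σ below the edge midpoint, biasing the boundary ~0.5σ
into the wound — which cancels in the velocity (a constant boundary offset
shifts A and P consistently) but not in the absolute area. All fixture
analyses in the tests and the acceptance script therefore use the
fixture-matched settings.

## Contour tracing and perimeter

The boundary of the (filled) region is traced at the 0.5 iso-level of the
zero-padded mask with marching squares; padding guarantees a closed contour
even for wounds touching the image edge. The padded mask is first
anti-aliased with a small Gaussian (σ_c = 1 px): the iso-contour of the raw
indicator lies on pixel-edge midpoints and overestimates smooth boundaries
by ~5% independent of size, while the regularized field localizes the
boundary to a fraction of a pixel (≤0.8% on rasterized disks r = 20…200,
decreasing with r; convex regions shrink by only ~σ_c²·κ/2, i.e. <0.01 px
at r = 100). Regions too thin to survive anti-aliasing (single pixels,
1-px-wide necks) fall back to the raw binary field. Saddle configurations
follow the convention that keeps the above-level (wound) phase 4-connected,
matching the component labelling. The alternative tracer is Moore-neighbour
8-direction chain coding with whole-pixel turns (length = axial moves +
√2·diagonal moves) — faster, with the classic staircase overestimate
(~5% on disks, always ≥ the sub-pixel tracer on convex regions).

The perimeter is the Euclidean contour length minus the summed length of
segments whose both endpoints lie on the same image-border line — one
geometric rule shared by both tracers, so border-flush wounds are measured
by their interior front only. A pixel-count variant of the border
correction (one unit per border vertex) is available as a config option.
Because the contour is traced on the filled region, interior hole
boundaries never contribute: the perimeter is the advancing front.

## Gaussian-process regression

Area and perimeter series are modelled independently as zero-mean GPs with
kernel k(t,t') = C + (σ_k² + t·t')². In feature space this is the inner
product of [√(C+σ_k⁴), √2·σ_k·t, t²] — a Bayesian quadratic polynomial with
correlated coefficient priors. A constant-speed front has exactly quadratic
area and linear perimeter in t, so the noiseless truth lies inside the
model space while the posterior can still track curvature changes within
the quadratic family. Because the function space has rank 3, posterior
interpolation of arbitrary (non-quadratic) data is not expected; residual
structure is absorbed by the heteroscedastic noise.

Normalization: targets centred and scaled to unit SD (justifying the zero
prior mean), times mapped to [0, 1], detection variances divided by the
target scale squared. A constant series (zero SD) keeps scale 1 and is
reproduced exactly. Hyperparameters (C, σ_k²) are optimized in log space
(bounds e±15) by L-BFGS-B from 10 starts — the origin plus 9 scrambled
Sobol points in [-6, 6]², seeded — maximizing the standard log marginal
likelihood −½yᵀK⁻¹y − ½log|K| − (n/2)log 2π. The noise diagonal carries the
per-point detection variances plus a jitter starting at 10⁻⁸·tr(K)/n and
escalating ×10 to at most 10⁻⁴·tr(K)/n before the fit is rejected. An
optional third hyperparameter (learned homoscedastic noise) exists but is
off by default, since detection variances already quantify measurement
noise. Fits require ≥3 retained points. Predictions are de-normalized
posterior means/SDs; extrapolation beyond the training range is allowed and
announces itself through the rapidly growing polynomial-kernel variance.

For imputation calibration the relevant predictive SD at a held-out
*measured* point is √(posterior function variance + that point's
measurement variance); the posterior function SD alone refers to the latent
curve.

## Velocity and statistics

The profile is evaluated on a uniform grid (default 101 points spanning the
retained measurement range — denser than any realistic frame rate).
dÂ/dt uses second-order central differences (interior grid points only);
halving the grid step changes v(t) by well under 1% on smooth fits. Error
propagation treats the area-derivative and perimeter errors as independent
first-order terms,

    σ_Ȧ = √(σ_A(t+h)² + σ_A(t−h)²)/(2h),
    σ_v² = (σ_Ȧ/P̂)² + (Ȧ·σ_P/P̂²)²,

ignoring the GP covariance between t−h and t+h; that covariance is positive
for this smooth kernel, so the neglect overstates σ_Ȧ — a conservative
choice, flagged here since the spread bars in the outputs inherit it.

Per series: the precision-weighted mean velocity v̄ = Σwᵢvᵢ/Σwᵢ with
wᵢ = σ_vᵢ⁻² capped at 10¹² (a numerically zero σ_v must not swallow the
average), reported with SD (Σwᵢ)^(−1/2); and the OLS slope of the measured
(retained) areas as the conventional readout. Per condition: group mean and
ddof=1 SD of both metrics; against a designated baseline condition,
SNR = (μ_cond − μ_base)/σ_base per metric. SNR is signed; comparisons of
assay windows should use magnitudes (area slopes are negative). A baseline
with zero SD yields an undefined (NaN) SNR.

## Synthetic fixtures

The generator rasterizes a shape eroded inward by d = v·t along its normal
— erosion acts on the analytic shape, never on the raster, so the ground
truth stays closed-form: disk (r0−d), rectangle (inner parallel rectangle),
ellipse as the true inner parallel curve with P(d) = P0 − 2πd (Ramanujan
P0) and A(d) = A0 − P0·d + πd² (Steiner), valid while d < b²/a (validated
at construction), and irregular polygons via Shapely negative buffering
with truth measured on the offset polygon. Frame times are (i+1)·Δt.
Intensities: cells 10 000, wound 500, i.i.d. Gaussian noise (default
SD 100 = 1% of the cell level) clipped to the 16-bit range. Optional
drifting-cell artifacts are bright blobs random-walking strictly inside the
wound (seeded), which the simply-connected fill must absorb. Identical
seeds give bit-identical frames.

The standard single-sequence fixture is a disk r0 = 100 px shrinking at
5 px/h over 16 hourly frames. The multi-condition study fixture draws
per-replicate front speeds lognormally around each condition mean and mixes
disks, rectangles and irregular polygons of varying size, emulating
well-to-well geometry variability; the baseline condition is slow but
moving (v = 1 px/h, relative SD 0.5) — a truly static wound would make both
SNR denominators degenerate (area-slope SD collapses to detection jitter
and sub-pixel motion defeats any velocity estimator), whereas a slow
variable control reproduces the intended comparison: shape heterogeneity
inflates the area-slope spread (slope ≈ −v·P̄) but not the velocity spread,
so the velocity readout yields the larger assay window.

What the fixtures do *not* emulate: cell texture and fluorescence
point-spread (edges are ideal steps), proliferation, uneven illumination,
stage drift, and wounds that change shape for non-frontal reasons. Passing
tests therefore demonstrate the correctness of the measurement chain and
the geometry independence of the velocity — not robustness to real-image
nuisances, which the σ = 18 / β = 0.3 defaults address but which can only
be validated on real data.

## Numerical choices and degenerate inputs

Documented throughout the code: strict threshold inequality (ties → cells);
anti-alias fallback for 1-px regions; closure at the first crossing with no
re-admission; closure at the very first time point rejects the sequence;
wound missing in one of the first two frames falls back to the single
detected centroid (warning), missing in both aborts; GP fits with <3 points
abort the sequence; a replicate aborting inside a study is recorded in the
failure table and excluded rather than fatal. All stochastic components
(fixture noise, artifact walks, GP restart designs) derive from explicit
seeds; study runs spawn per-replicate seeds from the study seed via hashed
label + replicate index, so results are independent of dict ordering and
reproducible byte-for-byte.

## Problem sizes

Default fixture images are 512² px (study fixtures 320², chosen so a full
synthetic study of a few dozen replicates analyses in tens of seconds);
the acceptance computations use the standard fixtures above — 16-frame
single sequences, 4-shape geometry comparison, 50 imputation trials, and a
2-condition × 6-replicate study.

## Known limitations

The area bias of threshold detection under heavy smoothing cancels in v
only to first order (exactly for straight/constant-curvature fronts); for
wounds with features at the scale of σ the velocity at late closure times
inherits curvature-dependent distortion. The weighted mean velocity treats
grid points as independent, which they are not (the GP posterior is
smooth); the reported SD of v̄ is therefore optimistic and is best used to
weight replicates, as done in the study statistics, not as a calibrated
interval. Replicates whose wound closes early contribute fewer interior
grid points with larger σ_v; all retained points contribute to v̄.
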