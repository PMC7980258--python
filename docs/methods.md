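# Methods

## The stochastic growth model

Each regulator concentration follows an Ornstein–Uhlenbeck (OU) process
`dA_i = θ(Ã_i − A_i)dt + dW` with noise correlation `⟨W(t)W(s)⟩ =
2θη²δ(t−s)`, giving stationary deviations `X_i` with mean 0, variance η²
and autocorrelation time 1/θ. The growth velocity is the sum of M products
of N deviations; for M = N = 2 its stationary law is exactly Laplace, and
`Var(F) = M η^{2N}` for any (M, N). Lengths integrate `dL/dt = F` with a
projection at zero (`L ← max(0, L + F·dt)`) — a projection rather than a
reflection, since only non-negativity is required — and are held at zero
before the initiation time.

Integration uses the Euler–Maruyama scheme at dt = 1 s. θ is specified in
min⁻¹ and converted internally (dt enters in minutes); the stability guard
requires θ·dt < 1 in those units. The explicit scheme inflates the
stationary variance by the factor 1/(1 − θ·dt/2): ~1.7% at θ = 2 min⁻¹,
~10% at θ = 11 min⁻¹. Closed-form checks therefore run at θ = 2 min⁻¹;
shape-based comparisons (KS on normalized samples) are unaffected because
the discretized process remains Gaussian per factor.

### Defaults and units

| parameter | default | unit | rationale |
|---|---|---|---|
| M, N | 2, 2 | – | minimal structure with an exact Laplace velocity law |
| θ | 11 | min⁻¹ | a shared velocity relaxation rate λ ≈ 22 min⁻¹ split over N = 2 factors (the velocity of a product of N OU factors decorrelates at Nθ) |
| η | 2 | conc. units | sets the length scale; at 20 min with random initiation the median of >5 µm lengths is ≈ 7.7 µm, matching the observed characteristic length of FLS snapshots (≈ 7.6 µm) |
| dt | 1 | s | explicit-scheme step |
| pixel size | 0.1487 | µm/px | implied by a 2.97 µm / 20 px ROI ratio; configurable |

The stationary velocity sampler draws from the exact OU stationary law
(i.i.d. `N(0, η²)` factors) by default — the infinite-burn-in limit — and
offers an Euler–Maruyama route (burn-in 10/θ, sampling every 5/θ) that is
distributionally identical and is cross-checked against the exact route in
the tests.

### Reaction network

The 2M-species mass-action network (production σ, pairing ρ, complex decay
η_decay) has species steady state `a = √(σ/ρ)` (setting ȧ = 0 in
`ȧ = σ − ρ a²` forces the radical). Fluctuating species follow OU dynamics
reflected at zero; complexes follow `ḃ_j = ρ a_{2j} a_{2j+1} − η_decay b_j`
and the velocity is Σ ḃ_j (proportionality constant 1), optionally with
alternating signs for growth- vs shrinkage-promoting complexes. In the
large-variance limit the velocity distribution is Laplace-*like*: Monte
Carlo shows the limiting signed law (a difference of absolute
normal-product variables) retains a residual KS ≈ 0.02 against an exact
Laplace even at n = 10⁶, so the network test asserts KS < 0.05 together
with a strictly better fit than a moment-matched normal, rather than the
< 0.01 bound that holds for the exact sum-of-products force.

## Inference

- **Laplace MLE**: location = sample median (lower median for even n, a
  deterministic tie-break), scale = mean absolute deviation; the
  distribution's variance is reported as 2b².
- **Truncated exponential MLE**: values outside [lower, upper] (defaults
  5 and 20 µm, the maturity/z-resolution window for snapshot lengths) are
  discarded; the scale solves the truncated-mean equation by bracketed root
  search, written in a form stable at tiny scales. No finite root exists
  when the retained mean reaches the window midpoint; that case is flagged,
  not guessed.
- **Persistence times**: maximal runs of constant velocity sign on the
  smoothed velocity; zeros inherit the preceding sign (leading zeros the
  following one); the censored first and last phases are discarded.
- **KS machinery**: two-sample KS with optional unit-variance scaling —
  "normalized" velocity distributions are compared by shape only.
- **(M, N) scan**: per-cell stationary velocity samples vs the reference,
  normalized two-sample KS; failures are flagged NaN, never dropped.
  Because structures along the N ≈ M ridge produce nearly identical
  Laplace-like laws, the raw argmin wanders the ridge within sampling
  noise; `best_cell_parsimonious` applies a one-standard-error-style rule
  (smallest M·N, then smallest M, among cells within one KS noise unit of
  the minimum). The raw argmin is retained alongside.
- **θ fit**: grid search (no gradients, fully reproducible); for each θ,
  n_sim trajectories with initiation uniform on [0, 20] min, lengths read
  at 20 min, truncated to > 5 µm, median-ratio scaled to the observations
  and compared by KS. Recovery on synthetic data is within one grid step on
  a geometric grid (2, 4, 8, 16 min⁻¹) at n_sim = 5000.
- **Timescale prediction**: per-protein rate λ/N; the characteristic time
  uses the reciprocal-rate convention 60/(λ/N) s (which reproduces the
  ~5 s figure for λ = 22 min⁻¹, N = 2); ln 2/rate is available as an
  option.

## Postprocessing

Filters: effective diameter `2√(A/π)` with a strict < 0.5 µm cut; length
truncation to [5, 20] µm only for length-distribution analyses. Track
repair merges fragment pairs with lifetime-mean base positions < 1 µm
apart, non-overlapping frame ranges, and at most 6 frames with neither
fragment present, greedily in ascending distance; the merged track keeps
the earlier id, and chains merge to one track independent of input order.
Smoothing is Savitzky–Golay (window 11, order 3) with the derivative taken
from the same filter. Spearman matrices, enrichment thresholds ("top half"
per channel) and cohort percentiles (70th/30th, linear interpolation) are
computed per field of view and averaged, so illumination differences
between fields never masquerade as biology; a global-threshold option
exists. Confidence intervals are 95% t-intervals of the mean, except shaft
decay fits which use the 66% resampled-residuals bootstrap they are
conventionally reported with. Negative background-corrected intensities
are preserved (ranks are unaffected). The headline enrichment comparison
(structures enriched in ≥ 2 channels vs ≤ 1) is the per-fov ratio of cohort
means, averaged across fovs.

## FRAP

Four ROIs (bleached/unbleached structure, paired backgrounds). The bleach
frame is the largest frame-to-frame drop (ties to earliest). Normalization:
background subtraction; division of the bleached series by the unbleached
series relative to its prebleach mean (the acquisition-bleach correction,
implemented as this ratio); prebleach mean scaled to 1; affine rescale
pinning the bleach frame to 0. The recovery fit is `A(1 − e^{−kt})` with no
offset (the bleach frame is pinned to 0 by construction), in real time
units — sampling is nonuniform (0.5 s frames early, 1 s later). Half-time
= ln 2/k, percent recovery = 100A. Recovered half-times across the 5–25 s
range are accurate within 10% when averaged over a handful of replicate
traces, mirroring multi-cell reporting.

## Image pipelines

Z-stack segmentation: per-plane difference of Gaussians `G(σ) − G(kσ)`,
thresholding (Otsu by default), connected components (≥ 4 px), greedy
z-tracing from base-plane candidates to the nearest next-plane candidate
within the tracing radius (ties by distance, then detection order). This is
a reduced-fidelity reimplementation of the original interactive plugin's
published algorithm, not a port. Ring background: annulus of 2–3× the base
equivalent radius, neighbouring bases excluded; an occluded ring yields a
flagged-missing background.

Movie tracer: 11-px Gaussian local thresholding; a random forest (depth
≤ 50, ≥ 5 samples/leaf) over raw 13×13 patches with negatives sampled at
20:1; components < 40 px removed (strict); DBSCAN (ε = 7 px, min 20
points); skeletonization, with each connected skeleton component kept as
its own fragment; tip joining when endpoints are ≤ 20 px apart and the
mean directions of the 3 pixels nearest each tip differ by ≤ 30°
(undirected angle). Lengths are longest paths through the 8-connected
skeleton graph (edges 1/√2); cycles — inevitable diagonal shortcut
triangles at junctions — are broken by removing each cycle's longest
(diagonal) edge, which deletes the shortcut without detouring the natural
path; leftover branches of ≥ 5 px are split off as separate filopodia.
Linking minimises `0.6·‖Δcenter‖ + 0.4·|ΔL|` by the Hungarian algorithm
with links > 30 px forbidden; the absolute length difference is used (a
signed term would reward pairing dissimilar filopodia; the signed variant
is available behind a flag). Tracks < 5 frames are dropped; velocities come
from a Savitzky–Golay filter (window 5, order 2) in µm/min.

## Synthetic data

Generators are pure functions of (parameters, seed); every scene carries a
ground-truth record sufficient to compute the true value of each downstream
statistic. What they emulate — and what they do not:

- **Trajectory sets**: the full OU → force → length chain with uniform
  random initiation over a 0–20 min window.
- **Intensity tables**: lognormal channel marginals with a Gaussian copula
  reproducing a target Spearman matrix (`r = 2 sin(πρ_s/6)`); only rank
  structure is controlled, since only rank correlations are reported.
  Lengths are exponential (scale 7.6 µm) with a multiplicative
  `(1 + effect)` on records enriched in ≥ 2 channels. The planted-effect
  rehearsal uses 50 fields × 1000 records, approximating the order-10⁵
  scale of pooled snapshot data and giving the effect estimator a standard
  error below 1 percentage point.
- **FRAP traces**: 5 prebleach frames at 1 s, then 40 at 0.5 s and 80 at
  1 s; instantaneous bleach, single-exponential recovery to the mobile
  fraction, multiplicative acquisition bleaching on both structure ROIs,
  additive Gaussian noise.
- **Rod stacks**: disks voxelized plane by plane along tilted axes from a
  jittered base grid, Gaussian-blurred per plane; rods exceeding the stack
  are clipped and flagged.
- **Filament movies**: gently curving filaments rising from fixed bases,
  lengths driven by the growth model (floored at 22 px so every rendered
  structure stays above the tracer's 40-px detection cut — immature
  sub-µm structures are not emulated), rendered at 3 px thickness.
  Geometry is resolvable by construction: tilt/curvature are redrawn until
  full-length curves stay in frame with > 22 px clearance (beyond the
  20-px joining gate), widening the frame if the requested filament count
  needs it. Crossing or touching filopodia are outside the tracer's
  contract and not generated. Breaks for the repair test split a track
  into fragments separated by 1–6 missing frames at < 1 µm base
  displacement; 20% of frames are exported as training annotations.

None of the generators model camera shot noise, illumination profiles or
point-spread anisotropy; passing tests therefore demonstrate correctness of
the algorithms under the stated geometric and statistical conditions, not
robustness to every optical artifact of real microscopes.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 10⁵ Euler steps for OU
closed forms (variance pooled over the four independent traces, ACF
averaged likewise); n = 10⁵ stationary velocities for the Laplace
emergence check (KS < 0.01 against the MLE-matched Laplace; a single
normal-product control fails the same test); n = 10⁶ for the
force-variance identity (5%); 100 replicates of n = 10⁴ for Laplace-scale
bias (< 2%); n_sim = 5000 for θ recovery; n_sim = 2×10⁴ per cell on the
6×6 (M, N) grid; 12-frame 4-filament movies for the tracer oracles; and
30-frame 8-filament movies with 50% break injection for track repair.
Persistence-time self-consistency pools two independent 1500-trajectory
cohorts sampled at 10 s. These sizes keep each quantity's sampling error
several times smaller than the tolerance it is checked against.

## Known limitations

- The Euler–Maruyama variance bias is O(θ·dt); simulations at θ ≳ 20 min⁻¹
  with the default 1 s step should reduce dt if absolute variances matter.
- The (M, N) family is nearly non-identifiable along N ≈ M; the scan
  reports both the raw argmin and the parsimonious selection, and honest
  uncertainty on the selected cell requires larger n_sim than the default.
- The tracer's tip joining cannot distinguish genuinely crossing filopodia
  from fragments of one structure; identity guarantees hold only for
  resolvable (non-crossing) geometries.
- The supplementary-spreadsheet loader ingests published per-structure
  tables, but no packaged data ships with the repository; all validation
  runs on synthetic scenes.
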