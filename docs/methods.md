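# Methods

`fixdur` implements a statistical pipeline for asking how the visual
content at, before, and after the currently fixated location controls how
long the eyes stay put during real-world scene viewing. This note records
the model, the algorithmic and numerical choices, what the synthetic-data
generator does and does not emulate, and the known limitations.

## The analysis model

The response is the natural log of the duration (ms) of the middle
fixation *n* of a triplet (*n*−1, *n*, *n*+1) of consecutive fixations.
The log transform brings the right-skewed duration distribution close to
normal and stabilizes the variance. The model is a Gaussian linear mixed
model with *crossed* random effects for subjects and scene items (every
subject views many scenes; every scene is viewed by many subjects), plus
random intercepts for scene list and subject group, the two counterbalancing
factors of the dual Latin-square design:

    log d = X b + Σ_k Z_k u_k + ε,   u_k ~ N(0, σ_k² I),   ε ~ N(0, σ_e² I).

The full fixed-effects structure has 23 terms: the intercept; five local
image statistics (luminance, RMS contrast, logit edge density, clutter,
segment count) at each of the three triplet positions (15 terms); and the
oculomotor/spatiotemporal covariates — previous-saccade amplitude (linear
and quadratic), next-saccade amplitude, the absolute angular difference
between the incoming and outgoing saccades, viewing time (linear and
quadratic), and distance from image center.

All input variables are z-standardized on the analyzed (post-exclusion)
table. Models are fitted per task, so standardization is per task.
Quadratic terms are the elementwise squares of the standardized linear
columns and are *not* re-standardized: for centered inputs the linear and
quadratic estimates then have interpretations independent of each other.

Every random component is independent of all others (the
zero-correlation-parameter model, zcpLMM). The full zcpLMM carries 48
variance components (23 by subject, 23 by item, 2 extra intercepts); the
reduced structure drops the 15 by-subject image-feature slopes and the
quadratic previous-saccade slopes for both factors, leaving 31. Maximal
(fully correlated) structures would need n(n+1)/2 parameters per factor —
554 in total for 23 terms — which motivates the zero-correlation
constraint.

## Estimation

`fit_zcplmm` profiles out the fixed effects and the residual variance and
optimizes the REML (or ML) criterion over the *relative* standard
deviations λ_k = σ_k/σ_e, bounded below by zero — the parameterization in
which variance components can legitimately converge to exactly zero. For
each candidate λ the penalized least-squares system

    [ Λ'Z'ZΛ + I   Λ'Z'X ] [u*]   [ Λ'Z'y ]
    [   X'ZΛ        X'X  ] [b ] = [  X'y  ]

is solved via two dense Cholesky factorizations (the scaled random-effects
block, then its Schur complement for the fixed effects); the profiled
criterion uses the standard identity

    −2·RL(θ) = log|Λ'Z'ZΛ + I| + log|S| + (n−p)(1 + log(2π·r²/(n−p))),

with S the fixed-effects Schur complement and r² the penalized residual
sum of squares (for ML, drop log|S| and use n instead of n−p). All
cross-products are precomputed once per design, so each function
evaluation costs one factorization of a q×q matrix (q = total number of
random-effect levels). The outer optimizer is bounded L-BFGS-B with
numerical gradients; convergence is declared at a relative criterion
change below 1e−10, with a 50,000-evaluation budget. Iteration and
evaluation counts are reported. The fitter reproduces lme4's estimates,
standard errors, variance components and both criteria to ≲1e−4 relative
on crossed test problems (see the oracle test), and collapses to ordinary
least squares in the noiseless limit.

Standard errors of fixed effects come from σ̂_e²·S⁻¹ at the optimum,
conditional on the estimated variance components (the same convention as
lme4). Significance uses the normal-approximation criterion |t| > 1.96,
with 1.645 < |t| ≤ 1.96 labeled marginal; no Satterthwaite/Kenward–Roger
correction is applied, consistent with the large-sample regime the
analysis targets.

Goodness of fit: marginal R² = var(Xb)/(var(Xb)+σ_r²+σ_e²) and conditional
R² = (var(Xb)+σ_r²)/(…), where the slope-aware random-effect variance σ_r²
is the observation-averaged diagonal of ZΣZ'; for independent components
this is Σ_k σ_k²·mean(z_k²), which reduces to the sum of intercept
variances in random-intercept models. Model comparisons refit by ML and
use the χ² reference for the likelihood-ratio statistic and
BIC = deviance + k·ln(n), counting fixed effects, variance components and
the residual variance in k.

## Feature maps and patch statistics

* **Luminance** — CIE L\* of the sRGB image (IEC 61966-2-1 conversion via
  scikit-image), min–max rescaled to [0, 1] per image. A constant image
  maps to zeros with a warning rather than NaNs.
* **Edges** — 3×3 Sobel gradient magnitude (reflect padding), binarized at
  an adaptive threshold of 4× the mean gradient magnitude. The factor is
  configurable; 4 mirrors the common automatic-threshold heuristic.
* **Clutter** — an in-house feature-congestion measure: at each of 3
  Gaussian-pyramid levels, the local a\*b\* covariance volume (color), the
  local SD of a center–surround luminance response (contrast), and the
  mean local SD of oriented-derivative energy at 4 orientations are
  combined with weights 0.24 / 0.06 / 0.70, upsampled, averaged across
  levels and min–max rescaled. Exact parity with the original MATLAB
  feature-congestion code is not claimed; the map's role is an
  object-density surrogate with the right qualitative behavior (flat
  regions → 0, dense texture → high).
* **Segmentation** — mean-shift-style mode filtering in the joint
  spatial–CIELab domain (spatial bandwidth 7 px, range bandwidth 6.5 Lab
  units, both configurable), connected-component grouping of similar
  neighbors, and fusion of regions smaller than 20 px into their most
  similar neighbor. The edge-confidence ("synergistic") weighting of the
  original tool is not implemented; segment-count semantics are preserved
  (constant image → 1 segment, well-separated regions → one segment each).

Patch statistics are taken in circular patches of 1° radius (pixel-center
geometry: a pixel belongs iff its center is within the radius). Patches
crossing the border are clipped to in-bounds pixels and flagged rather
than discarded — the alternative convention would silently drop peripheral
fixations. Contrast uses the population SD of patch luminance divided by
the mean image luminance (RMS-contrast convention). Edge density is
logit-transformed with 0.5·ln(p/(1−p)) after regularizing zeros to the
smallest nonzero density in the analysis dataset, computed per task (an
explicit floor can be supplied).

## Triplet construction and exclusions

Fixations are invalid if they are the first or last of a trial, shorter
than 50 ms or longer than 1000 ms, blink-adjacent, or (search) end after
the button press. A triplet survives if all three fixations are valid and
both flanking saccades exceed 2° — which guarantees the *n*−1/*n* and
*n*/*n*+1 patch pairs are disjoint for 1° patches. Disjointness of the
*n*−1/*n*+1 pair is *not* implied (return saccades), so it is enforced
explicitly and counted separately in the exclusion audit. The control
table relaxes only the saccade-amplitude rule (keeping the duration,
blink, boundary and button-press filters and requiring only the focal
fixation's blink adjacency), giving one row per valid fixation for
immediacy-only analyses.

## The synthetic-data generator

The generator emulates the study design and the statistical structure the
analysis assumes, not the visual world:

* **Design** — the dual Latin square: 9 groups (3 task orders × 3 list
  rotations) of 8 subjects, 3 lists of 45 scenes; every subject sees each
  scene exactly once, 24 subjects share any list×task cell and 8 share
  list×task×order. Scaled-down sizes keep the 9-cell/3-list skeleton with
  round-robin allocation.
* **Scenes** — composites of a smooth luminance gradient, solid elliptical
  regions and band-limited noise patches, sized 96×128 px at 5 px/° by
  default so the image subtends the display's 25.6°×19.2° geometry at
  reduced resolution. All five feature maps vary spatially on such scenes.
* **Scanpaths** — sequential: saccade directions are von-Mises around the
  previous direction (κ = 1.5 by default, producing the
  direction-persistence that makes ΔAngle informative), amplitudes are
  log-normal with median 5° (matching typical scene-viewing medians),
  landing points are pulled 25% of the way toward the center (central
  bias) and reflected at the borders; blinks are independent per-fixation
  events at rate 0.02; trials last 8 s. With zero central bias the
  reflected walk is only *approximately* uniform (momentum interacts with
  reflection near borders), which the tests acknowledge by checking
  occupancy ratios and mean central distance rather than an iid
  chi-square.
* **Durations** — generated *conditionally on the realized covariates*:
  scanpaths are laid out with provisional constant durations
  (exp(intercept) ≈ 253 ms) to fix onsets, validity windows and the
  viewing-time covariate; the analysis table and design matrices are built
  exactly as the analysis builds them; then log-durations are drawn from
  the generative zcpLMM. This makes the generating coefficients
  recoverable by construction and turns the recovery experiment into a
  genuine test of the pipeline and fitter. The cost is that the
  viewing-time covariate is provisional rather than recomputed from the
  drawn durations; the CLI `simulate` command, which writes actual drawn
  durations and rebuilt onsets, therefore attenuates the viewing-time
  coefficient slightly when its output is refitted end to end.
* **Generative defaults** — the fixed-effect vector defaults to the
  memorization-task estimates of the original corpus analysis (intercept
  5.534 log-ms, ΔAngle 0.065, …). Variance components default to subject
  and item intercept SDs of 0.12 and 0.08, three by-subject slope SDs of
  0.02, two by-item feature-slope SDs of 0.01, and residual SD 0.40 —
  chosen so that the conditional−marginal R² gap sits around 10–15
  percentage points and virtually all simulated durations fall inside the
  50–1000 ms analysis window.

The recovery experiment defaults to 24 subjects × 45 scenes (each subject
viewing one 15-scene list in the memorization task, ≈5,500–6,000 triplets
per replicate), all 23 fixed effects, and the seven generative variance
components. Scenes and feature maps are generated once per experiment;
scanpaths, tables, designs, responses and fits are redone from scratch per
replicate. Problem sizes were chosen so a 100–200 replicate experiment
completes in minutes on a single core.

## Numerical details and degenerate inputs

* Constant images: luminance and clutter maps are all-zero (with a warning
  for luminance); the edge map is empty; segmentation returns one segment.
  RMS contrast is undefined when the mean normalized luminance is zero and
  raises an error.
* Min–max normalizations treat ranges below 1e−9 as constant to avoid
  amplifying float noise.
* Quantile bins use stable sort-and-slice, so ties never create empty
  bins; bin sizes differ by at most one.
* Zero-length saccade vectors make ΔAngle undefined and raise; the control
  table silently drops such rows (they cannot occur in the triplet table,
  where amplitudes exceed 2°).
* Variance components sit on a bound at zero; the optimizer's occasional
  line-search breakdown at such a boundary optimum is accepted with a
  warning when the criterion has converged, and only evaluation-budget
  exhaustion is treated as a failure.

## Known limitations

* The clutter and segmentation maps are documented reimplementations of
  their algorithm families, not bit-exact ports of the original MATLAB/C++
  tools; analyses that depend on absolute clutter values or absolute
  segment counts should calibrate against their own reference.
* The simulator's covariate joint distribution is far simpler than real
  scanpaths (no object-level guidance, no fixation-duration/saccade
  coupling, independent blinks); recovery results are internal-validity
  checks of the pipeline, not claims about any real corpus.
* SEs are conditional on estimated variance components, so 95% intervals
  undercover slightly in small designs — the recovery suite bounds this
  (coverage within [90%, 99%]) rather than pretending it away.
* Saccade detection, drift correction and other vendor preprocessing are
  out of scope: the pipeline starts from a fixation report table.
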