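# Methods

This note documents the models, parameters and design choices behind
`fatseg`, in the order the pipeline runs.

## Signal model and T2 fitting (`fatseg.t2fit`)

Each pixel's echo train is modelled as mono-exponential transverse decay,
S_i = S0·exp(−Te_i/T2) with Te_i = i·te (1-based echo index i; array index
k maps to echo k+1).  S0 is a *pseudo* proton density: true proton density
confounded with T1 weighting and coil response, which is why it is fitted
per pixel rather than assumed.  A bi-exponential variant is deliberately
not offered — for adipose tissue at this field strength the decay is well
described by a single component, and a second component is unidentifiable
from ten echoes at realistic SNR.

Two merit functions are provided: plain least squares and weighted least
squares with w_i equal to the *measured* intensity I_i, held fixed during
optimization (no iterative reweighting).  Low echoes sit near the noise
floor, so down-weighting them stabilises the fit; the echo-subset
experiment (`compare_echo_subsets`) shows the WLS mean T2 moves far less
than LS when the number of fitted echoes varies from 5 to 10.
Consequences of this weighting worth knowing:

* weights correlated with noise bias the fitted T2 slightly upward as SNR
  falls (order 1/SNR², about 8 % at SNR 10 in simulation, under 2 % above
  SNR ≈ 25).  This is intrinsic to w_i = I_i, not a defect of the
  optimizer, and is one reason the calibration stage flags low-SNR trials;
* baseline subtraction (drop echoes below a threshold; default threshold
  3× the background RMS from a user or corner-patch background region)
  removes noise-floor points, and a pixel is only fitted when ≥ 5 echoes
  survive (`min_valid_points`, default 5).  Fits with T2 above
  `t2_trim_max` (default 200 ms) are non-physical at this protocol and are
  marked invalid rather than clipped.

The optimizer is a Levenberg–Marquardt iteration on (S0, log T2) — the log
parametrization excludes non-positive T2 without constraint machinery —
vectorized across all pixels of a stack (2×2 normal equations solved in
closed form per pixel, per-pixel damping).  Initialisation is
deterministic: T2 from the two-point log-linear estimate through the first
and last valid echoes (fallback 50 ms when degenerate), S0 by
extrapolating the first valid intensity to t = 0 with that T2.
Convergence: relative merit change below 1e−8 or 200 iterations; on
noiseless data the fit recovers parameters to machine precision, and on
any data the returned merit is at or below the minimum of a dense
brute-force (S0, T2) grid (tested property).

## Filter bank (`fatseg.filters`)

Five window-based filters are implemented for the first-echo image: mean,
Gaussian (σ defaults to window/6, the conventional 3σ support), median,
selective blurring (weights by intensity similarity only,
exp(−ΔI²/2σ_r²), uniform spatial support — distinguished from bilateral
precisely by the absence of spatial weighting) and bilateral (product of a
spatial and an intensity Gaussian).  Default window is 7×7; borders are
handled by reflect padding, which avoids the dark-border bias that
zero-padding would feed into SNR-sensitive steps.  All weights are
normalized per pixel, so constant images pass through unchanged and the
output is always inside the window's intensity range.  The pipeline
default is bilateral: fat forms spatially continuous regions, so using
spatial as well as intensity proximity is the right prior.  All five kinds
share one explicit padded-window implementation whose arithmetic matches a
per-pixel double-loop evaluation bit for bit, which is how the tests pin
them down.

## Mean-shift segmentation (`fatseg.segment`)

Pixels are lifted into the joint space (row/h_s, col/h_s, I/h_r) and
iterated to their density mode with a unit-bandwidth kernel.  The default
kernel is Epanechnikov (indicator of the unit ball): finite support gives
guaranteed convergence and allows the batched implementation to gather
only a fixed window of the padded image per iteration, which is exactly
equivalent to iterating over the full data set.  A Gaussian kernel is
available, truncated at 3 joint units inside `segment_image` (the
reference `mean_shift_point` is untruncated).

Modes are fused into regions by connected components on the 4-connected
pixel lattice, linking neighbours whose converged modes lie within
`merge_distance` (default 1.0 joint units).  On a constant image every
interior pixel is its own fixed point, so only a transitive closure gives
the expected single region; restricting the closure to the lattice keeps
it linear-time and keeps regions spatially coherent, which is what the
casting step needs.  Regions smaller than `min_region_size` (default 4 px)
are absorbed into the spatially adjacent region with the nearest mode.
Labels are deterministic: decreasing size, ties by scan order.

No cluster count is ever supplied; granularity is controlled by h_s
(default max(4, rows/32) px in the pipeline) and h_r (default 10 % of the
robust intensity range of the masked pixels).  The bandwidths are the
method's genuine tuning knobs and are exposed as CLI flags; over-fragmented
regions are harmless downstream (scores are aggregated per region), while
an h_r large enough to merge fat with muscle is not — the default is
deliberately on the small side.

## SNR calibration (`fatseg.calibrate`)

SNR is defined as mean(signal ROI)/RMS(background ROI) on the first-echo
image.  The sweep injects white Gaussian noise into a clean homogeneous
phantom stack at variance k·step (step default 1e−4, k = 1..100),
normalized to the squared maximum of the clean first echo; each trial uses
an independent sub-seed, re-derives the baseline threshold from its own
noisy background (3× RMS), fits T2 in the signal ROI by WLS and records
the mean/std of surviving values.  Noise is added independently to each
echo, and negative intensities are kept — clipping would re-introduce
exactly the floor bias the Gaussian model avoids.  Rician statistics are
not simulated: magnitude noise is quasi-Gaussian above SNR ≈ 2, and trials
below that bound are flagged; trials below SNR 5 are excluded from curve
fitting altogether, since the fitted T2 there is dominated by noise.

The calibration curve σ_T2(SNR) = a·exp(−b·SNR) + c is fitted by
Levenberg–Marquardt on the logs of (a, b, c), which enforces positivity
and hence a monotone non-increasing curve.  The three-parameter family is
weakly identified from short tables — recovery to 10 % under 5 % noise
needs on the order of a hundred rows spanning the exponential's active
region, which the 100-trial sweep provides.  Evaluation outside the fitted
SNR domain clamps to the nearest endpoint: extrapolating the exponential
beyond measured SNRs is not supported by the phantom data.

## Confidence image and fat extraction (`fatseg.confidence`)

T2 histogram modes are found by 1-D Gaussian-kernel mean shift over the
valid T2 values (an evenly-spaced subsample of at most 2000 when larger;
bandwidth default 5 ms), merging converged points within half a bandwidth.
Among multiple tissue modes the fat mode is chosen as the one nearest a
user-supplied reference T2 (default 60 ms; `largest_peak` is available) —
an explicit, auditable rule.  Each valid pixel is assigned to the mode its
own trajectory converges to (trajectories are run from values rounded to
1e−3 ms and mapped back) and weighted with the SNR-adaptive Gaussian
kernel w_p = exp(−(T2,p − T2,m)²/(2σ²_SNR)).  The squared-σ denominator is
the true Gaussian form and the default; the single-power variant is kept
behind `squared_sigma=False` for comparison.  Pixels with a difference
beyond four standard deviations contribute exp(−8) ≈ 3.3e−4 — effectively
nothing.  Only fat-mode pixels contribute to fat scoring; region scores
are the sum of member weights, reported also as the mean (the default for
thresholding, since a [0,1] score transfers across resolutions; the raw
sum is in the CSV as well).  The fat mask is the union of regions whose
score clears `score_threshold` (default 0.5); area and volume follow from
pixel size and slice thickness.

The pipeline's SNR is measured on the analysed image itself (signal ROI =
valid-fit pixels, background ROI = corner patches unless supplied).  A
noiseless input has zero background RMS; SNR is then taken as infinite and
σ_SNR clamps to the calibration curve's high-SNR endpoint.

## Synthetic data (`fatseg.synthdata`)

The generator renders tissue compartments (elliptic/annular geometry with
per-tissue S0 and T2), blurs the parameter fields to emulate partial
volume, multiplies S0 by a smooth low-frequency bias field, synthesizes
echoes from the mono-exponential model and adds Gaussian noise scaled to a
target first-echo SNR (one deterministic correction pass keeps the
achieved SNR within 5 %).  Defaults: fat 60 ms, muscle 25 ms, free fluid
150 ms, S0 1000/800/900 — well-separated fixture conventions chosen to
exercise mode finding, not biological claims; echo timing follows the
reference protocol (te = 8.3 ms, 10 echoes, 40×40 mm field of view,
0.9 mm slice).  The partial-volume blur is fixed in *pixels* across the
resolution series (default 0.7 px): a voxel mixes tissue over its own
footprint, so the physical extent of the mixing — and the boundary
degradation — worsens at low resolution, which is what drives the overlap
percentage down at 64×64 and up at 256×256.

What the generator does not emulate: Rician/multi-coil noise, anatomical
complexity (organs, bowel gas, motion), chemical-shift artefacts, and
through-slice partial volume.  Passing tests therefore demonstrate the
method's correctness and its behaviour under controlled SNR and partial
volume, not performance on real scans.

## Problem sizes and determinism

The test suite and the acceptance script run the noise sweep on a 64×64
phantom (100 trials), the stability comparison on 48×48 phantoms over 20
seeds, and the end-to-end pipeline on 64/128/256 mouse slices — sizes at
which every stage's behaviour is already resolution-converged while the
whole suite completes in minutes on one CPU.  All randomness flows from
explicit seeds (the CLI expands one top-level seed per stage via
`numpy.random.SeedSequence([seed, stage])`); reruns with the same inputs
and seeds are bit-identical, which the tests assert.

## Known limitations

* WLS T2 bias at low SNR (above) propagates into the confidence image;
  below SNR ≈ 10 the fat mode itself drifts upward.
* The fat/not-fat decision is per region: a region that genuinely mixes
  tissues (under-segmentation, h_r too large) is scored as a whole.
* Volume assumes a single slice with known thickness; no 3-D mean shift or
  through-plane regularisation.
* Visceral/subcutaneous and brown/white fat are not distinguished.
* Bruker raw data (2dseq) is not parsed; convert to NIfTI or TIFF first.
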