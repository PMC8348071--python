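# Methods

`arrcine` simulates, at the k-space level, why segmented cardiac cine MRI
develops arrhythmia-related artifacts (ARA) while single-shot real-time
compressed-sensing (CS) cine does not, and implements the image-quality and
statistical machinery used to compare the two sequences in arrhythmic
patients: RR-interval variability, the edge-spread-function (ESF) sharpness
metric, the modified EuroCMR artifact score, and a paired test battery.

## Rhythm model

Heart-rate irregularity is quantified by the coefficient of variation of the
RR intervals, `CV_RR = 100 * SD / mean` (percent), with the sample SD
(divisor n−1) by default and a population-SD switch (`ddof=0`).  The source
reports do not state which estimator was used clinically; on a finite beat
list the sample SD is the conventional choice, and for the window sizes
involved (dozens of beats) the two differ negligibly.  A rhythm is
classified irregular when CV_RR strictly exceeds 10%, matching the
"greater than 10%" enrolment wording.

Three generator mechanisms produce irregular series, all moment-matched so
the realized CV_RR is an unbiased estimator of the target:

- **afib** — i.i.d. log-normal durations; the log-normal keeps durations
  positive at any attainable CV and its two parameters are solved in closed
  form from (mean, CV).
- **ectopy** — a baseline rhythm with short-coupled ectopic beats placed in
  disjoint (ectopic, compensatory) beat pairs; the coupling deviation is
  solved from the target CV, capped at 85% of the baseline (a physiological
  short-coupling floor), with any residual variance supplied as log-normal
  baseline jitter.  About 15% of beats are ectopic by default.
- **pauses** — dropped beats that merge two cycles into one doubled
  duration.  The pause count is solved so pauses alone supply ~75% of the
  target CV (pure pauses saturate near CV 35%), and baseline jitter is
  solved from the exact two-point moment equations for the remainder.

Every stochastic operation takes a mandatory integer seed; there is no
global random state.  Calibration (tested): over 100 seeds at targets
15/25/40% with 256 beats, the mean realized CV_RR is within ±5% relative of
target for all three mechanisms.

## Phantom

A 2-D concentric-annulus phantom (bright blood pool, darker myocardial
ring, near-black background) stands in for a cine slice; the metrics of
interest (per-slice artifact flags, sharpness along a profile line) are
inherently 2-D, so no 3-D anatomy is modelled.  The default 168-px matrix
echoes the real-time sequence's short matrix axis; intensities default to
blood 1.0 / myocardium 0.25 / background 0.05, a bSSFP-like contrast
ordering.  The endocardial radius follows a cosine-smoothed contraction law
from end-diastole (phase 0) to end-systole (phase = `systole_fraction`,
default 0.35, default contraction 35%), and back; smooth velocity avoids
artificial k-space ringing unrelated to arrhythmia.  The epicardial radius
conserves the myocardial ring area (incompressible wall).  Boundaries are
rasterized with a 1-px anti-aliasing ramp and smoothed by a Gaussian of
0.8 px (`edge_softness`) so the ground-truth sharpness is finite and
measurable.

## Acquisition simulation

Both arms share a Cartesian, single-coil k-space model (phase-encode lines
= image rows in fftshifted order).  Parallel imaging, coil maps,
off-resonance/banding, respiratory motion and noise (available but off by
default) are out of scope.

**Beat-to-beat contractility.**  Arrhythmic cycles do not merely rescale
in time: a premature beat fills briefly and contracts weakly, a post-pause
beat contracts strongly (the Frank–Starling preload response, the
physiological driver of beat-to-beat appearance changes in arrhythmia).
The phantom models this as a per-beat contraction-amplitude multiplier
`(RR_prev / mean RR) ** preload_sensitivity`, clipped to [0.6, 1.4]
(`preload_sensitivity` defaults to 1; 0 disables it).  Without this term a
time-rescaled cycle leaves the end-systolic geometry nearly identical
across beats — wall velocity vanishes at the contraction extreme — and
segmented end-systolic frames would barely blur, contrary to the wall-border
blurring that defines ARA.

**Segmented (reference) arm.**  20 frames at 41.2 ms temporal resolution;
heartbeat *h* contributes one segment of v = 13 views to *every* frame.
Segments are interleaved combs `{h, h+n_beats, h+2·n_beats, …}` by default,
the usual segmented-cine layout, so every k-space band — including the
contrast-defining centre — mixes data from all heartbeats; contiguous
sequential bands are available (`interleaved_ordering=False`), but they
hand the whole centre band to a single heartbeat, which suppresses the
wall-border blurring the artifact is known for and leaves mostly ringing.
A frame is a fixed time `f·tr` after the R peak, so its true cardiac phase
in heartbeat *h* is `f·tr / RR_h` — the linear phase map makes the mixing
mechanism transparent — and each heartbeat renders with its own preload
scale.  The acquisition window is clamped to the shortest RR interval
(prospective triggering), dropping late frames when cycles are short.  With
a regular rhythm all segments agree: the output equals the truth to machine
precision (tested at RMSE < 1e-6).  Under RR variability each segment is
Fourier data of a slightly different anatomy, producing ghosting/blurring
whose severity grows with CV_RR (tested: median frame RMSE strictly
increases across CV 0/10/25/40%).

**Real-time (single-shot) arm.**  One heartbeat (the cohort runner shoots
a representative beat — own and preceding cycle length nearest the mean),
49 ms per frame, so
`floor(RR/49)` frames per cycle (17 at RR = 833 ms; fewer than 16 only
above 75 bpm).  Each frame's k-space is sampled on a fresh, seeded
variable-density random line mask (Gaussian density, width n/6; 12 centre
lines always sampled) at 11-fold nominal acceleration.  Reconstruction is
iterative soft-thresholding with hard data consistency: threshold the
temporal-Fourier coefficients at `λ = threshold_weight · max|coeff|` of the
zero-filled estimate, transform back, re-insert the measured k-space
samples; 40 iterations.  The vendor prototype's sparsifying transform and
regularization are unpublished; temporal-Fourier soft-thresholding is a
standard stand-in and is stated as such.  `threshold_weight` defaults to
0.005: in phantom experiments 0.02 visibly over-shrinks temporal harmonics
of the moving wall, biasing its measured sharpness low and destabilising
it, while 0.005 keeps the data-consistency/denoising balance in the regime
where full sampling is recovered exactly and undersampled reconstruction
still beats zero-filling (both tested).

Temporal interpolation to a fixed 20-phase grid (as required by clinical
post-processing) is linear in phase with periodic wrap-around and is the
identity when the grid already matches.

## Edge sharpness (ESF 20–80)

A profile line is cast across the blood/myocardium boundary; intensities
are sampled bilinearly every 0.1 px (well below the 3-decimal precision at
which ε is reported).  The analysis finds the steepest gradient, walks
outward on both sides to estimate the *local* plateau intensities I_min and
I_max — local, not global, because ghosted images carry extra peaks (e.g.
a doubled septal border) that would corrupt global extrema — and locates
the sub-pixel crossings of I_min + 0.2·ΔI and I_min + 0.8·ΔI by linear
interpolation.  Then `d = |x80 − x20|` and `ε = 1/d` (pixel⁻¹; higher =
sharper).

Plateau estimation is two-staged: walk while the gradient magnitude is
above 5% of the edge's peak (the body of the edge), continue through the
tail until it falls below 0.5% of peak, then take the median of the next 5
samples; if the profile ends first the endpoint value is used.  The 0.5%
tail stage matters for wide edges: stopping at the 5% point of a Gaussian
edge (2.45σ) captures only ~99.3% of the plateau and biases ε by 1.5–2.5%
for σ ≈ 12 px, while the 0.5% point (3.26σ) brings the bias below 0.2%.
Tested against closed forms: a linear ramp over 10 px gives ε = 1/6
exactly, and an erf edge gives ε within 1% of `1/(1.6832σ)` for σ from 2 to
12 px.  ε is exactly invariant under positive affine intensity maps.

Callers can restrict the whole analysis to a window (the reader's manual
line placement) and, separately, restrict only the steepest-gradient search
(`seek`) to a known anatomical position — used by the automated pipeline so
that a ghost edge elsewhere in the window is not mistaken for the wall.
When the plateau-median levels are never crossed (heavily ringing edges),
the analysis falls back to the extremal values within the window, as a
reader marking min/max crosses on a printed profile would.

**Wall sharpness of a frame** (`wall_sharpness`) is the median ε over six
radial profiles near the readout axis (0°, ±7.5° and the mirrored triplet),
anchored on the reference (truth) frame's boundary position with a ±3 px
seek range.  Near-readout directions are used because Cartesian
undersampling and ghosting displace structure along the phase-encode axis,
and the narrow ±7.5° fan keeps each line close to perpendicular incidence
on the circular wall, as the measurement prescribes; the median over six
lines suppresses single-line ghost luck.  A line on
which no 20–80 rise exists at the boundary contributes ε = 0: an
obliterated border has no measurable sharpness.  This robustified reading
is the package's own operationalization of the reader's measurement; the
single-line `edge_sharpness` API remains the primitive.

## Artifact scoring

The modified EuroCMR score sums item 1 (ventricular coverage: full 0,
no apex 2, base/slice missing 3, both 5), items 2–7 (wrap-around,
respiratory ghost, cardiac ghost, blurring/ARA, metallic, shimming; each
0/1/2/3 for 0/1/2/≥3 affected slices) as a block capped at 3, and item 8
(inactive coil element: 2), for a 0–10 total.  The block cap is the unique
reading consistent with the published maximum of 10 alongside item maxima 5
and 2; an uncapped per-item sum is available behind `cap_block=False`.
The ARA rate is the percentage of slices flagged with blurring/ARA.

`auto_flag_ara` automates the reader's blur judgement for simulated data
only: a slice is flagged when the end-systolic wall sharpness of the
reconstruction falls below 0.75 of the matching truth frame's.  End-systole
is located as the frame with minimal blood-pool area.

## Statistics

- **Wilcoxon signed-rank** (ordinal scores): zeros dropped by default
  (classic convention; Pratt available — with many ties the choice is
  material and therefore surfaced), mid-ranks for ties, exact null by
  dynamic programming over sign assignments for ≤25 effective pairs
  (doubled mid-ranks are integers, so the null is a polynomial product
  computed by convolution), tie-corrected normal approximation with
  continuity correction beyond.  Two-sided p = P(|W − μ| ≥ |w − μ|).
  Tested against exhaustive 2ⁿ enumeration and scipy; null type-I error at
  n = 71 calibrated to [0.03, 0.07] at α = 0.05.
- **Paired t** for continuous endpoints (sharpness, ARA rates).
- **ICC(2,1)** (two-way random, absolute agreement, single measure) as the
  interobserver default — the standard choice when raters are a random
  sample; ICC(3,1) behind a flag.  Computed from two-way ANOVA mean
  squares; cross-checked against pingouin in the tests.
- **Cohen's kappa**, optionally linearly weighted for ordinal scales.
- Medians use the conventional midpoint of the two central order statistics
  for even n (half-integers are reported as such).

## Cohort experiments and fixtures

`run_cohort` mirrors the paired design: per synthetic patient an irregular
rhythm (redrawn until CV_RR > 10%), both acquisitions per slice, real-time
interpolation to 20 phases, wall sharpness at end-diastole and end-systole,
automatic ARA flags, EuroCMR scores, then the paired battery.  Cohort
defaults state the study conditions: 71 patients, HR ~ N(71.8, 19.0) bpm
truncated to 42–116, CV_RR targets ~ N(25.0, 9.4)% truncated to 10.2–50.9,
mechanism mix 59/24/17% (afib/ectopy/pauses), 8 slices per patient.  Tests
and the acceptance script run reduced sizes (3–10 patients, 2–3 slices,
10–20 seeds for the mechanism study), chosen so the full battery still
exercises every stage; each run states its n.

The published paired cross-tabulations of the two quality comparisons ship
as JSON fixtures.  The artifact-score table is banded (0, 1–3, 4–6, 7–10),
so "equal-or-better" is computed on band indices — only band-level pairing
is recoverable from the published counts.  Note one internal inconsistency
of the published subjective-quality table: its cells sum to 63/71 (88.7%)
real-time-equal-or-better pairs while its caption states 64/71 (90.1%); the
marginals and both medians confirm the cells, so the computed 63/88.7% is
reported.

## What the simulation does and does not show

The simulator reproduces the *mechanism* and the *direction* of every
finding: segmented frame error grows monotonically with CV_RR while
real-time error is flat; at CV_RR 25% the real-time end-systolic wall is
sharper than the segmented one in ≥90% of seeds; automatic ARA flags are
near-universal for the segmented arm and near-zero for the real-time arm;
with a regular rhythm the segmented arm is exact.

It does not — and is not meant to — reproduce patient-level clinical
magnitudes: sharpness values in physical pixels of a 1.3–1.6 mm grid, the
85.9% clinical ARA rate, the cohort's CV_RR distribution as measured on
scanner DICOMs, or acquisition times.  Those depend on real anatomy,
coil/noise physics and the vendor reconstruction.  Two known limitations of
the phantom pipeline: (i) at 11-fold single-shot undersampling only ~60 of
168 lines can ever be sampled within one heartbeat, so the CS
reconstruction's wall sharpness saturates around 80–90% of truth — under a
regular rhythm the two arms therefore agree only to ~15–25% rather than
being identical; and (ii) Gibbs ringing from the unsampled outer k-space
can make an apparent edge *steeper* than truth at the motion extremes,
which the seek-pinned, median-over-lines wall reading mitigates but does
not remove for single lines.

## Numerical conventions

0-based pixel-centre coordinates; profile points are (x, y) = (column,
row); positions in pixels from the first endpoint.  Phases live in [0, 1).
FFTs are numpy's unnormalized pairs; masks index fftshifted phase-encode
lines.  ε is reported in pixel⁻¹ and never converted to physical units.
All randomness flows through explicit integer seeds (numpy Generator /
SeedSequence spawning in the cohort runner), making every report
reproducible bit-for-bit from (config, master seed).
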