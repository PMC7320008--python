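# Methods

This note documents the models, numerical choices and known limitations
behind `fuscon`, in the order the pipeline runs.

## Signal conditioning

ROI traces are spatial means of the power-Doppler movie over binary ROI
masks.  Conditioning is: (1) subtract the row mean, (2) band-pass in the
resting-state band, 0.05–0.2 Hz by default, (3) divide each row by the
square root of its energy.

* **Filter.**  4th-order Butterworth band-pass (second-order sections),
  applied forward–backward (`sosfiltfilt`), so the phase response is
  identically zero.  Zero phase matters because the dynamic stage reads
  instantaneous phases off the filtered signal — any phase distortion
  would bias every phase difference.  At a 2.5 Hz frame rate the
  passband gain at the 0.1 Hz band center is ≈ 1; a 1 Hz physiological
  nuisance tone is attenuated by far more than 40 dB.  The measured gain
  of the chain is validated in the tests against the designed transfer
  function (`bandpass_response`).
* **Edge handling.**  Filtering keeps full length; the dynamic stage's
  100-sample trim at each end (below) absorbs both filter and Hilbert
  edge transients.  A 1500-frame acquisition at 0.4 s/frame therefore
  analyzes 1300 frames = 520 s of phase data.
* **Energy normalization** does not change any Pearson correlation (it
  is a per-row scaling); it is kept so maps, phases and stored
  preprocessed series share a common scale, and the `preprocessed` flag
  on a series asserts unit row energy.

## Static connectivity statistics

Per-animal ROI–ROI Pearson matrices are compared between groups pair by
pair on the Fisher scale, z = atanh(r) (variance-stabilizing; per-animal
measured correlations are clipped to |r| ≤ 1 − 1e−7 before the
transform).

* **Test choice.**  The distributional gate is Shapiro–Wilk at α = 0.05
  on each group's z values; Welch's unequal-variance t-test runs only if
  both groups pass, otherwise the Mann–Whitney U test.  The U test uses
  the exact null distribution when both groups have ≤ 12 observations
  and no ties (at n = 9 + 9 complete separation gives the exact
  two-sided p = 2/C(18,9) ≈ 4.1·10⁻⁵), and the tie-corrected normal
  approximation otherwise.  Two groups of identical constants return
  p = 1.
* **Multiplicity.**  Benjamini–Hochberg step-up at FDR 0.05, applied
  within one imaging plane's pair set (45 pairs for the 10-ROI plane).
  Tests verify the step-up against hand-computed toy vectors, its
  monotonicity in the FDR level, and empirical control on 500
  group-identical cohorts.
* **Degenerate pixels.**  In seed maps, pixels with constant traces get
  r = 0 plus a QC flag (`constant_pixels`) instead of NaN, so maps stay
  renderable; flagged pixels are excluded from statistics.

## Dynamic brain states

Phases come from the analytic signal via the Hilbert transform; the
phase is the four-quadrant arctangent of the imaginary and real parts
(a plain ratio arctangent would fold quadrants and corrupt cosine phase
differences).  The first and last 100 samples are discarded.  The
frame-wise feature is the strict upper triangle of
M_PL(i,j,t) = cos(φᵢ − φⱼ) — the diagonal is constantly 1 and the matrix
symmetric, so the 45 unique off-diagonal entries carry all information.

Frames from all animals of both groups are pooled into one clustering
per k (default k = 5, 6, 7), so states are defined on a common basis and
group differences appear only in the occurrence rates.

* **k-means under L1.**  Assignment minimizes cityblock distance;
  the centroid update is the component-wise median, the exact L1
  minimizer (k-medians).  Initialization samples k distinct rows
  uniformly; empty clusters are repaired by reseeding on the point
  farthest from its centroid; iteration stops when assignments are
  unchanged or after 300 sweeps.  200 random restarts are run and the
  replicate with the lowest total within-cluster distance kept; the
  objective is non-increasing within a run and the whole model is
  bit-reproducible given the seed.  States are relabeled by decreasing
  overall occurrence, so `state_0` is always the dominant pattern.
* **Cross-k correspondence.**  `match_states` solves the rectangular
  assignment problem minimizing summed L1 centroid distance; no
  canonical ordering across k is claimed beyond this tool.
* **Occurrence statistics** reuse the normality-gated group comparison
  and BH correction, across the k states.

## Synthetic cohorts

The generator produces exactly the structure the dynamic analysis
assumes, which makes the whole chain identifiable on planted truth:

x_i(t) = A_i·cos(2π f_c t·Δt + θ_{s(t),i}) + ε_i(t),  ε ~ N(0, σ²)

* **States.**  Five default states on the bilateral 10-ROI plane
  (hind-limb somatosensory S1HL, motor M1/M2, cingulate Cg1/Cg2, left
  and right): global synchrony; right and left sensorimotor blocks in
  antiphase with the rest; cingulate antiphase; secondary cingulate a
  quarter-cycle out.  Offsets are normalized so ROI 0 has offset 0 — a
  global phase rotation changes no pairwise difference.
* **Switching.**  A first-order Markov chain with
  T = (1−ε)I + ε·1πᵀ, ε = 1/dwell_scale: the chain holds its target
  stationary occupancy π exactly and has mean dwell
  dwell_scale/(1−π_s).  Default dwell_scale = 100 frames (state dwells
  ≈ 45–80 s), chosen as a comfortable multiple of the band's temporal
  resolution (≈ 1/0.15 Hz ≈ 7 s) so that phase transients at switches
  corrupt only a small fraction of frames; state occupancies are
  π = (0.5, 0.1, 0.1, 0.15, 0.15) for controls and
  (0.3, 0.2, 0.2, 0.15, 0.15) for the arthritic target — less global
  synchrony, more unilateral desynchronization.  Phase offsets are
  linearly smoothed over 2 frames at each switch so the band-pass filter
  sees no broadband step.
* **Carrier and noise.**  f_c = 0.08 Hz (inside the band), amplitude
  A = 1, white noise σ = 0.1.  Note that Pearson correlation is
  scale-invariant: amplitude attenuation lowers measured correlations
  only through the in-band noise floor.  For an attenuation a the
  group difference on the Fisher scale tends to ½·ln((1 + a⁻²)/2)
  (≈ 0.46 for a = 0.5), independent of σ as σ → 0, while the per-animal
  z dispersion is ≈ 1/√(n−3); this is why halved-amplitude pairs are
  detected essentially always at these cohort sizes.
* **Group structure.**  Arthritic animals draw a latent severity
  s ~ U(0.4, 1); it scales the S1HL amplitude attenuation
  (1 − (1−a)·s/s̄, a = 0.5 at the severity midpoint s̄ = 0.7),
  interpolates the animal's stationary occupancy between the control
  and arthritic targets, and drives the behavior table.  Severity is
  the single latent cause linking connectivity and behavior, so their
  correlation is planted by construction.
* **Behavior.**  Group means default to values typical of
  adjuvant-induced-arthritis cohorts at three weeks: weight gain
  136.00 g in controls vs 49.44 g in arthritic animals (SEM ≈ 11.7 at
  N = 9, hence generative SDs near 35 g), inflammation median 0 vs 22
  out of 60, reduced von Frey thresholds and near-maximal foot-bend
  scores.  Within-group variation is loading·severity plus Gaussian
  noise; bounded scores are clipped and rounded, and control animals
  carry no pathology noise (their inflammation and bend scores are
  structurally 0).  Within-group dispersions are plausible defaults,
  configurable and not claimed faithful to any particular cohort.
* **What the generator does not emulate:** vascular point-spread and
  spatial noise correlation, anesthesia depth drift, motion, cardiac or
  respiratory residues, non-sinusoidal hemodynamics, and continuous
  (non-discrete) FC fluctuation.  Passing tests demonstrate that the
  analysis recovers the planted discrete-state structure, not that real
  data satisfies it.

## Diagnostics

Composite scores over selected ROI pairs come in two modes: the plain
sum of correlations (one threshold on the scale of a sum of r values)
and the linear predictor of a logistic regression of group on the pair
values, fit on the test cohort only.  At these cohort sizes (14
animals) complete separation is common; the maximum-likelihood fit then
diverges and the package falls back to a ridge-stabilized fit (penalty
1e−4) with a warning — the score ordering, which is all ROC analysis
uses, is preserved.  The empirical ROC is computed over all unique
thresholds; AUC equals the Mann–Whitney U statistic divided by n₊·n₋
(verified against exhaustive pair counting); the confidence interval is
DeLong's.  Score orientation (whether high or low raw scores indicate
disease) is auto-detected on the test cohort and recorded.  The Youden
threshold (maximizing sensitivity + specificity − 1, ties broken toward
sensitivity; calls are positive when the oriented score is ≥ the
oriented threshold, i.e. at or beyond the threshold on the disease
side) is frozen and applied unchanged to a disjoint validation cohort
(9 + 5 test / 8 + 4 validation by default); any animal overlap is
rejected.

## Problem sizes and determinism

The test-suite and the reproduction script use the study-scale problem
sizes throughout: 18-animal cohorts of 1500 frames (23 400 pooled
frames × 45 features for the clustering, 200 restarts), 500
group-identical cohorts for the FDR check, 100 seeds for the detection
and diagnostic round-trip rates, and 50 seeds in the reproduction
script's detection block.  Every random quantity flows from an explicit
seed (`numpy` `default_rng`); identical configuration + seed gives
bit-identical cohorts, models and reports.

## Known limitations

* Occupancy-rate group tests are underpowered when state dwells are
  long relative to the record (few independent visits per animal): at
  the default 100-frame dwell a 0.5 → 0.3 occupancy shift is detected in
  well under half of the cohorts, while at a 25-frame dwell detection is
  essentially certain.  The dwell/duration ratio, not the test, is the
  limiting factor.
* The behavior-correlation stage treats animals as exchangeable and
  pools groups; no mixed-effects or causal structure is modeled.
* Seed maps correlate single pixels without spatial inference; cluster
  or surface statistics are out of scope.
* Beamforming, plane-wave compounding and SVD clutter filtering are
  hardware-side and not implemented; the pipeline starts from Doppler
  movies or ROI series, and only the acquisition arithmetic is exposed.
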