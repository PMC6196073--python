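# Methods

This note documents the models, parameters, and design decisions behind
`oppokin`, and what the synthetic validation does and does not establish.

## The analysis chain

**Wrist frame.** Every sensor's position is expressed relative to the wrist
reference sensor, sample by sample, before any filtering. This removes hand
and forearm translation (and the common drift the generator injects). The
ordering (subtract first, filter second) is a package decision; because both
operations are linear it only matters for artefacts that differ between
sensors.

**Filtering.** Each axis is low-passed with a 2nd-order Butterworth at 5 Hz,
applied forward and backward (`scipy.signal.filtfilt`), so the effective
attenuation is doubled and the phase response cancels exactly. Edges use
reflective padding of 3 × order samples. Voluntary digit movement content
lies well below 5 Hz, so the passband is flat where it matters (amplitude
error < 1% at 1 Hz, ≥ 20 dB attenuation at 30 Hz after the double pass).

**Resultant kinematics.** `RD(t)` is the Euclidean distance from the rest
position, taken as the mean of the first 20 samples (0.2 s) of the filtered
wrist-frame trace rather than a single sample, for noise robustness.
`RV(t)` is the Euclidean norm of the per-axis five-point-stencil
derivatives,

    f'(t) = (−f(t+2h) + 8f(t+h) − 8f(t−h) + f(t−2h)) / (12h),  h = 1/fs,

exact for polynomials up to degree 4. The two samples at each edge use
one-sided differences of progressively lower order (4-point, then 3-point)
so the output length equals the input length; trials begin and end at rest,
so segmentation never depends on edge samples.

**Segmentation.** The onward movement is bounded by 5%-of-peak-speed
crossings: from the global speed maximum (earliest sample on ties), walk
backward to the first sub-threshold sample — the next sample is the onset —
and forward to the first sub-threshold sample — the previous sample is the
end. The threshold being relative makes detection exactly invariant to
speed rescaling. Segments failing plausibility gates (duration < 0.1 s, or
segment displacement < 10% of the trial's RD range) are re-detected from the
longest contiguous supra-threshold run containing a re-identified peak and
flagged `fallback=True`; the pipeline logs the fallback rate. This replaces,
with a reproducible rule, the manual rescue that lab practice applies to the
few trials with spurious detections. An isolated artefact much larger than
the movement (several times peak speed) raises the relative threshold above
the movement itself; such trials fail with an explicit no-movement error
rather than returning a wrong segment. Segmented profiles are linearly
interpolated to 100 points (the profiles are already band-limited to 5 Hz,
so higher-order interpolation adds nothing testable).

**Displacement ratio.** `D_T = |d_T| / (|d_T| + |d_F|)` with
`d = RD(end) − RD(onset)` per effector; `D_F` is stored as `1 − D_T` so the
identity `D_T + D_F = 1` holds exactly in floating point. The Fisher
z-transform `z = atanh(d)` is applied per trial, before any averaging, with
`d` clamped to `1 − 1e−9` so a vanishing counterpart displacement yields a
large finite value instead of an infinity that would poison downstream
means.

**Spectral arc length.** The segmented onward speed profile is zero-padded
to the next power of two ≥ 16 × its length, Fourier transformed, the
magnitude spectrum divided by its DC value, restricted to 0–10 Hz, the
frequency axis rescaled to [0, 1], and the arc length of the resulting curve
negated. The 10 Hz band retains all movement content (the signal is filtered
at 5 Hz); the padding density controls the discretization error of the arc
length. Both are configurable (`sal_f_max_hz`, `sal_pad_factor`). The
adaptive amplitude-threshold band variant is available behind
`adaptive_cutoff` but is off by default. Absolute SAL values depend on these
parameterization choices; only comparisons computed with one configuration
are meaningful.

**Statistics.** Trials are averaged within participant × task × effector
first, so the participant is the experimental unit. The two-way
repeated-measures ANOVA partitions sums of squares directly on the balanced
participant × finger × phalanx cube, testing each effect against its own
effect-by-participant interaction; the partition is checked to add up to the
total SS at machine precision. Sphericity is handled per effect with the
Huynh–Feldt epsilon (Greenhouse–Geisser estimate from the contrast
covariance, then `ε̃ = (n·d·ε̂ − 2)/(d(n − 1 − d·ε̂))`, clipped to (ε̂, 1]);
a two-level factor has ε = 1 identically. The per-task effector ANOVA with
its two-level factor is algebraically a paired t-test (`F = t²`, verified to
1e−8). Post-hoc pairwise comparisons are paired t-tests with Bonferroni
correction (Holm available). The textbook claim that epsilon adjustment
inflates p holds for F ≥ 1; for F < 1 the F-distribution tail behaves
oppositely, so the package asserts it only in the rejection-relevant regime.

## The synthetic generator

Each trial moves the thumb-distal sensor and the instructed phalanx sensor
toward each other along the line joining their anatomically plausible rest
positions; the thumb covers the fraction `r` of the gap, the finger `1 − r`,
so `r` is the ground-truth `D_T`. All 16 sensors are simulated: non-moving
digits rest at fixed offsets, the whole hand shares a slow sinusoidal drift
(amplitude 0.1 cm, removed by the wrist-frame transform), and every sensor
receives independent per-axis Gaussian noise.

Key defaults and why:

| parameter | default | rationale |
|---|---|---|
| participants × tasks × trials | 8 × 12 × 15 | the recorded protocol |
| fs, trial duration | 100 Hz, 3 s | the recorded protocol |
| movement duration | 0.6 s | comfortable-speed opposition movement times (~0.4–0.7 s) |
| movement onset | 0.6 s + U(0, 0.1 s) jitter | cue-to-onset latency with natural variability |
| noise_sd | 0.005 cm | electromagnetic-tracker jitter scale (resolution ≪ this ≪ 0.076 cm static accuracy) |
| reference_noise_sd | 0.005 cm | the wrist sensor is mechanically stable; "small independent noise" |
| ratio map | additive in Fisher z: base(phalanx) ∈ {0.62, 0.89, 1.54} + delta(finger) ∈ {−0.15, −0.05, 0.06, 0.21} | anchored to the reported mean z-ratios; additivity on the analysis scale makes the finger × phalanx interaction truly null, matching the reported non-significant interaction |
| participant / trial spread of z(r) | N(0, 0.15) / N(0, 0.05) | plausible between/within-participant variability; applied on the z scale so participant effects stay additive under the analysis transform |
| submovement counts | thumb 1; finger 2 (+1 for ring/little, +1 for proximal) | reproduces the reported smoothness asymmetry and its gradients |
| submovement overlap | successive onsets staggered by 0.55 × unit duration | rough but single-burst composite profiles |
| amplitudes | thumb-tip-to-target distances from the rest geometry (~4.6–9.8 cm) | they meet at a single contact point |

Ground truth per trial and effector records the 5%-of-peak crossings of the
noise-free composite speed profile evaluated on a 10×-oversampled grid —
the right reference for the detector, which cannot see the instant of true
(zero-speed) movement start — plus the true displacement, ratio, and
submovement count.

**What the generator does not emulate:** articulated joint kinematics (the
moving sensor translates along a straight line), orientation data,
correlated multi-digit enslaving motion, return movements, amplitude-
dependent movement time, or heavy-tailed tracker artefacts. Passing the
synthetic recovery tests therefore demonstrates the correctness of the
pipeline's algorithms under the stated noise model, not robustness to every
failure mode of real recordings.

## Noise and detectability

White position noise of sd σ at 100 Hz leaves, after the 5 Hz zero-phase
filter and the stencil, a speed-noise floor of ≈ 5.2σ cm/s per axis
(≈ 8.3σ on the 3D resultant at rest). At σ = 0.05 cm that floor (~0.4 cm/s)
is comparable to the 5% threshold of slow or small movements (peak speed
below ~10 cm/s), which is precisely the regime where threshold detection
degrades and the fallback/manual-rescue territory begins. Validation
therefore checks three distinct things: (i) the detector agrees with an
independent dense threshold search on the same profile (noise-free: ±1
sample always; σ = 0.05 cm: ±2 samples in ≥ 95% of draws); (ii) on a brisk
canonical trial, σ = 0.05 cm noise moves onset/end by ≤ 2 samples relative
to the noise-free detection in ≥ 95% of repeats; (iii) at the generator's
default noise the full task battery recovers noise-free segmentation within
±2 samples in ≥ 90% of effector traces, the shortfall being concentrated in
the intrinsically small proximal/little-finger movements.

## Validation problem sizes

The stochastic guarantees are checked at the following sizes, chosen to
keep the default test run fast while leaving negligible Monte-Carlo
ambiguity: segmentation/oracle agreement on 1,000 draws; ratio recovery on
one participant × 12 tasks × 15 trials at σ = 0.05 cm (tolerance 0.02); SAL
submovement monotonicity on 100 draws; ANOVA closed-form agreement on 100
random datasets; qualitative effect reproduction on 20 full default
sessions (all conditions must hold in ≥ 90%); type-I calibration on 200
null sessions of 3 trials per task (trials per cell only tighten the cell
means; the test statistic operates on participant means, so calibration is
unaffected), expecting a 5% ± 3% rejection rate. `scripts/acceptance.py`
recomputes the same quantities at moderate sizes and prints them.

## Known limitations

- Absolute SAL values are parameterization-dependent (band, padding); only
  within-configuration comparisons are meaningful.
- The Huynh–Feldt epsilon is unreliable when participants ≤ levels − 1
  (singular contrast covariance); the package warns rather than fails.
- The fallback segmentation is a declared convention for spurious trials,
  not a reconstruction of any particular lab's manual procedure.
- The trajectory TSV dialect is an artifact convention; no vendor formats
  are read.
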