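# Methods

This note documents the models, numerical choices and known limitations of
the `hrvnoci` pipeline: RR-interval resampling, empirical mode
decomposition (EMD), HF/LF band recombination, sliding-time-window (STW)
endpoint-difference features, binary detection, and the synthetic tachogram
generator the experiments run on.

## Resampling (`preprocess`)

RR intervals are a function of beat count; spectral and windowed analysis
need a function of time. Each RR value (ms) is anchored at the time of its
terminating beat, tᵢ = Σ_{j≤i} RRⱼ/1000 — the standard tachogram
convention, which guarantees strictly increasing abscissae. A not-a-knot
cubic spline through (tᵢ, RRᵢ) is evaluated on the uniform grid
t₁, t₁+1/fs, … clipped to the observed time span (extrapolated cubic
splines oscillate; no sample is ever extrapolated). The not-a-knot end
condition reproduces cubic polynomials exactly, which the test suite
exploits as an oracle. Default rate fs = 8 Hz, the conventional choice for
short-term HRV. Validation rejects non-positive, non-finite or too-short
(< 4 beats) inputs; physiologically implausible but positive values
(outside 300–2000 ms by default) are *warned about and kept* — this
pipeline deliberately performs no artifact editing. The tachogram is not
mean-centered before EMD; the decomposition's residue absorbs the mean, so
centering would be a no-op downstream.

## Empirical mode decomposition (`emd`)

Classical sifting with cubic-spline envelopes:

* **Extrema.** Strict interior local maxima/minima; a flat plateau
  contributes its midpoint index (deterministic tie-break on quantized
  data).
* **Envelopes.** Cubic splines through the maxima (upper) and minima
  (lower), with the 2 extrema nearest each end mirrored past the boundary
  before fitting. Mirroring suppresses the envelope divergence that
  otherwise leaks large boundary artifacts into every IMF.
* **Inner stop rule.** Sifting h_n = h_{n−1} − m(h_{n−1}) stops when the
  Cauchy criterion Σ(h_{n−1}−h_n)²/Σh_{n−1}² < 0.2 **and** the candidate
  satisfies the IMF defining property (extrema and zero-crossing counts
  differ by ≤ 1), capped at 100 iterations. The SD-only rule, with the
  classical 0.2 threshold, accepts mid-order modes that still carry riding
  waves (in our synthetic suite ~17% of IMFs violated the defining
  property); requiring both conditions restores the property on > 95% of
  modes without a measurable effect on band routing.
* **Outer stop rule.** Extraction ends when the residue has fewer than 2
  maxima or 2 minima — operationally "a steady trend or a constant" — or
  after 12 IMFs.
* **Completeness.** The residue is what remains after subtracting each
  extracted IMF, so Σ IMFᵢ + r reconstructs the input by telescoping;
  the suite asserts ≤ 1e−8 relative error on every decomposition (observed:
  ~1e−16, pure floating-point noise).

Ensemble/CEEMDAN variants and Hilbert spectral analysis are out of scope.

## Band recombination (`bands`)

Each IMF gets the dominant frequency of its one-sided boxcar periodogram
(zero bin excluded; the periodogram integrates to the variance, which the
suite checks via Parseval). Labels: HF if dominant ≥ 0.15 Hz, else LF —
the 0.15 Hz boundary is HF-inclusive by convention, fixed and documented
rather than principled. VLF (< 0.04 Hz) is merged into LF, and the EMD
residue (a trend, i.e. VLF-like) joins LF by default (`residue_band`
switches it off, at the cost of the hf+lf=source partition). IMFs whose
dominant frequency exceeds 0.4 Hz (broadband beat noise) stay in HF by
default; `exclude_above_hz=0.4` drops them instead. Assignment is by
whole-IMF dominant frequency, not band-power fraction: it matches per-IMF
spectral inspection practice and is deterministic.

## STW endpoint-difference features (`features`)

For window size W and stride 1, feature k is lf[k+W−1] − lf[k] (right minus
left; detection uses the magnitude, so the orientation is immaterial but
fixed). Only full windows are emitted — padding would fabricate endpoint
values. The sweep runs W = 100…650 in steps of 50 resampled points
(12.5–81.25 s at 8 Hz); the detection experiment keeps
W ∈ {150, 250, 350, 450, 550, 650}. The feature is linear and
shift-equivariant (property-tested), and on stimulation recordings its
maximum magnitude grows with W until the window spans the event's full rise
— the window-size effect the experiment measures. Adaptive window sizing is
out of scope.

## Detection (`detect`)

* **Split.** 104 recordings are partitioned 71/15/18 (train/validation/
  test) by largest-remainder rounding of those ratios, deterministically
  per seed; "verified multiple times" is operationalized as repeated random
  splits with averaged test accuracy (5 repeats by default, split seed =
  base seed + repeat index).
* **Threshold backend (default).** Computes max|feature| per recording,
  orients itself toward the class with the larger training mean, and scans
  candidate cutoffs (midpoints of observed statistics) for the one
  maximizing validation accuracy (ties: training accuracy, then the
  smaller cutoff). The scientific claim is about the *feature*, not the
  classifier, so the default detector is the most transparent one able to
  read it.
* **Recurrent backend.** A single-layer LSTM (hidden size 16, scalar input,
  sigmoid readout of the final hidden state) written in numpy with manual
  backpropagation through time and full-batch Adam (50 epochs, lr 0.02);
  gradients are verified against finite differences in the suite. Inputs
  are truncated/zero-padded to `input_length` (default 300) and globally
  standardized with training statistics. Training is bit-reproducible given
  the seed.
* **Raw baseline.** The same recurrent model fed raw resampled tachograms,
  evenly decimated to `input_length` samples (4801 → 300, i.e. an effective
  0.5 Hz rate — this preserves the < 0.25 Hz band where the event lives
  while bounding BPTT length), with the same split seeds as the feature
  experiment.

## Synthetic generator (`synth`)

Instantaneous RR level (ms):

RR(t) = base + A_hf·sin(2π f_hf t + φ_hf) + A_lf·sin(2π f_lf t + φ_lf)
      + Δ·ramp((t − t_event)/τ)   [stimulation recordings only]

with defaults base = 900 ms (~67 bpm under anesthesia), f_hf = 0.25 Hz /
A_hf = 20 ms (respiratory sinus arrhythmia), f_lf = 0.08 Hz / A_lf = 35 ms
(Mayer wave), Δ = 60 ms, τ = 10 s, t_event = 300 s in a 600 s recording,
and white per-beat noise of sd 5 ms. The ramp is a logistic sigmoid clipped
to exactly 0 below −5τ and 1 above +5τ, so a same-seed T1/T2 pair is
bit-identical before event onset and differs by exactly Δ once settled (the
0.7% clipped tail is far below the beat noise). The event is a smooth
monotone *level shift* of the LF trend rather than an added oscillation:
that is precisely the signature an endpoint difference detects, and it
leaves the HF component untouched (same-seed pairs keep HF correlation
> 0.9 while LF decorrelates). Event magnitudes are plausibility-scaled
choices that make the default regime separable at large windows but not
trivially at W = 100; they are not measured clinical values.

Beats are laid down by forward integration t_{k+1} = t_k + RR(t_k)/1000
with additive per-beat noise — an approximation to an integral
pulse-frequency-modulation model that is adequate at these modulation
depths. Cohorts (default 42 T1 / 62 T2) draw per-recording sub-seeds,
random phases, and event times jittered uniformly by ±60 s. No baroreflex,
respiration coupling, ectopy or waveform synthesis is modeled: passing
tests demonstrate the pipeline's mechanics and its sensitivity to an
LF-confined transient, not clinical performance on real ECG.

## Problem sizes and runtime

The default experiment (104 recordings × 600 s at 8 Hz, 5 repeated splits,
six window sizes, plus the recurrent baseline) completes in well under a
minute on one CPU; the full test suite runs in about half a minute. Sizes
were chosen to mirror the reference cohort exactly while staying
interactive.

## Known limitations

* EMD has no uniqueness theory; band routing is validated empirically on
  well-spaced tones (≥ 80% variance routed correctly, observed ≈ 99.9%).
* The 0.15 Hz HF boundary and the residue-into-LF defaults are conventions;
  both are switchable.
* The recurrent backend is a minimal reference implementation, not a tuned
  deep model; its baseline accuracy is a comparison point, not a ceiling.
* Synthetic separability is by construction; accuracies near 100% on the
  default regime say nothing quantitative about clinical data.
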