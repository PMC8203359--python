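# hrvnoci

Detection of noxious stimulation (tracheal intubation) under general
anesthesia from heart-rate-variability (HRV) signals.

Depth-of-anesthesia monitors judge hypnosis well but analgesia poorly: an
adequately anesthetized patient can still mount an autonomic stress response
to an intense stimulus such as intubation. That response is visible in the
beat-to-beat RR-interval series. This package implements a feature-based
detection pipeline for it:

1. **Resampling** — the RR tachogram (a function of beat number) is turned
   into a function of time with a cubic spline evaluated at 8 Hz.
2. **Empirical mode decomposition (EMD)** — the tachogram s(t) is sifted
   into intrinsic mode functions, s(t) = Σᵢ IMFᵢ(t) + r(t), using
   cubic-spline envelope means m(t) = (s_up(t) + s_low(t))/2.
3. **Band recombination** — each IMF is labeled HF (dominant frequency
   ≥ 0.15 Hz, parasympathetic/respiratory) or LF (< 0.15 Hz, with VLF
   merged in), and the IMFs are summed per band into two component signals.
   Stimulation perturbs the LF component and leaves HF largely unchanged.
4. **Sliding-time-window (STW) features** — a window of W resampled points
   slides along the LF component; the feature is the difference between the
   window's right and left endpoint values. W is swept from 100 to 650
   points in steps of 50 (12.5–81.25 s at 8 Hz).
5. **Detection** — a binary detector (threshold on max|feature|, or a small
   LSTM) is trained on a 71/15/18 train/validation/test split of 104
   recordings (42 stimulation "T1", 62 control "T2") and evaluated over
   repeated random splits, per window size.

Because the clinical recordings behind this design are not public, the
package ships a synthetic tachogram generator with the same statistical
structure (HF + LF oscillations, beat noise, and a T1-only smooth LF level
shift at a known event time), so the whole pipeline is testable and
reproducible end to end.

## Worked example

```python
import numpy as np
from hrvnoci import (SynthConfig, generate_recording, resample_uniform,
                     decompose, assign_bands, recombine, endpoint_difference,
                     WindowConfig)

cfg = SynthConfig(seed=42)
rec = generate_recording(cfg, "T1")
print(f"{len(rec)} beats over {cfg.duration_s:.0f} s (label {rec.label}, "
      f"event at {rec.event_time_s:.0f} s)")

tach = resample_uniform(rec, fs=8.0)
d = decompose(tach)
a = assign_bands(d)
for i, (band, f) in enumerate(zip(a.labels, a.dominant_frequency_hz), 1):
    print(f"IMF {i}: dominant {f:.3f} Hz -> {band}")
comp = recombine(d, a)
for w in (150, 650):
    feat = endpoint_difference(comp.lf, WindowConfig(w))
    print(f"window {w:>3}: max|feature| = {np.max(np.abs(feat.values)):.1f} ms")
```

prints

```
646 beats over 600 s (label T1, event at 300 s)
IMF 1: dominant 0.251 Hz -> HF
IMF 2: dominant 0.080 Hz -> LF
IMF 3: dominant 0.038 Hz -> LF
IMF 4: dominant 0.010 Hz -> LF
IMF 5: dominant 0.005 Hz -> LF
IMF 6: dominant 0.002 Hz -> LF
window 150: max|feature| = 96.5 ms
window 650: max|feature| = 137.6 ms
```

The generator's 0.25 Hz respiratory and 0.08 Hz Mayer-wave oscillations are
recovered as the dominant frequencies of IMFs 1 and 2 and routed to the HF
and LF components. The stimulation event (a 60 ms RR shift at 300 s) shows
up as a large endpoint difference, and the feature grows as the window
widens past the event's ~10 s rise time — the window-size effect the
detection experiment quantifies.

The same stages are available from a shell:

```bash
hrvnoci simulate --out-dir data --seed 1          # cohort + manifest.csv
hrvnoci run data/manifest.csv --out-dir out      # full chain + summary.csv
hrvnoci bands data/rec000-T1.csv --out-dir out   # inspect one stage
```

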