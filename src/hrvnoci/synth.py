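"""Synthetic RR-interval recordings with a controllable stimulation event.

The generator emulates the statistical structure the detection pipeline
relies on, not cardiac physiology: an instantaneous RR level composed of a
baseline, an HF oscillation (respiratory band, 0.15-0.4 Hz), an LF
oscillation (< 0.15 Hz), white per-beat noise — and, for stimulation (T1)
recordings only, a smooth sigmoid level shift of the LF trend at a known
event time.  The noxious stimulus perturbs the LF component and leaves the
HF component untouched, which is exactly the contrast the endpoint-
difference feature is designed to pick up.

Beats are laid down by forward integration: t_{k+1} = t_k + RR(t_k)/1000
with additive per-beat noise.  This is an approximation to an integral
pulse-frequency-modulation model, adequate at the modulation depths used
here.  A matched T1/T2 pair generated from the same seed shares phases and
noise draws, so the two recordings are identical before event onset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .detect import LabeledDataset
from .preprocess import RRIntervalSequence

__all__ = [
    "SynthConfig",
    "instantaneous_rr",
    "generate_recording",
    "generate_dataset",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters (times in seconds, amplitudes in milliseconds).

    Defaults give a 600 s recording at a resting anesthetic heart rate
    (~67 bpm) with respiratory sinus arrhythmia at 0.25 Hz, a Mayer-wave-like
    LF oscillation at 0.08 Hz, mild beat-to-beat noise, and — for T1 — a
    60 ms RR shift rising over ~10 s around the 300 s mark.  Event
    magnitudes are plausibility-scaled choices, not measured clinical
    values.
    """

    duration_s: float = 600.0
    base_rr_ms: float = 900.0
    hf_freq_hz: float = 0.25
    hf_amp_ms: float = 20.0
    lf_freq_hz: float = 0.08
    lf_amp_ms: float = 35.0
    noise_sd_ms: float = 5.0
    event_time_s: float = 300.0
    event_rise_s: float = 10.0
    event_delta_ms: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.duration_s, self.base_rr_ms, self.hf_amp_ms,
               self.lf_amp_ms, self.event_rise_s, self.event_delta_ms) <= 0:
            raise ValueError("durations and amplitudes must be positive")
        if self.noise_sd_ms < 0:
            raise ValueError("noise_sd_ms must be nonnegative")
        if not (0.15 <= self.hf_freq_hz < 0.4):
            raise ValueError("hf_freq_hz must lie in [0.15, 0.4)")
        if not (0.0 < self.lf_freq_hz < 0.15):
            raise ValueError("lf_freq_hz must lie in (0, 0.15)")
        if not (0.0 <= self.event_time_s <= self.duration_s):
            raise ValueError("event window must lie inside the recording")


def _phases(cfg: SynthConfig) -> tuple[float, float]:
    """HF and LF phases, a deterministic function of the seed."""
    rng = np.random.default_rng(cfg.seed)
    phi_hf, phi_lf = rng.uniform(0.0, 2.0 * np.pi, size=2)
    return phi_hf, phi_lf


def _ramp(u):
    """Sigmoid event ramp clipped to exactly 0 below u=-5 and 1 above u=5.

    The clipping makes a same-seed T1/T2 pair bit-identical before the event
    and their post-event difference exactly event_delta; the truncated tail
    (sigma(-5) ~ 0.7%) is far below the beat noise.
    """
    u = np.asarray(u, dtype=float)
    out = np.where(u <= -5.0, 0.0,
                   np.where(u >= 5.0, 1.0, 1.0 / (1.0 + np.exp(-np.clip(u, -5, 5)))))
    return out if out.ndim else float(out)


def instantaneous_rr(t, cfg: SynthConfig, label: str):
    """Noise-free instantaneous RR level (ms) at time ``t`` seconds.

    baseline + HF sine + LF sine + (T1 only) the event level shift.
    Accepts scalars or arrays; t must lie within [0, duration].
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0) or np.any(t_arr > cfg.duration_s):
        raise ValueError("t outside [0, duration_s]")
    if label not in ("T1", "T2"):
        raise ValueError(f"label must be 'T1' or 'T2', got {label!r}")
    phi_hf, phi_lf = _phases(cfg)
    rr = (
        cfg.base_rr_ms
        + cfg.hf_amp_ms * np.sin(2.0 * np.pi * cfg.hf_freq_hz * t_arr + phi_hf)
        + cfg.lf_amp_ms * np.sin(2.0 * np.pi * cfg.lf_freq_hz * t_arr + phi_lf)
    )
    if label == "T1":
        rr = rr + cfg.event_delta_ms * _ramp(
            (t_arr - cfg.event_time_s) / cfg.event_rise_s
        )
    return rr if rr.ndim else float(rr)


def generate_recording(
    cfg: SynthConfig, label: str, recording_id: str | None = None
) -> RRIntervalSequence:
    """Generate one RR recording by forward integration of the RR level.

    Beats accumulate while their cumulative time stays within the recording
    duration; each emitted RR gets additive Gaussian noise (sd
    ``cfg.noise_sd_ms``).  Fully deterministic given ``cfg.seed``.
    """
    if label not in ("T1", "T2"):
        raise ValueError(f"label must be 'T1' or 'T2', got {label!r}")
    rng = np.random.default_rng(cfg.seed)
    rng.uniform(0.0, 2.0 * np.pi, size=2)  # consume the phase draws
    phi_hf, phi_lf = _phases(cfg)
    rr_list: list[float] = []
    t = 0.0
    while True:
        rr_clean = (
            cfg.base_rr_ms
            + cfg.hf_amp_ms * np.sin(2 * np.pi * cfg.hf_freq_hz * t + phi_hf)
            + cfg.lf_amp_ms * np.sin(2 * np.pi * cfg.lf_freq_hz * t + phi_lf)
        )
        if label == "T1":
            rr_clean += cfg.event_delta_ms * _ramp(
                (t - cfg.event_time_s) / cfg.event_rise_s
            )
        rr = rr_clean + (rng.normal(0.0, cfg.noise_sd_ms)
                         if cfg.noise_sd_ms > 0 else 0.0)
        rr = max(rr, 1.0)  # guard: RR durations must stay positive
        t_next = t + rr / 1000.0
        if t_next > cfg.duration_s + 1e-9:
            break
        rr_list.append(rr)
        t = t_next
    return RRIntervalSequence(
        np.asarray(rr_list),
        label=label,
        recording_id=recording_id or f"{label.lower()}-{cfg.seed}",
        event_time_s=cfg.event_time_s if label == "T1" else None,
    )


def generate_dataset(
    n_t1: int = 42,
    n_t2: int = 62,
    cfg: SynthConfig = SynthConfig(),
    seed: int = 0,
    event_jitter_s: float = 60.0,
) -> LabeledDataset:
    """A labeled cohort of synthetic recordings (default 42 T1 / 62 T2).

    Each recording gets its own derived seed (hence its own phases and
    noise) and a uniformly jittered event time within
    ``event_time_s ± event_jitter_s``, so no two recordings are degenerate
    copies of each other.
    """
    if n_t1 < 0 or n_t2 < 0:
        raise ValueError("class counts must be nonnegative")
    rng = np.random.default_rng(seed)
    recordings: list[RRIntervalSequence] = []
    for k, label in enumerate(["T1"] * n_t1 + ["T2"] * n_t2):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        jitter = float(rng.uniform(-event_jitter_s, event_jitter_s))
        event_time = float(
            np.clip(
                cfg.event_time_s + jitter,
                5.0 * cfg.event_rise_s,
                cfg.duration_s - 5.0 * cfg.event_rise_s,
            )
        )
        rec_cfg = replace(cfg, seed=sub_seed, event_time_s=event_time)
        recordings.append(
            generate_recording(rec_cfg, label, recording_id=f"rec{k:03d}-{label}")
        )
    return LabeledDataset(recordings=recordings)
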