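"""RR-interval validation and uniform tachogram resampling.

Raw heart-rate-variability data arrive as a sequence of RR intervals
(milliseconds between successive heartbeats), which is a function of beat
number, not of time.  Spectral and windowed analysis both need a uniformly
sampled series, so the RR sequence is interpolated with a cubic spline and
evaluated on a uniform grid — 8 Hz by default, the conventional rate for
short-term HRV work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "RRIntervalSequence",
    "UniformSeries",
    "validate_rr",
    "beat_times",
    "resample_uniform",
    "CubicSplineResampler",
    "read_rr_csv",
    "write_series_csv",
]

#: RR durations outside this band (ms) are physiologically implausible for an
#: adult under anesthesia and trigger a warning (never silent removal).
DEFAULT_RR_BAND_MS = (300.0, 2000.0)

MIN_BEATS = 4  # a cubic spline needs at least 4 support points


@dataclass(frozen=True)
class RRIntervalSequence:
    """Beat-indexed RR durations for one recording.

    Attributes
    ----------
    rr_ms : ndarray
        Strictly positive RR durations in milliseconds, one per beat.
    label : str or None
        ``"T1"`` (noxious stimulation present) or ``"T2"`` (anesthesia only).
    recording_id : str
        Opaque identifier used in file names and reports.
    event_time_s : float or None
        For synthetic T1 recordings, the known onset of the stimulation.
    """

    rr_ms: np.ndarray
    label: str | None = None
    recording_id: str = "recording"
    event_time_s: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "rr_ms", np.asarray(self.rr_ms, dtype=float))

    def __len__(self) -> int:
        return len(self.rr_ms)


@dataclass(frozen=True)
class UniformSeries:
    """A uniformly sampled real-valued series (tachogram or derived signal)."""

    values: np.ndarray
    sampling_rate_hz: float = 8.0
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if len(self.values) < 2:
            raise ValueError("a uniform series needs at least 2 samples")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        n = len(self.values)
        return self.start_time_s + np.arange(n) / self.sampling_rate_hz

    def __len__(self) -> int:
        return len(self.values)

    def with_values(self, values: np.ndarray) -> "UniformSeries":
        """Same grid, different sample values."""
        return UniformSeries(values, self.sampling_rate_hz, self.start_time_s)


def validate_rr(
    raw: Sequence[float],
    *,
    rr_band_ms: tuple[float, float] = DEFAULT_RR_BAND_MS,
    label: str | None = None,
    recording_id: str = "recording",
    event_time_s: float | None = None,
) -> RRIntervalSequence:
    """Validate a raw RR sequence and wrap it as :class:`RRIntervalSequence`.

    Raises
    ------
    ValueError
        If the sequence is empty, shorter than 4 beats, or contains a
        non-positive or non-finite duration (the offending index is named).

    Warns when positive values fall outside ``rr_band_ms``; suspect beats are
    reported, never dropped or edited.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("RR input must be a nonempty 1-D sequence")
    bad = np.flatnonzero(~np.isfinite(arr) | (arr <= 0))
    if bad.size:
        raise ValueError(
            f"non-positive or non-finite RR value at index {bad[0]} "
            f"(value={arr[bad[0]]!r})"
        )
    if arr.size < MIN_BEATS:
        raise ValueError(
            f"need at least {MIN_BEATS} beats for cubic-spline resampling, "
            f"got {arr.size}"
        )
    lo, hi = rr_band_ms
    out_of_band = np.flatnonzero((arr < lo) | (arr > hi))
    if out_of_band.size:
        warnings.warn(
            f"{out_of_band.size} RR value(s) outside the physiological band "
            f"[{lo}, {hi}] ms (first at index {out_of_band[0]}); "
            "kept unmodified",
            UserWarning,
            stacklevel=2,
        )
    return RRIntervalSequence(arr, label=label, recording_id=recording_id,
                              event_time_s=event_time_s)


def beat_times(rr: RRIntervalSequence) -> np.ndarray:
    """Time of each beat in seconds: cumulative sum of RR durations.

    RR value *i* is anchored at its terminating beat, so the returned times
    are strictly increasing and match the RR sequence in length.
    """
    return np.cumsum(rr.rr_ms) / 1000.0


def resample_uniform(rr: RRIntervalSequence, fs: float = 8.0) -> UniformSeries:
    """Resample the tachogram to a uniform grid with a cubic spline.

    A not-a-knot cubic spline is fit through ``(beat_time_i, rr_ms_i)`` and
    evaluated on ``t_first, t_first + 1/fs, ...`` up to the last grid point
    not exceeding the final beat time.  No extrapolation is performed:
    extrapolated cubic splines oscillate wildly outside the data.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if len(rr) < MIN_BEATS:
        raise ValueError(f"need at least {MIN_BEATS} beats, got {len(rr)}")
    t = beat_times(rr)
    spline = CubicSpline(t, rr.rr_ms, bc_type="not-a-knot")
    span = t[-1] - t[0]
    n = int(np.floor(span * fs + 1e-9)) + 1
    grid = t[0] + np.arange(n) / fs
    return UniformSeries(spline(grid), sampling_rate_hz=fs, start_time_s=t[0])


class CubicSplineResampler(BaseEstimator, TransformerMixin):
    """Transformer mapping RR-interval sequences to uniform tachograms.

    Parameters
    ----------
    fs : float, default 8.0
        Target sampling rate in Hz.

    Stateless (``fit`` only records metadata); provided so the resampling
    step composes with scikit-learn pipelines.
    """

    def __init__(self, fs: float = 8.0):
        self.fs = fs

    def fit(self, X, y=None):  # noqa: D102 - sklearn contract
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        """Resample one RRIntervalSequence or a list of them."""
        if isinstance(X, RRIntervalSequence):
            return resample_uniform(X, fs=self.fs)
        return [resample_uniform(rr, fs=self.fs) for rr in X]


# ---------------------------------------------------------------------------
# CSV I/O (one recording per file, header required)

def read_rr_csv(path, **validate_kwargs) -> RRIntervalSequence:
    """Read a one-column ``rr_ms`` CSV; extra columns are ignored."""
    df = pd.read_csv(path)
    if "rr_ms" not in df.columns:
        raise ValueError(f"{path}: missing required column 'rr_ms'")
    return validate_rr(df["rr_ms"].to_numpy(), **validate_kwargs)


def write_series_csv(series: UniformSeries, path) -> None:
    """Write a uniform series as ``time_s,value_ms``."""
    pd.DataFrame({"time_s": series.times, "value_ms": series.values}).to_csv(
        path, index=False
    )
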