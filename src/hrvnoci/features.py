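"""Sliding-time-window endpoint-difference feature extraction.

The noxious-stimulation signature lives in the LF component as a level
transition around the event.  A window of fixed length slides along the LF
signal and the feature is the difference between the window's two endpoint
values (right minus left; detection uses the magnitude, so the orientation
only needs to be fixed and documented).  Window sizes are counted in
resampled points — at 8 Hz, 100 points is 12.5 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .bands import ComponentSignals
from .preprocess import UniformSeries

__all__ = [
    "WindowConfig",
    "FeatureSeries",
    "endpoint_difference",
    "window_sweep",
    "selected_sizes",
    "SlidingEndpointDifference",
]

#: Default sweep over window sizes, in resampled points.
SWEEP_MIN = 100
SWEEP_MAX = 650
SWEEP_STEP = 50

#: The six sizes retained for the detection experiment.
SELECTED_SIZES = (150, 250, 350, 450, 550, 650)


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry: window length and stride, in samples."""

    size_samples: int
    step_samples: int = 1

    def __post_init__(self) -> None:
        if self.size_samples < 2:
            raise ValueError("window size must be >= 2 samples")
        if self.step_samples < 1:
            raise ValueError("window step must be >= 1 sample")


@dataclass(frozen=True)
class FeatureSeries:
    """Endpoint-difference values for one recording at one window size."""

    values: np.ndarray
    window_size: int
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)


def endpoint_difference(lf: UniformSeries, w: WindowConfig,
                        source_id: str = "") -> FeatureSeries:
    """Right-endpoint minus left-endpoint over every full window.

    For window start ``k*step``, the feature is
    ``lf[k*step + size - 1] - lf[k*step]``.  Only full windows are emitted;
    padding would fabricate endpoint values.
    """
    v = lf.values
    n, size, step = v.size, w.size_samples, w.step_samples
    if n < size:
        raise ValueError(f"series length {n} shorter than window {size}")
    starts = np.arange(0, n - size + 1, step)
    return FeatureSeries(v[starts + size - 1] - v[starts], size, source_id)


def window_sweep(
    lf: UniformSeries,
    min_size: int = SWEEP_MIN,
    max_size: int = SWEEP_MAX,
    increment: int = SWEEP_STEP,
    step_samples: int = 1,
    source_id: str = "",
) -> dict[int, FeatureSeries]:
    """Extract the endpoint-difference feature at every size in the sweep."""
    if max_size > len(lf):
        raise ValueError(
            f"window size {max_size} exceeds series length {len(lf)}"
        )
    return {
        size: endpoint_difference(
            lf, WindowConfig(size, step_samples), source_id
        )
        for size in range(min_size, max_size + 1, increment)
    }


def selected_sizes() -> tuple[int, ...]:
    """The window sizes retained for the detection experiment."""
    return SELECTED_SIZES


class SlidingEndpointDifference(BaseEstimator, TransformerMixin):
    """Transformer: LF component (or ComponentSignals) -> FeatureSeries."""

    def __init__(self, size_samples: int = SWEEP_MAX, step_samples: int = 1):
        self.size_samples = size_samples
        self.step_samples = step_samples

    def fit(self, X, y=None):
        return self

    def _one(self, x) -> FeatureSeries:
        if isinstance(x, ComponentSignals):
            x = x.lf
        return endpoint_difference(
            x, WindowConfig(self.size_samples, self.step_samples)
        )

    def transform(self, X):
        if isinstance(X, (ComponentSignals, UniformSeries)):
            return self._one(X)
        return [self._one(x) for x in X]
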