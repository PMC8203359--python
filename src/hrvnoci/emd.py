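"""Empirical mode decomposition by cubic-spline envelope sifting.

EMD splits a nonstationary signal s(t) into a small set of intrinsic mode
functions (IMFs) plus a residue trend:

    s(t) = sum_i IMF_i(t) + r(t)

Each IMF is obtained by *sifting*: repeatedly subtracting the mean of the
upper and lower cubic-spline envelopes, m(t) = (s_up(t) + s_low(t)) / 2,
until the candidate is locally symmetric.  The inner iteration stops on the
classical Cauchy criterion

    SD = sum_t (h_{n-1}(t) - h_n(t))^2 / sum_t h_{n-1}(t)^2 < sd_threshold

(with an iteration cap), and the outer loop stops once the residue has fewer
than two maxima or two minima — i.e. it is a steady trend or a constant.
The decomposition is complete by construction: the residue is what remains
after subtracting every extracted IMF, so summing everything back
reconstructs the input to floating-point accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import UniformSeries

__all__ = [
    "SiftConfig",
    "IMFDecomposition",
    "MonotoneResidueError",
    "find_local_extrema",
    "envelope_mean",
    "sift_once",
    "extract_imf",
    "decompose",
    "EMDTransformer",
]

MIN_DECOMPOSE_LENGTH = 16


class MonotoneResidueError(ValueError):
    """Signal has too few extrema to build upper/lower envelopes."""


@dataclass(frozen=True)
class SiftConfig:
    """Parameters of the sifting procedure.

    sd_threshold : Cauchy stopping threshold for the inner sift loop.
    max_sift_iterations : hard cap on inner iterations per IMF.
    max_imfs : hard cap on the number of extracted IMFs.
    boundary_mirror_extrema : number of extrema mirrored past each end
        before envelope spline fitting (suppresses edge divergence).
    """

    sd_threshold: float = 0.2
    max_sift_iterations: int = 100
    max_imfs: int = 12
    boundary_mirror_extrema: int = 2

    def __post_init__(self) -> None:
        if (
            self.sd_threshold <= 0
            or self.max_sift_iterations <= 0
            or self.max_imfs <= 0
            or self.boundary_mirror_extrema <= 0
        ):
            raise ValueError("all SiftConfig fields must be positive")


@dataclass(frozen=True)
class IMFDecomposition:
    """Ordered IMFs (highest frequency first) plus the residue trend."""

    imfs: tuple[UniformSeries, ...]
    residue: UniformSeries
    source_length: int

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        """Elementwise sum of all IMFs and the residue."""
        total = self.residue.values.copy()
        for imf in self.imfs:
            total += imf.values
        return total


def find_local_extrema(x) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior local maxima and minima.

    Flat plateaus contribute the plateau's midpoint index, which keeps the
    result deterministic on quantized data.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    # Collapse runs of equal values to a single representative point.
    run_start = np.flatnonzero(np.concatenate(([True], np.diff(x) != 0)))
    run_end = np.append(run_start[1:], x.size) - 1
    mids = (run_start + run_end) // 2
    xc = x[run_start]
    if xc.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    interior = xc[1:-1]
    is_max = (interior > xc[:-2]) & (interior > xc[2:])
    is_min = (interior < xc[:-2]) & (interior < xc[2:])
    return mids[1:-1][is_max], mids[1:-1][is_min]


def _mirrored_envelope(
    idx: np.ndarray, vals: np.ndarray, n: int, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Extend extrema by mirroring up to k of them past each boundary."""
    k_left = min(k, idx.size)
    k_right = min(k, idx.size)
    left_i = -idx[:k_left][::-1]          # reflect about sample 0
    left_v = vals[:k_left][::-1]
    right_i = 2 * (n - 1) - idx[-k_right:][::-1]  # reflect about sample n-1
    right_v = vals[-k_right:][::-1]
    return (
        np.concatenate([left_i, idx, right_i]),
        np.concatenate([left_v, vals, right_v]),
    )


def envelope_mean(x: UniformSeries, cfg: SiftConfig = SiftConfig()) -> UniformSeries:
    """Mean of the upper and lower cubic-spline envelopes of ``x``.

    Envelopes interpolate the local maxima (resp. minima), mirrored past the
    ends by ``cfg.boundary_mirror_extrema`` points so the splines stay tame
    at the boundaries.

    Raises
    ------
    MonotoneResidueError
        If fewer than two maxima or two minima exist.
    """
    v = x.values
    max_idx, min_idx = find_local_extrema(v)
    if max_idx.size < 2 or min_idx.size < 2:
        raise MonotoneResidueError(
            f"need >=2 maxima and >=2 minima, found {max_idx.size}/{min_idx.size}"
        )
    n = v.size
    grid = np.arange(n, dtype=float)
    k = cfg.boundary_mirror_extrema
    up_i, up_v = _mirrored_envelope(max_idx, v[max_idx], n, k)
    lo_i, lo_v = _mirrored_envelope(min_idx, v[min_idx], n, k)
    s_up = CubicSpline(up_i, up_v)(grid)
    s_low = CubicSpline(lo_i, lo_v)(grid)
    return x.with_values((s_up + s_low) / 2.0)


def sift_once(h: UniformSeries, cfg: SiftConfig = SiftConfig()) -> UniformSeries:
    """One sifting step: subtract the envelope mean from ``h``."""
    return h.with_values(h.values - envelope_mean(h, cfg).values)


def _zero_crossings(v: np.ndarray) -> int:
    s = np.sign(v)
    s = s[s != 0]
    return int(np.sum(s[:-1] != s[1:]))


def _is_imf_shaped(v: np.ndarray) -> bool:
    """Extrema and zero-crossing counts differ by at most one."""
    max_idx, min_idx = find_local_extrema(v)
    return abs(max_idx.size + min_idx.size - _zero_crossings(v)) <= 1


def extract_imf(s: UniformSeries, cfg: SiftConfig = SiftConfig()) -> UniformSeries:
    """Sift ``s`` until the candidate is an IMF or the iteration cap is hit.

    The stop test combines the Cauchy criterion (SD below
    ``cfg.sd_threshold``) with the IMF defining property (extrema and
    zero-crossing counts differing by at most one): a candidate only counts
    as an IMF once both hold, which prevents the SD test from accepting a
    mode that still carries riding waves.
    """
    h_prev = s
    m = envelope_mean(h_prev, cfg)  # raises MonotoneResidueError at entry
    for _ in range(cfg.max_sift_iterations):
        h = h_prev.with_values(h_prev.values - m.values)
        denom = float(np.sum(h_prev.values**2))
        if denom == 0.0:
            return h
        sd = float(np.sum((h_prev.values - h.values) ** 2)) / denom
        if sd < cfg.sd_threshold and _is_imf_shaped(h.values):
            return h
        h_prev = h
        try:
            m = envelope_mean(h_prev, cfg)
        except MonotoneResidueError:
            # Sifting exhausted the extrema; the candidate cannot be refined.
            return h_prev
    return h_prev


def decompose(s: UniformSeries, cfg: SiftConfig = SiftConfig()) -> IMFDecomposition:
    """Full EMD of a uniform series.

    IMFs are extracted from successive residues until the residue is a
    monotone trend / constant (fewer than 2 maxima or 2 minima) or
    ``cfg.max_imfs`` is reached.
    """
    if len(s) < MIN_DECOMPOSE_LENGTH:
        raise ValueError(
            f"series too short for EMD: {len(s)} < {MIN_DECOMPOSE_LENGTH}"
        )
    residue = s.values.copy()
    imfs: list[UniformSeries] = []
    for _ in range(cfg.max_imfs):
        max_idx, min_idx = find_local_extrema(residue)
        if max_idx.size < 2 or min_idx.size < 2:
            break
        imf = extract_imf(s.with_values(residue), cfg)
        imfs.append(imf)
        residue = residue - imf.values
    return IMFDecomposition(
        imfs=tuple(imfs),
        residue=s.with_values(residue),
        source_length=len(s),
    )


class EMDTransformer(BaseEstimator, TransformerMixin):
    """Sklearn-style wrapper around :func:`decompose`.

    Parameters mirror :class:`SiftConfig`; ``transform`` maps a
    :class:`~hrvnoci.preprocess.UniformSeries` (or a list of them) to
    :class:`IMFDecomposition` objects.
    """

    def __init__(
        self,
        sd_threshold: float = 0.2,
        max_sift_iterations: int = 100,
        max_imfs: int = 12,
        boundary_mirror_extrema: int = 2,
    ):
        self.sd_threshold = sd_threshold
        self.max_sift_iterations = max_sift_iterations
        self.max_imfs = max_imfs
        self.boundary_mirror_extrema = boundary_mirror_extrema

    def _config(self) -> SiftConfig:
        return SiftConfig(
            sd_threshold=self.sd_threshold,
            max_sift_iterations=self.max_sift_iterations,
            max_imfs=self.max_imfs,
            boundary_mirror_extrema=self.boundary_mirror_extrema,
        )

    def fit(self, X, y=None):
        self.config_ = self._config()
        return self

    def transform(self, X):
        cfg = self._config()
        if isinstance(X, UniformSeries):
            return decompose(X, cfg)
        return [decompose(s, cfg) for s in X]
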