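"""Spectral labeling of IMFs and HF/LF component recombination.

Short-term HRV spectra are conventionally split into a high-frequency band
(HF, 0.15-0.4 Hz, parasympathetic / respiratory), a low-frequency band
(LF, 0.04-0.15 Hz, mixed sympathetic) and a very-low-frequency band
(VLF, < 0.04 Hz).  Here VLF is merged into LF, so each IMF is labeled HF or
LF by the dominant frequency of its periodogram, and the IMFs are summed per
band into two component signals.  The EMD residue — a trend, i.e. VLF-like —
joins the LF component by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram
from sklearn.base import BaseEstimator, TransformerMixin

from .emd import IMFDecomposition
from .preprocess import UniformSeries

__all__ = [
    "HF_CUTOFF_HZ",
    "HF_UPPER_HZ",
    "BandAssignment",
    "ComponentSignals",
    "imf_spectrum",
    "dominant_frequency",
    "assign_bands",
    "recombine",
    "BandRecombiner",
]

HF_CUTOFF_HZ = 0.15   # HF band is [0.15, 0.4] Hz; boundary is HF-inclusive
HF_UPPER_HZ = 0.4

MIN_SPECTRUM_LENGTH = 32


@dataclass(frozen=True)
class BandAssignment:
    """Per-IMF band labels with the dominant frequencies that produced them.

    ``labels[i]`` is ``"HF"``, ``"LF"`` or ``"excluded"`` for IMF i;
    ``residue_band`` says whether the residue is summed into LF or dropped.
    """

    labels: tuple[str, ...]
    dominant_frequency_hz: tuple[float, ...]
    residue_band: str = "LF"


@dataclass(frozen=True)
class ComponentSignals:
    """The two recombined feature signals for one recording."""

    hf: UniformSeries
    lf: UniformSeries
    assignment: BandAssignment


def imf_spectrum(imf: UniformSeries) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of the mean-removed IMF.

    Returns (frequencies in [0, fs/2], power spectral density); the integral
    of the density equals the signal variance (Parseval).
    """
    if len(imf) < MIN_SPECTRUM_LENGTH:
        raise ValueError(
            f"series too short for a spectrum: {len(imf)} < {MIN_SPECTRUM_LENGTH}"
        )
    v = imf.values - np.mean(imf.values)
    freqs, power = periodogram(v, fs=imf.sampling_rate_hz, window="boxcar")
    return freqs, power


def dominant_frequency(freqs: np.ndarray, power: np.ndarray) -> float:
    """Frequency of the maximum-power bin, excluding the zero-frequency bin."""
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    if freqs.size < 2:
        raise ValueError("spectrum too short")
    p = power[1:]
    if not np.any(p > 0):
        raise ValueError("all-zero power spectrum has no dominant frequency")
    return float(freqs[1:][np.argmax(p)])


def assign_bands(
    d: IMFDecomposition,
    *,
    hf_cutoff_hz: float = HF_CUTOFF_HZ,
    residue_band: str = "LF",
    exclude_above_hz: float | None = None,
) -> BandAssignment:
    """Label each IMF HF or LF by its dominant periodogram frequency.

    Frequencies >= ``hf_cutoff_hz`` are HF (left-closed boundary), the rest
    LF; VLF-dominated IMFs therefore fall into LF.  With
    ``exclude_above_hz`` set, noise modes whose dominant frequency exceeds it
    (e.g. 0.4 Hz) are excluded from both components instead of joining HF.
    """
    if d.n_imfs < 1:
        raise ValueError("decomposition has no IMFs to assign")
    if residue_band not in ("LF", "excluded"):
        raise ValueError("residue_band must be 'LF' or 'excluded'")
    labels: list[str] = []
    dom: list[float] = []
    for imf in d.imfs:
        f = dominant_frequency(*imf_spectrum(imf))
        dom.append(f)
        if exclude_above_hz is not None and f > exclude_above_hz:
            labels.append("excluded")
        elif f >= hf_cutoff_hz:
            labels.append("HF")
        else:
            labels.append("LF")
    return BandAssignment(tuple(labels), tuple(dom), residue_band)


def recombine(d: IMFDecomposition, a: BandAssignment) -> ComponentSignals:
    """Sum IMFs per band into the HF and LF component signals.

    With every IMF assigned and the residue in LF, ``hf + lf`` reconstructs
    the source exactly (the band split is a partition of the EMD identity).
    """
    if len(a.labels) != d.n_imfs:
        raise ValueError(
            f"assignment covers {len(a.labels)} IMFs, decomposition has {d.n_imfs}"
        )
    n = len(d.residue)
    hf = np.zeros(n)
    lf = np.zeros(n)
    for imf, label in zip(d.imfs, a.labels):
        if len(imf) != n:
            raise ValueError("IMF length mismatch")
        if label == "HF":
            hf += imf.values
        elif label == "LF":
            lf += imf.values
    if a.residue_band == "LF":
        lf += d.residue.values
    return ComponentSignals(
        hf=d.residue.with_values(hf),
        lf=d.residue.with_values(lf),
        assignment=a,
    )


class BandRecombiner(BaseEstimator, TransformerMixin):
    """Transformer: IMFDecomposition -> ComponentSignals (HF and LF)."""

    def __init__(
        self,
        hf_cutoff_hz: float = HF_CUTOFF_HZ,
        residue_band: str = "LF",
        exclude_above_hz: float | None = None,
    ):
        self.hf_cutoff_hz = hf_cutoff_hz
        self.residue_band = residue_band
        self.exclude_above_hz = exclude_above_hz

    def fit(self, X, y=None):
        return self

    def _one(self, d: IMFDecomposition) -> ComponentSignals:
        a = assign_bands(
            d,
            hf_cutoff_hz=self.hf_cutoff_hz,
            residue_band=self.residue_band,
            exclude_above_hz=self.exclude_above_hz,
        )
        return recombine(d, a)

    def transform(self, X):
        if isinstance(X, IMFDecomposition):
            return self._one(X)
        return [self._one(d) for d in X]
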