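"""The BSEEG score: spectral-slowing ratio on 4-s windows.

Delirium shows up on EEG as *diffuse slowing* — power migrating from the
alpha range (~10 Hz) down into the delta range (~3 Hz).  The bispectral EEG
(BSEEG) score quantifies this with a single power-spectral-density ratio,

    score = log10( PSD(3 Hz) / PSD(10 Hz) ),

computed per clean 4-s window and aggregated (median by default) per
subject-channel.  A 4-s window puts both target frequencies exactly on the
0.25 Hz periodogram grid at either device rate (500 Hz or 128 Hz).  The log
makes the score signed: positive when slowing dominates, negative for a
normal alpha-dominant spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import signal as sps

from .preprocessing import Window

__all__ = [
    "PowerSpectrum",
    "BseegParams",
    "NoUsableWindowsError",
    "periodogram",
    "bseeg_window_score",
    "aggregate_bseeg",
]


class NoUsableWindowsError(ValueError):
    """Aggregation requested with no passed windows."""


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided periodogram: frequencies in Hz, densities in µV²/Hz."""

    frequencies: np.ndarray
    densities: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        d = np.asarray(self.densities, dtype=float)
        if f.shape != d.shape:
            raise ValueError("frequencies and densities must align")
        if np.any(d < -1e-12):
            raise ValueError("densities must be nonnegative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "densities", np.maximum(d, 0.0))

    @property
    def grid_spacing(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def density_at(self, target_hz: float, band_halfwidth: float = 0.0) -> float:
        """Density at the grid bin nearest ``target_hz``.

        With ``band_halfwidth`` > 0, the mean density over bins within
        ``target_hz ± band_halfwidth`` instead.
        """
        if band_halfwidth > 0:
            mask = np.abs(self.frequencies - target_hz) <= band_halfwidth + 1e-9
            return float(np.mean(self.densities[mask]))
        idx = int(np.argmin(np.abs(self.frequencies - target_hz)))
        return float(self.densities[idx])


@dataclass(frozen=True)
class BseegParams:
    """Frequencies, transform and aggregation for the BSEEG score."""

    low_hz: float = 3.0
    high_hz: float = 10.0
    log10: bool = True
    band_average: bool = False
    band_halfwidth: float = 0.25
    taper: str = "boxcar"
    aggregate: Literal["median", "mean"] = "median"

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.aggregate not in ("median", "mean"):
            raise ValueError(f"unknown aggregate {self.aggregate!r}")


def periodogram(window: Window, taper: str = "boxcar") -> PowerSpectrum:
    """One-sided FFT periodogram of a 4-s window on the 0.25 Hz grid.

    The input is de-meaned; with the default rectangular taper the estimate
    is Parseval-consistent: sum(density) × grid spacing equals the sample
    variance (up to the one-sided folding of the Nyquist bin).
    """
    if abs(window.duration - 4.0) > 1e-9:
        raise ValueError(f"BSEEG periodogram expects 4-s windows, got {window.duration} s")
    x = window.samples - window.samples.mean()
    freqs, psd = sps.periodogram(x, fs=window.sampling_rate, window=taper, detrend=False)
    return PowerSpectrum(frequencies=freqs, densities=psd)


def bseeg_window_score(window: Window, params: BseegParams = BseegParams()) -> float:
    """Score one 4-s window: log10 (or raw) ratio of PSD(3 Hz) to PSD(10 Hz).

    A zero density in either band is floored at 1e-6 × the smallest positive
    density in the spectrum, so the score is always finite; an all-zero
    spectrum (a flatline, which QC should have rejected) is an error.
    """
    spectrum = periodogram(window, taper=params.taper)
    halfwidth = params.band_halfwidth if params.band_average else 0.0
    p_low = spectrum.density_at(params.low_hz, halfwidth)
    p_high = spectrum.density_at(params.high_hz, halfwidth)

    positive = spectrum.densities[spectrum.densities > 0]
    if positive.size == 0:
        raise ValueError("all-zero spectrum: window should have been rejected as flatline")
    floor = float(positive.min()) * 1e-6
    p_low = max(p_low, floor)
    p_high = max(p_high, floor)

    ratio = p_low / p_high
    return float(np.log10(ratio)) if params.log10 else float(ratio)


def aggregate_bseeg(window_scores: Sequence[float], params: BseegParams = BseegParams()) -> float:
    """Combine per-window scores into the subject-channel score."""
    scores = np.asarray(list(window_scores), dtype=float)
    if scores.size == 0:
        raise NoUsableWindowsError("no usable windows to aggregate")
    if params.aggregate == "mean":
        return float(np.mean(scores))
    return float(np.median(scores))
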