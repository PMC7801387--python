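"""Band-pass filtering, windowing, per-window noise rejection, usability gate.

The screening method keeps only the 0.5–20 Hz band (slow delta waves up to the
low beta range), cuts each channel into fixed-length non-overlapping windows
(4 s for the spectral score, 2 s for the topological score), rejects windows
contaminated by artifacts, and scores a recording only when at least 30 s of
clean signal remain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy import signal as sps

from .signal_io import SignalRecord

__all__ = [
    "FilterSpec",
    "QcThresholds",
    "Window",
    "WindowSet",
    "bandpass_filter",
    "segment_windows",
    "qc_window",
    "qc_windows",
    "usable",
    "decimate_record",
]

QcStatus = Literal["pending", "passed", "rejected"]
QcReason = Literal["amplitude", "flatline", "high_freq_power"]


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth band-pass design.

    The method names only the band (0.5–20 Hz); a 4th-order Butterworth
    applied forward-backward is the conventional realization that keeps slow
    waves undistorted in phase.
    """

    low_cut: float = 0.5
    high_cut: float = 20.0
    family: str = "butter"
    order: int = 4

    def validate(self, sampling_rate: float) -> None:
        if not (0 < self.low_cut < self.high_cut):
            raise ValueError(f"need 0 < low_cut < high_cut, got {self.low_cut}, {self.high_cut}")
        if self.high_cut >= sampling_rate / 2:
            raise ValueError(
                f"high_cut {self.high_cut} Hz must lie below the Nyquist "
                f"frequency {sampling_rate / 2} Hz"
            )
        if self.family != "butter":
            raise ValueError(f"unsupported filter family {self.family!r}")

    def sos(self, sampling_rate: float) -> np.ndarray:
        self.validate(sampling_rate)
        return sps.butter(
            self.order, [self.low_cut, self.high_cut], btype="bandpass",
            fs=sampling_rate, output="sos",
        )


@dataclass(frozen=True)
class QcThresholds:
    """Per-window artifact-rejection thresholds (all on the filtered signal).

    * ``max_abs_amplitude_uv`` — reject above; catches EMG bursts, ECG spikes
      and electrode pops (scalp EEG rarely exceeds ~100 µV).
    * ``min_variance_uv2`` — reject below; catches flatline/disconnection.
      The default allows for the small (≪ 1 µV²) ripple a zero-phase
      band-pass filter rings into a dead span from the surrounding signal,
      while staying two orders of magnitude below any physiological window.
    * ``max_high_band_fraction`` — reject when more than this fraction of the
      window's power lies above ``high_band_hz``; catches muscle noise that
      survives the band-pass.
    """

    max_abs_amplitude_uv: float = 200.0
    min_variance_uv2: float = 0.5
    max_high_band_fraction: float = 0.5
    high_band_hz: float = 15.0

    def __post_init__(self) -> None:
        if min(self.max_abs_amplitude_uv, self.min_variance_uv2,
               self.max_high_band_fraction, self.high_band_hz) <= 0:
            raise ValueError("all QC thresholds must be positive")
        if self.max_high_band_fraction > 1:
            raise ValueError("max_high_band_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class Window:
    """A fixed-duration segment of a filtered signal with its QC verdict."""

    start_index: int
    duration: float
    sampling_rate: float
    samples: np.ndarray
    qc_status: QcStatus = "pending"
    qc_reason: QcReason | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        expected = round(self.duration * self.sampling_rate)
        if len(samples) != expected:
            raise ValueError(
                f"window of {self.duration} s at {self.sampling_rate} Hz needs "
                f"{expected} samples, got {len(samples)}"
            )
        if self.qc_status == "rejected" and self.qc_reason is None:
            raise ValueError("rejected window must carry a reason")
        object.__setattr__(self, "samples", samples)


@dataclass
class WindowSet:
    """Ordered windows of one duration cut from one record."""

    windows: list[Window]
    duration: float
    sampling_rate: float

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[Window]:
        return iter(self.windows)

    @property
    def n_total(self) -> int:
        return len(self.windows)

    @property
    def n_passed(self) -> int:
        return sum(1 for w in self.windows if w.qc_status == "passed")

    def passed(self) -> list[Window]:
        return [w for w in self.windows if w.qc_status == "passed"]

    def passed_seconds(self) -> float:
        return self.n_passed * self.duration


def bandpass_filter(record: SignalRecord, spec: FilterSpec = FilterSpec()) -> SignalRecord:
    """Zero-phase band-pass; output has identical length and sampling rate."""
    if len(record.samples) == 0:
        raise ValueError("cannot filter an empty record")
    sos = spec.sos(record.sampling_rate)
    # sosfiltfilt needs a minimum signal length for its edge padding
    padlen = 3 * (2 * spec.order + 1)
    if len(record.samples) <= padlen:
        raise ValueError(
            f"record too short to filter: {len(record.samples)} samples "
            f"(need > {padlen})"
        )
    filtered = sps.sosfiltfilt(sos, record.samples)
    return record.with_samples(filtered)


def segment_windows(record: SignalRecord, duration: float) -> WindowSet:
    """Cut consecutive non-overlapping windows; a short tail is dropped."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_per = round(duration * record.sampling_rate)
    if abs(n_per - duration * record.sampling_rate) > 1e-9:
        raise ValueError(
            f"duration {duration} s is not an integer number of samples at "
            f"{record.sampling_rate} Hz"
        )
    n_windows = len(record.samples) // n_per
    windows = [
        Window(
            start_index=i * n_per,
            duration=duration,
            sampling_rate=record.sampling_rate,
            samples=record.samples[i * n_per : (i + 1) * n_per],
        )
        for i in range(n_windows)
    ]
    return WindowSet(windows=windows, duration=duration, sampling_rate=record.sampling_rate)


def high_band_power_fraction(samples: np.ndarray, sampling_rate: float, cutoff_hz: float) -> float:
    """Fraction of (de-meaned) power strictly above ``cutoff_hz``."""
    x = np.asarray(samples, dtype=float)
    x = x - x.mean()
    total = float(np.sum(x * x))
    if total == 0.0:
        return 0.0
    freqs, psd = sps.periodogram(x, fs=sampling_rate, window="boxcar", detrend=False)
    mask = freqs > cutoff_hz
    return float(np.sum(psd[mask]) / np.sum(psd))


def qc_window(window: Window, thresholds: QcThresholds = QcThresholds()) -> Window:
    """Pure QC predicate; returns a copy with status (and reason) set.

    Checks run in a fixed order — amplitude, flatline, high-band power — so
    the recorded reason is deterministic when several would apply.
    """
    x = window.samples
    if np.max(np.abs(x)) > thresholds.max_abs_amplitude_uv:
        return replace(window, qc_status="rejected", qc_reason="amplitude")
    if float(np.var(x)) < thresholds.min_variance_uv2:
        return replace(window, qc_status="rejected", qc_reason="flatline")
    frac = high_band_power_fraction(x, window.sampling_rate, thresholds.high_band_hz)
    if frac > thresholds.max_high_band_fraction:
        return replace(window, qc_status="rejected", qc_reason="high_freq_power")
    return replace(window, qc_status="passed", qc_reason=None)


def qc_windows(windowset: WindowSet, thresholds: QcThresholds = QcThresholds()) -> WindowSet:
    """Apply :func:`qc_window` to every window (order-independent)."""
    return WindowSet(
        windows=[qc_window(w, thresholds) for w in windowset],
        duration=windowset.duration,
        sampling_rate=windowset.sampling_rate,
    )


def usable(windowset: WindowSet, min_seconds: float = 30.0) -> bool:
    """Gate: at least ``min_seconds`` of QC-passed windows.

    The boundary is inclusive: exactly 30 s of clean signal counts as usable.
    """
    return windowset.passed_seconds() >= min_seconds


def decimate_record(record: SignalRecord, target_hz: float) -> SignalRecord:
    """Integer-factor decimation (with anti-alias filter) to ``target_hz``.

    Used to bring 500 Hz recordings down to 125 Hz before the topological
    score so point-cloud geometry is comparable across devices.  The record
    must already be band-limited (run after :func:`bandpass_filter`).
    """
    factor = record.sampling_rate / target_hz
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"cannot decimate {record.sampling_rate} Hz to {target_hz} Hz: "
            "non-integer factor"
        )
    factor = round(factor)
    if factor == 1:
        return record
    out = sps.decimate(record.samples, factor, ftype="fir", zero_phase=True)
    return record.with_samples(out, sampling_rate=record.sampling_rate / factor)
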