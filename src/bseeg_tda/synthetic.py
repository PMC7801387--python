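"""Synthetic forehead-EEG generator: normal vs diffusely slowed signals.

The generator produces the two regimes the screening method discriminates:

* normal — alpha-dominant (~10 Hz) rhythm with a 1/f (pink) background;
* delirium-like — *diffuse slowing*: the oscillatory mass moves to the delta
  range. Slowing is broadband: band-limited noise over ±1 Hz around a 2.5 Hz
  center, deliberately off the 3 Hz scoring bin so the generator is not
  trivially tuned to the score.

A slowing index ``s`` in [0, 1] mixes the two regimes linearly in amplitude.
The alpha rhythm is a random-phase sinusoid with a slow (≤ 0.3 Hz) amplitude
modulation, as on real recordings; the delta component is a band-limited
Gaussian process so its spectral mass has the width of real slowing.  Four artifact kinds with per-minute
rates emulate the contamination the QC stage must catch: EMG bursts (> 15 Hz,
high amplitude), ECG spike trains (~1 Hz biphasic 80 ms transients), baseline
drift (< 0.3 Hz), and flatline spans.  Everything is reproducible from the
config and seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .signal_io import SignalRecord

__all__ = [
    "ArtifactRates",
    "SimulationConfig",
    "simulate_eeg",
    "inject_artifact",
    "simulate_cohort",
    "ARTIFACT_KINDS",
]

ARTIFACT_KINDS = ("emg", "ecg", "drift", "flatline")


@dataclass(frozen=True)
class ArtifactRates:
    """Expected artifact events per minute of recording."""

    emg: float = 1.0
    ecg: float = 4.0
    drift: float = 0.5
    flatline: float = 0.0

    def __post_init__(self) -> None:
        if min(self.emg, self.ecg, self.drift, self.flatline) < 0:
            raise ValueError("artifact rates must be nonnegative")


@dataclass(frozen=True)
class SimulationConfig:
    """One synthetic subject-channel recording.

    ``slowing_index`` 0 is a fully normal alpha-dominant trace, 1 a fully
    slowed delta-dominant one.  Amplitudes are µV: 30 µV oscillation over a
    10 µV pink background is a typical awake forehead EEG scale.
    """

    sampling_rate: float = 128.0
    duration: float = 120.0
    slowing_index: float = 0.0
    alpha_freq: float = 10.0
    delta_freq: float = 2.5
    base_amplitude: float = 30.0
    pink_noise_level: float = 10.0
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    seed: int = 0
    subject_id: str = "sim"
    channel: str = "Fp1-A1"
    device: str = "synthetic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.slowing_index <= 1.0:
            raise ValueError("slowing_index must lie in [0, 1]")
        if min(self.base_amplitude, self.pink_noise_level) < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")


def _lowpass_noise(rng: np.random.Generator, n: int, fs: float, cutoff_hz: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited below ``cutoff_hz`` (FFT mask)."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum[freqs > cutoff_hz] = 0.0
    out = np.fft.irfft(spectrum, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise (flat below 0.5 Hz to bound power)."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 0.5))
    shaping[0] = 0.0
    out = np.fft.irfft(spectrum * shaping, n)
    return out / out.std()


def _band_noise(rng: np.random.Generator, n: int, fs: float, low: float, high: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [low, high] Hz."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum[(freqs < low) | (freqs > high)] = 0.0
    out = np.fft.irfft(spectrum, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _oscillation(rng: np.random.Generator, t: np.ndarray, fs: float, freq: float) -> np.ndarray:
    """Random-phase sinusoid with slow amplitude modulation (unit RMS ~ 1/√2)."""
    phase = rng.uniform(0, 2 * np.pi)
    envelope = 1.0 + 0.25 * _lowpass_noise(rng, len(t), fs, 0.3)
    envelope = np.clip(envelope, 0.2, None)
    return envelope * np.sin(2 * np.pi * freq * t + phase)


def simulate_eeg(config: SimulationConfig) -> SignalRecord:
    """Generate one recording: mixed oscillations + pink noise + artifacts."""
    rng = np.random.default_rng(config.seed)
    n = round(config.duration * config.sampling_rate)
    t = np.arange(n) / config.sampling_rate
    s = config.slowing_index

    signal = np.zeros(n)
    if (1 - s) * config.base_amplitude > 0:
        signal += (1 - s) * config.base_amplitude * _oscillation(
            rng, t, config.sampling_rate, config.alpha_freq)
    if s * config.base_amplitude > 0:
        # broadband slowing: ±1 Hz of band noise around the delta center,
        # scaled so its RMS matches a sinusoid of the same nominal amplitude
        signal += s * config.base_amplitude / np.sqrt(2) * _band_noise(
            rng, n, config.sampling_rate,
            max(0.5, config.delta_freq - 1.0), config.delta_freq + 1.0)
    if config.pink_noise_level > 0:
        signal += config.pink_noise_level * _pink_noise(rng, n, config.sampling_rate)

    record = SignalRecord(
        subject_id=config.subject_id,
        channel=config.channel,
        sampling_rate=config.sampling_rate,
        samples=signal,
        device=config.device,
    )

    minutes = config.duration / 60.0
    rates = config.artifact_rates
    for kind, rate in (("emg", rates.emg), ("ecg", rates.ecg),
                       ("drift", rates.drift), ("flatline", rates.flatline)):
        n_events = rng.poisson(rate * minutes)
        for _ in range(n_events):
            record = inject_artifact(record, kind, seed=int(rng.integers(2**31)))
    return record


def inject_artifact(
    record: SignalRecord,
    kind: str,
    seed: int,
    amplitude: float | None = None,
) -> SignalRecord:
    """Inject one artifact event of the given kind at a seeded position.

    * ``emg`` — 0.5–2 s burst of > 15 Hz noise, default std 150 µV (≥ 5× a
      30 µV base rhythm);
    * ``ecg`` — train of 80 ms biphasic transients at ~1 Hz over a ~10 s span,
      default peak 120 µV;
    * ``drift`` — < 0.3 Hz high-amplitude baseline wave over a ~20 s span,
      default peak 150 µV (removed by the 0.5 Hz high-pass, not by QC);
    * ``flatline`` — a zeroed 5 s span.
    """
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}; choose from {ARTIFACT_KINDS}")
    rng = np.random.default_rng(seed)
    fs = record.sampling_rate
    n = len(record.samples)
    if n == 0:
        raise ValueError("cannot inject into an empty record")
    x = record.samples.copy()

    def span(length_s: float) -> tuple[int, int]:
        m = min(n, round(length_s * fs))
        start = int(rng.integers(0, max(1, n - m + 1)))
        return start, start + m

    if kind == "emg":
        amp = 150.0 if amplitude is None else amplitude
        start, stop = span(rng.uniform(0.5, 2.0))
        m = stop - start
        noise = rng.standard_normal(m)
        # keep only components above 15 Hz so the burst is EMG-band
        spec = np.fft.rfft(noise)
        freqs = np.fft.rfftfreq(m, d=1.0 / fs)
        spec[freqs <= 15.0] = 0.0
        burst = np.fft.irfft(spec, m)
        sd = burst.std()
        if sd > 0:
            burst = burst / sd * amp
        taper = np.hanning(m) if m > 2 else np.ones(m)
        x[start:stop] += burst * taper
    elif kind == "ecg":
        amp = 120.0 if amplitude is None else amplitude
        start, stop = span(10.0)
        width = max(2, round(0.080 * fs))
        half = width // 2
        pulse = np.concatenate([np.hanning(half), -0.6 * np.hanning(width - half)]) * amp
        pos = start
        while pos + width < stop:
            x[pos : pos + width] += pulse
            pos += round(fs * rng.uniform(0.85, 1.15))
    elif kind == "drift":
        amp = 150.0 if amplitude is None else amplitude
        start, stop = span(20.0)
        m = stop - start
        tt = np.arange(m) / fs
        f = rng.uniform(0.05, 0.25)
        taper = np.hanning(m) if m > 2 else np.ones(m)
        x[start:stop] += amp * np.sin(2 * np.pi * f * tt + rng.uniform(0, 2 * np.pi)) * taper
    elif kind == "flatline":
        start, stop = span(5.0)
        x[start:stop] = 0.0

    return record.with_samples(x)


def simulate_cohort(
    n_delirious: int,
    n_control: int,
    s_delirious: float = 0.9,
    s_control: float = 0.1,
    seed: int = 0,
    slowing_spread: float = 0.05,
    artifacts: bool = True,
    sampling_rate: float = 128.0,
    duration: float = 120.0,
    channel: str = "Fp1-A1",
) -> tuple[list[SignalRecord], pd.DataFrame]:
    """Simulate a labeled cohort ready for the full scoring pipeline.

    Per-subject slowing indices are drawn Normal(group mean, slowing_spread)
    clipped to [0, 1]; alpha/delta center frequencies get small per-subject
    jitter.  Returns the records and a labels table
    (subject_id, delirium_label).
    """
    if n_delirious < 1 or n_control < 1:
        raise ValueError("both groups need at least one subject")
    rng = np.random.default_rng(seed)
    rates = ArtifactRates() if artifacts else ArtifactRates(emg=0, ecg=0, drift=0, flatline=0)

    records: list[SignalRecord] = []
    rows = []
    for label, group_s, count, prefix in (
        (True, s_delirious, n_delirious, "case"),
        (False, s_control, n_control, "ctrl"),
    ):
        for i in range(count):
            sid = f"{prefix}{i:03d}"
            s = float(np.clip(rng.normal(group_s, slowing_spread), 0.0, 1.0))
            cfg = SimulationConfig(
                sampling_rate=sampling_rate,
                duration=duration,
                slowing_index=s,
                alpha_freq=float(rng.normal(10.0, 0.5)),
                delta_freq=float(np.clip(rng.normal(2.5, 0.3), 1.0, 4.0)),
                artifact_rates=rates,
                seed=int(rng.integers(2**31)),
                subject_id=sid,
                channel=channel,
            )
            records.append(simulate_eeg(cfg))
            rows.append({"subject_id": sid, "delirium_label": int(label),
                         "slowing_index": s})
    labels = pd.DataFrame(rows)
    return records, labels
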