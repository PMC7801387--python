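"""Reading and writing EEG signals and score tables.

Two-channel forehead EEG (Fp1-A1, Fp2-A2) arrives either as EDF/EDF+ or as a
plain CSV with one sample per row.  Amplitudes are microvolts (µV) throughout
the package; EDF physical dimensions are converted on read.  Per-subject score
tables (one row per subject-channel, with the BSEEG and TDA scores and window
bookkeeping) round-trip through a fixed CSV dialect in which a missing score
is an empty cell, never the text "NaN".
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignalRecord",
    "ScoreTableRow",
    "ChannelNotFoundError",
    "FormatError",
    "CANONICAL_CHANNELS",
    "read_edf",
    "write_edf",
    "read_csv_signal",
    "write_csv_signal",
    "read_scores",
    "write_scores",
]

#: Channel labels the devices produce for the two forehead derivations.
CANONICAL_CHANNELS = ("Fp1-A1", "Fp2-A2")

SCORE_COLUMNS = [
    "subject_id",
    "channel",
    "delirium_label",
    "bseeg_score",
    "tda_score",
    "n_windows_total",
    "n_windows_passed",
]


class ChannelNotFoundError(KeyError):
    """No channel in the file matches a requested label."""


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


def _normalize_label(label: str) -> str:
    """Collapse case and separator variants: 'Fp1-A1' == 'FP1A1' == 'fp1_a1'."""
    return re.sub(r"[^0-9a-z]", "", label.lower())


@dataclass(frozen=True)
class SignalRecord:
    """One subject-channel EEG trace.

    Amplitudes are µV; ``sampling_rate`` is in Hz.  The record is immutable;
    processing stages return new records via :func:`dataclasses.replace`.
    """

    subject_id: str
    channel: str
    sampling_rate: float
    samples: np.ndarray
    device: str = ""

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_seconds(self) -> float:
        return len(self.samples) / self.sampling_rate

    def with_samples(self, samples: np.ndarray, sampling_rate: float | None = None) -> "SignalRecord":
        if sampling_rate is None:
            sampling_rate = self.sampling_rate
        return replace(self, samples=np.asarray(samples, dtype=float), sampling_rate=sampling_rate)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalRecord):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.channel == other.channel
            and self.sampling_rate == other.sampling_rate
            and self.device == other.device
            and np.array_equal(self.samples, other.samples)
        )


@dataclass(frozen=True)
class ScoreTableRow:
    """Per-subject, per-channel scores with window bookkeeping.

    A score of ``None`` means the minimum-usable-signal gate failed for that
    subject-channel (for the corresponding window duration); the reason, when
    known, travels in ``missing_reason`` but is not serialized.
    """

    subject_id: str
    channel: str
    delirium_label: bool | None = None
    bseeg_score: float | None = None
    tda_score: float | None = None
    n_windows_total: int = 0
    n_windows_passed: int = 0
    missing_reason: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.n_windows_passed > self.n_windows_total:
            raise ValueError("n_windows_passed cannot exceed n_windows_total")
        if min(self.n_windows_total, self.n_windows_passed) < 0:
            raise ValueError("window counts must be nonnegative")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def read_edf(
    path: str | Path,
    channels: Sequence[str] = CANONICAL_CHANNELS,
    subject_id: str | None = None,
    device: str = "",
) -> list[SignalRecord]:
    """Read an EDF/EDF+ file and return one record per matching channel.

    Channel matching is case-insensitive and ignores separators, so device
    labels like ``FP1A1`` or ``Fp1_A1`` match the canonical ``Fp1-A1``.
    Sampling rate comes from the file header; amplitudes are converted to µV
    using the file's physical dimension.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise IOError(f"EDF file not found: {path}")
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    except Exception as exc:  # pragma: no cover - mne's error classes vary
        raise IOError(f"could not read EDF file {path}: {exc}") from exc

    available = {_normalize_label(name): name for name in raw.ch_names}
    records = []
    sid = subject_id if subject_id is not None else path.stem
    for wanted in channels:
        key = _normalize_label(wanted)
        if key not in available:
            raise ChannelNotFoundError(
                f"channel {wanted!r} not found in {path}; available: {raw.ch_names}"
            )
        data = raw.get_data(picks=[available[key]], units="uV")[0]
        records.append(
            SignalRecord(
                subject_id=sid,
                channel=wanted,
                sampling_rate=float(raw.info["sfreq"]),
                samples=data,
                device=device,
            )
        )
    return records


def write_edf(path: str | Path, records: Sequence[SignalRecord]) -> None:
    """Write records to a minimal single-data-record EDF file.

    All records must share length and sampling rate.  Samples are quantized
    to the 16-bit EDF integer range over each channel's physical span, so a
    round trip reproduces amplitudes to within one quantization step
    (span / 65535).
    """
    if not records:
        raise ValueError("no records to write")
    n = len(records[0].samples)
    fs = records[0].sampling_rate
    for r in records:
        if len(r.samples) != n or r.sampling_rate != fs:
            raise ValueError("all records must share length and sampling rate")
    if n == 0:
        raise ValueError("cannot write empty signal")

    ns = len(records)
    duration = n / fs
    header = b""
    header += b"0".ljust(8)
    header += records[0].subject_id.encode("ascii", "replace")[:80].ljust(80)
    header += b"Startdate 01-JAN-2020".ljust(80)
    header += b"01.01.20" + b"00.00.00"
    header += str(256 + 256 * ns).encode().ljust(8)
    header += b"".ljust(44)
    header += b"1".ljust(8)  # one data record holding the whole signal
    header += f"{duration:g}".encode().ljust(8)
    header += str(ns).encode().ljust(4)

    mins, maxs = [], []
    for r in records:
        lo, hi = float(np.min(r.samples)), float(np.max(r.samples))
        if lo == hi:  # EDF requires a nonzero physical span
            lo, hi = lo - 1.0, hi + 1.0
        mins.append(lo)
        maxs.append(hi)

    header += b"".join(r.channel.encode("ascii", "replace")[:16].ljust(16) for r in records)
    header += b"".ljust(80) * ns  # transducer
    header += b"uV".ljust(8) * ns
    header += b"".join(f"{v:.7g}".encode()[:8].ljust(8) for v in mins)
    header += b"".join(f"{v:.7g}".encode()[:8].ljust(8) for v in maxs)
    header += b"-32768".ljust(8) * ns
    header += b"32767".ljust(8) * ns
    header += b"".ljust(80) * ns  # prefiltering
    header += str(n).encode().ljust(8) * ns
    header += b"".ljust(32) * ns
    assert len(header) == 256 + 256 * ns

    with open(path, "wb") as fh:
        fh.write(header)
        for r, lo, hi in zip(records, mins, maxs):
            scaled = (np.asarray(r.samples) - lo) / (hi - lo) * 65535.0 - 32768.0
            fh.write(np.round(scaled).astype("<i2").tobytes())


# ---------------------------------------------------------------------------
# CSV signals
# ---------------------------------------------------------------------------

def read_csv_signal(
    path: str | Path,
    sampling_rate: float | None = None,
    subject_id: str | None = None,
    device: str = "",
) -> list[SignalRecord]:
    """Read the CSV signal dialect: header ``time_s,<channel>[,<channel>]``.

    The sampling rate is taken from the ``sampling_rate`` argument when given,
    otherwise inferred from the ``time_s`` column spacing.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if not header or header[0].strip() != "time_s":
            raise FormatError(f"{path}: first header column must be 'time_s', got {header[:1]}")
        channel_names = [h.strip() for h in header[1:]]
        if not channel_names:
            raise FormatError(f"{path}: no signal columns after time_s")
        times: list[float] = []
        columns: list[list[float]] = [[] for _ in channel_names]
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise FormatError(f"{path}: row {lineno} has {len(row)} fields, expected {len(header)}")
            try:
                times.append(float(row[0]))
                for j, cell in enumerate(row[1:]):
                    columns[j].append(float(cell))
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric value at row {lineno}: {exc}") from exc

    if sampling_rate is None:
        if len(times) < 2:
            raise FormatError(f"{path}: cannot infer sampling rate from fewer than 2 rows")
        dt = np.median(np.diff(times))
        if dt <= 0:
            raise FormatError(f"{path}: non-increasing time_s column")
        sampling_rate = 1.0 / dt

    sid = subject_id if subject_id is not None else path.stem
    return [
        SignalRecord(
            subject_id=sid,
            channel=name,
            sampling_rate=float(sampling_rate),
            samples=np.asarray(col, dtype=float),
            device=device,
        )
        for name, col in zip(channel_names, columns)
    ]


def write_csv_signal(path: str | Path, records: Sequence[SignalRecord]) -> None:
    """Write records as the CSV signal dialect (shared time base)."""
    if not records:
        raise ValueError("no records to write")
    n = len(records[0].samples)
    fs = records[0].sampling_rate
    for r in records:
        if len(r.samples) != n or r.sampling_rate != fs:
            raise ValueError("all records must share length and sampling rate")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s"] + [r.channel for r in records])
        for i in range(n):
            writer.writerow([repr(i / fs)] + [repr(float(r.samples[i])) for r in records])


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

def write_scores(path: str | Path, rows: Iterable[ScoreTableRow]) -> None:
    """Write a score-table CSV; missing values serialize as empty cells."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCORE_COLUMNS)
        for row in rows:
            writer.writerow(
                [
                    row.subject_id,
                    row.channel,
                    "" if row.delirium_label is None else int(row.delirium_label),
                    "" if row.bseeg_score is None else repr(float(row.bseeg_score)),
                    "" if row.tda_score is None else repr(float(row.tda_score)),
                    row.n_windows_total,
                    row.n_windows_passed,
                ]
            )


def read_scores(path: str | Path) -> list[ScoreTableRow]:
    """Read a score-table CSV written by :func:`write_scores`."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if header != SCORE_COLUMNS:
            raise FormatError(f"{path}: unexpected header {header}")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(SCORE_COLUMNS):
                raise FormatError(f"{path}: row {lineno} has {len(row)} fields")
            try:
                rows.append(
                    ScoreTableRow(
                        subject_id=row[0],
                        channel=row[1],
                        delirium_label=None if row[2] == "" else bool(int(row[2])),
                        bseeg_score=None if row[3] == "" else float(row[3]),
                        tda_score=None if row[4] == "" else float(row[4]),
                        n_windows_total=int(row[5]),
                        n_windows_passed=int(row[6]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: bad value at row {lineno}: {exc}") from exc
    return rows


def scores_to_frame(rows: Sequence[ScoreTableRow]) -> pd.DataFrame:
    """Score rows as a DataFrame (missing scores become NaN)."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in rows],
            "channel": [r.channel for r in rows],
            "delirium_label": [
                math.nan if r.delirium_label is None else float(r.delirium_label) for r in rows
            ],
            "bseeg_score": [math.nan if r.bseeg_score is None else r.bseeg_score for r in rows],
            "tda_score": [math.nan if r.tda_score is None else r.tda_score for r in rows],
            "n_windows_total": [r.n_windows_total for r in rows],
            "n_windows_passed": [r.n_windows_passed for r in rows],
        }
    )
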