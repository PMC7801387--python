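"""Compose the stages into subject-level and cohort-level computations.

Per subject-channel: band-pass filter → cut 4-s and 2-s windows → per-window
QC → independent ≥30 s usability gate per duration → BSEEG score from the
4-s windows, TDA score from the 2-s windows (after optional decimation of
500 Hz recordings to 125 Hz so point clouds are comparable across devices).
Per cohort: join scores to labels, drop missing scores per analysis, then
AUC with DeLong CI for each score, the paired DeLong test on subjects with
both scores, and the specificity achieved at sensitivity 0.80.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bseeg import BseegParams, aggregate_bseeg, bseeg_window_score
from .evaluation import (
    DegenerateCohortError,
    auc,
    delong_paired_test,
    specificity_at_sensitivity,
)
from .preprocessing import (
    FilterSpec,
    QcThresholds,
    bandpass_filter,
    decimate_record,
    qc_windows,
    segment_windows,
    usable,
)
from .signal_io import ScoreTableRow, SignalRecord
from .tda import EmbeddingParams, TdaParams, aggregate_tda, tda_window_score

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "score_subject",
    "score_records",
    "evaluate_cohort",
]

#: Reason string recorded when a recording has under 30 s of clean signal.
REASON_UNUSABLE = "usable<30s"


@dataclass(frozen=True)
class WindowingConfig:
    bseeg_seconds: float = 4.0
    tda_seconds: float = 2.0
    usable_min_seconds: float = 30.0


@dataclass(frozen=True)
class PipelineConfig:
    """Single structured config covering every stage."""

    filter: FilterSpec = field(default_factory=FilterSpec)
    qc: QcThresholds = field(default_factory=QcThresholds)
    windows: WindowingConfig = field(default_factory=WindowingConfig)
    bseeg: BseegParams = field(default_factory=BseegParams)
    tda: TdaParams = field(default_factory=TdaParams)
    tda_decimate_to_hz: float | None = 125.0

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        data = dict(data)
        kwargs: dict[str, Any] = {}
        if "filter" in data:
            kwargs["filter"] = FilterSpec(**data["filter"])
        if "qc" in data:
            kwargs["qc"] = QcThresholds(**data["qc"])
        if "windows" in data:
            kwargs["windows"] = WindowingConfig(**data["windows"])
        if "bseeg" in data:
            kwargs["bseeg"] = BseegParams(**data["bseeg"])
        if "tda" in data:
            tda = dict(data["tda"])
            if "embedding" in tda:
                tda["embedding"] = EmbeddingParams(**tda["embedding"])
            kwargs["tda"] = TdaParams(**tda)
        if "tda_decimate_to_hz" in data:
            kwargs["tda_decimate_to_hz"] = data["tda_decimate_to_hz"]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class RunManifest:
    """Provenance for one scoring run: config, inputs, counts, versions."""

    config: dict[str, Any]
    package_version: str = __version__
    started_at: str = ""
    finished_at: str = ""
    input_digests: dict[str, str] = field(default_factory=dict)
    subjects: dict[str, dict[str, Any]] = field(default_factory=dict)

    def add_input(self, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.input_digests[str(path)] = digest

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def score_subject(
    record: SignalRecord,
    config: PipelineConfig = PipelineConfig(),
    delirium_label: bool | None = None,
    compute_tda: bool = True,
    details: dict | None = None,
) -> ScoreTableRow:
    """Run the full per-subject pipeline on one record.

    The usability gate applies independently per window duration, so a
    recording can carry a BSEEG score but a missing TDA score (or vice
    versa).  ``details``, if given, is filled with per-duration window
    counts and missing-score reasons for the run manifest.
    """
    filtered = bandpass_filter(record, config.filter)

    # BSEEG branch: native rate, 4-s windows
    ws4 = qc_windows(segment_windows(filtered, config.windows.bseeg_seconds), config.qc)
    bseeg_score = None
    bseeg_reason = None
    if usable(ws4, config.windows.usable_min_seconds):
        scores4 = [bseeg_window_score(w, config.bseeg) for w in ws4.passed()]
        bseeg_score = aggregate_bseeg(scores4, config.bseeg)
    else:
        bseeg_reason = REASON_UNUSABLE

    # TDA branch: optional decimation for high-rate devices, 2-s windows
    tda_input = filtered
    if (
        config.tda_decimate_to_hz is not None
        and filtered.sampling_rate > config.tda_decimate_to_hz
        and (filtered.sampling_rate / config.tda_decimate_to_hz).is_integer()
    ):
        tda_input = decimate_record(filtered, config.tda_decimate_to_hz)
    ws2 = qc_windows(segment_windows(tda_input, config.windows.tda_seconds), config.qc)
    tda_score = None
    tda_reason = None
    if not compute_tda:
        tda_reason = "tda-disabled"
    elif usable(ws2, config.windows.usable_min_seconds):
        scores2 = [tda_window_score(w, config.tda) for w in ws2.passed()]
        tda_score = aggregate_tda(scores2, config.tda)
    else:
        tda_reason = REASON_UNUSABLE

    reasons = [r for r in (bseeg_reason, tda_reason) if r is not None]
    if details is not None:
        details.update(
            {
                "n_windows_bseeg_total": ws4.n_total,
                "n_windows_bseeg_passed": ws4.n_passed,
                "n_windows_tda_total": ws2.n_total,
                "n_windows_tda_passed": ws2.n_passed,
                "bseeg_missing_reason": bseeg_reason,
                "tda_missing_reason": tda_reason,
            }
        )
    return ScoreTableRow(
        subject_id=record.subject_id,
        channel=record.channel,
        delirium_label=delirium_label,
        bseeg_score=bseeg_score,
        tda_score=tda_score,
        n_windows_total=ws4.n_total + ws2.n_total,
        n_windows_passed=ws4.n_passed + ws2.n_passed,
        missing_reason=";".join(reasons) if reasons else None,
    )


def score_records(
    records: Sequence[SignalRecord],
    config: PipelineConfig = PipelineConfig(),
    labels: Mapping[str, bool] | None = None,
    compute_tda: bool = True,
    manifest: RunManifest | None = None,
) -> list[ScoreTableRow]:
    """Score a batch of records, filling the manifest's per-subject counts."""
    rows = []
    for record in records:
        details: dict[str, Any] = {}
        label = None if labels is None else labels.get(record.subject_id)
        row = score_subject(record, config, delirium_label=label,
                            compute_tda=compute_tda, details=details)
        if manifest is not None:
            manifest.subjects[f"{record.subject_id}/{record.channel}"] = details
        rows.append(row)
    return rows


def _cohort_frame(
    score_table: pd.DataFrame, labels: pd.DataFrame | None
) -> pd.DataFrame:
    df = score_table.copy()
    if labels is not None:
        lab = labels[["subject_id", "delirium_label"]]
        df = df.drop(columns=["delirium_label"], errors="ignore").merge(
            lab, on="subject_id", how="left", validate="many_to_one"
        )
    missing = df["delirium_label"].isna()
    if missing.any():
        raise ValueError(
            "no delirium label for subjects: "
            + ", ".join(sorted(df.loc[missing, "subject_id"].astype(str)))
        )
    return df


def evaluate_cohort(
    score_table: pd.DataFrame,
    labels: pd.DataFrame | None = None,
    target_sensitivity: float = 0.80,
) -> dict[str, Any]:
    """Cohort report: per-channel AUCs, paired DeLong, operating points.

    ``score_table`` columns follow the score CSV dialect; ``labels`` (columns
    subject_id, delirium_label) overrides/supplies the label column.  Missing
    scores are dropped pairwise per analysis: each single-score AUC uses all
    subjects with that score, while the paired DeLong test uses the
    intersection with both.
    """
    df = _cohort_frame(score_table, labels)
    report: dict[str, Any] = {"channels": {}}
    for channel, sub in df.groupby("channel", sort=True):
        entry: dict[str, Any] = {}
        y = sub["delirium_label"].astype(bool).to_numpy()
        for name in ("bseeg_score", "tda_score"):
            have = sub[name].notna().to_numpy()
            if have.sum() < 2 or len(set(y[have])) < 2:
                entry[name.replace("_score", "")] = {"error": "degenerate cohort"}
                continue
            roc = auc(sub[name].to_numpy()[have], y[have])
            op = specificity_at_sensitivity(roc, target_sensitivity)
            entry[name.replace("_score", "")] = {
                "n": int(have.sum()),
                "n_positive": int(y[have].sum()),
                "auc": roc.auc,
                "ci_low": roc.ci_low,
                "ci_high": roc.ci_high,
                "operating_point": {
                    "target_sensitivity": target_sensitivity,
                    "threshold": op.threshold,
                    "sensitivity": op.sensitivity,
                    "specificity": op.specificity,
                },
            }
        both = (sub["bseeg_score"].notna() & sub["tda_score"].notna()).to_numpy()
        if both.sum() >= 2 and len(set(y[both])) == 2:
            res = delong_paired_test(
                sub["bseeg_score"].to_numpy()[both],
                sub["tda_score"].to_numpy()[both],
                y[both],
            )
            entry["delong"] = {
                "n": int(both.sum()),
                "auc_bseeg": res.auc_a,
                "auc_tda": res.auc_b,
                "z": res.z,
                "p": res.p,
                "degenerate": res.degenerate,
            }
        report["channels"][str(channel)] = entry
    if not report["channels"]:
        raise DegenerateCohortError("empty score table")
    if all(
        all(isinstance(v, dict) and "error" in v for k, v in entry.items() if k != "delong")
        for entry in report["channels"].values()
    ):
        raise DegenerateCohortError("no channel has both classes with scores")
    return report


def roc_points_frame(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Threshold sweep as a DataFrame (for the ROC CSV export)."""
    roc = auc(scores, labels)
    return pd.DataFrame(roc.thresholds, columns=["threshold", "sensitivity", "specificity"])
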