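"""End-to-end study orchestration.

Reproduces the study's result tables from a batch of submission files:
ingestion and exclusion accounting, per-landmark accuracy (MRE/SDR),
interrater reliability of the reference (when rater tracings are
given), likelihood-ratio-selected mixed models for accuracy and
tracing time, and the 22-item measurement comparison between students
and expert raters.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__, tables
from .accuracy import AccuracyRecord, AccuracySummary, summarize
from .landmark_io import (
    ExclusionReport,
    InvalidSubmission,
    LandmarkSet,
    ReferenceSet,
    Submission,
    apply_exclusions,
    load_submission_file,
    pseudonymize_submissions,
    tracing_time,
)
from .muenster22 import PixelSpacing, compute_analysis
from .accuracy import radial_errors
from .reliability import landmark_icc
from .study_models import (
    SelectionResult,
    StudyRecord,
    select_model,
    welch_t,
)
from .synthetic_data import default_spacing

__all__ = ["StudyReport", "run_study", "write_report"]

log = logging.getLogger("cephmetrics")


@dataclass
class StudyReport:
    """All result tables of one end-to-end study run."""

    exclusions: ExclusionReport
    accuracy: AccuracySummary | None
    reliability: pd.DataFrame | None  # per-landmark ICC table
    model_mre: SelectionResult | None
    model_time: SelectionResult | None
    measurements: pd.DataFrame | None  # per-measurement comparison
    records: list[StudyRecord]
    metadata: dict

    @property
    def n_included(self) -> int:
        return len(self.exclusions.included)


def _study_records(
    included: Sequence[Submission],
    accuracy_records: Sequence[AccuracyRecord],
) -> list[StudyRecord]:
    out = []
    for sub, acc in zip(included, accuracy_records):
        try:
            minutes = tracing_time(sub)
        except ValueError:
            minutes = None
        gender = sub.gender if sub.gender in ("female", "male") else "female"
        out.append(
            StudyRecord(
                subject_id=sub.subject_id,
                device=sub.device,
                image=sub.image_id,
                gender=gender,
                order="first" if sub.order_index == 0 else "second",
                mre=acc.mre,
                time=minutes,
            )
        )
    return out


def _measurement_comparison(
    included: Sequence[Submission],
    rater_sets: Mapping[str, Sequence[LandmarkSet]],
    spacing: Mapping[str, PixelSpacing],
) -> pd.DataFrame:
    """Welch comparison of student vs rater measurement values."""
    stud_values: dict[str, list[float]] = {}
    for sub in included:
        res = compute_analysis(sub.landmarks, spacing[sub.image_id])
        for name, val in res.as_dict().items():
            stud_values.setdefault(name, []).append(val)
    rater_values: dict[str, list[float]] = {}
    for img, sets in rater_sets.items():
        for ls in sets:
            res = compute_analysis(ls, spacing[img])
            for name, val in res.as_dict().items():
                rater_values.setdefault(name, []).append(val)

    rows = []
    for name in stud_values:
        s = np.asarray(stud_values[name])
        r = np.asarray(rater_values[name])
        t, df, p = welch_t(r, s)
        rows.append(
            {
                "measurement": name,
                "reference_mean": r.mean(),
                "reference_sd": r.std(ddof=1),
                "student_mean": s.mean(),
                "student_sd": s.std(ddof=1),
                "t": t,
                "df": df,
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("measurement")


def run_study(
    submissions: Sequence[Submission | InvalidSubmission] | str | Path,
    references: Mapping[str, ReferenceSet] | None = None,
    spacing: Mapping[str, PixelSpacing] | None = None,
    rater_sets: Mapping[str, Sequence[LandmarkSet]] | None = None,
    salt: str | None = None,
    allowed_images: Sequence[str] = ("A", "B"),
    seed: int | None = None,
) -> StudyReport:
    """Run the full analysis pipeline over a submission batch.

    ``submissions`` may be parsed objects or a directory of JSON files.
    References default to the packaged expert coordinates and spacings.
    An empty batch yields a report with empty tables and a warning.
    """
    if isinstance(submissions, (str, Path)):
        paths = sorted(Path(submissions).glob("*.json"))
        batch = [load_submission_file(p) for p in paths]
    else:
        batch = list(submissions)

    references = references or {
        img: tables.reference_set(img) for img in allowed_images
    }
    spacing = spacing or default_spacing()

    report_meta = {
        "version": __version__,
        "seed": seed,
        "n_input": len(batch),
    }

    exclusions = apply_exclusions(batch, allowed_images)
    included = exclusions.included
    if salt:
        included = pseudonymize_submissions(included, salt)
    log.info(
        "ingested %d submissions: %d included, excluded %s",
        len(batch),
        len(included),
        exclusions.counts,
    )
    if not included:
        log.warning("no submissions included; report will be empty")
        return StudyReport(
            exclusions=exclusions,
            accuracy=None,
            reliability=None,
            model_mre=None,
            model_time=None,
            measurements=None,
            records=[],
            metadata=report_meta,
        )

    acc_records = [
        AccuracyRecord(
            subject_id=sub.subject_id,
            image_id=sub.image_id,
            device=sub.device,
            errors=radial_errors(
                sub.landmarks, references[sub.image_id], spacing[sub.image_id]
            ),
        )
        for sub in included
    ]
    acc_summary = summarize(acc_records) if len(acc_records) >= 2 else None

    rel_table = None
    if rater_sets:
        icc = landmark_icc(rater_sets)
        rel_table = pd.DataFrame(
            {
                "icc": {k: v.icc for k, v in icc.items()},
                "band": {k: v.band for k, v in icc.items()},
            }
        )

    records = _study_records(included, acc_records)
    n_subjects = len({r.subject_id for r in records})
    model_mre = model_time = None
    if n_subjects >= 2 and len(records) >= 8:
        model_mre = select_model(records, "mre")
        timed = [r for r in records if r.time is not None]
        if len(timed) >= 8:
            model_time = select_model(timed, "time")

    measurements = None
    if rater_sets:
        measurements = _measurement_comparison(included, rater_sets, spacing)

    report_meta["config_hash"] = hashlib.sha256(
        json.dumps(
            {"allowed_images": list(allowed_images), "salt": bool(salt), "seed": seed},
            sort_keys=True,
        ).encode()
    ).hexdigest()[:16]
    return StudyReport(
        exclusions=exclusions,
        accuracy=acc_summary,
        reliability=rel_table,
        model_mre=model_mre,
        model_time=model_time,
        measurements=measurements,
        records=records,
        metadata=report_meta,
    )


def _selection_frame(sel: SelectionResult) -> pd.DataFrame:
    rows = []
    for name, (est, lo, hi, p) in sel.fit.effects.items():
        rows.append(
            {"effect": name, "estimate": est, "ci_low": lo, "ci_high": hi, "p": p}
        )
    return pd.DataFrame(rows).set_index("effect")


def write_report(report: StudyReport, out_dir: str | Path) -> None:
    """Write the report tables as CSV/JSON files (two-decimal style)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {
        "metadata": report.metadata,
        "n_included": report.n_included,
        "n_landmarks": report.exclusions.n_landmarks,
        "exclusion_counts": report.exclusions.counts,
    }
    if report.accuracy is not None:
        report.accuracy.per_landmark.round(2).to_csv(out / "accuracy_per_landmark.csv")
        summary["overall_mre"] = round(report.accuracy.overall_mre, 2)
        summary["overall_sdr"] = {
            f"{t:g}mm": round(v, 1) for t, v in report.accuracy.overall_sdr.items()
        }
    if report.reliability is not None:
        report.reliability.round(2).to_csv(out / "reliability.csv")
    for name, sel in (("mre", report.model_mre), ("time", report.model_time)):
        if sel is not None:
            _selection_frame(sel).round(4).to_csv(out / f"model_{name}.csv")
            summary[f"model_{name}_effects"] = list(sel.kept)
    if report.measurements is not None:
        report.measurements.round(4).to_csv(out / "measurements.csv")
    if report.records:
        pd.DataFrame([vars(r) for r in report.records]).to_csv(
            out / "records.csv", index=False
        )
    (out / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
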