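"""Landmark localization accuracy: radial errors, MRE and SDR.

The accuracy of a tracing is measured per landmark as the radial error
d_i — the Euclidean distance in mm between the placed point and the
reference point — and per submission as the mean radial error (MRE),
the arithmetic mean of the 33 d_i.  The successful detection rate
(SDR) at a threshold is the percentage of placements whose radial
error falls below it; 2 mm is the conventional clinically acceptable
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .landmark_io import LANDMARK_NAMES, LandmarkSet, ReferenceSet
from .muenster22 import PixelSpacing

__all__ = [
    "AccuracyRecord",
    "AccuracySummary",
    "radial_errors",
    "mre",
    "sdr",
    "summarize",
    "DEFAULT_THRESHOLDS",
]

#: SDR thresholds in mm reported by convention.
DEFAULT_THRESHOLDS: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)


@dataclass(frozen=True)
class AccuracyRecord:
    """Per-landmark radial errors and the MRE of one submission."""

    subject_id: str
    image_id: str
    device: str
    errors: Mapping[str, float]  # landmark -> d_i in mm

    @property
    def mre(self) -> float:
        return float(np.mean(list(self.errors.values())))


@dataclass(frozen=True)
class AccuracySummary:
    """Cohort-level accuracy: per-landmark table plus overall aggregates."""

    per_landmark: pd.DataFrame  # mean, sd, ci_low, ci_high, sdr_<t>mm columns
    overall_mre: float
    overall_sdr: Mapping[float, float]
    n_records: int


def radial_errors(
    stud: LandmarkSet, ref: ReferenceSet, spacing: PixelSpacing
) -> dict[str, float]:
    """Per-landmark Euclidean distances to the reference, in mm.

    d_i = spacing * sqrt((x_stud - x_ref)^2 + (y_stud - y_ref)^2)
    """
    missing = [n for n in stud.points if n not in ref.points]
    if missing:
        raise KeyError(f"landmarks absent from reference: {missing}")
    s = spacing.mm_per_px
    return {
        name: s * stud[name].distance_to(ref[name]) for name in stud.points
    }


def mre(errors: Mapping[str, float] | Sequence[float]) -> float:
    """Mean radial error: arithmetic mean of per-landmark errors (mm)."""
    values = (
        list(errors.values()) if isinstance(errors, Mapping) else list(errors)
    )
    if not values:
        raise ValueError("mre of an empty error set is undefined")
    return float(np.mean(values))


def sdr(
    errors: Iterable[float],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    strict: bool = True,
) -> dict[float, float]:
    """Successful detection rate (%) per threshold.

    A placement is successful when its radial error is below the
    threshold; ``strict`` chooses d < t (default) over d <= t — a
    measure-zero distinction for continuously distributed errors.
    """
    arr = np.asarray(list(errors), dtype=float)
    out: dict[float, float] = {}
    for t in thresholds:
        if t <= 0:
            raise ValueError("thresholds must be positive")
        if arr.size == 0:
            out[t] = float("nan")
        else:
            hits = (arr < t) if strict else (arr <= t)
            out[t] = float(100.0 * hits.mean())
    return out


def summarize(
    records: Sequence[AccuracyRecord],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    strict: bool = True,
) -> AccuracySummary:
    """Cohort accuracy table: per-landmark M, SD, 95% CI and SDRs.

    The confidence interval is the normal approximation
    mean ± 1.96·SD/√n, matching two-decimal table reporting.
    Overall aggregates pool every placement of every record.
    """
    if len(records) < 2:
        raise ValueError("need at least two records to summarize")
    frame = pd.DataFrame([r.errors for r in records])
    order = [n for n in LANDMARK_NAMES if n in frame.columns]
    frame = frame[order]

    mean = frame.mean()
    sd = frame.std(ddof=1)
    half = 1.96 * sd / np.sqrt(len(frame))
    table = pd.DataFrame(
        {"mean": mean, "sd": sd, "ci_low": mean - half, "ci_high": mean + half}
    )
    for t in thresholds:
        hits = (frame < t) if strict else (frame <= t)
        table[f"sdr_{t:g}mm"] = 100.0 * hits.mean()

    pooled = frame.to_numpy().ravel()
    pooled = pooled[~np.isnan(pooled)]
    return AccuracySummary(
        per_landmark=table,
        overall_mre=float(pooled.mean()),
        overall_sdr=sdr(pooled, thresholds, strict),
        n_records=len(records),
    )
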