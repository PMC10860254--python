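"""Interrater reliability: ICC(A,k) for absolute agreement of k raters.

The intraclass correlation for absolute agreement of averaged ratings
under a two-way model (McGraw & Wong's ICC(A,k), equivalently ICC2k)
is computed from the classical two-way ANOVA decomposition of an
n-targets × k-raters matrix:

    ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

with MSR the between-target, MSC the between-rater and MSE the
residual mean square.  Reliability bands follow Koo & Li: poor < 0.5,
moderate < 0.75, good < 0.9, excellent above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .landmark_io import LANDMARK_NAMES, LandmarkSet

__all__ = ["ICCResult", "icc_a_k", "landmark_icc", "koo_li_band"]

#: Relative tolerance below which the matrix is treated as constant.
_DEGENERATE_TOL = 1e-12


def koo_li_band(icc: float) -> str:
    """Koo–Li interpretation band for an ICC estimate."""
    if math.isnan(icc):
        return "undefined"
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class ICCResult:
    """ICC(A,k) estimate with its ANOVA mean squares and Koo–Li band."""

    icc: float
    band: str
    msr: float  # between-targets mean square
    msc: float  # between-raters mean square
    mse: float  # residual mean square
    n_targets: int
    n_raters: int


def icc_a_k(matrix) -> ICCResult:
    """ICC(A,k) of a complete n×k ratings matrix (targets × raters).

    Negative estimates are reported as computed (band "poor"), not
    truncated.  A matrix with zero total variance has no defined ICC
    and is reported as NaN with band "undefined".
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings matrix must be 2-D (targets x raters)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 targets and 2 raters")
    if np.isnan(m).any():
        raise ValueError("ratings matrix must be complete")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((m - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    scale = max(abs(grand), 1.0)
    if sst <= _DEGENERATE_TOL * scale**2:
        icc = float("nan")
    else:
        denom = msr + (msc - mse) / n
        icc = (msr - mse) / denom if denom != 0 else float("nan")
    return ICCResult(
        icc=icc,
        band=koo_li_band(icc),
        msr=msr,
        msc=msc,
        mse=mse,
        n_targets=n,
        n_raters=k,
    )


def landmark_icc(
    rater_sets: Mapping[str, Sequence[LandmarkSet]],
    mode: Literal["per_coordinate_pooled", "per_axis"] = "per_coordinate_pooled",
) -> dict[str, ICCResult] | dict[str, dict[str, ICCResult]]:
    """Per-landmark interrater ICC from rater tracings of the study images.

    ``rater_sets`` maps image id → one LandmarkSet per rater, with raters
    aligned across images (the i-th set of every image is the same
    rater).  In the default pooled mode each landmark's ratings matrix
    stacks the (image × axis) coordinate values as targets, yielding one
    ICC per landmark; ``per_axis`` keeps x and y as separate matrices
    (targets = images) and returns one ICC per landmark per axis.
    """
    images = sorted(rater_sets)
    if not images:
        raise ValueError("no rater sets given")
    k = len(rater_sets[images[0]])
    if k < 2:
        raise ValueError("need at least 2 raters")
    if any(len(rater_sets[img]) != k for img in images):
        raise ValueError("every image needs the same raters")

    def rows(name: str, axis: int) -> list[list[float]]:
        return [
            [rater_sets[img][r][name][axis] for r in range(k)] for img in images
        ]

    if mode == "per_coordinate_pooled":
        out: dict[str, ICCResult] = {}
        for name in LANDMARK_NAMES:
            matrix = rows(name, 0) + rows(name, 1)
            out[name] = icc_a_k(matrix)
        return out
    if mode == "per_axis":
        if len(images) < 2:
            raise ValueError("per_axis mode needs >= 2 images as targets")
        nested: dict[str, dict[str, ICCResult]] = {}
        for name in LANDMARK_NAMES:
            nested[name] = {
                "x": icc_a_k(rows(name, 0)),
                "y": icc_a_k(rows(name, 1)),
            }
        return nested
    raise ValueError(f"unknown mode {mode!r}")
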