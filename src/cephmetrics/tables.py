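"""Loaders for the packaged study tables.

Two small CSVs ship with the package: the expert reference coordinates
for the two study cephalograms (with per-landmark interrater ICCs) and
the per-landmark accuracy summary of the student cohort (mean radial
error and successful detection rates).  Both are printed study results
and double as default inputs for the simulator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .geometry import Point2D
from .landmark_io import LANDMARK_NAMES, ReferenceSet

__all__ = [
    "reference_coordinates",
    "reference_set",
    "landmark_accuracy",
    "N_RATERS",
]

#: Number of expert orthodontists whose mean defines the reference.
N_RATERS = 6


def _read(name: str) -> pd.DataFrame:
    with resources.files("cephmetrics.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def reference_coordinates() -> pd.DataFrame:
    """Reference landmark coordinates (landmark, image, x, y, icc)."""
    return _read("reference_coordinates.csv")


def reference_set(image: str = "A") -> ReferenceSet:
    """The packaged reference as a :class:`ReferenceSet` for one image."""
    df = reference_coordinates()
    sub = df[df["image"] == image]
    if sub.empty:
        raise KeyError(f"no reference coordinates for image {image!r}")
    points = {
        row.landmark: Point2D(float(row.x), float(row.y))
        for row in sub.itertuples()
    }
    missing = set(LANDMARK_NAMES) - set(points)
    if missing:
        raise ValueError(f"packaged reference incomplete: {sorted(missing)}")
    return ReferenceSet(image_id=image, points=points, n_raters=N_RATERS)


def landmark_accuracy() -> pd.DataFrame:
    """Per-landmark accuracy of the student cohort, indexed by landmark.

    Columns: mre_mean, mre_sd, ci_low, ci_high (mm) and sdr_1mm..sdr_8mm (%).
    """
    return _read("landmark_accuracy.csv").set_index("landmark")
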