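"""The Münster 22-item cephalometric analysis.

The analysis, rooted in the classic Downs, Ricketts, Rakosi and Steiner
analyses, computes 22 skeletal, dental and soft-tissue measurements
from 33 landmarks placed on a lateral cephalogram.  Angles come out in
degrees, distances in millimetres once a pixel spacing (mm/px) is
supplied, and one item is a unitless length ratio.

Each measurement rule carries a provenance status: ``verified`` rules
reproduce the study's printed reference means when applied to the
printed reference coordinates of image A; the length-ratio rule is a
plausible ``reconstructed`` definition that comes close but is not
exactly confirmed by the printed value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Mapping

from .geometry import (
    Line,
    Point2D,
    angle_at_vertex,
    angle_between_lines,
    construct_xi,
    inclination_difference,
    line_intersection,
    signed_point_line_distance,
    project_along,
)
from .landmark_io import LandmarkSet

__all__ = [
    "PixelSpacing",
    "MeasurementDefinition",
    "AnalysisResult",
    "MEASUREMENTS",
    "compute_analysis",
    "calibrate_spacing",
    "derive_constructed",
    "frankfurt_horizontal",
]

Unit = Literal["degrees", "mm", "ratio"]


@dataclass(frozen=True)
class PixelSpacing:
    """Calibration of the radiograph: millimetres per pixel."""

    mm_per_px: float

    def __post_init__(self):
        if not self.mm_per_px > 0:
            raise ValueError("pixel spacing must be positive")


@dataclass(frozen=True)
class MeasurementDefinition:
    """One measurement rule of the 22-item analysis."""

    name: str
    unit: Unit
    landmarks: tuple[str, ...]
    rule: Callable[[Mapping[str, Point2D]], float]
    status: Literal["verified", "reconstructed"] = "verified"


@dataclass(frozen=True)
class MeasurementValue:
    value: float
    unit: str  # "degrees" | "mm" | "ratio" | "px" (mm item without spacing)


@dataclass(frozen=True)
class AnalysisResult:
    """The 22 measurement values for one tracing."""

    image_id: str
    values: Mapping[str, MeasurementValue]
    spacing: PixelSpacing | None

    def __getitem__(self, name: str) -> float:
        return self.values[name].value

    def as_dict(self) -> dict[str, float]:
        return {k: v.value for k, v in self.values.items()}


def frankfurt_horizontal(pts: Mapping[str, Point2D]) -> Line:
    """The Frankfurt horizontal, directed posterior→anterior (P→Or)."""
    return Line.through(pts["P"], pts["Or"])


# -- individual rules -------------------------------------------------------
# Lines are always built from ordered landmark pairs so that the signed
# conventions (anterior_positive on cranial→caudal lines,
# inferior_positive on posterior→anterior lines) hold under any rigid
# motion of the whole tracing.


def _facial_axis(p):
    return angle_between_lines(
        Line.through(p["Ba"], p["N"]), Line.through(p["Pt"], p["Gnk"]), "obtuse"
    )


def _facial_depth(p):
    return angle_between_lines(
        Line.through(p["N"], p["Po"]), frankfurt_horizontal(p), "acute"
    )


def _snb(p):
    return angle_at_vertex(p["S"], p["N"], p["B"])


def _mandibular_plane(p):
    return angle_between_lines(
        Line.through(p["hT"], p["Me"]), frankfurt_horizontal(p), "acute"
    )


def _inner_gonion(p):
    return angle_at_vertex(p["DC"], p["Xi"], p["Pm"])


def _rel_mand_length(p):
    return p["Co"].distance_to(p["Po"])


def _maxillary_position(p):
    return angle_at_vertex(p["Ba"], p["N"], p["A"])


def _sna(p):
    return angle_at_vertex(p["S"], p["N"], p["A"])


def _palatal_plane(p):
    return inclination_difference(
        frankfurt_horizontal(p), Line.through(p["Spp"], p["Spa"])
    )


def _rel_max_length(p):
    return p["Co"].distance_to(p["A"])


def _lower_facial_height(p):
    return angle_at_vertex(p["Spa"], p["Xi"], p["Pm"])


def _convexity_a(p):
    return signed_point_line_distance(
        p["A"], Line.through(p["N"], p["Po"]), "anterior_positive"
    )


def _max_mand_ratio(p):
    return p["Co"].distance_to(p["Po"]) / p["Co"].distance_to(p["A"])


def _lower_incisor_position(p):
    return signed_point_line_distance(
        p["LoIe"], Line.through(p["A"], p["Po"]), "anterior_positive"
    )


def _lower_incisor_inclination(p):
    return angle_between_lines(
        Line.through(p["LoIa"], p["LoIe"]), Line.through(p["A"], p["Po"]), "acute"
    )


def _upper_incisor_position(p):
    return signed_point_line_distance(
        p["UpIe"], Line.through(p["A"], p["Po"]), "anterior_positive"
    )


def _upper_incisor_inclination(p):
    return angle_between_lines(
        Line.through(p["UpIa"], p["UpIe"]), Line.through(p["A"], p["Po"]), "acute"
    )


def _inter_incisor_angle(p):
    # angle between the directed incisor axes (apex→edge)
    u = Line.through(p["UpIa"], p["UpIe"])
    l = Line.through(p["LoIa"], p["LoIe"])
    ux, uy = u.unit()
    lx, ly = l.unit()
    import math

    c = max(-1.0, min(1.0, ux * lx + uy * ly))
    return math.degrees(math.acos(c))


def _vertical_molar_distance(p):
    return signed_point_line_distance(
        p["1UpMma"], Line.through(p["Spp"], p["Spa"]), "inferior_positive"
    )


def _sagittal_molar_distance(p):
    # distance of the molar from the pterygoid vertical, measured along FH
    return project_along(p["1UpMdc"], p["Pt"], frankfurt_horizontal(p))


def _lower_lip_e_line(p):
    return signed_point_line_distance(
        p["LoL"], Line.through(p["Ap"], p["Pom"]), "anterior_positive"
    )


def _upper_lip_drape(p):
    return angle_between_lines(
        Line.through(p["Sn"], p["UpL"]), frankfurt_horizontal(p), "acute"
    )


def _defn(name, unit, landmarks, rule, status="verified"):
    return MeasurementDefinition(name, unit, tuple(landmarks), rule, status)


#: The 22 measurement rules, in the analysis' conventional order.
MEASUREMENTS: tuple[MeasurementDefinition, ...] = (
    _defn("facial_axis", "degrees", ("Ba", "N", "Pt", "Gnk"), _facial_axis),
    _defn("facial_depth", "degrees", ("N", "Po", "P", "Or"), _facial_depth),
    _defn("snb", "degrees", ("S", "N", "B"), _snb),
    _defn("mandibular_plane", "degrees", ("hT", "Me", "P", "Or"), _mandibular_plane),
    _defn("inner_gonion_angle", "degrees", ("DC", "Xi", "Pm"), _inner_gonion),
    _defn("rel_mand_length", "mm", ("Co", "Po"), _rel_mand_length),
    _defn("maxillary_position", "degrees", ("Ba", "N", "A"), _maxillary_position),
    _defn("sna", "degrees", ("S", "N", "A"), _sna),
    _defn("palatal_plane", "degrees", ("P", "Or", "Spp", "Spa"), _palatal_plane),
    _defn("rel_max_length", "mm", ("Co", "A"), _rel_max_length),
    _defn("lower_facial_height", "degrees", ("Spa", "Xi", "Pm"), _lower_facial_height),
    _defn("convexity_point_a", "mm", ("A", "N", "Po"), _convexity_a),
    _defn(
        "rel_max_mand_length",
        "ratio",
        ("Co", "Po", "A"),
        _max_mand_ratio,
        status="reconstructed",
    ),
    _defn(
        "lower_incisor_position", "mm", ("LoIe", "A", "Po"), _lower_incisor_position
    ),
    _defn(
        "lower_incisor_inclination",
        "degrees",
        ("LoIa", "LoIe", "A", "Po"),
        _lower_incisor_inclination,
    ),
    _defn(
        "upper_incisor_position", "mm", ("UpIe", "A", "Po"), _upper_incisor_position
    ),
    _defn(
        "upper_incisor_inclination",
        "degrees",
        ("UpIa", "UpIe", "A", "Po"),
        _upper_incisor_inclination,
    ),
    _defn(
        "inter_incisor_angle",
        "degrees",
        ("UpIa", "UpIe", "LoIa", "LoIe"),
        _inter_incisor_angle,
    ),
    _defn(
        "vertical_molar_distance",
        "mm",
        ("1UpMma", "Spp", "Spa"),
        _vertical_molar_distance,
    ),
    _defn(
        "sagittal_molar_distance",
        "mm",
        ("1UpMdc", "Pt", "P", "Or"),
        _sagittal_molar_distance,
    ),
    _defn("lower_lip_e_line", "mm", ("LoL", "Ap", "Pom"), _lower_lip_e_line),
    _defn("upper_lip_drape", "degrees", ("Sn", "UpL", "P", "Or"), _upper_lip_drape),
)

_BY_NAME = {m.name: m for m in MEASUREMENTS}


def compute_analysis(
    landmarks: LandmarkSet, spacing: PixelSpacing | None = None
) -> AnalysisResult:
    """Compute all 22 measurements for one complete tracing.

    mm-valued items require ``spacing``; without it they are reported
    in raw pixels with unit ``"px"`` so the caller can still calibrate.
    """
    pts = landmarks.points
    values: dict[str, MeasurementValue] = {}
    for m in MEASUREMENTS:
        missing = [n for n in m.landmarks if n not in pts]
        if missing:
            raise ValueError(f"{m.name}: missing landmarks {missing}")
        raw = m.rule(pts)
        if m.unit == "mm":
            if spacing is None:
                values[m.name] = MeasurementValue(raw, "px")
            else:
                values[m.name] = MeasurementValue(raw * spacing.mm_per_px, "mm")
        else:
            values[m.name] = MeasurementValue(raw, m.unit)
    return AnalysisResult(
        image_id=landmarks.image_id, values=values, spacing=spacing
    )


def calibrate_spacing(
    landmarks: LandmarkSet, item: str, known_mm: float
) -> PixelSpacing:
    """Recover the pixel spacing from one known mm-valued measurement.

    The radiograph's scale is not part of the landmark export; inverting
    a single mm item (e.g. the convexity of point A) against a known
    physical value yields it.
    """
    if known_mm <= 0:
        raise ValueError("known_mm must be positive")
    m = _BY_NAME[item]
    if m.unit != "mm":
        raise ValueError(f"{item} is not a mm-valued measurement")
    raw_px = abs(m.rule(landmarks.points))
    if raw_px == 0:
        raise ValueError(f"{item} has zero pixel magnitude; cannot calibrate")
    return PixelSpacing(known_mm / raw_px)


def derive_constructed(
    landmarks: LandmarkSet, prefer: Literal["manual", "constructed"] = "manual"
) -> tuple[LandmarkSet, dict[str, float]]:
    """Derive the constructed landmarks Gnk and Xi geometrically.

    Gnk is the intersection of the mandibular plane (hT→Me) with the
    facial plane (N→Po); Xi the FH-aligned ramus-rectangle center from
    R1–R4.  When a manual placement exists it is validated against the
    construction; ``prefer`` selects which one the returned set keeps.
    Returns the set and a report of manual-vs-constructed distances in
    pixels (absent when no manual point existed).
    """
    pts = dict(landmarks.points)
    for req in ("hT", "Me", "N", "Po", "R1", "R2", "R3", "R4", "P", "Or"):
        if req not in pts:
            raise ValueError(f"cannot construct landmarks without {req}")
    fh = frankfurt_horizontal(pts)
    constructed = {
        "Gnk": line_intersection(
            Line.through(pts["hT"], pts["Me"]), Line.through(pts["N"], pts["Po"])
        ),
        "Xi": construct_xi(pts["R1"], pts["R2"], pts["R3"], pts["R4"], fh),
    }
    report: dict[str, float] = {}
    for name, cpt in constructed.items():
        if name in pts:
            report[name] = pts[name].distance_to(cpt)
            if prefer == "constructed":
                pts[name] = cpt
        else:
            pts[name] = cpt
    return LandmarkSet(landmarks.image_id, pts), report
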