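"""Data model and I/O for cephalometric landmark submissions.

A *submission* is one student's complete tracing of one lateral
cephalogram, exported by the tracing application as a JSON document
(schema shipped in ``data/submission.schema.json``).  This module
parses and writes those documents, applies the study's exclusion
rules, pseudonymizes student names, builds mean reference coordinates
from expert rater sets and computes per-submission tracing times.
"""

from __future__ import annotations

import csv
import hashlib
import io
import json
from dataclasses import dataclass, replace
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .geometry import Point2D

__all__ = [
    "LANDMARK_NAMES",
    "LandmarkSet",
    "Submission",
    "InvalidSubmission",
    "ReferenceSet",
    "ExclusionReason",
    "ExclusionReport",
    "SubmissionError",
    "parse_submission",
    "write_submission",
    "load_submission_file",
    "apply_exclusions",
    "pseudonymize",
    "build_reference",
    "tracing_time",
    "read_reference_csv",
    "write_reference_csv",
]

#: The 33 landmarks of the Münster 22-item analysis, in conventional order.
LANDMARK_NAMES: tuple[str, ...] = (
    "S", "N", "P", "Ba", "Or", "Pt", "Spp", "Spa", "A", "Co", "DC",
    "R1", "R2", "R3", "R4", "Xi", "hT", "Me", "Po", "B", "Pm", "Gnk",
    "UpIe", "UpIa", "LoIe", "LoIa", "1UpMdc", "1UpMma",
    "Ap", "Sn", "UpL", "LoL", "Pom",
)

_LANDMARK_SET = frozenset(LANDMARK_NAMES)


class SubmissionError(ValueError):
    """A submission document that cannot be parsed or violates the schema."""


@dataclass(frozen=True)
class LandmarkSet:
    """Named 2-D landmark points for one tracing of one image."""

    image_id: str
    points: Mapping[str, Point2D]

    def __post_init__(self):
        unknown = set(self.points) - _LANDMARK_SET
        if unknown:
            raise SubmissionError(f"unknown landmark names: {sorted(unknown)}")

    @property
    def missing(self) -> tuple[str, ...]:
        """Landmark names absent from this set, in canonical order."""
        return tuple(n for n in LANDMARK_NAMES if n not in self.points)

    @property
    def is_complete(self) -> bool:
        return not self.missing

    def __getitem__(self, name: str) -> Point2D:
        return self.points[name]

    def __len__(self) -> int:
        return len(self.points)

    def transform(self, fn) -> "LandmarkSet":
        """A new set with ``fn`` applied to every point."""
        return LandmarkSet(
            self.image_id, {n: Point2D(*fn(p)) for n, p in self.points.items()}
        )


@dataclass(frozen=True)
class Submission:
    """One student's tracing of one image plus its metadata."""

    subject_id: str
    image_id: str
    device: str  # "tablet" | "desktop"
    landmarks: LandmarkSet
    t_first: datetime | None = None
    t_last: datetime | None = None
    order_index: int = 0  # 0 if this is the subject's first analysis
    gender: str = "unknown"  # "female" | "male" | "unknown"
    image_source: str = "dicom"  # "dicom" | "screenshot"

    def __post_init__(self):
        if self.device not in ("tablet", "desktop"):
            raise SubmissionError(f"unknown device {self.device!r}")
        if self.gender not in ("female", "male", "unknown"):
            raise SubmissionError(f"unknown gender {self.gender!r}")
        if self.t_first and self.t_last and self.t_last < self.t_first:
            raise SubmissionError("last placement precedes first placement")

    def with_subject_id(self, subject_id: str) -> "Submission":
        return replace(self, subject_id=subject_id)


@dataclass(frozen=True)
class InvalidSubmission:
    """Stub for a file that could not be parsed; enters exclusion as-is."""

    source: str
    error: str


@dataclass(frozen=True)
class ReferenceSet:
    """Mean landmark coordinates over multiple expert raters for one image."""

    image_id: str
    points: Mapping[str, Point2D]
    n_raters: int

    def __getitem__(self, name: str) -> Point2D:
        return self.points[name]

    @property
    def landmark_set(self) -> LandmarkSet:
        return LandmarkSet(self.image_id, dict(self.points))


class ExclusionReason(str, Enum):
    WRONG_CEPHALOGRAM = "wrong_cephalogram"
    SCREENSHOT = "screenshot"
    WRONG_DEVICE_ASSIGNMENT = "wrong_device_assignment"
    MISSING_LANDMARKS = "missing_landmarks"
    DUPLICATE = "duplicate"
    INVALID_FILE = "invalid_file"


@dataclass
class ExclusionReport:
    """Partition of a submission batch into included and excluded."""

    included: list[Submission]
    excluded: list[tuple[Submission | InvalidSubmission, ExclusionReason]]

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {r.value: 0 for r in ExclusionReason}
        for _, reason in self.excluded:
            out[reason.value] += 1
        return out

    @property
    def n_landmarks(self) -> int:
        return sum(len(s.landmarks) for s in self.included)


# ---------------------------------------------------------------------------
# JSON submission format


def _parse_timestamp(value: str) -> datetime:
    try:
        return datetime.fromisoformat(value.replace("Z", "+00:00"))
    except (TypeError, ValueError) as exc:
        raise SubmissionError(f"bad timestamp {value!r}") from exc


def parse_submission(raw_json: bytes | str) -> Submission:
    """Parse one exported submission document.

    Malformed JSON or schema violations raise :class:`SubmissionError`.
    Missing landmark names are recorded on the returned set (they lead
    to a ``missing_landmarks`` exclusion downstream), never silently
    filled.
    """
    if isinstance(raw_json, bytes):
        raw_json = raw_json.decode("utf-8", errors="replace")
    try:
        doc = json.loads(raw_json)
    except json.JSONDecodeError as exc:
        raise SubmissionError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SubmissionError("top-level JSON value must be an object")

    try:
        image = doc["image"]
        device = doc["device"]
        raw_landmarks = doc["landmarks"]
    except KeyError as exc:
        raise SubmissionError(f"missing required key {exc.args[0]!r}") from exc
    if not isinstance(image, dict) or "id" not in image:
        raise SubmissionError("'image' must be an object with an 'id'")
    if not isinstance(raw_landmarks, list):
        raise SubmissionError("'landmarks' must be an array")

    points: dict[str, Point2D] = {}
    times: list[datetime] = []
    for entry in raw_landmarks:
        try:
            name = entry["name"]
            x = float(entry["x"])
            y = float(entry["y"])
        except (TypeError, KeyError, ValueError) as exc:
            raise SubmissionError(f"bad landmark entry {entry!r}") from exc
        if name in points:
            raise SubmissionError(f"duplicate landmark {name!r}")
        points[name] = Point2D(x, y)
        if "t" in entry:
            times.append(_parse_timestamp(entry["t"]))

    t_first = min(times) if times else None
    t_last = max(times) if times else None
    if "t_first" in doc:
        t_first = _parse_timestamp(doc["t_first"])
    if "t_last" in doc:
        t_last = _parse_timestamp(doc["t_last"])

    landmarks = LandmarkSet(str(image["id"]), points)
    return Submission(
        subject_id=str(doc.get("name", "")),
        image_id=str(image["id"]),
        device=str(device),
        landmarks=landmarks,
        t_first=t_first,
        t_last=t_last,
        order_index=int(doc.get("order", 0)),
        gender=str(doc.get("gender", "unknown")),
        image_source=str(image.get("source", "dicom")),
    )


def write_submission(sub: Submission) -> bytes:
    """Serialize a submission to the JSON export format (round-trips)."""
    doc = {
        "version": 1,
        "name": sub.subject_id,
        "image": {"id": sub.image_id, "source": sub.image_source},
        "device": sub.device,
        "order": sub.order_index,
        "gender": sub.gender,
        "landmarks": [
            {"name": n, "x": p.x, "y": p.y}
            for n, p in sorted(sub.landmarks.points.items())
        ],
    }
    if sub.t_first is not None:
        doc["t_first"] = sub.t_first.isoformat()
    if sub.t_last is not None:
        doc["t_last"] = sub.t_last.isoformat()
    return json.dumps(doc, sort_keys=True, indent=1).encode()


def load_submission_file(path: str | Path) -> Submission | InvalidSubmission:
    """Parse a submission file, returning a stub on failure."""
    path = Path(path)
    try:
        return parse_submission(path.read_bytes())
    except (SubmissionError, OSError) as exc:
        return InvalidSubmission(source=str(path), error=str(exc))


# ---------------------------------------------------------------------------
# Exclusions


def apply_exclusions(
    submissions: Sequence[Submission | InvalidSubmission],
    allowed_images: Iterable[str] = ("A", "B"),
    expected_device: Mapping[str, str] | None = None,
) -> ExclusionReport:
    """Partition a batch into included submissions and excluded ones.

    Rules, applied in order: unparsable files; tracings of a cephalogram
    other than the provided ones; screenshots of a provided cephalogram
    (re-imported captures rather than the DICOM); wrong image-to-device
    assignment when an expected mapping is given; incomplete landmark
    sets; and duplicates, resolved by keeping the earliest submission
    per (subject, image, device) by first-placement timestamp.

    The function is total: every input ends up in exactly one partition.
    """
    allowed = set(allowed_images)
    included: list[Submission] = []
    excluded: list[tuple[Submission | InvalidSubmission, ExclusionReason]] = []

    candidates: list[Submission] = []
    for sub in submissions:
        if isinstance(sub, InvalidSubmission):
            excluded.append((sub, ExclusionReason.INVALID_FILE))
        elif sub.image_id not in allowed:
            excluded.append((sub, ExclusionReason.WRONG_CEPHALOGRAM))
        elif sub.image_source == "screenshot":
            excluded.append((sub, ExclusionReason.SCREENSHOT))
        elif expected_device is not None and expected_device.get(
            sub.image_id
        ) not in (None, sub.device):
            excluded.append((sub, ExclusionReason.WRONG_DEVICE_ASSIGNMENT))
        elif not sub.landmarks.is_complete:
            excluded.append((sub, ExclusionReason.MISSING_LANDMARKS))
        else:
            candidates.append(sub)

    seen: dict[tuple[str, str, str], Submission] = {}
    order: list[tuple[str, str, str]] = []
    for sub in candidates:
        key = (sub.subject_id, sub.image_id, sub.device)
        if key not in seen:
            seen[key] = sub
            order.append(key)
        else:
            prev = seen[key]
            # keep the earliest by first-placement time; stable on ties
            if (
                sub.t_first is not None
                and prev.t_first is not None
                and sub.t_first < prev.t_first
            ):
                excluded.append((prev, ExclusionReason.DUPLICATE))
                seen[key] = sub
            else:
                excluded.append((sub, ExclusionReason.DUPLICATE))
    included = [seen[k] for k in order]
    return ExclusionReport(included=included, excluded=excluded)


# ---------------------------------------------------------------------------
# Pseudonymization


def pseudonymize(names: Sequence[str], salt: str) -> dict[str, str]:
    """Map plain names to rank-label pseudonyms via salted SHA3-256.

    Each distinct name is hashed as ``SHA3-256(name + salt)``; names are
    then ordered by hex digest and assigned 1-based, zero-padded rank
    labels.  Deterministic for a fixed salt; equal names share a
    pseudonym; the raw name never appears in the output values.
    """
    if not salt:
        raise ValueError("salt must be non-empty")
    unique = sorted(set(names))
    digests = {
        name: hashlib.sha3_256((name + salt).encode("utf-8")).hexdigest()
        for name in unique
    }
    ranked = sorted(unique, key=lambda n: digests[n])
    width = len(str(len(ranked)))
    return {name: str(i + 1).zfill(width) for i, name in enumerate(ranked)}


def pseudonymize_submissions(
    submissions: Sequence[Submission], salt: str
) -> list[Submission]:
    """Replace subject identifiers by salted rank pseudonyms."""
    mapping = pseudonymize([s.subject_id for s in submissions], salt)
    return [s.with_subject_id(mapping[s.subject_id]) for s in submissions]


# ---------------------------------------------------------------------------
# Reference construction and tracing time


def build_reference(rater_sets: Sequence[LandmarkSet]) -> ReferenceSet:
    """Coordinate-wise mean of complete rater tracings of one image."""
    if len(rater_sets) < 2:
        raise ValueError("at least two rater sets are required")
    image_ids = {s.image_id for s in rater_sets}
    if len(image_ids) != 1:
        raise ValueError(f"rater sets span multiple images: {sorted(image_ids)}")
    for s in rater_sets:
        if not s.is_complete:
            raise ValueError(f"incomplete rater set (missing {s.missing})")
    k = len(rater_sets)
    points = {
        name: Point2D(
            sum(s[name].x for s in rater_sets) / k,
            sum(s[name].y for s in rater_sets) / k,
        )
        for name in LANDMARK_NAMES
    }
    return ReferenceSet(image_id=image_ids.pop(), points=points, n_raters=k)


def tracing_time(sub: Submission) -> float:
    """Minutes elapsed between first and last landmark placement."""
    if sub.t_first is None or sub.t_last is None:
        raise ValueError("submission lacks placement timestamps")
    delta = (sub.t_last - sub.t_first).total_seconds()
    if delta < 0:
        raise ValueError("reversed timestamps")
    return delta / 60.0


# ---------------------------------------------------------------------------
# Reference CSV


def read_reference_csv(source: str | Path | io.TextIOBase) -> dict[str, ReferenceSet]:
    """Read reference coordinates (columns landmark,image,x,y[,icc]).

    Returns one :class:`ReferenceSet` per image id.  ``n_raters`` is not
    recoverable from the CSV and is recorded as 0.
    """
    if isinstance(source, (str, Path)):
        fh: io.TextIOBase = open(source, newline="")
        close = True
    else:
        fh, close = source, False
    try:
        by_image: dict[str, dict[str, Point2D]] = {}
        for row in csv.DictReader(fh):
            by_image.setdefault(row["image"], {})[row["landmark"]] = Point2D(
                float(row["x"]), float(row["y"])
            )
    finally:
        if close:
            fh.close()
    return {
        img: ReferenceSet(image_id=img, points=pts, n_raters=0)
        for img, pts in by_image.items()
    }


def write_reference_csv(refs: Mapping[str, ReferenceSet], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["landmark", "image", "x", "y"])
        for img in sorted(refs):
            ref = refs[img]
            for name in LANDMARK_NAMES:
                p = ref[name]
                writer.writerow([name, img, f"{p.x:.2f}", f"{p.y:.2f}"])
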