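"""Synthetic study generator emulating student landmark submissions.

Generates complete synthetic device-comparison studies with the
statistical structure the analysis pipeline assumes: per-landmark
placement noise whose expected radial error follows the observed
per-landmark difficulty profile, per-submission shifts from image,
gender and subject effects, a crossover image/device design switched
semester-wise, and tracing times driven by an order (learning) effect.

Placement noise is bivariate normal, optionally anisotropic (elongated
along a given orientation, as expected for landmarks on gradually
curved surfaces).  For axis SDs a >= b the expected radial error has
the closed form E[r] = sqrt(2/pi) * a * E(1 - b^2/a^2), with E the
complete elliptic integral of the second kind; scales are calibrated
by inverting it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from typing import Mapping

import numpy as np
from scipy.special import ellipe

from .geometry import Point2D
from .landmark_io import (
    LANDMARK_NAMES,
    LandmarkSet,
    ReferenceSet,
    Submission,
    write_submission,
)
from .muenster22 import PixelSpacing
from .study_models import StudyRecord
from . import tables

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "simulate_placement",
    "simulate_raters",
    "simulate_records",
    "simulate_study",
    "exclusion_fixture",
    "default_spacing",
]

_EPOCH = datetime(2021, 10, 1, 9, 0, tzinfo=timezone.utc)


def default_spacing() -> dict[str, PixelSpacing]:
    """Pixel spacings for the two study images.

    Image A's spacing is calibrated from the printed convexity of
    point A; image B's follows by matching the anatomical S–N distance
    across the two radiographs (the two films show the same order of
    skull size at different digitization scales).
    """
    from .muenster22 import calibrate_spacing

    ref_a = tables.reference_set("A")
    ref_b = tables.reference_set("B")
    sp_a = calibrate_spacing(ref_a.landmark_set, "convexity_point_a", 3.25)
    sn_a = ref_a["S"].distance_to(ref_a["N"])
    sn_b = ref_b["S"].distance_to(ref_b["N"])
    return {"A": sp_a, "B": PixelSpacing(sp_a.mm_per_px * sn_a / sn_b)}


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters of a synthetic study.

    Defaults reproduce the study conditions: 161 students (108 female),
    116 of whom submit both analyses (277 submissions), a 2.04 mm
    baseline MRE with +0.21 mm for image B and -0.24 mm for male
    students, and tracing times of 23.79 min for a first analysis with
    an 11.72 min learning gain on the second.
    """

    n_students: int = 161
    n_repeat: int = 116  # students who also submit the second analysis
    female_fraction: float = 108 / 161
    n_semesters: int = 8

    baseline_mre_mm: float = 2.04  # image A / female / desktop baseline
    image_b_effect_mm: float = 0.21
    male_effect_mm: float = -0.24
    device_effect_mm: float = 0.0  # the study found none
    order_effect_mm: float = 0.0
    subject_sd_mm: float = 0.3
    residual_sd_mm: float = 0.4

    time_intercept_min: float = 23.79
    time_order_effect_min: float = -11.72
    time_subject_sd_min: float = 4.0
    time_residual_sd_min: float = 3.0
    time_model: str = "normal"  # "normal" | "lognormal"

    #: landmark -> (anisotropy ratio a/b, orientation of the major axis
    #: in degrees, y-down frame).  Isotropic when absent.
    anisotropy: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    #: per-landmark expected radial error profile (mm); None = packaged
    #: cohort profile.
    landmark_mre_means: Mapping[str, float] | None = None

    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must lie in [0, 1]")
        if self.n_repeat > self.n_students:
            raise ValueError("n_repeat cannot exceed n_students")
        for sd in (
            self.subject_sd_mm,
            self.residual_sd_mm,
            self.time_subject_sd_min,
            self.time_residual_sd_min,
        ):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")


@dataclass
class SyntheticStudy:
    """A generated study: submissions, tidy records, and the truth."""

    config: SimulationConfig
    submissions: list[Submission]
    records: list[StudyRecord]  # realized responses per submission
    expected_mre: list[float]  # generating E[MRE] per submission
    references: dict[str, ReferenceSet]
    spacing: dict[str, PixelSpacing]

    @property
    def expected_overall_mre(self) -> float:
        return float(np.mean(self.expected_mre))


def _axis_sds(error_scale_mm: float, anisotropy: float) -> tuple[float, float]:
    """Axis SDs (major, minor) whose expected radial error is the scale."""
    if error_scale_mm < 0:
        raise ValueError("error scale must be >= 0")
    if anisotropy < 1.0:
        raise ValueError("anisotropy ratio must be >= 1")
    if error_scale_mm == 0.0:
        return 0.0, 0.0
    m = 1.0 - 1.0 / anisotropy**2
    a = error_scale_mm / (math.sqrt(2.0 / math.pi) * float(ellipe(m)))
    return a, a / anisotropy


def simulate_placement(
    ref: Point2D,
    error_scale_mm: float,
    spacing: PixelSpacing,
    rng: np.random.Generator,
    anisotropy: float = 1.0,
    orientation_deg: float = 0.0,
) -> Point2D:
    """One noisy placement around a reference point.

    ``error_scale_mm`` is the expected radial error; noise is bivariate
    normal with the major axis along ``orientation_deg``.
    """
    a, b = _axis_sds(error_scale_mm, anisotropy)
    u, v = rng.standard_normal(2)
    du, dv = a * u, b * v
    th = math.radians(orientation_deg)
    dx = du * math.cos(th) - dv * math.sin(th)
    dy = du * math.sin(th) + dv * math.cos(th)
    s = spacing.mm_per_px
    return Point2D(ref.x + dx / s, ref.y + dy / s)


def simulate_raters(
    ref_truth: LandmarkSet,
    k: int,
    noise_px: float,
    rng: np.random.Generator,
) -> list[LandmarkSet]:
    """k expert tracings as isotropic noisy copies of a true set (pixels)."""
    if k < 2:
        raise ValueError("need at least 2 raters")
    out = []
    for _ in range(k):
        pts = {
            name: Point2D(*(np.asarray(p) + noise_px * rng.standard_normal(2)))
            for name, p in ref_truth.points.items()
        }
        out.append(LandmarkSet(ref_truth.image_id, pts))
    return out


# ---------------------------------------------------------------------------
# Study-level generation


def _covariates(config: SimulationConfig, rng: np.random.Generator):
    """Per-submission design: (student, gender, device, image, order)."""
    n = config.n_students
    female = rng.random(n) < config.female_fraction
    semester = rng.integers(0, config.n_semesters, size=n)
    tablet_first = rng.random(n) < 0.5
    repeats = np.zeros(n, dtype=bool)
    repeats[rng.choice(n, size=config.n_repeat, replace=False)] = True

    rows = []
    for i in range(n):
        # semester-wise crossover: even semesters pair tablet with A,
        # odd semesters pair tablet with B
        tablet_image = "A" if semester[i] % 2 == 0 else "B"
        other_image = "B" if tablet_image == "A" else "A"
        seq = [("tablet", tablet_image), ("desktop", other_image)]
        if not tablet_first[i]:
            seq.reverse()
        n_sub = 2 if repeats[i] else 1
        for order_idx in range(n_sub):
            device, image = seq[order_idx]
            rows.append(
                {
                    "student": i,
                    "gender": "female" if female[i] else "male",
                    "device": device,
                    "image": image,
                    "order": "first" if order_idx == 0 else "second",
                }
            )
    return rows


def _expected_mre(config: SimulationConfig, row, b_subj: float, eps: float) -> float:
    m = (
        config.baseline_mre_mm
        + (config.image_b_effect_mm if row["image"] == "B" else 0.0)
        + (config.male_effect_mm if row["gender"] == "male" else 0.0)
        + (config.device_effect_mm if row["device"] == "tablet" else 0.0)
        + (config.order_effect_mm if row["order"] == "second" else 0.0)
        + b_subj
        + eps
    )
    return max(m, 0.0)


def _tracing_time(config: SimulationConfig, row, b_time: float, eps: float) -> float:
    t = (
        config.time_intercept_min
        + (config.time_order_effect_min if row["order"] == "second" else 0.0)
        + b_time
        + eps
    )
    if config.time_model == "lognormal":
        # interpret the linear predictor as the median of a lognormal
        t = max(t, 1.0) * math.exp(0.4 * eps / max(config.time_residual_sd_min, 1e-9))
    return max(t, 1.0)


def simulate_records(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[StudyRecord]:
    """Fast path: tidy study records without landmark-level simulation.

    The MRE response is drawn directly from the linear model
    (baseline + fixed effects + subject intercept + residual), which is
    what the mixed-model machinery assumes; use :func:`simulate_study`
    for the full landmark-level pipeline.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows = _covariates(config, rng)
    b_mre = config.subject_sd_mm * rng.standard_normal(config.n_students)
    b_time = config.time_subject_sd_min * rng.standard_normal(config.n_students)
    records = []
    for row in rows:
        i = row["student"]
        eps = config.residual_sd_mm * rng.standard_normal()
        eps_t = config.time_residual_sd_min * rng.standard_normal()
        records.append(
            StudyRecord(
                subject_id=f"student_{i:03d}",
                device=row["device"],
                image=row["image"],
                gender=row["gender"],
                order=row["order"],
                mre=_expected_mre(config, row, b_mre[i], eps),
                time=_tracing_time(config, row, b_time[i], eps_t),
            )
        )
    return records


def simulate_study(config: SimulationConfig | None = None) -> SyntheticStudy:
    """Generate a full synthetic study with landmark-level submissions.

    Each submission's landmarks are placed around the packaged
    reference coordinates with per-landmark radial scales proportional
    to the cohort difficulty profile, rescaled so the submission's
    expected MRE carries the configured fixed effects, subject
    intercept, and residual.  Deterministic for a fixed seed.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    refs = {img: tables.reference_set(img) for img in ("A", "B")}
    spacing = default_spacing()

    profile_tbl = tables.landmark_accuracy()["mre_mean"]
    if config.landmark_mre_means is not None:
        profile = {n: float(config.landmark_mre_means[n]) for n in LANDMARK_NAMES}
    else:
        profile = {n: float(profile_tbl[n]) for n in LANDMARK_NAMES}
    m0 = float(np.mean(list(profile.values())))

    rows = _covariates(config, rng)
    b_mre = config.subject_sd_mm * rng.standard_normal(config.n_students)
    b_time = config.time_subject_sd_min * rng.standard_normal(config.n_students)

    submissions: list[Submission] = []
    records: list[StudyRecord] = []
    expected: list[float] = []
    for k, row in enumerate(rows):
        i = row["student"]
        eps = config.residual_sd_mm * rng.standard_normal()
        eps_t = config.time_residual_sd_min * rng.standard_normal()
        m_sub = _expected_mre(config, row, b_mre[i], eps)
        minutes = _tracing_time(config, row, b_time[i], eps_t)
        image = row["image"]
        ref = refs[image]
        sp = spacing[image]

        pts: dict[str, Point2D] = {}
        for name in LANDMARK_NAMES:
            ratio, orient = config.anisotropy.get(name, (1.0, 0.0))
            pts[name] = simulate_placement(
                ref[name],
                profile[name] * m_sub / m0,
                sp,
                rng,
                anisotropy=ratio,
                orientation_deg=orient,
            )
        t_first = _EPOCH + timedelta(hours=2 * k)
        sub = Submission(
            subject_id=f"student_{i:03d}",
            image_id=image,
            device=row["device"],
            landmarks=LandmarkSet(image, pts),
            t_first=t_first,
            t_last=t_first + timedelta(minutes=minutes),
            order_index=0 if row["order"] == "first" else 1,
            gender=row["gender"],
        )
        submissions.append(sub)
        expected.append(m_sub)
        records.append(
            StudyRecord(
                subject_id=sub.subject_id,
                device=sub.device,
                image=image,
                gender=sub.gender,
                order=row["order"],
                mre=m_sub,
                time=minutes,
            )
        )
    return SyntheticStudy(
        config=config,
        submissions=submissions,
        records=records,
        expected_mre=expected,
        references=refs,
        spacing=spacing,
    )


def exclusion_fixture(
    study: SyntheticStudy,
    rng: np.random.Generator | None = None,
    n_wrong_image: int = 16,
    n_screenshot: int = 5,
    n_missing: int = 3,
    n_invalid: int = 2,
) -> list[tuple[str, bytes]]:
    """Serialize the study plus a batch of excludable submissions.

    Returns (filename, bytes) payloads: every valid submission of the
    study followed by tracings of a wrong cephalogram, screenshot
    re-imports, incomplete tracings, and invalid JSON files — the mix
    an ingestion run must filter out.
    """
    rng = np.random.default_rng(study.config.seed + 1) if rng is None else rng
    payloads: list[tuple[str, bytes]] = []
    for k, sub in enumerate(study.submissions):
        payloads.append((f"submission_{k:03d}.json", write_submission(sub)))

    def sample_valid() -> Submission:
        return study.submissions[int(rng.integers(len(study.submissions)))]

    n0 = len(payloads)
    for j in range(n_wrong_image):
        base = sample_valid()
        bad = replace(
            base,
            subject_id=f"extra_w{j:02d}",
            image_id="C",
            landmarks=LandmarkSet("C", dict(base.landmarks.points)),
        )
        payloads.append((f"submission_{n0 + j:03d}.json", write_submission(bad)))
    n0 = len(payloads)
    for j in range(n_screenshot):
        bad = replace(
            sample_valid(), subject_id=f"extra_s{j:02d}", image_source="screenshot"
        )
        payloads.append((f"submission_{n0 + j:03d}.json", write_submission(bad)))
    n0 = len(payloads)
    for j in range(n_missing):
        base = sample_valid()
        kept = {
            n: p
            for n, p in base.landmarks.points.items()
            if n not in ("Xi", "Gnk", "DC")
        }
        bad = replace(
            base,
            subject_id=f"extra_m{j:02d}",
            landmarks=LandmarkSet(base.image_id, kept),
        )
        payloads.append((f"submission_{n0 + j:03d}.json", write_submission(bad)))
    n0 = len(payloads)
    for j in range(n_invalid):
        payloads.append(
            (f"submission_{n0 + j:03d}.json", b'{"name": "broken", "image": ')
        )
    return payloads
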