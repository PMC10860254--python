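"""Submission parsing, exclusions, pseudonymization, reference building."""

import hashlib
import json
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from cephmetrics.geometry import Point2D
from cephmetrics.landmark_io import (
    LANDMARK_NAMES,
    ExclusionReason,
    InvalidSubmission,
    LandmarkSet,
    Submission,
    SubmissionError,
    apply_exclusions,
    build_reference,
    parse_submission,
    pseudonymize,
    pseudonymize_submissions,
    tracing_time,
    write_submission,
)

T0 = datetime(2022, 3, 1, 12, 0, tzinfo=timezone.utc)


def make_submission(
    subject="stu1",
    image="A",
    device="tablet",
    drop=(),
    t0=T0,
    minutes=10.0,
    **kwargs,
):
    pts = {
        name: Point2D(float(10 * i), float(5 * i + 1))
        for i, name in enumerate(LANDMARK_NAMES)
        if name not in drop
    }
    return Submission(
        subject_id=subject,
        image_id=image,
        device=device,
        landmarks=LandmarkSet(image, pts),
        t_first=t0,
        t_last=t0 + timedelta(minutes=minutes),
        **kwargs,
    )


class TestParseRoundTrip:
    def test_round_trip_identity(self):
        sub = make_submission(gender="male", order_index=1)
        again = parse_submission(write_submission(sub))
        assert again == sub

    def test_complete_submission_has_33_points(self):
        sub = parse_submission(write_submission(make_submission()))
        assert len(sub.landmarks) == 33
        assert sub.landmarks.is_complete

    def test_truncated_stream_rejected(self):
        with pytest.raises(SubmissionError):
            parse_submission(b'{"name": "x", "image": ')

    def test_missing_metadata_rejected(self):
        with pytest.raises(SubmissionError, match="device"):
            parse_submission(json.dumps({"image": {"id": "A"}, "landmarks": []}))

    def test_incomplete_set_flagged_not_filled(self):
        sub = make_submission(drop=("Xi", "Gnk", "DC"))
        again = parse_submission(write_submission(sub))
        assert not again.landmarks.is_complete
        assert set(again.landmarks.missing) == {"Xi", "Gnk", "DC"}

    def test_unknown_landmark_name_rejected(self):
        doc = {
            "image": {"id": "A"},
            "device": "tablet",
            "landmarks": [{"name": "Nose", "x": 1, "y": 2}],
        }
        with pytest.raises(SubmissionError):
            parse_submission(json.dumps(doc))

    def test_timestamps_from_landmark_entries(self):
        doc = {
            "image": {"id": "A"},
            "device": "desktop",
            "landmarks": [
                {"name": "S", "x": 1, "y": 2, "t": "2022-03-01T12:00:00Z"},
                {"name": "N", "x": 3, "y": 4, "t": "2022-03-01T12:11:48Z"},
            ],
        }
        sub = parse_submission(json.dumps(doc))
        assert tracing_time(sub) == pytest.approx(11.8)


class TestExclusions:
    def test_study_mix_partition(self):
        batch = (
            [make_submission(subject=f"s{i}") for i in range(12)]
            + [make_submission(subject=f"w{i}", image="C") for i in range(4)]
            + [
                make_submission(subject=f"sc{i}", image_source="screenshot")
                for i in range(2)
            ]
            + [make_submission(subject="m0", drop=("Xi",))]
            + [InvalidSubmission("f.json", "not valid JSON")]
        )
        report = apply_exclusions(batch, {"A", "B"})
        assert len(report.included) == 12
        assert report.counts["wrong_cephalogram"] == 4
        assert report.counts["screenshot"] == 2
        assert report.counts["missing_landmarks"] == 1
        assert report.counts["invalid_file"] == 1
        assert len(report.included) + len(report.excluded) == len(batch)
        assert report.n_landmarks == 12 * 33

    def test_empty_input(self):
        report = apply_exclusions([])
        assert report.included == [] and report.excluded == []

    def test_duplicates_keep_earliest(self):
        first = make_submission(t0=T0)
        later = make_submission(t0=T0 + timedelta(hours=2))
        report = apply_exclusions([later, first])
        assert report.included == [first]
        assert [r for _, r in report.excluded] == [ExclusionReason.DUPLICATE]

    def test_idempotent_and_order_stable(self):
        batch = [make_submission(subject=f"s{i}") for i in range(6)]
        batch.insert(3, make_submission(subject="s1", image="C"))
        once = apply_exclusions(batch)
        twice = apply_exclusions(once.included)
        assert twice.included == once.included
        assert twice.excluded == []

    def test_wrong_device_assignment(self):
        sub = make_submission(device="tablet")
        report = apply_exclusions([sub], expected_device={"A": "desktop"})
        assert report.counts["wrong_device_assignment"] == 1


class TestPseudonymize:
    def test_deterministic_and_consistent(self):
        m1 = pseudonymize(["alice", "alice", "bob"], "s")
        m2 = pseudonymize(["bob", "alice"], "s")
        assert m1["alice"] == m2["alice"]
        assert m1["bob"] == m2["bob"]

    def test_ranks_are_a_bijection(self):
        m = pseudonymize(["a", "b", "c"], "s")
        assert sorted(m.values()) == ["1", "2", "3"]

    def test_digest_matches_known_answer(self):
        # SHA3-256 known-answer vector: digest("abc")
        kat = "3a985da74fe225b2045c172d6bd390bd855f086e3e9d525b46bfe24511431532"
        assert hashlib.sha3_256(b"abc").hexdigest() == kat
        # the ranking must order names by exactly this digest function
        names = ["ab", "a"]
        digests = {n: hashlib.sha3_256((n + "c").encode()).hexdigest() for n in names}
        expect_first = min(names, key=lambda n: digests[n])
        m = pseudonymize(names, "c")
        assert m[expect_first] == "1"

    def test_salt_required(self):
        with pytest.raises(ValueError):
            pseudonymize(["a"], "")

    def test_raw_names_never_leak(self):
        subs = [make_submission(subject="Top Secret Name")]
        out = pseudonymize_submissions(subs, "salt")
        blob = write_submission(out[0]).decode()
        assert "Top Secret Name" not in blob

    def test_zero_padding_at_scale(self):
        m = pseudonymize([f"n{i}" for i in range(12)], "s")
        assert all(len(v) == 2 for v in m.values())


class TestBuildReference:
    def test_identical_sets_are_fixed_point(self):
        s = make_submission().landmarks
        ref = build_reference([s] * 6)
        assert ref.n_raters == 6
        for name in LANDMARK_NAMES:
            assert ref[name] == s[name]

    def test_two_point_mean(self):
        a = make_submission().landmarks
        b = a.transform(lambda p: (p[0] + 2, p[1] + 2))
        ref = build_reference([a, b])
        assert ref["S"].x == pytest.approx(a["S"].x + 1)
        assert ref["S"].y == pytest.approx(a["S"].y + 1)

    def test_zero_sum_noise_recovers_truth(self, ref_a_landmarks, rng):
        """Six perturbed copies with zero-sum noise average back exactly."""
        noise = rng.normal(scale=3.0, size=(6, 33, 2))
        noise -= noise.mean(axis=0, keepdims=True)
        sets = []
        for r in range(6):
            pts = {
                name: Point2D(
                    ref_a_landmarks[name].x + noise[r, i, 0],
                    ref_a_landmarks[name].y + noise[r, i, 1],
                )
                for i, name in enumerate(LANDMARK_NAMES)
            }
            sets.append(LandmarkSet("A", pts))
        ref = build_reference(sets)
        assert ref["S"].x == pytest.approx(588.88, abs=1e-9)
        assert ref["S"].y == pytest.approx(152.56, abs=1e-9)

    def test_translation_commutes(self, rng):
        sets = [
            make_submission().landmarks.transform(
                lambda p, d=rng.normal(size=2): (p[0] + d[0], p[1] + d[1])
            )
            for _ in range(4)
        ]
        ref = build_reference(sets)
        shifted = [s.transform(lambda p: (p[0] + 7, p[1] - 3)) for s in sets]
        ref2 = build_reference(shifted)
        for name in LANDMARK_NAMES:
            assert ref2[name].x == pytest.approx(ref[name].x + 7, abs=1e-9)
            assert ref2[name].y == pytest.approx(ref[name].y - 3, abs=1e-9)

    def test_incomplete_or_mixed_sets_rejected(self):
        good = make_submission().landmarks
        with pytest.raises(ValueError):
            build_reference([good])
        with pytest.raises(ValueError):
            build_reference([good, make_submission(drop=("S",)).landmarks])
        with pytest.raises(ValueError):
            build_reference([good, make_submission(image="B").landmarks])


class TestTracingTime:
    def test_zero_interval(self):
        sub = make_submission(minutes=0)
        assert tracing_time(sub) == 0.0

    def test_known_interval(self):
        assert tracing_time(make_submission(minutes=11.8)) == pytest.approx(11.8)

    def test_median_matches_sort_oracle(self, rng):
        times = np.exp(rng.normal(2.4, 0.5, size=41))
        subs = [make_submission(subject=f"s{i}", minutes=t) for i, t in enumerate(times)]
        measured = sorted(tracing_time(s) for s in subs)
        oracle = measured[len(measured) // 2]  # odd n: middle element
        assert np.median([tracing_time(s) for s in subs]) == pytest.approx(oracle)

    def test_reversed_timestamps_rejected(self):
        with pytest.raises((ValueError, SubmissionError)):
            make_submission(minutes=-5)
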