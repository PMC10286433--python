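"""Category mapping, proxemics zone classification and count aggregation."""

import json

import numpy as np
import pytest

from crowdstress.errors import ConfigError, FormatError
from crowdstress.proxemics import (
    COUNT_COLUMNS,
    Detection,
    FrameDetections,
    ZoneThresholds,
    classify_zone,
    map_category,
    read_detections,
    write_detections,
    zoned_counts,
)

H, W = 720, 1280


def person(mask_fraction: float, d: float, confidence: float = 0.9) -> Detection:
    """Person detection whose bottom edge sits ``d`` pixels above the image
    bottom (d = |Yi − h|)."""
    height = min(100.0, H - d)
    return Detection("person", (10.0, H - d - height, 50.0, height), mask_fraction, confidence)


@pytest.mark.parametrize(
    "label,category",
    [
        ("person", "human"),
        ("bus", "motor_vehicle"),
        ("car", "motor_vehicle"),
        ("truck", "motor_vehicle"),
        ("motorcycle", "motor_vehicle"),
        ("bicycle", "bike"),
        ("chair", "sitting"),
        ("bench", "sitting"),
        ("dining table", "sitting"),
        ("dog", "ignored"),
        ("traffic light", "ignored"),
    ],
)
def test_map_category(label, category):
    assert map_category(label) == category


class TestClassifyZone:
    def test_large_mask_overrides_distance(self):
        # a quarter-frame person is in the personal space wherever it stands
        assert classify_zone(person(0.15, 150.0), H) == "personal_space"

    @pytest.mark.parametrize(
        "d,zone",
        [(3.0, "close"), (50.0, "medium"), (150.0, "far"), (5.0, "close"), (100.0, "medium")],
    )
    def test_distance_bands_with_boundaries(self, d, zone):
        assert classify_zone(person(0.02, d), H) == zone

    def test_mask_fraction_boundary_not_personal(self):
        # the personal-space rule is strictly 'greater than'
        assert classify_zone(person(0.10, 50.0), H) == "medium"

    def test_non_person_rejected(self):
        det = Detection("car", (0, 0, 10, 10), 0.01, 0.9)
        with pytest.raises(ConfigError, match="person"):
            classify_zone(det, H)

    def test_threshold_rescaling(self):
        thr = ZoneThresholds(reference_height=H)
        # same geometry at double resolution: d doubles, bands double too
        det_lo = person(0.02, 50.0)
        x, y, w, hh = det_lo.box
        det_hi = Detection("person", (2 * x, 2 * (H - 50 - hh) , 2 * w, 2 * hh), 0.02, 0.9)
        assert classify_zone(det_lo, H, thr) == classify_zone(det_hi, 2 * H, thr) == "medium"

    def test_oracle_predicate_chain_on_grid(self):
        """Independent predicate-chain classifier agrees on an exhaustive
        grid of (mask_fraction, d) including every boundary value."""

        def oracle(frac: float, d: float) -> str:
            personal = frac > 0.10
            close = d <= 5.0
            medium = 5.0 < d <= 100.0
            far = d > 100.0
            if personal:
                return "personal_space"
            if close:
                return "close"
            if medium:
                return "medium"
            return "far" if far else "unreachable"

        for frac in (0.0, 0.05, 0.0999, 0.10, 0.1001, 0.15, 0.5):
            for d in (0.0, 1.0, 4.999, 5.0, 5.001, 50.0, 99.9, 100.0, 100.001, 150.0, 700.0):
                assert classify_zone(person(frac, d), H) == oracle(frac, d), (frac, d)


class TestZonedCounts:
    def test_empty_frame(self):
        frame = FrameDetections(0, 0.0, W, H)
        zc = zoned_counts(frame)
        assert all(getattr(zc, c) == 0 for c in COUNT_COLUMNS)

    def test_mixed_frame(self):
        dets = [
            person(0.2, 50.0),
            person(0.01, 50.0),
            person(0.01, 150.0),
            Detection("bicycle", (0, 300, 60, 40), 0.01, 0.9),
            Detection("bicycle", (100, 300, 60, 40), 0.01, 0.9),
        ]
        zc = zoned_counts(FrameDetections(0, 0.0, W, H, dets))
        assert (zc.persons_personal, zc.persons_close, zc.persons_medium, zc.persons_far) == (1, 0, 1, 1)
        assert zc.bikes == 2

    def test_confidence_filter(self):
        frame = FrameDetections(0, 0.0, W, H, [person(0.2, 10.0, confidence=0.1)])
        zc = zoned_counts(frame, min_confidence=0.5)
        assert zc.persons_personal == 0

    def test_partition_property(self):
        """Every person lands in exactly one zone: zone counts always sum to
        the person count (10^4 random detections)."""
        rng = np.random.default_rng(0)
        dets = [
            person(float(rng.uniform(0, 0.3)), float(rng.uniform(0, 600)))
            for _ in range(10_000)
        ]
        zc = zoned_counts(FrameDetections(0, 0.0, W, H, dets), min_confidence=0.0)
        assert (
            zc.persons_personal + zc.persons_close + zc.persons_medium + zc.persons_far
            == 10_000
        )


class TestDetectionsIO:
    def test_roundtrip(self, tmp_path, small_bundles):
        frames = small_bundles[0].frames[:50]
        path = tmp_path / "det.json"
        write_detections(frames, path)
        back = read_detections(path)
        assert len(back) == len(frames)
        for a, b in zip(frames, back):
            assert a.timestamp == b.timestamp
            assert len(a.detections) == len(b.detections)
            for da, db in zip(a.detections, b.detections):
                assert da.label == db.label
                assert da.box == pytest.approx(db.box)
                assert da.mask_fraction == pytest.approx(db.mask_fraction)

    def test_empty_document(self, tmp_path):
        path = tmp_path / "empty.json"
        path.write_text(json.dumps({"images": [], "annotations": []}))
        assert read_detections(path) == []

    def test_malformed_entries_skipped_with_warning(self, tmp_path, caplog):
        doc = {
            "images": [{"id": 0, "timestamp": 1.0, "width": W, "height": H}],
            "annotations": [
                {"image_id": 0, "label": "person"},  # missing bbox
                {"image_id": 0, "label": "person", "bbox": [0, 0, 10, 20],
                 "area": 500, "score": 0.8},
            ],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with caplog.at_level("WARNING"):
            frames = read_detections(path)
        assert len(frames) == 1
        assert len(frames[0].detections) == 1
        assert "skipp" in caplog.text.lower()

    def test_unreadable_file_raises(self, tmp_path):
        with pytest.raises(FormatError):
            read_detections(tmp_path / "missing.json")
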