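"""Crowd quantification from per-frame object detections.

Detections from a first-person wearable camera (COCO-vocabulary labels,
pixel bounding boxes, instance-mask areas) are mapped to four overcrowding
categories — human crowds, motor vehicles, bikes, sitting facilities — and
each person is placed in one of four proxemics distance zones.

The distance proxy follows the perspective principle: a person near the
observer sits low in the frame, so the pixel gap ``d = |Yi − h|`` between
the box bottom edge ``Yi`` and the image bottom ``h`` grows with ground
distance.  A person whose instance mask covers more than a threshold
fraction of the image (default 10%) is taken to have entered the wearer's
personal space regardless of ``d``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import pandas as pd

from .errors import ConfigError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "Detection",
    "FrameDetections",
    "ZoneThresholds",
    "ZonedCounts",
    "ZONES",
    "COUNT_COLUMNS",
    "map_category",
    "classify_zone",
    "zoned_counts",
    "read_detections",
    "write_detections",
]

ZONES = ("personal_space", "close", "medium", "far")

#: predictor columns in the order used throughout the pipeline
COUNT_COLUMNS = (
    "persons_personal",
    "persons_close",
    "persons_medium",
    "persons_far",
    "motor_vehicles",
    "bikes",
    "sitting_facilities",
)

_ZONE_TO_COLUMN = dict(zip(ZONES, COUNT_COLUMNS[:4]))

_CATEGORY_MAP = {
    "person": "human",
    "bus": "motor_vehicle",
    "car": "motor_vehicle",
    "truck": "motor_vehicle",
    "motorcycle": "motor_vehicle",
    "bicycle": "bike",
    "chair": "sitting",
    "bench": "sitting",
    "dining table": "sitting",
}

_CATEGORY_TO_COLUMN = {
    "motor_vehicle": "motor_vehicles",
    "bike": "bikes",
    "sitting": "sitting_facilities",
}


@dataclass(frozen=True)
class Detection:
    """One detected object in a frame.

    ``box`` is ``(x_left, y_top, width, height)`` in pixels with the origin
    at the top-left corner and y increasing downward; ``mask_fraction`` is
    the instance-mask area divided by the image area.
    """

    label: str
    box: tuple[float, float, float, float]
    mask_fraction: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mask_fraction <= 1.0:
            raise ConfigError(f"mask_fraction must be in [0, 1], got {self.mask_fraction}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ConfigError(f"confidence must be in [0, 1], got {self.confidence}")

    @property
    def bottom_y(self) -> float:
        """Yi — the y pixel coordinate of the bounding-box bottom edge."""
        return self.box[1] + self.box[3]


@dataclass
class FrameDetections:
    """All detections of one extracted video frame (1 Hz)."""

    frame_id: int
    timestamp: float
    image_width: int
    image_height: int
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.image_width <= 0 or self.image_height <= 0:
            raise ConfigError("image dimensions must be positive")


@dataclass(frozen=True)
class ZoneThresholds:
    """Calibration constants of the zone classifier.

    ``y_close`` and ``y_mid`` are the two pixel lines separating close,
    medium and far distance; ``personal_fraction`` is the mask-area fraction
    above which a person counts as inside the personal space.  The pixel
    thresholds are expressed in the native frame; set ``reference_height``
    to rescale them proportionally for cameras with a different resolution.
    """

    personal_fraction: float = 0.10
    y_close: float = 5.0
    y_mid: float = 100.0
    reference_height: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.personal_fraction < 1.0:
            raise ConfigError("personal_fraction must be in (0, 1)")
        if not 0.0 < self.y_close < self.y_mid:
            raise ConfigError("need 0 < y_close < y_mid")

    def scaled(self, image_height: int) -> "ZoneThresholds":
        if self.reference_height is None or image_height == self.reference_height:
            return self
        f = image_height / self.reference_height
        return ZoneThresholds(self.personal_fraction, self.y_close * f, self.y_mid * f)


def map_category(label: str) -> str:
    """Map a detector class label to an overcrowding category.

    person → human; bus/car/truck/motorcycle → motor_vehicle;
    bicycle → bike; chair/bench/dining table → sitting; all other labels
    (traffic lights, dogs, ...) are ignored.
    """
    return _CATEGORY_MAP.get(label, "ignored")


def classify_zone(
    det: Detection, image_height: int, thresholds: ZoneThresholds = ZoneThresholds()
) -> str:
    """Assign a person detection to one proxemics zone.

    The personal-space test runs first: a mask fraction above
    ``personal_fraction`` overrides the distance bands (a person this large
    in a first-person frame has invaded the wearer's personal space).
    Otherwise the pixel gap ``d = |Yi − h|`` is banded:
    ``d ≤ y_close`` → close, ``y_close < d ≤ y_mid`` → medium,
    ``d > y_mid`` → far.
    """
    if map_category(det.label) != "human":
        raise ConfigError(f"classify_zone expects a person detection, got {det.label!r}")
    thr = thresholds.scaled(image_height)
    if det.mask_fraction > thr.personal_fraction:
        return "personal_space"
    d = abs(det.bottom_y - image_height)
    if d > thr.y_mid:
        return "far"
    if d > thr.y_close:
        return "medium"
    return "close"


@dataclass(frozen=True)
class ZonedCounts:
    """Per-frame tallies of the seven overcrowding predictors."""

    timestamp: float
    persons_personal: int = 0
    persons_close: int = 0
    persons_medium: int = 0
    persons_far: int = 0
    motor_vehicles: int = 0
    bikes: int = 0
    sitting_facilities: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def zoned_counts(
    frame: FrameDetections,
    thresholds: ZoneThresholds = ZoneThresholds(),
    min_confidence: float = 0.5,
) -> ZonedCounts:
    """Tally one frame's detections into the seven predictor counts.

    Detections scoring below ``min_confidence`` are dropped; persons are
    tallied per zone, the other categories by raw count.
    """
    counts = dict.fromkeys(COUNT_COLUMNS, 0)
    for det in frame.detections:
        if det.confidence < min_confidence:
            continue
        cat = map_category(det.label)
        if cat == "human":
            zone = classify_zone(det, frame.image_height, thresholds)
            counts[_ZONE_TO_COLUMN[zone]] += 1
        elif cat in _CATEGORY_TO_COLUMN:
            counts[_CATEGORY_TO_COLUMN[cat]] += 1
    return ZonedCounts(timestamp=frame.timestamp, **counts)


def counts_frame(
    frames: list[FrameDetections],
    thresholds: ZoneThresholds = ZoneThresholds(),
    min_confidence: float = 0.5,
) -> pd.DataFrame:
    """ZonedCounts for a frame series as a DataFrame (timestamp + 7 columns)."""
    rows = [zoned_counts(f, thresholds, min_confidence).as_dict() for f in frames]
    return pd.DataFrame(rows, columns=["timestamp", *COUNT_COLUMNS])


# ---------------------------------------------------------------------------
# I/O — COCO-style detection JSON

def write_detections(frames: list[FrameDetections], path) -> None:
    """Write a frame series as COCO-style JSON (images + annotations)."""
    images, annotations = [], []
    for f in frames:
        images.append(
            {
                "id": f.frame_id,
                "timestamp": f.timestamp,
                "width": f.image_width,
                "height": f.image_height,
            }
        )
        area = f.image_width * f.image_height
        for det in f.detections:
            annotations.append(
                {
                    "image_id": f.frame_id,
                    "label": det.label,
                    "bbox": list(det.box),
                    "area": det.mask_fraction * area,
                    "score": det.confidence,
                }
            )
    with open(path, "w") as fh:
        json.dump({"images": images, "annotations": annotations}, fh)


def read_detections(path) -> list[FrameDetections]:
    """Parse COCO-style detection JSON into a timestamp-sorted frame series.

    Malformed entries (missing bbox, unknown image id, out-of-range values)
    are skipped with a warning rather than aborting the parse.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read detections from {path}: {exc}") from exc

    frames: dict[int, FrameDetections] = {}
    skipped = 0
    for img in doc.get("images", []):
        try:
            frames[img["id"]] = FrameDetections(
                frame_id=img["id"],
                timestamp=float(img["timestamp"]),
                image_width=int(img["width"]),
                image_height=int(img["height"]),
            )
        except (KeyError, TypeError, ValueError, ConfigError) as exc:
            skipped += 1
            logger.warning("skipping malformed image entry %r: %s", img, exc)
    for ann in doc.get("annotations", []):
        try:
            frame = frames[ann["image_id"]]
            x, y, w, h = ann["bbox"]
            det = Detection(
                label=str(ann["label"]),
                box=(float(x), float(y), float(w), float(h)),
                mask_fraction=float(ann["area"]) / (frame.image_width * frame.image_height),
                confidence=float(ann.get("score", 1.0)),
            )
            frame.detections.append(det)
        except (KeyError, TypeError, ValueError, ConfigError) as exc:
            skipped += 1
            logger.warning("skipping malformed annotation %r: %s", ann, exc)
    if skipped:
        logger.warning("read_detections: skipped %d malformed entries in %s", skipped, path)
    return sorted(frames.values(), key=lambda f: f.timestamp)
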