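"""Timestamp fusion of change scores, zone counts and GPS positions.

All streams of one session are joined on the per-second change-score
timeline: each scored second picks up the zone counts of the nearest frame
within a tolerance and a linearly interpolated GPS position, then a site
label by point-in-polygon lookup.  Seconds that cannot be matched are
dropped and accounted for in a fusion report, so that
``records_out + dropped_no_frame + dropped_no_gps == records_in`` always
holds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape

from .errors import ConfigError, FusionError
from .proxemics import COUNT_COLUMNS

logger = logging.getLogger(__name__)

__all__ = ["GpsTrack", "fuse", "assign_sites", "session_summary", "load_sites"]


@dataclass
class GpsTrack:
    """Timestamped positions (epoch s, degrees) with strictly increasing time."""

    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if not (self.t.size == self.lat.size == self.lon.size):
            raise ConfigError("track arrays must have equal length")
        if self.t.size == 0:
            raise ConfigError("track must be non-empty")
        if np.any(np.diff(self.t) <= 0):
            raise ConfigError("track timestamps must be strictly increasing")
        if np.any(np.abs(self.lat) > 90) or np.any(np.abs(self.lon) > 180):
            raise ConfigError("lat must be in [-90, 90] and lon in [-180, 180]")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GpsTrack":
        return cls(df["timestamp"].to_numpy(), df["lat"].to_numpy(), df["lon"].to_numpy())


def fuse(
    cs: pd.DataFrame,
    counts: pd.DataFrame,
    track: GpsTrack,
    tolerance_s: float = 1.0,
    max_clock_offset_s: float = 600.0,
    meta: dict | None = None,
    annotations: list[tuple[float, str]] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Join per-second change scores with frame counts and GPS positions.

    For each scored second, the counts of the nearest frame within
    ``±tolerance_s`` are attached and the GPS position is linearly
    interpolated; seconds lacking a frame or a bracketing GPS fix are
    dropped.  ``meta`` (participant_id, timeslot, gender, ...) is copied
    onto every record.

    ``annotations`` are self-reported stress events ``(timestamp, text)``;
    each is attached as a flag to the nearest fused second within the
    tolerance, purely for mapping — they never enter the models.

    Returns ``(records, report)`` where the report counts records in/out
    and drops by cause.
    """
    if cs.empty or counts.empty:
        raise FusionError("fuse requires non-empty change-score and count inputs")
    t_cs = cs["t"].to_numpy(dtype=float)
    t_fr = counts["timestamp"].to_numpy(dtype=float)

    gap = max(t_cs.min(), t_fr.min(), track.t.min()) - min(
        t_cs.max(), t_fr.max(), track.t.max()
    )
    if gap > max_clock_offset_s:
        raise FusionError(
            "streams do not overlap: closest approach "
            f"{gap:.0f} s apart exceeds the {max_clock_offset_s:.0f} s sanity bound "
            f"(CS [{t_cs.min():.0f}, {t_cs.max():.0f}], frames "
            f"[{t_fr.min():.0f}, {t_fr.max():.0f}], GPS [{track.t.min():.0f}, {track.t.max():.0f}])"
        )

    order = np.argsort(t_fr, kind="stable")
    t_fr_sorted = t_fr[order]
    # nearest frame within tolerance
    pos = np.searchsorted(t_fr_sorted, t_cs)
    left = np.clip(pos - 1, 0, t_fr_sorted.size - 1)
    right = np.clip(pos, 0, t_fr_sorted.size - 1)
    d_left = np.abs(t_cs - t_fr_sorted[left])
    d_right = np.abs(t_fr_sorted[right] - t_cs)
    nearest = np.where(d_left <= d_right, left, right)
    d_nearest = np.minimum(d_left, d_right)
    has_frame = d_nearest <= tolerance_s

    has_gps = (t_cs >= track.t[0]) & (t_cs <= track.t[-1])

    keep = has_frame & has_gps
    report = {
        "records_in": int(t_cs.size),
        "records_out": int(keep.sum()),
        "dropped_no_frame": int((~has_frame).sum()),
        "dropped_no_gps": int((has_frame & ~has_gps).sum()),
        "tolerance_s": tolerance_s,
    }
    if report["dropped_no_frame"] or report["dropped_no_gps"]:
        logger.info(
            "fuse: dropped %d seconds without a frame and %d without GPS (of %d)",
            report["dropped_no_frame"], report["dropped_no_gps"], report["records_in"],
        )

    counts_sorted = counts.iloc[order].reset_index(drop=True)
    out = cs.loc[keep, ["t", "CS"]].reset_index(drop=True).rename(columns={"t": "timestamp"})
    matched = counts_sorted.iloc[nearest[keep]].reset_index(drop=True)
    for col in COUNT_COLUMNS:
        out[col] = matched[col].to_numpy()
    out["lat"] = np.interp(out["timestamp"], track.t, track.lat)
    out["lon"] = np.interp(out["timestamp"], track.t, track.lon)
    for key, val in (meta or {}).items():
        out[key] = val
    if annotations is not None:
        out["reported_stress"] = False
        out["report_text"] = ""
        tt = out["timestamp"].to_numpy()
        n_matched = 0
        for ts, text in annotations:
            if tt.size == 0:
                break
            i = int(np.argmin(np.abs(tt - ts)))
            if abs(tt[i] - ts) <= tolerance_s:
                out.loc[i, "reported_stress"] = True
                out.loc[i, "report_text"] = text
                n_matched += 1
        report["annotations_matched"] = n_matched
        report["annotations_total"] = len(annotations)
    return out, report


def load_sites(path) -> list[tuple[str, object]]:
    """Read site polygons from a GeoJSON FeatureCollection.

    Returns ``(name, shapely polygon)`` pairs in file order; order matters
    because overlapping polygons are resolved first-listed-wins.
    """
    with open(path) as fh:
        doc = json.load(fh)
    sites = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = shape(feat["geometry"])
        name = feat.get("properties", {}).get("name", f"site_{i}")
        if not geom.is_valid:
            raise ConfigError(f"site polygon {name!r} is invalid (self-intersecting?)")
        sites.append((name, geom))
    return sites


def assign_sites(records: pd.DataFrame, sites: list[tuple[str, object]]) -> pd.DataFrame:
    """Label each record with the first site polygon covering its position.

    Points on a shared boundary of two polygons match both; the first-listed
    polygon wins and a warning reports how many ties occurred.  Points in no
    polygon are labelled ``"unassigned"``.
    """
    out = records.copy()
    labels = np.full(len(out), "unassigned", dtype=object)
    n_ties = 0
    pts = [Point(xy) for xy in zip(out["lon"].to_numpy(), out["lat"].to_numpy())]
    masks = []
    for name, geom in sites:
        # covers(): boundary points count as inside
        masks.append(np.fromiter((geom.covers(p) for p in pts), bool, len(pts)))
    if masks:
        stacked = np.column_stack(masks)
        n_ties = int((stacked.sum(axis=1) > 1).sum())
        first = np.argmax(stacked, axis=1)
        any_hit = stacked.any(axis=1)
        names = np.array([name for name, _ in sites], dtype=object)
        labels[any_hit] = names[first[any_hit]]
    if n_ties:
        logger.warning(
            "assign_sites: %d points fell in more than one polygon; "
            "assigned to the first-listed site", n_ties,
        )
    out["site"] = labels
    return out


def session_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Observation counts and CS descriptives per site plus an overall row."""
    if records.empty:
        return pd.DataFrame(columns=["site", "n", "cs_mean", "cs_sd"])
    rows = []
    for site, grp in records.groupby("site", sort=False):
        rows.append(
            {"site": site, "n": len(grp), "cs_mean": grp["CS"].mean(), "cs_sd": grp["CS"].std()}
        )
    rows.append(
        {
            "site": "overall",
            "n": len(records),
            "cs_mean": records["CS"].mean(),
            "cs_sd": records["CS"].std(),
        }
    )
    return pd.DataFrame(rows)
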