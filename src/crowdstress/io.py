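"""Readers and writers for the pipeline's on-disk formats.

Formats: wearable-export CSV ("E4 dialect": line 1 = start epoch seconds,
line 2 = sampling rate Hz, then one sample per line), COCO-style detection
JSON (see :mod:`crowdstress.proxemics`), GPS CSV (``timestamp,lat,lon``),
GeoJSON for site polygons and fused point features, and plain CSV for
change scores, zone counts and fused records.

All timestamps are epoch seconds UTC.  Writers format floats explicitly so
that identical data produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .fusion import GpsTrack
from .proxemics import COUNT_COLUMNS, write_detections
from .scoring import PhysioStream

__all__ = [
    "read_e4_csv",
    "write_e4_csv",
    "read_gps_csv",
    "write_gps_csv",
    "write_sites_geojson",
    "write_cs_csv",
    "read_cs_csv",
    "write_counts_csv",
    "read_counts_csv",
    "write_fused_csv",
    "read_fused_csv",
    "write_fused_geojson",
    "write_session",
]

_CHANNEL_BY_FILE = {"EDA.csv": "GSR", "TEMP.csv": "ST"}


def read_e4_csv(path, channel: str) -> PhysioStream:
    """Parse a wearable-export CSV: start epoch, sampling rate, samples."""
    path = Path(path)
    try:
        with open(path) as fh:
            lines = fh.read().splitlines()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if len(lines) < 3:
        raise FormatError(f"{path}: expected header (2 lines) plus samples, got {len(lines)} lines")
    try:
        start_epoch = float(lines[0])
    except ValueError as exc:
        raise FormatError(f"{path}:1: start epoch is not numeric: {lines[0]!r}") from exc
    try:
        fs = float(lines[1])
    except ValueError as exc:
        raise FormatError(f"{path}:2: sampling rate is not numeric: {lines[1]!r}") from exc
    samples = np.empty(len(lines) - 2)
    for i, line in enumerate(lines[2:], start=3):
        s = line.strip()
        if s.lower() in {"", "nan"}:
            samples[i - 3] = np.nan
            continue
        try:
            samples[i - 3] = float(s)
        except ValueError as exc:
            raise FormatError(f"{path}:{i}: sample is not numeric: {line!r}") from exc
    return PhysioStream(channel=channel, start_epoch=start_epoch, fs=fs, samples=samples)


def write_e4_csv(stream: PhysioStream, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{stream.start_epoch:.6f}\n{stream.fs:.6f}\n")
        fh.writelines(f"{x:.6f}\n" if np.isfinite(x) else "nan\n" for x in stream.samples)


def read_gps_csv(path) -> GpsTrack:
    df = pd.read_csv(path)
    need = {"timestamp", "lat", "lon"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: GPS CSV needs columns {sorted(need)}, got {list(df.columns)}")
    return GpsTrack.from_frame(df)


def write_gps_csv(track: GpsTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write("timestamp,lat,lon\n")
        for t, la, lo in zip(track.t, track.lat, track.lon):
            fh.write(f"{t:.3f},{la:.8f},{lo:.8f}\n")


def write_sites_geojson(site_specs, path) -> None:
    feats = []
    for spec in site_specs:
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[[float(v) for v in p] for p in spec.polygon]],
                },
                "properties": {"name": spec.name, "context": spec.context},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)


def write_cs_csv(cs: pd.DataFrame, path) -> None:
    cs.to_csv(path, index=False, float_format="%.6f")


def read_cs_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"t", "s1", "s2", "s3", "s4", "CS"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: change-score CSV needs columns {sorted(need)}")
    return df


def write_counts_csv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, index=False, float_format="%.3f")


def read_counts_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"timestamp", *COUNT_COLUMNS}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: counts CSV needs columns {sorted(need)}")
    return df


def write_fused_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, float_format="%.8f")


def read_fused_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_fused_geojson(records: pd.DataFrame, path) -> None:
    """One point feature per fused record, all attributes as properties."""
    feats = []
    cols = [c for c in records.columns if c not in ("lat", "lon")]
    for _, row in records.iterrows():
        props = {}
        for c in cols:
            v = row[c]
            if isinstance(v, (np.integer,)):
                v = int(v)
            elif isinstance(v, (np.floating, float)):
                v = None if np.isnan(v) else float(v)
            props[c] = v
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [float(row["lon"]), float(row["lat"])],
                },
                "properties": props,
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def write_session(bundle, out_dir) -> Path:
    """Write one synthetic session to ``out_dir/<participant_id>/``.

    Files: EDA.csv, TEMP.csv (wearable dialect), detections.json
    (COCO-style), gps.csv, truth.csv (per-second ground-truth counts and
    model-level change score) and truth.json (events, intercepts, effects).
    """
    out = Path(out_dir) / bundle.participant_id
    out.mkdir(parents=True, exist_ok=True)
    write_e4_csv(bundle.gsr, out / "EDA.csv")
    write_e4_csv(bundle.st, out / "TEMP.csv")
    write_detections(bundle.frames, out / "detections.json")
    write_gps_csv(bundle.track, out / "gps.csv")
    bundle.truth.records.to_csv(out / "truth.csv", index=False, float_format="%.8f")
    meta = {
        "participant_id": bundle.participant_id,
        "timeslot": bundle.timeslot,
        "gender": bundle.gender,
        "intercepts": bundle.truth.intercepts,
        "true_effects": bundle.truth.true_effects,
        "events": [
            {
                "onset": ev.onset,
                "amplitude": ev.amplitude,
                "rise_time": ev.rise_time,
                "decay_tau": ev.decay_tau,
                "st_dip": ev.st_dip,
            }
            for ev in bundle.truth.events
        ],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return out
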