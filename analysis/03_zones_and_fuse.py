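#!/usr/bin/env python
"""Quantify crowding per frame and fuse all streams per second.

Detections are mapped to the four overcrowding categories, persons are
placed in proxemics zones, and every scored second is joined with the
nearest frame's counts and an interpolated GPS position, then labelled
with its site polygon.  Writes scratch/fused.csv (analysis input for
04/05) and a per-site observation summary to results/.
"""

import json
from pathlib import Path

import pandas as pd

from crowdstress.fusion import assign_sites, fuse, load_sites, session_summary
from crowdstress.io import read_cs_csv, read_gps_csv, write_fused_csv
from crowdstress.proxemics import ZoneThresholds, counts_frame, read_detections

ROOT = Path(__file__).resolve().parents[1]
SCENARIO = ROOT / "scratch" / "scenario"
CS_DIR = ROOT / "scratch" / "cs"
RESULTS = ROOT / "results"


def main() -> None:
    sites = load_sites(SCENARIO / "sites.geojson")
    fused_parts, reports = [], {}
    for sess_dir in sorted(SCENARIO.iterdir()):
        if not (sess_dir / "detections.json").exists():
            continue
        pid = sess_dir.name
        meta = json.loads((sess_dir / "truth.json").read_text())
        frames = read_detections(sess_dir / "detections.json")
        counts = counts_frame(frames, ZoneThresholds())
        cs = read_cs_csv(CS_DIR / f"{pid}.csv")
        track = read_gps_csv(sess_dir / "gps.csv")
        rec, report = fuse(
            cs, counts, track,
            meta={"participant_id": pid, "timeslot": meta["timeslot"],
                  "gender": meta["gender"]},
        )
        fused_parts.append(rec)
        reports[pid] = report
    fused = assign_sites(pd.concat(fused_parts, ignore_index=True), sites)
    write_fused_csv(fused, ROOT / "scratch" / "fused.csv")
    table = session_summary(fused)
    table.to_csv(RESULTS / "03_site_summary.csv", index=False, float_format="%.3f")
    (RESULTS / "03_fusion_report.json").write_text(json.dumps(reports, indent=1, sort_keys=True))
    dropped = sum(r["dropped_no_frame"] + r["dropped_no_gps"] for r in reports.values())
    print(table.to_string(index=False))
    print(f"\nfused {len(fused)} records ({dropped} seconds dropped) -> scratch/fused.csv")


if __name__ == "__main__":
    main()
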