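#!/usr/bin/env python
"""Score every simulated session: preprocess the GSR/ST streams and compute
the per-second change score from rules R1-R4.

Reads scratch/scenario/ (from 01_simulate.py), writes per-session change
scores to scratch/cs/ and a distribution summary to results/.
"""

from pathlib import Path

import pandas as pd

from crowdstress.io import read_e4_csv, write_cs_csv
from crowdstress.scoring import ScoringParams, preprocess, score_segments

ROOT = Path(__file__).resolve().parents[1]
SCENARIO = ROOT / "scratch" / "scenario"
CS_DIR = ROOT / "scratch" / "cs"
RESULTS = ROOT / "results"


def main() -> None:
    params = ScoringParams()
    CS_DIR.mkdir(parents=True, exist_ok=True)
    rows = []
    for sess_dir in sorted(SCENARIO.iterdir()):
        if not (sess_dir / "EDA.csv").exists():
            continue
        gsr = read_e4_csv(sess_dir / "EDA.csv", "GSR")
        st = read_e4_csv(sess_dir / "TEMP.csv", "ST")
        cs = score_segments(preprocess(gsr, gsr.fs), preprocess(st, st.fs), params)
        write_cs_csv(cs, CS_DIR / f"{sess_dir.name}.csv")
        rows.append(
            {
                "participant_id": sess_dir.name,
                "n_seconds": len(cs),
                "cs_mean": cs["CS"].mean(),
                "cs_sd": cs["CS"].std(),
                "cs_max": cs["CS"].max(),
                "pct_nonzero": (cs["CS"] > 0).mean() * 100,
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "02_change_scores.csv", index=False, float_format="%.3f")
    print(summary.to_string(index=False))
    print(f"\nscored {len(rows)} sessions -> {CS_DIR}")


if __name__ == "__main__":
    main()
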