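#!/usr/bin/env python
"""Extract the nine spindle features (A-I) per cell.

Reads the spot table and scored landmarks, computes the per-cell feature
vector (pole separation before NEBD, duration, mean spindle length, length
variance and fluctuation, rotation, elongation rate, anaphase rotation,
telophase pole separation) and writes the screen's cells × features table.
"""

from pathlib import Path

import pandas as pd

from gspcmitosis.features import extract_features, features_table
from gspcmitosis.timing import MitoticLandmarks
from gspcmitosis.track_io import (
    pair_poles,
    read_spots_table,
    spindle_axes,
    spindle_length_series,
)

COHORT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 11


def main() -> None:
    landmarks = pd.read_csv(COHORT / "landmarks.csv").set_index("cell_id")
    tracks, _ = pair_poles(read_spots_table(COHORT / "spots.csv"),
                           frame_interval=0.5)
    vectors = []
    for tr in tracks:
        if tr.cell_id not in landmarks.index:
            continue
        row = landmarks.loc[tr.cell_id]
        tr.group, tr.gonad_id = row["group"], row["gonad_id"]
        lm = MitoticLandmarks(t_nebd=row["t_nebd"], t_s=row["t_s"], t_ao=row["t_ao"])
        series = spindle_length_series(tr)
        _, axes = spindle_axes(tr)
        vectors.append(extract_features(series, axes, lm, seed=SEED))
    df = features_table(vectors)
    df.to_csv(COHORT / "features.csv", index=False)
    print(f"extracted features for {len(df)} cells")
    print(df.groupby("group")[list("BCFG")].mean().round(2).to_string())
    flagged = df[df["flags"] != ""]
    print(f"{len(flagged)} cells carry feature flags")
    print(f"wrote {COHORT / 'features.csv'}")


if __name__ == "__main__":
    main()
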