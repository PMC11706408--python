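#!/usr/bin/env python
"""Score mitotic landmarks from the simulated spot table and benchmark them.

Reads the spot table written by 01, pairs poles, scores NEBD / "start" /
anaphase onset from each spindle-length trace, and compares scored durations
with the generator's ground truth.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gspcmitosis.timing import LandmarkError, score_landmarks_from_length
from gspcmitosis.track_io import pair_poles, read_spots_table, spindle_length_series

COHORT = Path(__file__).resolve().parents[1] / "results" / "cohort"
FRAME_INTERVAL = 0.5


def main() -> None:
    truth = pd.read_csv(COHORT / "ground_truth.csv").set_index("cell_id")
    tracks, errors = pair_poles(read_spots_table(COHORT / "spots.csv"),
                                frame_interval=FRAME_INTERVAL)
    rows = []
    for tr in tracks:
        try:
            lm = score_landmarks_from_length(spindle_length_series(tr))
        except LandmarkError as exc:
            errors[tr.cell_id] = str(exc)
            continue
        rows.append({
            "cell_id": tr.cell_id, "group": truth.at[tr.cell_id, "group"],
            "gonad_id": truth.at[tr.cell_id, "gonad_id"],
            "t_nebd": lm.t_nebd, "t_s": lm.t_s, "t_ao": lm.t_ao,
            "duration_min": lm.duration,
            "true_duration_min": truth.at[tr.cell_id, "duration"],
            "flags": ";".join(sorted(lm.quality_flags)),
        })
    df = pd.DataFrame(rows)
    df.to_csv(COHORT / "landmarks.csv", index=False)
    err_frames = (df["duration_min"] - df["true_duration_min"]) / FRAME_INTERVAL
    print(f"scored {len(df)} of {len(df) + len(errors)} cells "
          f"({len(errors)} rejected)")
    print(f"duration error: median |err| = {np.median(np.abs(err_frames)):.2f} frames, "
          f"mean signed = {err_frames.mean():+.2f} frames")
    for g, sub in df.groupby("group"):
        print(f"  {g}: scored mean duration {sub['duration_min'].mean():.2f} min "
              f"(true {sub['true_duration_min'].mean():.2f})")
    print(f"wrote {COHORT / 'landmarks.csv'}")


if __name__ == "__main__":
    main()
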