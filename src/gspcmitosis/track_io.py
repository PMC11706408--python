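"""Reading spindle-pole tracking exports and deriving spindle-length series.

Spindle poles are tracked (one track per pole) in a spot-tracking GUI such as
TrackMate and exported as a "Spots" table: one row per detected spot with a
label, XYZ position (μm) and a time coordinate.  Pole pairing — which two
tracks belong to the same mitotic cell — is encoded in the spot labels using a
configurable ``<cell>_p<1|2>`` suffix convention, so that pairing done by
renaming spots in the GUI becomes scriptable here.

No gap interpolation happens at I/O time: frames missing from either pole are
simply absent from the derived length series, and downstream scoring declares
its own gap policy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SpotDialect",
    "SpindleTrack",
    "LengthSeries",
    "read_spots_table",
    "write_spots_table",
    "pair_poles",
    "spindle_length_series",
    "write_length_table",
]


@dataclass(frozen=True)
class SpotDialect:
    """Column mapping and parsing conventions of a spot-table export.

    Defaults follow the TrackMate "Spots" CSV export.  ``time_unit_per_min``
    and ``space_unit_per_um`` rescale the file's units to minutes and μm
    (1.0 when the export is already calibrated, as TrackMate's is).
    """

    label: str = "LABEL"
    x: str = "POSITION_X"
    y: str = "POSITION_Y"
    z: str = "POSITION_Z"
    t: str = "POSITION_T"
    frame: str = "FRAME"
    delimiter: str = ","
    decimal: str = "."
    space_unit_per_um: float = 1.0
    time_unit_per_min: float = 1.0
    # pole-pairing convention: label = "<cell_id><sep>p<pole_id>"
    pole_pattern: str = r"^(?P<cell>.+)_p(?P<pole>\d+)$"


@dataclass
class SpindleTrack:
    """Paired pole trajectories for one mitotic cell.

    ``pole1``/``pole2`` are DataFrames with columns ``frame, t_min, x_um,
    y_um, z_um``, sorted by frame; gaps (missing frames) are allowed.
    """

    cell_id: str
    pole1: pd.DataFrame
    pole2: pd.DataFrame
    frame_interval: float
    group: str = ""
    gonad_id: str = ""

    def __post_init__(self) -> None:
        for name, df in (("pole1", self.pole1), ("pole2", self.pole2)):
            if len(df) == 0:
                raise ValueError(f"{name} of cell {self.cell_id!r} is empty")
            if not np.all(np.diff(df["t_min"].to_numpy()) > 0):
                raise ValueError(
                    f"{name} of cell {self.cell_id!r}: timestamps not strictly increasing"
                )

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "SpindleTrack":
        """Apply a rigid transform (rotation matrix then translation) to both poles."""
        rotation = np.eye(3) if rotation is None else np.asarray(rotation, float)
        translation = np.zeros(3) if translation is None else np.asarray(translation, float)
        cols = ["x_um", "y_um", "z_um"]
        out = []
        for df in (self.pole1, self.pole2):
            new = df.copy()
            new[cols] = df[cols].to_numpy() @ rotation.T + translation
            out.append(new)
        return replace(self, pole1=out[0], pole2=out[1])


@dataclass
class LengthSeries:
    """Pole-to-pole distance (spindle length, μm) against time (minutes)."""

    t: np.ndarray
    length: np.ndarray
    frame_interval: float
    cell_id: str = ""
    group: str = ""
    gonad_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.length = np.asarray(self.length, dtype=float)
        if self.t.shape != self.length.shape:
            raise ValueError("t and length must have the same shape")
        if np.any(self.length < 0):
            raise ValueError("spindle length must be non-negative")


_POLE_COLS = ["frame", "t_min", "x_um", "y_um", "z_um"]


def read_spots_table(path, dialect: SpotDialect | None = None) -> pd.DataFrame:
    """Read a spot-table export into a tidy spot DataFrame.

    Returns a DataFrame with columns ``label, frame, t_min, x_um, y_um, z_um``.
    Rows with missing coordinates are dropped (and counted in the
    ``attrs['n_dropped']`` annotation).  Raises ``ValueError`` when required
    columns are absent or a (label, frame) pair occurs twice.
    """
    dialect = dialect or SpotDialect()
    raw = pd.read_csv(path, sep=dialect.delimiter, decimal=dialect.decimal,
                      float_precision="round_trip")
    # TrackMate CSV exports carry up to three header-ish rows of units/names;
    # keep only rows where the frame/position columns parse as numbers.
    required = [dialect.label, dialect.x, dialect.y, dialect.z, dialect.t]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(
            f"cannot map spot-table columns {missing}; found headers: {list(raw.columns)}"
        )
    num_cols = [dialect.x, dialect.y, dialect.z, dialect.t]
    if dialect.frame in raw.columns:
        num_cols.append(dialect.frame)
    numeric = raw[num_cols].apply(pd.to_numeric, errors="coerce")
    parseable = numeric[[dialect.x, dialect.y, dialect.z, dialect.t]].notna().all(axis=1)
    # distinguish unit/sub-header rows (nothing numeric) from data rows with holes
    any_numeric = numeric.notna().any(axis=1)
    n_dropped = int((any_numeric & ~parseable).sum())

    spots = pd.DataFrame({
        "label": raw.loc[parseable, dialect.label].astype(str).to_numpy(),
        "t_min": numeric.loc[parseable, dialect.t].to_numpy() / dialect.time_unit_per_min,
        "x_um": numeric.loc[parseable, dialect.x].to_numpy() / dialect.space_unit_per_um,
        "y_um": numeric.loc[parseable, dialect.y].to_numpy() / dialect.space_unit_per_um,
        "z_um": numeric.loc[parseable, dialect.z].to_numpy() / dialect.space_unit_per_um,
    })
    if dialect.frame in raw.columns:
        spots["frame"] = numeric.loc[parseable, dialect.frame].astype(int).to_numpy()
    else:  # infer frame index from the time grid
        dt = _infer_frame_interval(spots["t_min"].to_numpy())
        spots["frame"] = np.rint(spots["t_min"].to_numpy() / dt).astype(int)
    dup = spots.duplicated(subset=["label", "frame"])
    if dup.any():
        bad = spots.loc[dup, ["label", "frame"]].iloc[0]
        raise ValueError(f"duplicate spot for label {bad['label']!r} at frame {int(bad['frame'])}")
    spots = spots[["label", "frame", "t_min", "x_um", "y_um", "z_um"]]
    spots.attrs["n_dropped"] = n_dropped
    return spots.sort_values(["label", "frame"], kind="stable").reset_index(drop=True)


def _infer_frame_interval(t_min: np.ndarray) -> float:
    diffs = np.diff(np.unique(t_min))
    diffs = diffs[diffs > 0]
    if diffs.size == 0:
        return 1.0
    return float(np.min(diffs))


def write_spots_table(tracks, path, dialect: SpotDialect | None = None) -> None:
    """Write tracks as a spot table in the same dialect ``read_spots_table`` reads."""
    dialect = dialect or SpotDialect()
    rows = []
    for tr in tracks:
        for pole_id, df in ((1, tr.pole1), (2, tr.pole2)):
            for _, r in df.iterrows():
                rows.append({
                    dialect.label: f"{tr.cell_id}_p{pole_id}",
                    dialect.frame: int(r["frame"]),
                    dialect.t: r["t_min"] * dialect.time_unit_per_min,
                    dialect.x: r["x_um"] * dialect.space_unit_per_um,
                    dialect.y: r["y_um"] * dialect.space_unit_per_um,
                    dialect.z: r["z_um"] * dialect.space_unit_per_um,
                })
    pd.DataFrame(rows).to_csv(path, sep=dialect.delimiter, index=False)


def pair_poles(spots: pd.DataFrame, frame_interval: float | None = None,
               dialect: SpotDialect | None = None,
               groups: dict[str, str] | None = None,
               gonads: dict[str, str] | None = None):
    """Pair pole tracks into one :class:`SpindleTrack` per cell label.

    Cells whose label matches other than exactly two pole identities are
    skipped and reported in the returned ``errors`` dict.

    Returns ``(tracks, errors)``.
    """
    dialect = dialect or SpotDialect()
    pat = re.compile(dialect.pole_pattern)
    cells: dict[str, dict[str, pd.DataFrame]] = {}
    errors: dict[str, str] = {}
    for label, df in spots.groupby("label", sort=True):
        m = pat.match(str(label))
        if m is None:
            errors[str(label)] = "label does not match pole-pairing pattern"
            continue
        cells.setdefault(m.group("cell"), {})[m.group("pole")] = df

    tracks = []
    for cell_id in sorted(cells):
        poles = cells[cell_id]
        if len(poles) != 2:
            errors[cell_id] = (
                f"ambiguous pairing: expected 2 pole identities, found {sorted(poles)}"
            )
            continue
        k1, k2 = sorted(poles)  # deterministic lexicographic pole order
        dfs = []
        for k in (k1, k2):
            df = poles[k].sort_values("frame", kind="stable")
            dfs.append(df[_POLE_COLS].reset_index(drop=True))
        dt = frame_interval
        if dt is None:
            dt = _infer_frame_interval(
                np.concatenate([d["t_min"].to_numpy() for d in dfs]))
        tracks.append(SpindleTrack(
            cell_id=cell_id, pole1=dfs[0], pole2=dfs[1], frame_interval=dt,
            group=(groups or {}).get(cell_id, ""),
            gonad_id=(gonads or {}).get(cell_id, ""),
        ))
    return tracks, errors


def spindle_length_series(track: SpindleTrack) -> LengthSeries:
    """Euclidean pole-to-pole distance at every frame where both poles exist."""
    m = track.pole1.merge(track.pole2, on="frame", suffixes=("_1", "_2"))
    if len(m) == 0:
        raise ValueError(f"cell {track.cell_id!r}: poles share no common frames")
    d = np.sqrt(
        (m["x_um_1"] - m["x_um_2"]) ** 2
        + (m["y_um_1"] - m["y_um_2"]) ** 2
        + (m["z_um_1"] - m["z_um_2"]) ** 2
    ).to_numpy()
    return LengthSeries(
        t=m["t_min_1"].to_numpy(), length=d, frame_interval=track.frame_interval,
        cell_id=track.cell_id, group=track.group, gonad_id=track.gonad_id,
    )


def spindle_axes(track: SpindleTrack) -> tuple[np.ndarray, np.ndarray]:
    """Per-common-frame unit spindle-axis vectors (undirected convention left
    to the consumer) and their times.

    Returns ``(t_min, axes)`` with ``axes`` of shape (n, 3).
    """
    m = track.pole1.merge(track.pole2, on="frame", suffixes=("_1", "_2"))
    if len(m) == 0:
        raise ValueError(f"cell {track.cell_id!r}: poles share no common frames")
    v = np.column_stack([
        (m[f"{c}_1"] - m[f"{c}_2"]).to_numpy() for c in ("x_um", "y_um", "z_um")
    ])
    norm = np.linalg.norm(v, axis=1)
    axes = np.divide(v, norm[:, None], out=np.zeros_like(v), where=norm[:, None] > 0)
    return m["t_min_1"].to_numpy(), axes


def write_length_table(series_list, path) -> None:
    """Tidy per-frame CSV: cell_id, group, gonad_id, t_min, length_um."""
    rows = []
    for s in series_list:
        for t, L in zip(s.t, s.length):
            rows.append({"cell_id": s.cell_id, "group": s.group,
                         "gonad_id": s.gonad_id, "t_min": t, "length_um": L})
    pd.DataFrame(rows).to_csv(path, index=False)
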