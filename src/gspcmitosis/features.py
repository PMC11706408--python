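"""The nine spindle features (A–I) extracted per mitotic cell.

Feature definitions (lengths in μm, times in minutes, angles in degrees):

A. Pole separation prior to NEBD — mean of the top 3 spindle-length
   measurements within 3 min prior to NEBD.
B. Duration of mitosis — t_AO − t_s.
C. Spindle length — mean spindle length between the "start" of mitosis
   (t_s) and anaphase onset (t_AO).
D. Spindle length variance — standard deviation of a random sample of 7
   length measurements between t_s and t_AO, lengths normalised to C.
E. Spindle length fluctuation — mean frame-to-frame change in spindle
   length, as a percent of C, divided by the frame interval (%/min).
F. Spindle rotation — mean angle between spindle axes in adjacent frames
   divided by the frame interval (angular velocity, deg/min), over mitosis.
G. Spindle elongation rate — slope of the least-squares line fit to length
   vs time between t_AO and t_AO + 2.5 min (μm/min).
H. Spindle rotation, anaphase — as F, on [t_AO, t_AO + 2.5 min].
I. Pole separation, telophase — second largest spindle length measured at
   least 7 min after t_AO, as a percent of C.

Conventions (the original description leaves these open; both are recorded
in the output and configurable): D samples without replacement with an
explicit seed; E uses the absolute frame-to-frame change (a signed mean
would cancel to ≈0 on a plateau).  The spindle axis is undirected — pole
labels are arbitrary — so inter-frame angles are folded to [0°, 90°].
Window boundaries are closed at the landmark frames; "within 3 min prior"
means (t_NEBD − 3, t_NEBD].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timing import MitoticLandmarks
from .track_io import LengthSeries

__all__ = ["SpindleFeatureVector", "extract_features", "features_table", "FEATURE_COLUMNS"]

FEATURE_COLUMNS = list("ABCDEFGHI")

FEATURE_NAMES = {
    "A": "pole_separation_pre_nebd_um",
    "B": "duration_min",
    "C": "mean_spindle_length_um",
    "D": "length_variance",
    "E": "length_fluctuation_pct_per_min",
    "F": "rotation_deg_per_min",
    "G": "elongation_rate_um_per_min",
    "H": "rotation_anaphase_deg_per_min",
    "I": "pole_separation_telophase_pct",
}


@dataclass
class SpindleFeatureVector:
    """Features A–I for one cell; missing windows leave a NaN plus a flag."""

    A: float
    B: float
    C: float
    D: float
    E: float
    F: float
    G: float
    H: float
    I: float
    flags: frozenset = frozenset()
    cell_id: str = ""
    group: str = ""
    gonad_id: str = ""
    seed: int = 0

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in FEATURE_COLUMNS}
        d.update(cell_id=self.cell_id, group=self.group, gonad_id=self.gonad_id,
                 seed=self.seed, flags=";".join(sorted(self.flags)))
        return d


def axis_angles_deg(axes: np.ndarray) -> np.ndarray:
    """Angles (degrees, in [0, 90]) between consecutive undirected axes."""
    a = np.asarray(axes, float)
    dots = np.abs(np.sum(a[:-1] * a[1:], axis=1))
    return np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))


def _mean_rate(values: np.ndarray, t: np.ndarray) -> float:
    """Mean of per-consecutive-pair value/Δt."""
    dt = np.diff(t)
    return float(np.mean(values / dt))


def extract_features(series: LengthSeries, axes: np.ndarray,
                     landmarks: MitoticLandmarks, seed: int = 0, *,
                     d_sample_size: int = 7,
                     d_with_replacement: bool = False,
                     e_signed: bool = False) -> SpindleFeatureVector:
    """Compute features A–I from a length series, per-frame spindle axes and
    scored landmarks.

    ``axes`` must be aligned with ``series`` (one unit vector per frame of
    the series).  Features whose time window is not covered by the series
    are returned as NaN with an explanatory flag; all others are still
    computed.
    """
    t = np.asarray(series.t, float)
    L = np.asarray(series.length, float)
    axes = np.asarray(axes, float)
    if axes.shape != (t.size, 3):
        raise ValueError("axes must have one unit vector per series frame")
    flags: set[str] = set()
    nan = float("nan")

    lm = landmarks
    mit = (t >= lm.t_s) & (t <= lm.t_ao)
    n_mit = int(mit.sum())

    # A — mean of the 3 largest lengths in (t_nebd - 3, t_nebd]
    pre = (t > lm.t_nebd - 3.0) & (t <= lm.t_nebd)
    if pre.sum() < 3:
        A = nan
        flags.add("A_absent")
    else:
        A = float(np.mean(np.sort(L[pre])[-3:]))

    B = float(lm.duration)
    C = float(np.mean(L[mit])) if n_mit else nan
    if n_mit == 0:
        flags.add("no_mitotic_frames")

    # D — SD of a seeded random sample of 7 normalised lengths in [t_s, t_ao]
    if n_mit == 0 or not np.isfinite(C) or C <= 0:
        D = nan
    else:
        norm = L[mit] / C
        if n_mit < d_sample_size + 1 and not d_with_replacement:
            sample = norm
            flags.add("D_all_frames")
        else:
            rng = np.random.default_rng(seed)
            idx = rng.choice(n_mit, size=d_sample_size, replace=d_with_replacement)
            sample = norm[idx]
        D = float(np.std(sample, ddof=1)) if sample.size > 1 else nan

    # E — mean |ΔL| per pair as % of C per minute
    if n_mit >= 2 and np.isfinite(C) and C > 0:
        dL = np.diff(L[mit])
        if not e_signed:
            dL = np.abs(dL)
        E = _mean_rate(dL / C * 100.0, t[mit])
    else:
        E = nan
        flags.add("E_absent")

    # F — mean inter-frame axis angle per minute over mitosis
    if n_mit >= 2:
        ang = axis_angles_deg(axes[mit])
        F = _mean_rate(ang, t[mit])
    else:
        F = nan
        flags.add("F_absent")

    # G, H — anaphase window [t_ao, t_ao + 2.5 min]
    ana = (t >= lm.t_ao) & (t <= lm.t_ao + 2.5)
    n_ana = int(ana.sum())
    if n_ana >= 2:
        G = float(np.polyfit(t[ana], L[ana], 1)[0])
        H = _mean_rate(axis_angles_deg(axes[ana]), t[ana])
    else:
        G = H = nan
        flags.add("anaphase_window_absent")

    # I — second-largest length at t >= t_ao + 7 min, as % of C
    late = t >= lm.t_ao + 7.0
    if late.sum() < 2 or not np.isfinite(C) or C <= 0:
        I = nan
        flags.add("I_absent")
    else:
        I = float(np.sort(L[late])[-2] * 100.0 / C)

    return SpindleFeatureVector(
        A=A, B=B, C=C, D=D, E=E, F=F, G=G, H=H, I=I,
        flags=frozenset(flags), cell_id=series.cell_id, group=series.group,
        gonad_id=series.gonad_id, seed=seed,
    )


def features_table(vectors) -> pd.DataFrame:
    """Per-cell feature table with columns A…I + cell_id, group, gonad_id,
    seed, flags (the layout of the screen's per-cell feature export)."""
    df = pd.DataFrame([v.to_dict() for v in vectors])
    order = ["cell_id", "group", "gonad_id", *FEATURE_COLUMNS, "seed", "flags"]
    return df[order]
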