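"""Scoring mitotic landmarks and durations.

Mitotic progression of a germline stem/progenitor cell (GSPC) is read out
from the pole-to-pole spindle-length trace: pole separation holds roughly
constant before nuclear envelope breakdown (NEBD), collapses during NEBD,
sits at a noisy stable minimum through prometa/metaphase, and elongates
rapidly after the metaphase-anaphase transition.  Three landmarks are scored
on this trace:

* ``t_nebd`` — NEBD, the onset of the steep length decrease;
* ``t_s`` — the "start" of mitosis, the first time point after NEBD at which
  spindle length reaches its stable minimum (used instead of NEBD itself as
  the start of the duration measurement because it is far less ambiguous);
* ``t_ao`` — anaphase onset, after which spindle length increases rapidly.

``duration = t_ao − t_s``.

Scoring was done by eye (clicking on length-vs-time plots) in the original
workflow; here it is a deterministic procedure with tunable thresholds,
validated by simulation.  Cells the procedure finds ambiguous are flagged,
never silently guessed.

A second, marker-independent route scores NEBD and anaphase onset from the
variance of a fluorescent histone signal within a nuclear ROI: variance is
low in interphase, rises sharply as chromosomes congress into a compact
plate, and falls sharply as they segregate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .track_io import LengthSeries

__all__ = [
    "MitoticLandmarks",
    "LandmarkConfig",
    "ChromatinTrace",
    "VarianceLandmarks",
    "score_landmarks_from_length",
    "chromatin_variance_trace",
    "score_landmarks_from_variance",
]


class LandmarkError(ValueError):
    """A landmark could not be scored from the given trace."""


@dataclass
class MitoticLandmarks:
    """NEBD, mitosis "start" and anaphase onset on a common time axis (min)."""

    t_nebd: float
    t_s: float
    t_ao: float
    quality_flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not (self.t_nebd <= self.t_s <= self.t_ao):
            raise ValueError(
                f"landmarks must be ordered t_nebd <= t_s <= t_ao, got "
                f"{self.t_nebd}, {self.t_s}, {self.t_ao}"
            )
        self.quality_flags = frozenset(self.quality_flags)

    @property
    def duration(self) -> float:
        """Duration of mitosis in minutes (anaphase onset minus "start")."""
        return self.t_ao - self.t_s


@dataclass(frozen=True)
class LandmarkConfig:
    """Thresholds of the length-based landmark scorer.

    All thresholds are relative to the plateau minimum ``B`` so scoring is
    invariant to the length unit.

    delta        : plateau band half-width; frames with smoothed length
                   within ±delta*B of the plateau level B are "at the
                   stable minimum".  B is estimated robustly as the median
                   of the smoothed frames in the lower ``plateau_region_frac``
                   of the smoothed range, so a few noisy dips near the
                   minimum cannot drag the band off the plateau.
    plateau_region_frac : fraction of the smoothed min-max range (above the
                   minimum) whose frames vote for the plateau level B.
    rise_frac    : net increase (fraction of B) within ``rise_window_min``
                   minutes that qualifies a plateau frame as pre-anaphase.
    rise_window_min : look-ahead window for the anaphase rise (min).
    delta_nebd   : NEBD threshold; t_nebd is the last pre-start frame whose
                   smoothed length exceeds B*(1+delta_nebd) on a falling run.
    smooth_window: centred moving-median window (frames).
    min_frames   : minimum series length to attempt scoring.
    max_gap_frames : longest tolerated run of missing frames inside the
                   plateau before the cell is flagged.
    """

    delta: float = 0.15
    plateau_region_frac: float = 0.25
    rise_frac: float = 0.25
    rise_window_min: float = 4.0
    delta_nebd: float = 0.30
    smooth_window: int = 3
    min_frames: int = 8
    max_gap_frames: int = 2


def score_landmarks_from_length(series: LengthSeries,
                                cfg: LandmarkConfig | None = None) -> MitoticLandmarks:
    """Score NEBD, "start" and anaphase onset from a spindle-length series.

    Algorithm: (1) smooth with a centred moving median; (2) estimate the
    stable-minimum plateau level B (median of the smoothed frames in the
    lower quarter of the smoothed range) and call frames within ±delta*B of B
    the plateau band; (3) anaphase onset is the last band frame followed by
    a net smoothed increase >= rise_frac*B within rise_window_min minutes;
    (4) the "start" is the first band frame after the collapse; (5) NEBD is
    the last pre-start frame on a falling run whose smoothed length exceeds
    B*(1+delta_nebd).

    Raises :class:`LandmarkError` when no plateau or no anaphase rise exists.
    """
    cfg = cfg or LandmarkConfig()
    t = np.asarray(series.t, float)
    L = np.asarray(series.length, float)
    if t.size < cfg.min_frames:
        raise LandmarkError(
            f"series has {t.size} frames; need >= {cfg.min_frames}")
    flags: set[str] = set()

    smoothed = ndi.median_filter(L, size=cfg.smooth_window, mode="nearest")
    m = float(smoothed.min())
    level_thr = m + cfg.plateau_region_frac * (float(smoothed.max()) - m)
    B = float(np.median(smoothed[smoothed <= level_thr]))
    if B <= 0:
        B = np.finfo(float).tiny
    band = np.abs(smoothed - B) <= cfg.delta * B
    band_idx = np.flatnonzero(band)
    # a strictly monotone series has no stable minimum at all
    if band_idx.size == 0 or np.all(np.diff(smoothed) > 0) or np.all(np.diff(smoothed) < 0):
        raise LandmarkError("no metaphase plateau detected")

    # anaphase onset: last band frame followed by a qualifying net rise
    i_ao = None
    for i in band_idx[::-1]:
        ahead = (t > t[i]) & (t <= t[i] + cfg.rise_window_min)
        if np.any(ahead) and (smoothed[ahead].max() - smoothed[i]) >= cfg.rise_frac * B:
            i_ao = int(i)
            break
    if i_ao is None:
        raise LandmarkError("no anaphase elongation detected")

    # "start": first band frame at/after the pre-plateau maximum (the collapse)
    first_band = int(band_idx[0])
    i_peak = int(np.argmax(smoothed[: first_band + 1]))
    later = band_idx[band_idx >= i_peak]
    i_s = int(later[0]) if later.size else first_band
    if i_s > i_ao:
        i_s = i_ao
        flags.add("start_after_anaphase")

    # NEBD: last pre-start frame above B*(1+delta_nebd) on a falling run
    thr = B * (1.0 + cfg.delta_nebd)
    i_nebd = None
    for i in range(i_s - 1, -1, -1):
        if smoothed[i] > thr and smoothed[i] >= smoothed[min(i + 1, len(smoothed) - 1)]:
            i_nebd = i
            break
    if i_nebd is None:
        i_nebd = i_s
        flags.add("nebd_not_found")

    # gap check inside the plateau (missing frames between start and AO)
    in_plateau = (t >= t[i_s]) & (t <= t[i_ao])
    dt_seen = np.diff(t[in_plateau])
    if dt_seen.size and dt_seen.max() > (cfg.max_gap_frames + 1) * series.frame_interval + 1e-9:
        flags.add("plateau_gap")

    return MitoticLandmarks(
        t_nebd=float(t[i_nebd]), t_s=float(t[i_s]), t_ao=float(t[i_ao]),
        quality_flags=frozenset(flags),
    )


@dataclass
class ChromatinTrace:
    """Variance of a histone-marker signal within a nuclear ROI over time.

    ``normalized`` is the min-max normalisation of ``variance`` over the
    cell's time span (in [0, 1] whenever max > min).
    """

    t: np.ndarray
    variance: np.ndarray
    normalized: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.variance = np.asarray(self.variance, float)
        if self.normalized is None:
            lo, hi = float(self.variance.min()), float(self.variance.max())
            if hi <= lo:
                raise LandmarkError("flat trace, cannot normalize")
            self.normalized = (self.variance - lo) / (hi - lo)
        else:
            self.normalized = np.asarray(self.normalized, float)


@dataclass
class VarianceLandmarks:
    t_nebd: float
    t_ao: float
    quality_flags: frozenset = frozenset()

    @property
    def duration(self) -> float:
        return self.t_ao - self.t_nebd


def chromatin_variance_trace(stack: np.ndarray, centers_um: np.ndarray, *,
                             pixel_size_xy: float, z_step: float = 0.75,
                             roi_diameter: float = 4.5,
                             frame_interval: float = 1.0,
                             n_project: int = 5) -> ChromatinTrace:
    """Per-frame histone-signal variance inside a tracked nuclear ROI.

    For each frame of the (T, Z, Y, X) ``stack``, ``n_project`` z-slices
    centred on the tracked nucleus are mean-projected and the pixel variance
    is taken within a circular ROI of ``roi_diameter`` μm centred on the
    nucleus.  The trace is min-max normalised over the cell's time span.

    ``centers_um`` has shape (T, 3) as (x, y, z) in μm.
    """
    stack = np.asarray(stack, float)
    if stack.ndim != 4:
        raise ValueError("stack must be (T, Z, Y, X)")
    n_t, n_z, n_y, n_x = stack.shape
    centers_um = np.asarray(centers_um, float)
    if centers_um.shape != (n_t, 3):
        raise ValueError("centers_um must have shape (T, 3)")
    if n_z < n_project:
        raise ValueError(f"stack has {n_z} z-slices; need >= {n_project}")
    half = n_project // 2
    r_px = (roi_diameter / 2.0) / pixel_size_xy
    var = np.empty(n_t)
    yy, xx = np.mgrid[0:n_y, 0:n_x]
    for f in range(n_t):
        cx, cy, cz = centers_um[f]
        zc = int(round(cz / z_step))
        if zc - half < 0 or zc + half >= n_z:
            raise ValueError(f"frame {f}: projection window outside stack in Z")
        proj = stack[f, zc - half: zc + half + 1].mean(axis=0)
        mask = ((xx + 0.5) - cx / pixel_size_xy) ** 2 + \
               ((yy + 0.5) - cy / pixel_size_xy) ** 2 <= r_px ** 2
        if not mask.any() or (cx - roi_diameter / 2 < 0) or (cy - roi_diameter / 2 < 0) \
                or (cx + roi_diameter / 2 > n_x * pixel_size_xy) \
                or (cy + roi_diameter / 2 > n_y * pixel_size_xy):
            raise ValueError(f"frame {f}: ROI outside image")
        var[f] = float(proj[mask].var())
    t = np.arange(n_t) * frame_interval
    return ChromatinTrace(t=t, variance=var)


def score_landmarks_from_variance(trace: ChromatinTrace) -> VarianceLandmarks:
    """Score NEBD and anaphase onset from a normalised chromatin-variance trace.

    NEBD is the last time point strictly before the global maximum with
    normalised variance < 0.5 (just prior to the sharp congression rise);
    anaphase onset is the last time point with normalised variance > 0.7
    (just prior to the sharp segregation fall).  Thresholds are strict
    inequalities.
    """
    v = np.asarray(trace.normalized, float)
    t = np.asarray(trace.t, float)
    flags: set[str] = set()
    i_max = int(np.argmax(v))
    before = np.flatnonzero(v[:i_max] < 0.5)
    if before.size == 0:
        flags.add("NEBD outside window")
        i_nebd = 0
    else:
        i_nebd = int(before[-1])
    above = np.flatnonzero(v > 0.7)
    i_ao = int(above[-1])  # max normalises to 1, so this always exists
    if t[i_ao] < t[i_nebd]:
        raise LandmarkError("anaphase onset scored before NEBD")
    return VarianceLandmarks(t_nebd=float(t[i_nebd]), t_ao=float(t[i_ao]),
                             quality_flags=frozenset(flags))
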