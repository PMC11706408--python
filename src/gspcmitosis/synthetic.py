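"""Synthetic microscopy-derived data with known ground truth.

Every downstream stage of the pipeline — landmark scoring, spindle features,
cohort statistics, intensity quantification and nucleus counting — is
validated against data produced here, so nothing requires the original
imaging data.

What is emulated (and what is not): spindle-length kinematics follow the
stereotyped GSPC profile (constant pole separation before NEBD, linear
collapse through NEBD, a noisy metaphase plateau, linear anaphase elongation
capped at a transient telophase peak, then relaxation); the spindle axis
performs small random rotations frame to frame; chromatin-variance traces
rise sigmoidally at congression and fall sharply at segregation; nucleus /
cytoplasm images are flat-intensity disks with neighbours and additive
background; proliferative-zone stacks are fields of Gaussian blobs at
germline densities.  Optics (PSF, bleaching), animal movement and
photon-physics are deliberately not modelled — registration is upstream of
this pipeline and the scorers only rely on relative intensities.

Default magnitudes are illustrative choices realistic for ~4 μm germline
nuclei; the original study does not print its kinematic magnitudes, so these
defaults are not calibrated to real GSPCs (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timing import MitoticLandmarks
from .track_io import SpindleTrack

__all__ = [
    "SpindleSimParams",
    "NucleusRenderParams",
    "PZFieldParams",
    "simulate_spindle_track",
    "spindle_length_profile",
    "simulate_chromatin_trace",
    "render_chromatin_stack",
    "render_nucleus_image",
    "simulate_pz_stack",
    "simulate_cohort",
]


def _snap(t: float, dt: float) -> float:
    """Snap a time to the frame grid (ground-truth landmarks live on it)."""
    return round(t / dt) * dt


@dataclass(frozen=True)
class SpindleSimParams:
    """Generative parameters of one mitotic spindle-length trajectory.

    Times in minutes, lengths in μm, rates in μm/min or degrees/min.
    ``metaphase_length`` is the plateau mean (the quantity whose in-mitosis
    mean is the spindle-length feature), ``elongation_rate`` the ground truth
    for the anaphase elongation feature, ``telophase_peak`` the transient
    maximum that defines the telophase pole-separation feature.
    """

    frame_interval: float = 0.5
    t_nebd: float = 3.0
    t_s: float = 4.0
    t_ao: float = 8.5
    pre_nebd_separation: float = 5.0
    metaphase_length: float = 3.5
    plateau_noise_sd: float = 0.2
    length_noise_sd: float = 0.05  # measurement noise on every frame
    elongation_rate: float = 1.2
    rotation_rate_sd: float = 5.0
    telophase_peak: float = 8.0
    relax_rate: float = 0.25
    centroid_drift_sd: float = 0.05
    n_frames: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.t_nebd < self.t_s <= self.t_ao):
            raise ValueError("landmark times must satisfy t_nebd < t_s <= t_ao")
        for name in ("frame_interval", "pre_nebd_separation", "metaphase_length",
                     "telophase_peak"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.telophase_peak < self.metaphase_length:
            raise ValueError("telophase_peak must be >= metaphase_length")


def spindle_length_profile(params: SpindleSimParams, t: np.ndarray) -> np.ndarray:
    """Closed-form noise-free spindle length at times ``t`` (minutes)."""
    t = np.asarray(t, float)
    dt = params.frame_interval
    t_nebd = _snap(params.t_nebd, dt)
    t_s = _snap(params.t_s, dt)
    t_ao = _snap(params.t_ao, dt)
    L = np.empty_like(t)
    pre = t < t_nebd
    collapse = (t >= t_nebd) & (t < t_s)
    plateau = (t >= t_s) & (t <= t_ao)
    ana = t > t_ao
    L[pre] = params.pre_nebd_separation
    span = max(t_s - t_nebd, dt)
    L[collapse] = params.pre_nebd_separation + (
        params.metaphase_length - params.pre_nebd_separation
    ) * (t[collapse] - t_nebd) / span
    L[plateau] = params.metaphase_length
    # anaphase: linear elongation capped at the telophase peak, then a slow
    # relaxation so "second largest late length" is well defined
    rise = params.metaphase_length + params.elongation_rate * (t[ana] - t_ao)
    if params.elongation_rate > 0:
        t_peak = t_ao + (params.telophase_peak - params.metaphase_length) / params.elongation_rate
    else:
        t_peak = np.inf
    after = t[ana] > t_peak
    rise = np.minimum(rise, params.telophase_peak)
    rise[after] = np.maximum(
        params.telophase_peak - params.relax_rate * (t[ana][after] - t_peak),
        0.8 * params.telophase_peak,
    )
    L[ana] = rise
    return L


def _perp_unit(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    w = rng.normal(size=3)
    w -= w.dot(v) * v
    n = np.linalg.norm(w)
    if n < 1e-12:  # pathologically parallel draw; retry deterministically
        return _perp_unit(v, rng)
    return w / n


def _rotate(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    return (v * np.cos(angle_rad)
            + np.cross(axis, v) * np.sin(angle_rad)
            + axis * axis.dot(v) * (1 - np.cos(angle_rad)))


def simulate_spindle_track(params: SpindleSimParams, *, cell_id: str = "cell",
                           group: str = "", gonad_id: str = ""
                           ) -> tuple[SpindleTrack, MitoticLandmarks]:
    """Simulate paired spindle-pole trajectories plus ground-truth landmarks.

    The pole-to-pole distance follows :func:`spindle_length_profile` with
    Gaussian noise (sd ``plateau_noise_sd``) added on the metaphase plateau;
    the spindle axis rotates by a Gaussian angle each frame; both poles share
    a random-walk centroid drift.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval
    t = np.arange(params.n_frames) * dt
    L = spindle_length_profile(params, t)
    t_s = _snap(params.t_s, dt)
    t_ao = _snap(params.t_ao, dt)
    on_plateau = (t >= t_s) & (t <= t_ao)
    L = L.copy()
    if params.length_noise_sd > 0:  # localisation error, every frame
        L += rng.normal(0.0, params.length_noise_sd, L.shape)
    if params.plateau_noise_sd > 0:  # genuine plateau length fluctuation
        L[on_plateau] += rng.normal(0.0, params.plateau_noise_sd, on_plateau.sum())
    L = np.maximum(L, 0.1)

    axis = np.zeros((params.n_frames, 3))
    a = rng.normal(size=3)
    a /= np.linalg.norm(a)
    axis[0] = a
    for i in range(1, params.n_frames):
        ang = np.deg2rad(rng.normal(0.0, params.rotation_rate_sd * dt))
        a = _rotate(a, _perp_unit(a, rng), ang)
        a /= np.linalg.norm(a)
        axis[i] = a

    drift = np.cumsum(rng.normal(0.0, params.centroid_drift_sd, (params.n_frames, 3)), axis=0)
    center = np.array([20.0, 20.0, 10.0]) + drift
    p1 = center + axis * (L[:, None] / 2.0)
    p2 = center - axis * (L[:, None] / 2.0)

    frames = np.arange(params.n_frames)
    pole = lambda p: pd.DataFrame({
        "frame": frames, "t_min": t,
        "x_um": p[:, 0], "y_um": p[:, 1], "z_um": p[:, 2],
    })
    track = SpindleTrack(cell_id=cell_id, pole1=pole(p1), pole2=pole(p2),
                         frame_interval=dt, group=group, gonad_id=gonad_id)
    truth = MitoticLandmarks(t_nebd=_snap(params.t_nebd, dt), t_s=t_s, t_ao=t_ao)
    return track, truth


def simulate_chromatin_trace(t_nebd: float, t_ao: float, frame_interval: float,
                             baseline: float = 1.0, peak: float = 5.0,
                             noise_sd: float = 0.0, seed: int = 0,
                             n_frames: int | None = None,
                             rise_min: float = 1.5, fall_min: float = 1.0):
    """Synthetic chromatin-variance trace with known NEBD / anaphase onset.

    Variance sits at ``baseline`` before NEBD, rises along a smooth sigmoid
    to ``peak`` over ``rise_min`` minutes (chromosome congression), holds,
    then falls sharply over ``fall_min`` minutes after anaphase onset
    (segregation).  Returns ``(t, variance, truth)`` with ``truth`` a dict of
    grid-snapped ``t_nebd`` and ``t_ao``.
    """
    if peak <= baseline:
        raise ValueError("peak must exceed baseline")
    if not t_nebd < t_ao:
        raise ValueError("t_nebd must precede t_ao")
    dt = frame_interval
    t_nebd = _snap(t_nebd, dt)
    t_ao = _snap(t_ao, dt)
    if n_frames is None:
        n_frames = int(round((t_ao + 2.0 * fall_min) / dt)) + 1
    t = np.arange(n_frames) * dt

    def smoothstep(u):
        u = np.clip(u, 0.0, 1.0)
        return 3 * u ** 2 - 2 * u ** 3

    up = smoothstep((t - t_nebd) / rise_min)
    down = smoothstep((t - t_ao) / fall_min)
    v = baseline + (peak - baseline) * np.minimum(up, 1.0 - down)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, v.shape)
    return t, v, {"t_nebd": t_nebd, "t_ao": t_ao}


def render_chromatin_stack(t_nebd: float, t_ao: float, frame_interval: float, *,
                           baseline: float = 1.0, peak: float = 5.0,
                           pixel_size_xy: float = 0.25, z_step: float = 0.75,
                           image_size_um: float = 12.0, n_z: int = 7,
                           roi_diameter: float = 4.5, seed: int = 0):
    """Render a chromatin-variance trace into a 4D pixel stack.

    Inside the nuclear ROI the pixel values are a fixed zero-mean texture
    scaled so the within-ROI variance at frame f equals the generating trace
    value; the histone-variance scorer can then be validated end to end from
    pixels.  Returns ``(stack, centers_um, truth_trace, truth_landmarks)``.
    """
    t, v, truth = simulate_chromatin_trace(t_nebd, t_ao, frame_interval,
                                           baseline=baseline, peak=peak, seed=seed)
    n_t = t.size
    n_px = int(round(image_size_um / pixel_size_xy))
    cx = cy = image_size_um / 2.0
    cz = (n_z // 2) * z_step
    yy, xx = np.mgrid[0:n_px, 0:n_px]
    mask = ((xx + 0.5) * pixel_size_xy - cx) ** 2 + \
           ((yy + 0.5) * pixel_size_xy - cy) ** 2 <= (roi_diameter / 2) ** 2
    rng = np.random.default_rng(seed)
    texture = rng.normal(size=mask.sum())
    texture = (texture - texture.mean()) / texture.std()  # exact unit variance
    stack = np.zeros((n_t, n_z, n_px, n_px))
    for f in range(n_t):
        frame = np.full((n_px, n_px), 10.0)
        frame[mask] = 10.0 + np.sqrt(v[f]) * texture
        stack[f] = frame[None, :, :]
    centers = np.tile(np.array([cx, cy, cz]), (n_t, 1))
    return stack, centers, (t, v), truth


@dataclass(frozen=True)
class NucleusRenderParams:
    """Flat-disk nucleus/cytoplasm geometry for N:C-ratio validation."""

    nucleus_diameter: float = 4.5
    true_nc_ratio: float = 2.0
    cytoplasm_intensity: float = 100.0
    background_intensity: float = 0.0
    neighbor_centers: tuple = ()
    pixel_size: float = 0.1
    noise_sd: float = 0.0
    seed: int = 0
    cell_diameter: float = 9.0
    image_size_um: float = 16.0

    def __post_init__(self) -> None:
        if self.true_nc_ratio <= 0:
            raise ValueError("true_nc_ratio must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


def render_nucleus_image(params: NucleusRenderParams):
    """Render a nucleus-in-cytoplasm image plus ground-truth masks.

    The nucleus disk carries ``true_nc_ratio × cytoplasm_intensity`` above
    background, the surrounding cell region carries ``cytoplasm_intensity``,
    neighbour nuclei are drawn at the same nuclear intensity, and
    ``background_intensity`` is added everywhere.  Returns
    ``(image, masks)`` with masks ``nucleus``, ``cytoplasm``, ``neighbors``.
    """
    p = params
    n_px = int(round(p.image_size_um / p.pixel_size))
    c = p.image_size_um / 2.0
    yy, xx = np.mgrid[0:n_px, 0:n_px]
    X = (xx + 0.5) * p.pixel_size
    Y = (yy + 0.5) * p.pixel_size
    r_nuc = p.nucleus_diameter / 2.0
    for nc in p.neighbor_centers:
        d = np.hypot(nc[0] - c, nc[1] - c)
        if d < p.nucleus_diameter:  # overlapping the central nucleus disk
            raise ValueError(
                f"neighbor at {nc} overlaps the central nucleus (distance {d:.2f} μm)")
    nucleus = (X - c) ** 2 + (Y - c) ** 2 <= r_nuc ** 2
    cell = (X - c) ** 2 + (Y - c) ** 2 <= (p.cell_diameter / 2.0) ** 2
    neighbors = np.zeros_like(nucleus)
    for nc in p.neighbor_centers:
        neighbors |= (X - nc[0]) ** 2 + (Y - nc[1]) ** 2 <= r_nuc ** 2

    nuclear_level = p.true_nc_ratio * p.cytoplasm_intensity
    img = np.zeros((n_px, n_px))
    img[cell | neighbors] = p.cytoplasm_intensity
    img[neighbors] = nuclear_level
    img[nucleus] = nuclear_level
    img += p.background_intensity
    if p.noise_sd > 0:
        img = img + np.random.default_rng(p.seed).normal(0.0, p.noise_sd, img.shape)
    masks = {
        "nucleus": nucleus,
        "cytoplasm": cell & ~nucleus & ~neighbors,
        "neighbors": neighbors,
        "cell": cell,
    }
    return img, masks


@dataclass(frozen=True)
class PZFieldParams:
    """A field of nuclei at proliferative-zone densities.

    ``volume`` is the (x, y, z) box in μm; ``snr`` is blob amplitude over
    additive Gaussian noise sd (``inf`` = noise-free).  The 4.25 μm default
    diameter matches the blob size used for germline nucleus detection.
    """

    n_nuclei: int = 50
    nucleus_diameter: float = 4.25
    min_spacing: float = 5.5  # centre spacing of non-interpenetrating cells
    volume: tuple = (85.0, 35.0, 16.0)
    snr: float = 10.0
    n_frames: int = 6
    seed: int = 0
    pixel_size_xy: float = 0.4
    z_step: float = 0.75
    jitter_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.min_spacing < 0:
            raise ValueError("min_spacing must be >= 0")


def _place_centers(p: PZFieldParams, rng: np.random.Generator) -> np.ndarray:
    """Random sequential placement with a hard minimum spacing."""
    margin = p.nucleus_diameter / 2.0
    lo = np.array([margin] * 3)
    hi = np.array(p.volume) - margin
    if np.any(hi <= lo) and p.n_nuclei > 0:
        raise ValueError("volume too small for the nucleus diameter")
    centers: list[np.ndarray] = []
    attempts = 0
    max_attempts = 20000 * max(p.n_nuclei, 1)
    while len(centers) < p.n_nuclei:
        attempts += 1
        if attempts > max_attempts:
            box = float(np.prod(np.maximum(np.array(p.volume), 1e-9)))
            dens = len(centers) / box
            raise ValueError(
                f"cannot place {p.n_nuclei} nuclei at min_spacing="
                f"{p.min_spacing} μm in volume {p.volume}; achievable density "
                f"~{dens:.4f}/μm³ ({len(centers)} placed)")
        c = rng.uniform(lo, hi)
        if all(np.linalg.norm(c - o) >= p.min_spacing for o in centers):
            centers.append(c)
    return np.array(centers).reshape(-1, 3)


def simulate_pz_stack(params: PZFieldParams):
    """Simulate a (T, Z, Y, X) stack of Gaussian-blob nuclei plus true centers.

    Blobs have FWHM ≈ ``nucleus_diameter`` and persist (with small positional
    jitter) through every frame.  Returns ``(stack, centers_um)`` where
    ``centers_um`` is the (n, 3) array of base (x, y, z) positions.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    centers = _place_centers(p, rng)
    nx = int(round(p.volume[0] / p.pixel_size_xy))
    ny = int(round(p.volume[1] / p.pixel_size_xy))
    nz = int(round(p.volume[2] / p.z_step))
    sigma = p.nucleus_diameter / 2.35482  # FWHM -> Gaussian sd
    amp = 100.0
    zz = (np.arange(nz) + 0.5) * p.z_step
    yy = (np.arange(ny) + 0.5) * p.pixel_size_xy
    xx = (np.arange(nx) + 0.5) * p.pixel_size_xy
    stack = np.zeros((p.n_frames, nz, ny, nx))
    for f in range(p.n_frames):
        jit = centers + rng.normal(0.0, p.jitter_sd, centers.shape) if p.jitter_sd > 0 else centers
        vol = np.zeros((nz, ny, nx))
        for (cx, cy, cz) in jit:
            gz = np.exp(-((zz - cz) ** 2) / (2 * sigma ** 2))
            gy = np.exp(-((yy - cy) ** 2) / (2 * sigma ** 2))
            gx = np.exp(-((xx - cx) ** 2) / (2 * sigma ** 2))
            vol += amp * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        if np.isfinite(p.snr) and p.snr > 0:
            vol = vol + rng.normal(0.0, amp / p.snr, vol.shape)
        stack[f] = vol
    return stack, centers


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class GroupSpec:
    """Per-genotype simulation conditions for a synthetic screen cohort."""

    n_cells: int = 20
    duration_mean: float = 4.5
    duration_sd: float = 1.0
    cells_per_gonad: int = 4
    overrides: dict = field(default_factory=dict)


def simulate_cohort(groups: dict[str, GroupSpec], seed: int = 0,
                    base: SpindleSimParams | None = None):
    """Simulate a multi-genotype cohort of spindle tracks.

    Per-cell mitotic durations are drawn from the group's Normal duration
    distribution (clipped to [1, 25] min) and snapped to the frame grid.
    Returns ``(tracks, truth)`` where ``truth`` is a DataFrame of per-cell
    ground-truth landmarks and generative parameters.
    """
    base = base or SpindleSimParams()
    rng = np.random.default_rng(seed)
    tracks, rows = [], []
    for gname in groups:
        spec = groups[gname]
        for i in range(spec.n_cells):
            dur = float(np.clip(rng.normal(spec.duration_mean, spec.duration_sd), 1.0, 25.0))
            dur = max(_snap(dur, base.frame_interval), base.frame_interval)
            cell_seed = int(rng.integers(0, 2 ** 31 - 1))
            n_frames = int(round((base.t_s + dur + 10.0) / base.frame_interval)) + 1
            params = dataclasses.replace(
                base, t_ao=base.t_s + dur, n_frames=n_frames, seed=cell_seed,
                **spec.overrides)
            cell_id = f"{gname}_c{i:03d}"
            gonad_id = f"{gname}_g{i // spec.cells_per_gonad:02d}"
            track, truth = simulate_spindle_track(
                params, cell_id=cell_id, group=gname, gonad_id=gonad_id)
            tracks.append(track)
            rows.append({
                "cell_id": cell_id, "group": gname, "gonad_id": gonad_id,
                "t_nebd": truth.t_nebd, "t_s": truth.t_s, "t_ao": truth.t_ao,
                "duration": truth.duration, "seed": cell_seed,
                "elongation_rate": params.elongation_rate,
                "metaphase_length": params.metaphase_length,
            })
    return tracks, pd.DataFrame(rows)


def write_ground_truth(truth: pd.DataFrame, csv_path, json_path=None,
                       meta: dict | None = None) -> None:
    """Ground-truth CSV plus a JSON sidecar with run metadata."""
    truth.to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump({"n_cells": int(len(truth)),
                       "groups": sorted(truth["group"].unique().tolist()),
                       **(meta or {})}, fh, indent=2)
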