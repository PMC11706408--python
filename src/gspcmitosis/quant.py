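"""Image-derived scalar quantifications.

Covers the nuclear:cytoplasmic (N:C) fluorescence ratio used to read out
transcription-factor nuclear enrichment, its pre-mitotic summary, germline
reporter-depletion fluorescence, proliferative-zone (PZ) nucleus counting by
Difference-of-Gaussians blob detection with nearest-neighbour track linking,
the mitotic index, and the simple count-based assay ratios (mitotic-error
classes, embryonic lethality).

Pixel conventions: 0-based indices, pixel centres at (index + 0.5) ×
pixel_size, rectangular ROIs half-open in pixel coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from scipy import stats
from skimage.feature import peak_local_max

__all__ = [
    "NCMeasurement",
    "PZCount",
    "PZDetectConfig",
    "measure_nc_ratio",
    "premitotic_nc",
    "count_pz_nuclei",
    "mitotic_index",
    "measure_depletion_fi",
    "assay_ratios",
    "embryonic_lethality",
]


@dataclass
class NCMeasurement:
    """Background-subtracted nuclear-to-cytoplasmic fluorescence ratio."""

    nuclear_fi: float
    cytoplasmic_fi: float
    background_fi: float
    nc_ratio: float
    flags: frozenset = frozenset()


def disk_mask(shape, center_um, radius_um, pixel_size) -> np.ndarray:
    """Boolean disk in pixel space; centre and radius in μm."""
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
    return ((xx + 0.5) * pixel_size - center_um[0]) ** 2 + \
           ((yy + 0.5) * pixel_size - center_um[1]) ** 2 <= radius_um ** 2


def _roi_mean(image: np.ndarray, roi) -> float:
    """Mean over a half-open pixel rectangle (y0, x0, y1, x1)."""
    y0, x0, y1, x1 = roi
    if y0 < 0 or x0 < 0 or y1 > image.shape[0] or x1 > image.shape[1] or y1 <= y0 or x1 <= x0:
        raise ValueError(f"ROI {roi} outside image {image.shape}")
    return float(image[y0:y1, x0:x1].mean())


def measure_nc_ratio(image: np.ndarray, nucleus_center_um, *, pixel_size: float,
                     nucleus_diameter: float = 4.5, annulus_expand: float = 1.0,
                     neighbor_masks=None, background_rois=None,
                     background_value: float | None = None,
                     autofluorescence: np.ndarray | None = None,
                     min_annulus_pixels: int = 10) -> NCMeasurement:
    """Nuclear over cytoplasmic mean fluorescence, background subtracted.

    The nuclear ROI is a circle of ``nucleus_diameter`` (default 4.5 μm)
    centred on the nucleus; the cytoplasmic ROI is the donut obtained by
    enlarging the radius by ``annulus_expand`` (default 1 μm) and excluding
    the nuclear disk and any neighbour-nucleus masks.  Background is the
    mean per-pixel FI over rectangular ROIs placed outside the animal (or a
    precomputed scalar).  An optional matched autofluorescence image is
    subtracted first (second background pass).
    """
    image = np.asarray(image, float)
    if autofluorescence is not None:
        image = image - np.asarray(autofluorescence, float)
    r = nucleus_diameter / 2.0
    cx, cy = nucleus_center_um
    h, w = image.shape
    if (cx - r - annulus_expand < 0 or cy - r - annulus_expand < 0
            or cx + r + annulus_expand > w * pixel_size
            or cy + r + annulus_expand > h * pixel_size):
        raise ValueError("nuclear/cytoplasmic ROI outside image")
    nuc = disk_mask(image.shape, (cx, cy), r, pixel_size)
    donut = disk_mask(image.shape, (cx, cy), r + annulus_expand, pixel_size) & ~nuc
    if neighbor_masks is not None:
        for m in neighbor_masks:
            donut &= ~np.asarray(m, bool)
    if donut.sum() < min_annulus_pixels:
        raise ValueError(
            f"cytoplasmic annulus has {int(donut.sum())} pixels after neighbor "
            f"exclusion; need >= {min_annulus_pixels}")

    if background_value is not None:
        bg = float(background_value)
    elif background_rois:
        bg = float(np.mean([_roi_mean(image, roi) for roi in background_rois]))
    else:
        raise ValueError("provide background_rois or background_value")

    nuclear = float(image[nuc].mean())
    cyto = float(image[donut].mean())
    flags: set[str] = set()
    denom = cyto - bg
    if denom <= 0:
        flags.add("cytoplasm_at_or_below_background")
        ratio = float("nan")
    else:
        ratio = (nuclear - bg) / denom
    return NCMeasurement(nuclear_fi=nuclear, cytoplasmic_fi=cyto,
                         background_fi=bg, nc_ratio=ratio, flags=frozenset(flags))


def premitotic_nc(t_min, ratios, t_nebd: float, lead_min: float = 10.0,
                  top_k: int = 3):
    """Pre-mitotic N:C ratio: mean of the highest 3 values measured at least
    ``lead_min`` minutes prior to NEBD.

    Returns ``(value, flags)``; with 1–2 eligible frames the mean of what is
    available is returned with a flag, with none a ``ValueError`` is raised.
    """
    t = np.asarray(t_min, float)
    r = np.asarray(ratios, float)
    eligible = r[t <= t_nebd - lead_min]
    eligible = eligible[np.isfinite(eligible)]
    if eligible.size == 0:
        raise ValueError(f"no N:C values at least {lead_min} min before NEBD")
    flags: set[str] = set()
    if eligible.size < top_k:
        flags.add("fewer_than_3_premitotic_frames")
    top = np.sort(eligible)[-top_k:]
    return float(top.mean()), frozenset(flags)


@dataclass(frozen=True)
class PZDetectConfig:
    """Detection/linking parameters for PZ nucleus counting (μm unless noted).

    Defaults follow the germline nucleus-counting recipe: median 3D filter
    with XY radius 2 μm and Z radius 1 μm, Gaussian blur sigma 2 (pixels, the
    convention of the GUI the recipe comes from), DoG blob size 4.25 μm, link
    and gap-closing distance 3.0 μm with a 2-frame gap allowance, and tracks
    kept when they persist at least 5 frames.
    """

    blob_diameter: float = 4.25
    median_radius_xy: float = 2.0
    median_radius_z: float = 1.0
    gaussian_sigma_px: float = 2.0
    background_subtraction: str = "median"  # "median" | "none"
    threshold_rel: float = 0.3
    noise_floor_sigmas: float = 6.0
    link_distance: float = 3.0
    max_gap_frames: int = 2
    min_track_frames: int = 5


@dataclass
class PZCount:
    """Nucleus count, mitotic-cell count and their ratio for one PZ."""

    n_pz_nuclei: int
    n_mitotic: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_mitotic:
            raise ValueError("n_mitotic must be >= 0")
        if self.n_pz_nuclei and self.n_mitotic > self.n_pz_nuclei:
            raise ValueError("n_mitotic cannot exceed n_pz_nuclei")

    @property
    def mitotic_index(self) -> float:
        return mitotic_index(self.n_mitotic, self.n_pz_nuclei)


def _preprocess_volume(vol: np.ndarray, cfg: PZDetectConfig,
                       pixel_size_xy: float, z_step: float) -> np.ndarray:
    if cfg.background_subtraction == "median":
        vol = vol - np.median(vol)
    rxy = max(int(round(cfg.median_radius_xy / pixel_size_xy)), 1)
    rz = max(int(round(cfg.median_radius_z / z_step)), 1)
    vol = ndi.median_filter(vol, size=(2 * rz + 1, 2 * rxy + 1, 2 * rxy + 1))
    return ndi.gaussian_filter(vol, sigma=cfg.gaussian_sigma_px)


def _raw_noise_sigma(vol: np.ndarray) -> float:
    """Robust pixel-noise sd from adjacent-voxel differences.

    Blobs are smooth at the sampling scale, so first differences along the
    finest axis are noise dominated even in dense fields.
    """
    d = np.diff(vol, axis=-1).ravel()
    return float(np.median(np.abs(d - np.median(d))) * 1.4826 / np.sqrt(2.0))


def _dog_kernel_norm(cfg: PZDetectConfig, s1) -> float:
    """L2 norm of the composite blur+DoG kernel (noise gain of the linear
    part of the pipeline; the median filter only attenuates further)."""
    half = [int(np.ceil(4 * (1.6 * s + cfg.gaussian_sigma_px))) for s in s1]
    imp = np.zeros([2 * h + 1 for h in half])
    imp[tuple(half)] = 1.0
    g = ndi.gaussian_filter(imp, cfg.gaussian_sigma_px)
    k = ndi.gaussian_filter(g, s1) - ndi.gaussian_filter(g, tuple(1.6 * s for s in s1))
    return float(np.sqrt(np.sum(k ** 2)))


def _detect_blobs(vol: np.ndarray, cfg: PZDetectConfig,
                  pixel_size_xy: float, z_step: float,
                  raw_sigma: float = 0.0) -> np.ndarray:
    """DoG detection parameterised by the expected blob diameter.

    Returns detections as (n, 3) μm coordinates (x, y, z).
    """
    # target scale for a blob of the stated diameter, minus the smoothing the
    # preprocessing blur already applied (per axis, floored at half a pixel)
    sigma_um = cfg.blob_diameter / 2.0 / np.sqrt(3.0)
    s1 = tuple(
        max(np.sqrt(max((sigma_um / step) ** 2 - cfg.gaussian_sigma_px ** 2, 0.0)), 0.5)
        for step in (z_step, pixel_size_xy, pixel_size_xy))
    dog = ndi.gaussian_filter(vol, s1) - ndi.gaussian_filter(vol, tuple(1.6 * s for s in s1))
    if dog.max() <= 0:
        return np.empty((0, 3))
    # threshold relative to the response maximum (invariant to intensity
    # rescaling), floored at what pure pixel noise could produce so an
    # object-free noise field yields nothing
    thr = cfg.threshold_rel * dog.max()
    if raw_sigma > 0:
        thr = max(thr, cfg.noise_floor_sigmas * raw_sigma * _dog_kernel_norm(cfg, s1))
    peaks = peak_local_max(dog, min_distance=2, exclude_border=False,
                           threshold_abs=thr)
    if peaks.size == 0:
        return np.empty((0, 3))
    um = np.column_stack([
        (peaks[:, 2] + 0.5) * pixel_size_xy,
        (peaks[:, 1] + 0.5) * pixel_size_xy,
        (peaks[:, 0] + 0.5) * z_step,
    ])
    # prune peaks closer than half a blob diameter, brightest first
    resp = dog[tuple(peaks.T)]
    order = np.argsort(resp)[::-1]
    kept: list[int] = []
    for i in order:
        if all(np.linalg.norm(um[i] - um[j]) >= cfg.blob_diameter / 2.0 for j in kept):
            kept.append(i)
    return um[kept]


def _link_tracks(detections_per_frame, cfg: PZDetectConfig):
    """Greedy nearest-neighbour linking with gap closing.

    Stands in for a linear-assignment linker: at PZ densities (spacing well
    above the 3 μm gate) the two give identical links.
    """
    tracks: list[dict] = []  # {"pos": last xyz, "frames": [..], "points": [..]}
    for f, dets in enumerate(detections_per_frame):
        active = [tr for tr in tracks if f - tr["frames"][-1] <= cfg.max_gap_frames + 1]
        pairs = []
        for ti, tr in enumerate(active):
            for di, d in enumerate(dets):
                dist = np.linalg.norm(tr["pos"] - d)
                if dist <= cfg.link_distance:
                    pairs.append((dist, ti, di))
        pairs.sort(key=lambda p: p[0])
        used_t, used_d = set(), set()
        for dist, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            tr = active[ti]
            tr["pos"] = dets[di]
            tr["frames"].append(f)
            tr["points"].append(dets[di])
        for di, d in enumerate(dets):
            if di not in used_d:
                tracks.append({"pos": d, "frames": [f], "points": [d]})
    return tracks


def count_pz_nuclei(stack: np.ndarray, *, pixel_size_xy: float, z_step: float,
                    pz_roi=None, cfg: PZDetectConfig | None = None):
    """Count proliferative-zone nuclei in a (T, Z, Y, X) stack.

    Each frame is background-subtracted, median-3D filtered and Gaussian
    blurred, nuclei are detected with a Difference-of-Gaussians blob
    detector at the expected diameter, detections are linked frame to frame
    (3 μm gate, ≤2-frame gaps) and tracks persisting at least 5 frames whose
    mean position falls inside ``pz_roi`` (μm rectangle ``(x0, y0, x1, y1)``,
    ``None`` = everywhere) are counted.

    Returns ``(count, centers_um)``: the count and the mean (x, y, z) of each
    counted track.
    """
    cfg = cfg or PZDetectConfig()
    stack = np.asarray(stack, float)
    if stack.ndim != 4:
        raise ValueError("stack must be (T, Z, Y, X)")
    if pixel_size_xy <= 0 or z_step <= 0:
        raise ValueError("pixel sizes must be positive")
    if stack.shape[0] < cfg.min_track_frames:
        raise ValueError(
            f"stack has {stack.shape[0]} frames; need >= {cfg.min_track_frames}")
    dets = []
    for f in range(stack.shape[0]):
        raw_sigma = _raw_noise_sigma(stack[f])
        vol = _preprocess_volume(stack[f], cfg, pixel_size_xy, z_step)
        dets.append(_detect_blobs(vol, cfg, pixel_size_xy, z_step, raw_sigma))
    tracks = _link_tracks(dets, cfg)
    centers = []
    for tr in tracks:
        if len(tr["frames"]) < cfg.min_track_frames:
            continue
        c = np.mean(tr["points"], axis=0)
        if pz_roi is not None:
            x0, y0, x1, y1 = pz_roi
            if not (x0 <= c[0] < x1 and y0 <= c[1] < y1):
                continue
        centers.append(c)
    centers = np.array(centers).reshape(-1, 3)
    return len(centers), centers


def mitotic_index(n_mitotic: int, n_pz_nuclei: int) -> float:
    """Number of mitotic cells divided by the number of PZ nuclei."""
    if n_pz_nuclei <= 0:
        raise ValueError("n_pz_nuclei must be > 0")
    if n_mitotic < 0 or n_mitotic > n_pz_nuclei:
        raise ValueError("need 0 <= n_mitotic <= n_pz_nuclei")
    return n_mitotic / n_pz_nuclei


def measure_depletion_fi(image: np.ndarray, three_rois, background_value: float,
                         reference_group_mean: float | None = None) -> float:
    """Germline reporter fluorescence from three rectangular ROIs.

    Mean of the three ROI means minus background; germ lines at or below
    background are set to 0; optionally normalised to a reference-group
    mean.
    """
    image = np.asarray(image, float)
    if len(three_rois) < 1:
        raise ValueError("need at least one ROI")
    fi = float(np.mean([_roi_mean(image, roi) for roi in three_rois])) - background_value
    fi = max(fi, 0.0)
    if reference_group_mean is not None:
        if reference_group_mean <= 0:
            raise ValueError("reference_group_mean must be > 0")
        fi /= reference_group_mean
    return fi


def assay_ratios(category_counts: dict) -> dict:
    """Per-class percentages for count-based assays (e.g. mitotic-error
    classes: no obvious defects / misaligned prometa-metaphase chromosomes /
    lagging-bridging-misaligned anaphase chromosomes)."""
    counts = {k: int(v) for k, v in category_counts.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be >= 0")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total count must be > 0")
    return {k: 100.0 * v / total for k, v in counts.items()}


def embryonic_lethality(n_unhatched: int, n_total: int) -> float:
    """Percent embryonic lethality: unhatched eggs over total eggs laid."""
    if n_total <= 0:
        raise ValueError("total egg count must be > 0")
    if not 0 <= n_unhatched <= n_total:
        raise ValueError("need 0 <= n_unhatched <= n_total")
    return 100.0 * n_unhatched / n_total


def error_rate_exact_test(errors_a: int, total_a: int,
                          errors_b: int, total_b: int) -> float:
    """Two-sided Fisher exact p for error/no-error counts in two conditions."""
    for e, t in ((errors_a, total_a), (errors_b, total_b)):
        if not 0 <= e <= t:
            raise ValueError("need 0 <= errors <= total")
    table = [[errors_a, total_a - errors_a], [errors_b, total_b - errors_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
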