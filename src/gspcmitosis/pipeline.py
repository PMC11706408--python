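"""End-to-end, config-driven screen analysis.

One call runs the whole chain in the screen's order: spot tables (or a
synthetic cohort) → pole pairing → spindle-length series → landmark scoring
→ features A–I → per-genotype outlier removal → control-referenced heatmap
with rank-based significance → duration correlations → PCA → delayed-cell
labels → CSV outputs plus a machine-readable JSON summary.  Runs are fully
reproducible from config + seeds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cohort as cohort_stats
from . import synthetic, track_io
from .features import FEATURE_COLUMNS, extract_features, features_table
from .timing import LandmarkConfig, LandmarkError, score_landmarks_from_length

__all__ = ["RunConfig", "run_screen_analysis", "write_report"]


@dataclass
class RunConfig:
    """Configuration of one screen-analysis run.

    Exactly one input mode: ``spots_files`` (list of ``{path, group,
    gonad_id}`` entries in the spot-table dialect) or ``synthetic_groups``
    (per-group simulation specs).  ``control_group`` must name one of the
    groups.
    """

    control_group: str
    frame_interval: float = 0.5
    seed: int = 0
    output_dir: str = "results/run"
    spots_files: list = field(default_factory=list)
    synthetic_groups: dict = field(default_factory=dict)
    landmark: LandmarkConfig = field(default_factory=LandmarkConfig)
    pca_after_outlier_removal: bool = True
    statistical_unit: str = "cell"  # "cell" | "gonad"

    def __post_init__(self) -> None:
        if bool(self.spots_files) == bool(self.synthetic_groups):
            raise ValueError("exactly one input mode: spots_files or synthetic_groups")
        if self.synthetic_groups and self.control_group not in self.synthetic_groups:
            raise ValueError(
                f"control group {self.control_group!r} not among synthetic groups "
                f"{sorted(self.synthetic_groups)}")
        if self.statistical_unit not in ("cell", "gonad"):
            raise ValueError("statistical_unit must be 'cell' or 'gonad'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "landmark" in raw:
            raw["landmark"] = LandmarkConfig(**raw["landmark"])
        if "synthetic_groups" in raw:
            raw["synthetic_groups"] = {
                g: synthetic.GroupSpec(**spec) if isinstance(spec, dict) else spec
                for g, spec in raw["synthetic_groups"].items()}
        return cls(**raw)


def _load_tracks(config: RunConfig):
    if config.synthetic_groups:
        return synthetic.simulate_cohort(config.synthetic_groups, seed=config.seed)
    tracks = []
    for entry in config.spots_files:
        spots = track_io.read_spots_table(entry["path"])
        file_tracks, errors = track_io.pair_poles(spots, frame_interval=config.frame_interval)
        for tr in file_tracks:
            tr.group = entry.get("group", "")
            tr.gonad_id = entry.get("gonad_id", "")
        tracks.extend(file_tracks)
    return tracks, None


def run_screen_analysis(config: RunConfig) -> dict:
    """Run the full screen analysis and write every stage's outputs.

    Returns the result bundle: landmarks and feature tables, outlier log,
    heatmap matrix + significance, comparisons, correlations, PCA, delayed
    labels, per-cell errors and the JSON summary (also written to disk).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tracks, truth = _load_tracks(config)

    landmark_rows, feat_vectors, cell_errors = [], [], {}
    for tr in tracks:
        try:
            series = track_io.spindle_length_series(tr)
            lm = score_landmarks_from_length(series, config.landmark)
            _, axes = track_io.spindle_axes(tr)
            fv = extract_features(series, axes, lm, seed=config.seed)
        except (LandmarkError, ValueError) as exc:
            cell_errors[tr.cell_id] = str(exc)
            continue
        landmark_rows.append({
            "cell_id": tr.cell_id, "group": tr.group, "gonad_id": tr.gonad_id,
            "t_nebd": lm.t_nebd, "t_s": lm.t_s, "t_ao": lm.t_ao,
            "duration_min": lm.duration, "flags": ";".join(sorted(lm.quality_flags)),
        })
        feat_vectors.append(fv)

    landmarks_df = pd.DataFrame(landmark_rows)
    features_df = features_table(feat_vectors)
    usable_groups = set(features_df["group"]) if len(features_df) else set()
    expected = set(config.synthetic_groups) if config.synthetic_groups else \
        {e.get("group", "") for e in config.spots_files}
    missing = expected - usable_groups
    if missing:
        raise RuntimeError(f"whole group(s) unusable: {sorted(missing)}; "
                           f"per-cell errors: {cell_errors}")

    # statistics, in the screen's order
    clean, outlier_log = cohort_stats.remove_outliers_per_group(features_df)
    comparisons = cohort_stats.compare_groups_to_control(clean, config.control_group)
    heatmap, significance = cohort_stats.build_heatmap_matrix(
        clean, config.control_group, comparisons=comparisons)
    corr = cohort_stats.correlate_features_with_duration(clean)
    pca_input = clean if config.pca_after_outlier_removal else features_df
    std, _ = cohort_stats.standardize(pca_input, reference="pooled")
    scores, loadings, explained, pca_dropped = cohort_stats.run_pca(std)
    control_dur = features_df.loc[features_df["group"] == config.control_group, "B"]
    delayed = pd.DataFrame({
        "cell_id": features_df["cell_id"], "group": features_df["group"],
        "duration_min": features_df["B"],
        "delayed": cohort_stats.classify_delayed(features_df["B"], control_dur),
    })

    per_gonad = features_df.groupby(["group", "gonad_id"], sort=True)["B"] \
        .mean().rename("mean_duration_min").reset_index()

    summary = {
        "package_version": __version__,
        "config": _config_dict(config),
        "n_cells": int(len(features_df)),
        "n_rejected": len(cell_errors),
        "groups": {
            g: {
                "n": int((features_df["group"] == g).sum()),
                "mean_duration_min": float(features_df.loc[features_df["group"] == g, "B"].mean()),
                "median_duration_min": float(features_df.loc[features_df["group"] == g, "B"].median()),
                "n_delayed": int(delayed.loc[delayed["group"] == g, "delayed"].sum()),
            } for g in sorted(usable_groups)
        },
        "pca_explained_pct": [float(x) for x in explained],
        "significant_contrasts": [
            {"feature": r["feature"], "group": r["group"], "p_adj": float(r["p_adj"])}
            for _, r in comparisons.iterrows() if r["significant"]
        ],
    }

    bundle = {
        "tracks": tracks, "truth": truth, "landmarks": landmarks_df,
        "features": features_df, "features_clean": clean,
        "outlier_log": outlier_log, "comparisons": comparisons,
        "heatmap": heatmap, "significance": significance,
        "correlations": corr, "pca_scores": scores, "pca_loadings": loadings,
        "pca_explained": explained, "pca_dropped": pca_dropped,
        "delayed": delayed, "per_gonad": per_gonad,
        "cell_errors": cell_errors, "summary": summary, "output_dir": str(outdir),
    }
    _write_bundle(bundle, outdir)
    return bundle


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["synthetic_groups"] = {
        g: dataclasses.asdict(s) if dataclasses.is_dataclass(s) else s
        for g, s in config.synthetic_groups.items()}
    return d


def _write_bundle(bundle: dict, outdir: Path) -> None:
    bundle["landmarks"].to_csv(outdir / "landmarks.csv", index=False)
    bundle["features"].to_csv(outdir / "features.csv", index=False)
    bundle["features_clean"].to_csv(outdir / "features_outlier_removed.csv", index=False)
    bundle["outlier_log"].to_csv(outdir / "outlier_log.csv", index=False)
    bundle["comparisons"].to_csv(outdir / "group_comparisons.csv", index=False)
    bundle["heatmap"].to_csv(outdir / "heatmap_matrix.csv")
    bundle["significance"].to_csv(outdir / "heatmap_significance.csv")
    bundle["correlations"].to_csv(outdir / "duration_correlations.csv", index=False)
    bundle["pca_scores"].to_csv(outdir / "pca_scores.csv", index=False)
    bundle["pca_loadings"].to_csv(outdir / "pca_loadings.csv")
    bundle["delayed"].to_csv(outdir / "delayed_cells.csv", index=False)
    bundle["per_gonad"].to_csv(outdir / "per_gonad_duration.csv", index=False)
    if bundle["truth"] is not None:
        bundle["truth"].to_csv(outdir / "ground_truth.csv", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(bundle["summary"], fh, indent=2, sort_keys=True)


def _boxplot_stats(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    inliers = values[(values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)]
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "whisker_low": float(inliers.min()), "whisker_high": float(inliers.max())}


def write_report(bundle: dict, path=None, plots: bool = False) -> str:
    """Human-readable run report; numbers are taken verbatim from the bundle.

    Per-group duration summaries follow boxplot convention (median, IQR,
    most extreme non-outlier values) with per-gonad-arm means alongside the
    per-cell values, mirroring how the screen reports durations.
    """
    lines = [f"GSPC mitosis screen report (gspcmitosis {__version__})", ""]
    feats = bundle["features"]
    lines.append("Per-group duration of mitosis (min):")
    for g in sorted(feats["group"].unique()):
        vals = feats.loc[feats["group"] == g, "B"].to_numpy(float)
        bs = _boxplot_stats(vals)
        gmeans = bundle["per_gonad"].query("group == @g")["mean_duration_min"]
        lines.append(
            f"  {g}: n={vals.size}  median={bs['median']:.2f}  "
            f"IQR=[{bs['q1']:.2f}, {bs['q3']:.2f}]  "
            f"whiskers=[{bs['whisker_low']:.2f}, {bs['whisker_high']:.2f}]  "
            f"gonad means={', '.join(f'{m:.2f}' for m in gmeans)}")
    lines.append("")
    lines.append("Control-referenced heatmap (control-SD units; * = post hoc p < 0.05):")
    heat, sig = bundle["heatmap"], bundle["significance"]
    lines.append("  feature  " + "  ".join(f"{g:>12s}" for g in heat.columns))
    for f in heat.index:
        cells = []
        for g in heat.columns:
            star = "*" if sig.at[f, g] else " "
            cells.append(f"{heat.at[f, g]:>11.2f}{star}")
        lines.append(f"  {f:>7s}  " + "  ".join(cells))
    lines.append("")
    expl = bundle["pca_explained"]
    lines.append(f"PCA: PC1 {expl[0]:.1f}%, PC2 {expl[1]:.1f}% "
                 f"(PC1+PC2 {expl[0] + expl[1]:.1f}% of total variance)")
    corr_sig = bundle["correlations"].query("reported != 0")
    if len(corr_sig):
        lines.append("Features correlated with duration (Bonferroni p < 0.05):")
        for _, r in corr_sig.iterrows():
            lines.append(f"  {r['feature']}: r={r['r']:.2f} (p_adj={r['p_adj']:.2g})")
    else:
        lines.append("No feature correlates with duration after Bonferroni correction.")
    n_delayed = int(bundle["delayed"]["delayed"].sum())
    lines.append(f"Delayed cells (duration > control P90): {n_delayed} of "
                 f"{len(bundle['delayed'])}")
    if bundle["cell_errors"]:
        lines.append("")
        lines.append(f"Cells rejected by landmark scoring: {len(bundle['cell_errors'])}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    if plots:
        _write_plots(bundle)
    return text


def _write_plots(bundle: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(bundle["output_dir"])
    feats = bundle["features"]
    groups = sorted(feats["group"].unique())
    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 2, 4))
    data = [feats.loc[feats["group"] == g, "B"].dropna().to_numpy() for g in groups]
    ax.boxplot(data, tick_labels=groups)
    for i, g in enumerate(groups, start=1):
        gm = bundle["per_gonad"].query("group == @g")["mean_duration_min"]
        ax.plot(np.full(len(gm), i), gm, "o", ms=7, alpha=0.6)
    ax.set_ylabel("duration of mitosis (min)")
    fig.tight_layout()
    fig.savefig(outdir / "duration_boxplot.png", dpi=120)
    plt.close(fig)

    heat = bundle["heatmap"]
    fig, ax = plt.subplots(figsize=(1.0 * len(heat.columns) + 2, 5))
    im = ax.imshow(heat.to_numpy(float), cmap="RdBu_r", vmin=-3, vmax=3, aspect="auto")
    ax.set_xticks(range(len(heat.columns)), heat.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(heat.index)), heat.index)
    fig.colorbar(im, label="SDs from control mean")
    fig.tight_layout()
    fig.savefig(outdir / "feature_heatmap.png", dpi=120)
    plt.close(fig)

    scores = bundle["pca_scores"]
    fig, ax = plt.subplots(figsize=(5, 5))
    for g in groups:
        sub = scores[scores["group"] == g]
        ax.plot(sub["PC1"], sub["PC2"], "o", ms=4, label=g, alpha=0.7)
    load = bundle["pca_loadings"]
    scale = 0.8 * np.abs(scores[["PC1", "PC2"]].to_numpy()).max()
    for f in load.index:
        ax.annotate(f, (load.at[f, "PC1"] * scale, load.at[f, "PC2"] * scale))
        ax.plot([0, load.at[f, "PC1"] * scale], [0, load.at[f, "PC2"] * scale], "k-", lw=0.5)
    expl = bundle["pca_explained"]
    ax.set_xlabel(f"PC1 ({expl[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({expl[1]:.1f}%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / "pca_biplot.png", dpi=120)
    plt.close(fig)
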