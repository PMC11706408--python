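#!/usr/bin/env python
"""Cohort statistics over the feature table.

Applies the screen's statistical chain to the cells × features table from
03: per-genotype Tukey-fence outlier removal (duration exempt), rank-based
group comparisons with a Tukey-Kramer post hoc, the control-referenced
heatmap, Bonferroni-corrected duration correlations, PCA and delayed-cell
classification.
"""

from pathlib import Path

from gspcmitosis.cohort import (
    build_heatmap_matrix,
    classify_delayed,
    compare_groups_to_control,
    correlate_features_with_duration,
    load_cohort,
    remove_outliers_per_group,
    run_pca,
    standardize,
)

COHORT = Path(__file__).resolve().parents[1] / "results" / "cohort"
CONTROL = "control"


def main() -> None:
    table = load_cohort(COHORT / "features.csv")
    clean, log = remove_outliers_per_group(table)
    log.to_csv(COHORT / "outlier_log.csv", index=False)
    print(f"outlier removal: {int((log['action'] == 'removed').sum())} values "
          f"removed across {table.shape[0]} cells")

    comp = compare_groups_to_control(clean, CONTROL)
    comp.to_csv(COHORT / "group_comparisons.csv", index=False)
    sig = comp[comp["significant"]]
    print(f"significant control-vs-genotype contrasts (post hoc p < 0.05):")
    for _, r in sig.iterrows():
        print(f"  {r['feature']} in {r['group']}: effect {r['effect']:+.2f} "
              f"control SDs, p_adj={r['p_adj']:.2g}")

    heat, sigmask = build_heatmap_matrix(clean, CONTROL, comparisons=comp)
    heat.to_csv(COHORT / "heatmap_matrix.csv")
    corr = correlate_features_with_duration(clean)
    corr.to_csv(COHORT / "duration_correlations.csv", index=False)
    reported = corr[corr["reported"] != 0]
    print("features correlated with duration after Bonferroni:"
          + (" none" if reported.empty else ""))
    for _, r in reported.iterrows():
        print(f"  {r['feature']}: r={r['r']:.2f}")

    std, _ = standardize(clean, reference="pooled")
    scores, loadings, explained, dropped = run_pca(std)
    scores.to_csv(COHORT / "pca_scores.csv", index=False)
    loadings.to_csv(COHORT / "pca_loadings.csv")
    print(f"PCA ({len(dropped)} incomplete cells dropped): "
          f"PC1 {explained[0]:.1f}%, PC2 {explained[1]:.1f}%, "
          f"PC1+PC2 {explained[0] + explained[1]:.1f}%")

    control_dur = table.loc[table["group"] == CONTROL, "B"]
    table["delayed"] = classify_delayed(table["B"], control_dur)
    table[["cell_id", "group", "B", "delayed"]].to_csv(
        COHORT / "delayed_cells.csv", index=False)
    for g, sub in table.groupby("group"):
        print(f"  {g}: {int(sub['delayed'].sum())}/{len(sub)} delayed "
              f"(duration > control P90)")


if __name__ == "__main__":
    main()
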