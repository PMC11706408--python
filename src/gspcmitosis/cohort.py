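"""Cohort-level statistics over the cells × features matrix.

This is the screen's statistical layer: per-genotype Tukey-fence outlier
removal (duration is never filtered), control-referenced standardisation and
heatmap, rank-based group comparisons (Kruskal-Wallis omnibus with a
Tukey-Kramer post hoc on mean ranks), Bonferroni-corrected Pearson
correlations of each feature with mitotic duration, PCA of the standardised
feature matrix, and classification of "delayed" cells against the control
duration distribution.

Quartiles and percentiles use linear interpolation between order statistics
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_COLUMNS

__all__ = [
    "load_cohort",
    "remove_outliers_per_group",
    "standardize",
    "compare_groups_to_control",
    "build_heatmap_matrix",
    "correlate_features_with_duration",
    "run_pca",
    "classify_delayed",
]

DURATION = "B"


def load_cohort(path, feature_columns=None) -> pd.DataFrame:
    """Load a cells × features table from CSV or XLSX.

    Expects one column per feature letter A–I plus at least a ``group``
    column (``cell_id`` / ``gonad_id`` optional), the layout of the screen's
    per-cell feature export.
    """
    path = str(path)
    df = pd.read_excel(path) if path.endswith((".xlsx", ".xls")) else pd.read_csv(path)
    cols = feature_columns or FEATURE_COLUMNS
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"feature columns missing from {path}: {missing}")
    if "group" not in df.columns:
        raise ValueError("cohort table must carry a 'group' column")
    return df


def _fences(values: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.percentile(values, [25, 75])  # linear interpolation
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def remove_outliers_per_group(table: pd.DataFrame,
                              feature_columns=None,
                              exclude=(DURATION,),
                              min_group_size: int = 4):
    """Tukey-fence outlier removal, assessed per feature per genotype.

    Values more than 1.5×IQR above Q3 or below Q1 of their own group are set
    missing (the cell is kept for its other features).  The duration column
    is never filtered.  Returns ``(table, log)`` where ``log`` records every
    removal and every skipped (feature, group).
    """
    cols = [c for c in (feature_columns or FEATURE_COLUMNS) if c not in exclude]
    out = table.copy()
    log_rows = []
    for g, sub in table.groupby("group", sort=True):
        for f in cols:
            vals = sub[f].dropna()
            if len(vals) < min_group_size:
                log_rows.append({"feature": f, "group": g, "action": "skipped",
                                 "detail": f"n={len(vals)} < {min_group_size}"})
                continue
            lo, hi = _fences(vals.to_numpy())
            bad = sub.index[(sub[f] < lo) | (sub[f] > hi)]
            for idx in bad:
                log_rows.append({
                    "feature": f, "group": g, "action": "removed",
                    "detail": f"value={table.at[idx, f]:.6g} outside [{lo:.6g}, {hi:.6g}]",
                    "cell_id": table.at[idx, "cell_id"] if "cell_id" in table else idx,
                })
                out.at[idx, f] = np.nan
    log = pd.DataFrame(log_rows, columns=["feature", "group", "action", "detail", "cell_id"])
    return out, log


def standardize(table: pd.DataFrame, reference: str = "pooled",
                control_group: str | None = None, feature_columns=None):
    """Replace each feature by (x − μ)/σ.

    ``reference='pooled'`` takes μ, σ over all cells (for correlation and
    PCA); ``reference='control'`` takes them from the control group (for the
    control-relative heatmap scale).  σ uses ddof=1.  Features with zero σ
    are dropped and logged.  Returns ``(table, dropped)``.
    """
    cols = feature_columns or [c for c in FEATURE_COLUMNS if c in table.columns]
    if reference not in ("pooled", "control"):
        raise ValueError("reference must be 'pooled' or 'control'")
    if reference == "control":
        if control_group is None:
            raise ValueError("control reference requires control_group")
        ref = table[table["group"] == control_group]
        if len(ref) == 0:
            raise ValueError(f"control group {control_group!r} not present")
    else:
        ref = table
    out = table.copy()
    dropped = []
    for f in cols:
        mu = ref[f].mean()
        sd = ref[f].std(ddof=1)
        if not np.isfinite(sd) or _degenerate_sd(sd, mu):
            out = out.drop(columns=[f])
            dropped.append(f)
            continue
        out[f] = (table[f] - mu) / sd
    return out, dropped


def _degenerate_sd(sd: float, mu: float) -> bool:
    """A spread at float-rounding scale is a constant column, not signal."""
    return sd <= 1e-12 * max(1.0, abs(mu))


@dataclass
class GroupComparisonResult:
    """Control-vs-group contrast for one feature."""

    feature: str
    group: str
    effect: float        # (mean_g − mean_control) in control-SD units
    p_omnibus: float
    p_adj: float         # Tukey-Kramer post hoc p for the contrast
    significant: bool
    degenerate: bool = False


def _tukey_kramer_rank_p(values_by_group: list[np.ndarray],
                         i: int, j: int) -> float:
    """Post hoc p for groups i vs j: studentized range on mean ranks.

    Mean ranks are taken over the pooled sample with tie correction; the
    comparison statistic follows the classic rank-based Tukey-Kramer form
    (infinite-df studentized range), the convention of common statistical
    environments' multiple-comparison routines after a Kruskal-Wallis test.
    """
    pooled = np.concatenate(values_by_group)
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / max(n_tot ** 3 - n_tot, 1)
    s2 = n_tot * (n_tot + 1) / 12.0 * tie
    if s2 <= 0:
        return 1.0
    offs = np.cumsum([0] + [v.size for v in values_by_group])
    mean_rank = [ranks[offs[k]: offs[k + 1]].mean() for k in range(len(values_by_group))]
    ni, nj = values_by_group[i].size, values_by_group[j].size
    se = np.sqrt(s2 / 2.0 * (1.0 / ni + 1.0 / nj))
    q = abs(mean_rank[i] - mean_rank[j]) / se
    return float(stats.studentized_range.sf(q, k=len(values_by_group), df=1e6))


def compare_groups_to_control(table: pd.DataFrame, control_group: str,
                              feature_columns=None, alpha: float = 0.05,
                              omnibus: str = "asymptotic",
                              n_permutations: int = 10000,
                              seed: int = 0) -> pd.DataFrame:
    """Rank-based omnibus test per feature plus control-vs-group post hocs.

    ``omnibus='asymptotic'`` uses the chi-square approximation of the
    Kruskal-Wallis H statistic; ``'permutation'`` estimates the null of H by
    label permutation (for small groups).  Only control-vs-group contrasts
    are reported; ``significant`` means post hoc p < alpha.
    """
    cols = feature_columns or [c for c in FEATURE_COLUMNS if c in table.columns]
    groups = sorted(table["group"].unique())
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not present")
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    rng = np.random.default_rng(seed)
    rows = []
    for f in cols:
        by_group = [table.loc[table["group"] == g, f].dropna().to_numpy() for g in groups]
        if min(v.size for v in by_group) < 3:
            raise ValueError(f"feature {f}: every group needs >= 3 cells")
        degenerate = np.unique(np.concatenate(by_group)).size == 1
        if degenerate:
            p_omni = 1.0
        elif omnibus == "permutation":
            p_omni = _kw_permutation_p(by_group, n_permutations, rng)
        else:
            p_omni = float(stats.kruskal(*by_group).pvalue)
        ci = groups.index(control_group)
        ctrl = by_group[ci]
        sd_c = ctrl.std(ddof=1)
        for gi, g in enumerate(groups):
            if g == control_group:
                continue
            p_adj = 1.0 if degenerate else _tukey_kramer_rank_p(by_group, ci, gi)
            effect = (by_group[gi].mean() - ctrl.mean()) / sd_c if sd_c > 0 else np.nan
            rows.append({
                "feature": f, "group": g, "effect": effect,
                "p_omnibus": p_omni, "p_adj": p_adj,
                "significant": bool(p_adj < alpha) and not degenerate,
                "degenerate": degenerate,
            })
    return pd.DataFrame(rows)


def _kw_permutation_p(by_group: list[np.ndarray], n_perm: int,
                      rng: np.random.Generator) -> float:
    pooled = np.concatenate(by_group)
    sizes = [v.size for v in by_group]
    h_obs = stats.kruskal(*by_group).statistic
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        if stats.kruskal(*parts).statistic >= h_obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def build_heatmap_matrix(table: pd.DataFrame, control_group: str,
                         feature_columns=None,
                         comparisons: pd.DataFrame | None = None):
    """Features × groups matrix of control-referenced effect sizes.

    Entry (f, g) = (mean_g(f) − mean_control(f)) / SD_control(f): the number
    of control standard deviations the group mean sits above/below the
    control mean.  Outlier removal is expected upstream.  Returns
    ``(matrix, significance)`` where ``significance`` is a boolean mask from
    ``comparisons`` (control column False).
    """
    cols = feature_columns or [c for c in FEATURE_COLUMNS if c in table.columns]
    groups = sorted(table["group"].unique())
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not present")
    ctrl = table[table["group"] == control_group]
    mat = pd.DataFrame(index=cols, columns=groups, dtype=float)
    for f in cols:
        mu_c = ctrl[f].mean()
        sd_c = ctrl[f].std(ddof=1)
        for g in groups:
            vals = table.loc[table["group"] == g, f].dropna()
            if len(vals) == 0 or not np.isfinite(sd_c) or sd_c <= 0:
                mat.at[f, g] = np.nan
            else:
                mat.at[f, g] = (vals.mean() - mu_c) / sd_c
    sig = pd.DataFrame(False, index=cols, columns=groups)
    if comparisons is not None:
        for _, r in comparisons.iterrows():
            if r["feature"] in sig.index and r["group"] in sig.columns:
                sig.at[r["feature"], r["group"]] = bool(r["significant"])
    return mat, sig


def correlate_features_with_duration(table: pd.DataFrame,
                                     feature_columns=None,
                                     duration_column: str = DURATION,
                                     alpha: float = 0.05,
                                     m: int | None = None) -> pd.DataFrame:
    """Pearson correlation of each feature with mitotic duration, pooled
    across genotypes, Bonferroni-corrected.

    p-values are multiplied by the number of features tested (8 when all of
    A, C–I are present).  The reported coefficient is r when the corrected p
    is < alpha and 0 otherwise (non-significant correlations shown as 0).
    """
    cols = [c for c in (feature_columns or [c for c in FEATURE_COLUMNS if c in table.columns])
            if c != duration_column]
    m = m if m is not None else len(cols)
    rows = []
    dur = table[duration_column]
    for f in cols:
        ok = table[f].notna() & dur.notna()
        x, y = table.loc[ok, f].to_numpy(), dur[ok].to_numpy()
        if len(x) < 3 or _degenerate_sd(np.std(x), x.mean()) \
                or _degenerate_sd(np.std(y), y.mean()):
            rows.append({"feature": f, "r": np.nan, "p": np.nan, "p_adj": np.nan,
                         "reported": 0.0, "flag": "undefined"})
            continue
        r, p = stats.pearsonr(x, y)
        p_adj = min(1.0, p * m)
        rows.append({"feature": f, "r": r, "p": p, "p_adj": p_adj,
                     "reported": float(r) if p_adj < alpha else 0.0, "flag": ""})
    return pd.DataFrame(rows)


def run_pca(table: pd.DataFrame, feature_columns=None):
    """PCA of the standardised feature matrix (complete cases only).

    Eigen-decomposition of the covariance of the (already standardised)
    features; each loading vector's sign is fixed so its largest-magnitude
    element is positive.  Returns ``(scores, loadings, explained_pct,
    dropped_rows)`` with explained-variance percentages summing to 100.
    """
    cols = feature_columns or [c for c in FEATURE_COLUMNS if c in table.columns]
    complete = table[cols].notna().all(axis=1)
    dropped = table.index[~complete].tolist()
    X = table.loc[complete, cols].to_numpy(float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError(f"need more cells ({X.shape[0]}) than features ({X.shape[1]})")
    Xc = X - X.mean(axis=0)
    cov = np.cov(Xc, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    for k in range(evecs.shape[1]):  # deterministic sign convention
        if evecs[np.argmax(np.abs(evecs[:, k])), k] < 0:
            evecs[:, k] = -evecs[:, k]
    scores = Xc @ evecs
    explained = evals / evals.sum() * 100.0
    pc_names = [f"PC{i + 1}" for i in range(len(cols))]
    scores_df = pd.DataFrame(scores, columns=pc_names, index=table.index[complete])
    for meta in ("cell_id", "group", "gonad_id"):
        if meta in table.columns:
            scores_df[meta] = table.loc[complete, meta]
    loadings_df = pd.DataFrame(evecs, index=cols, columns=pc_names)
    return scores_df, loadings_df, explained, dropped


def classify_delayed(durations, control_durations) -> np.ndarray:
    """Delayed iff duration > 90th percentile of the control durations.

    The percentile uses linear interpolation between order statistics.
    Requires >= 10 control values.
    """
    control = np.asarray(control_durations, float)
    if control.size == 0:
        raise ValueError("empty control duration set")
    if control.size < 10:
        raise ValueError(f"need >= 10 control durations, got {control.size}")
    p90 = np.percentile(control, 90)
    return np.asarray(durations, float) > p90
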