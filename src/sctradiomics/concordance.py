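"""Lin's concordance correlation coefficient and the cohort-level analyses.

For each radiomic feature, agreement between its values on the real CTs and
on one model's synthetic CTs across subjects is measured with Lin's CCC,

    CCC = 2 cov(x, y) / (var(x) + var(y) + (mean x - mean y)^2),

with population (1/n) moment estimators — the classic concordance
definition, which penalizes both decorrelation and location/scale shift
(a bias-corrected small-sample variant is available but off by default).
Each feature is then classified into four similarity levels at the
conventional cut-points 0.9 / 0.75 / 0.5 (boundaries inclusive upward).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AlignmentError,
    DegenerateTestError,
    InsufficientPointsError,
    LookupError_,
)
from .radiomics import feature_category

LEVELS = ("excellent", "good", "moderate", "poor")


@dataclass
class LevelThresholds:
    """Cut-points for the four similarity levels (inclusive lower bounds)."""

    excellent_min: float = 0.9
    good_min: float = 0.75
    moderate_min: float = 0.5

    def __post_init__(self):
        if not (self.excellent_min > self.good_min > self.moderate_min):
            raise ValueError("thresholds must be strictly decreasing")


@dataclass
class CccRecord:
    roi_name: str
    model_name: str
    feature_name: str
    category: str
    ccc: float
    level: str
    degenerate: bool = False


def lin_ccc(x, y, bias_corrected: bool = False) -> float:
    """Lin's concordance correlation coefficient of two equal-length samples.

    Both-constant inputs: equal constants -> 1.0 (perfect agreement),
    unequal constants -> 0.0 sentinel.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    vx, vy = x.var(), y.var()
    if vx == 0 and vy == 0:
        return 1.0 if np.allclose(x.mean(), y.mean()) else 0.0
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    if bias_corrected:
        corr = n / (n - 1)
        vx, vy, cov = vx * corr, vy * corr, cov * corr
    return float(2.0 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


def classify_level(ccc: float, thresholds: LevelThresholds | None = None) -> str:
    """Map a CCC to excellent/good/moderate/poor; boundaries go upward."""
    t = thresholds or LevelThresholds()
    if not np.isfinite(ccc):
        raise ValueError("ccc must be finite")
    if ccc >= t.excellent_min:
        return "excellent"
    if ccc >= t.good_min:
        return "good"
    if ccc >= t.moderate_min:
        return "moderate"
    return "poor"


def ccc_table(
    feature_frame: pd.DataFrame,
    thresholds: LevelThresholds | None = None,
    bias_corrected: bool = False,
) -> list[CccRecord]:
    """Per-(ROI x model x feature) concordance records.

    ``feature_frame``: rows indexed by (subject_id, roi, image) where image
    is "real" or a model name; columns are feature names.  For each feature,
    x = the real-image values across subjects, y = the model's values,
    aligned by subject.
    """
    thresholds = thresholds or LevelThresholds()
    req = {"subject_id", "roi", "image"}
    if not req.issubset(feature_frame.columns):
        raise AlignmentError(f"feature frame must carry columns {sorted(req)}")
    feature_names = [c for c in feature_frame.columns if c not in req]
    images = sorted(set(feature_frame["image"]))
    if "real" not in images:
        raise AlignmentError("feature frame has no 'real' image rows")
    models = [m for m in images if m != "real"]
    records: list[CccRecord] = []
    for roi, roi_df in feature_frame.groupby("roi", sort=False):
        pivot = {
            img: sub.set_index("subject_id").sort_index()
            for img, sub in roi_df.groupby("image", sort=False)
        }
        real = pivot["real"]
        if len(real) < 2:
            raise AlignmentError(f"ROI {roi}: need >= 2 subjects for CCC")
        for model in models:
            syn = pivot.get(model)
            if syn is None or list(syn.index) != list(real.index):
                raise AlignmentError(
                    f"ROI {roi}, model {model}: subject sets differ from real"
                )
            for feat in feature_names:
                x = real[feat].to_numpy(dtype=np.float64)
                y = syn[feat].to_numpy(dtype=np.float64)
                degenerate = bool(x.var() == 0 and y.var() == 0)
                c = lin_ccc(x, y, bias_corrected)
                records.append(
                    CccRecord(
                        roi_name=roi,
                        model_name=model,
                        feature_name=feat,
                        category=feature_category(feat),
                        ccc=c,
                        level=classify_level(c, thresholds),
                        degenerate=degenerate,
                    )
                )
    return records


def records_to_frame(records: list[CccRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "roi": r.roi_name,
                "model": r.model_name,
                "feature": r.feature_name,
                "category": r.category,
                "ccc": r.ccc,
                "level": r.level,
                "degenerate": r.degenerate,
            }
            for r in records
        ]
    )


def summarize_levels(
    records: list[CccRecord] | pd.DataFrame,
    grouping: tuple[str, ...] = ("roi", "model", "category"),
) -> pd.DataFrame:
    """Percent of features per level plus mean +/- SD CCC, per group.

    Percentages within a group sum to 100.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValueError("no records to summarize")
    rows = []
    for keys, sub in df.groupby(list(grouping), sort=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        n = len(sub)
        counts = sub["level"].value_counts()
        row = dict(zip(grouping, keys))
        for lv in LEVELS:
            row[f"pct_{lv}"] = 100.0 * counts.get(lv, 0) / n
        row["n_features"] = n
        row["mean_ccc"] = float(sub["ccc"].mean())
        row["sd_ccc"] = float(sub["ccc"].std(ddof=1)) if n > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def overlap_analysis(
    records_a: list[CccRecord] | pd.DataFrame,
    records_b: list[CccRecord] | pd.DataFrame,
    level: str,
) -> pd.DataFrame:
    """Two-model overlap of the feature sets at a given level, per ROI.

    Reports |A only|, |B only|, |A and B|, Jaccard, and the intersection as
    a fraction of each model's own set (the denominator convention differs
    across reports, so all three normalizations are emitted).
    """
    a = records_a if isinstance(records_a, pd.DataFrame) else records_to_frame(records_a)
    b = records_b if isinstance(records_b, pd.DataFrame) else records_to_frame(records_b)
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    rois = sorted(set(a.get("roi", [])) | set(b.get("roi", [])))
    rows = []
    for roi in rois:
        sa = set(a[(a["roi"] == roi) & (a["level"] == level)]["feature"])
        sb = set(b[(b["roi"] == roi) & (b["level"] == level)]["feature"])
        inter, union = len(sa & sb), len(sa | sb)
        rows.append(
            {
                "roi": roi,
                "level": level,
                "a_only": len(sa - sb),
                "b_only": len(sb - sa),
                "intersection": inter,
                "union": union,
                "jaccard": inter / union if union else 0.0,
                "frac_of_a": inter / len(sa) if sa else 0.0,
                "frac_of_b": inter / len(sb) if sb else 0.0,
                "empty_union": union == 0,
            }
        )
    return pd.DataFrame(rows)


def paired_ttest(a, b) -> tuple[float, float, int]:
    """Two-sided paired t-test; returns (t, p, n).  df = n - 1."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-D samples with n >= 2")
    d = a - b
    if d.var() == 0:
        raise DegenerateTestError("paired differences have zero variance")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), int(a.size)


SIGNIFICANCE_ALPHA = 0.05


def mae_ccc_correlation(
    iqm_summary: pd.DataFrame, level_summary: pd.DataFrame
) -> pd.DataFrame:
    """Correlate cohort-mean MAE with mean CCC across ROIs.

    One correlation per (model x category); each point is an ROI.  Pearson
    and Spearman are both reported (zero-variance inputs yield a flagged 0).
    Requires >= 3 common ROIs.
    """
    mae_tab = iqm_summary[iqm_summary["metric"] == "mae"][["roi", "model", "mean"]]
    mae_tab = mae_tab.rename(columns={"mean": "mae"})
    merged = level_summary.merge(mae_tab, on=["roi", "model"])
    rows = []
    for (model, category), sub in merged.groupby(["model", "category"], sort=False):
        if len(sub) < 3:
            raise InsufficientPointsError(
                f"model {model}, category {category}: {len(sub)} ROI points < 3"
            )
        x = sub["mae"].to_numpy()
        y = sub["mean_ccc"].to_numpy()
        degenerate = x.var() == 0 or y.var() == 0
        if degenerate:
            pear = spear = 0.0
        else:
            pear = float(stats.pearsonr(x, y).statistic)
            spear = float(stats.spearmanr(x, y).statistic)
        rows.append(
            {
                "model": model,
                "category": category,
                "n_points": len(sub),
                "pearson": pear,
                "spearman": spear,
                "degenerate": degenerate,
                "points": list(zip(sub["roi"], x.tolist(), y.tolist())),
            }
        )
    return pd.DataFrame(rows)


def subset_report(
    records: list[CccRecord] | pd.DataFrame, feature_names: list[str]
) -> pd.DataFrame:
    """Level counts/fractions per model for a curated feature subset.

    Intended for externally curated lists (e.g. features reported as
    prognostic in the literature); unknown names raise a lookup error
    naming them.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    universe = set(df["feature"])
    missing = set(feature_names) - universe
    if missing:
        raise LookupError_(missing)
    sub = df[df["feature"].isin(set(feature_names))]
    rows = []
    for (roi, model), grp in sub.groupby(["roi", "model"], sort=False):
        n = len(set(feature_names))
        counts = grp["level"].value_counts()
        row = {"roi": roi, "model": model, "n_subset": n}
        for lv in LEVELS:
            row[f"count_{lv}"] = int(counts.get(lv, 0))
            row[f"frac_{lv}"] = counts.get(lv, 0) / n
        rows.append(row)
    return pd.DataFrame(rows)
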