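"""Concordance analyses: per-feature CCC, levels, overlap, correlations.

Reads the feature table from step 03 and the IQM summary from step 02, then
computes: Lin's CCC per (ROI, model, feature) across subjects, four-level
classification and per-category summaries, the two-model overlap of
excellent/good feature sets, MAE-vs-mean-CCC correlations across ROIs,
paired t-tests, and a curated-subset report.

The 21-name subset in analysis/data/gtv_literature_subset_synthetic.txt is
a synthetic stand-in for an externally curated list of tumor features (the
real literature list is supplied by the user in production use).
"""

from pathlib import Path

import pandas as pd

from sctradiomics.concordance import (
    LevelThresholds,
    ccc_table,
    mae_ccc_correlation,
    overlap_analysis,
    records_to_frame,
    subset_report,
    summarize_levels,
)
from sctradiomics.pipeline import _ccc_ttests, _iqm_ttests

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    features = pd.read_csv(RESULTS / "features.csv")
    iqm_records = pd.read_csv(RESULTS / "iqm_records.csv")
    iqm_summary = pd.read_csv(RESULTS / "iqm_summary.csv")

    records = ccc_table(features, LevelThresholds())
    ccc_df = records_to_frame(records)
    ccc_df.to_csv(RESULTS / "ccc_records.csv", index=False)

    level_summary = summarize_levels(ccc_df)
    level_summary.to_csv(RESULTS / "level_summary.csv", index=False)

    models = sorted(set(ccc_df["model"]))
    overlaps = []
    for level in ("excellent", "good"):
        ov = overlap_analysis(
            ccc_df[ccc_df.model == models[0]], ccc_df[ccc_df.model == models[1]], level
        )
        ov.insert(0, "model_a", models[0])
        ov.insert(1, "model_b", models[1])
        overlaps.append(ov)
    overlap = pd.concat(overlaps, ignore_index=True)
    overlap.to_csv(RESULTS / "overlap.csv", index=False)

    mae_ccc = mae_ccc_correlation(iqm_summary, level_summary)
    mae_ccc.to_csv(RESULTS / "mae_ccc.csv", index=False)

    _iqm_ttests(iqm_records, models).to_csv(RESULTS / "iqm_ttests.csv", index=False)
    _ccc_ttests(ccc_df, models).to_csv(RESULTS / "ccc_ttests.csv", index=False)

    subset_names = [
        line.strip()
        for line in (ROOT / "analysis" / "data" / "gtv_literature_subset_synthetic.txt")
        .read_text().splitlines()
        if line.strip()
    ]
    subset = subset_report(ccc_df[ccc_df.roi == "GTVnx"], subset_names)
    subset.to_csv(RESULTS / "subset_report.csv", index=False)

    print(f"{len(ccc_df)} CCC records over {ccc_df.roi.nunique()} ROIs, "
          f"{len(models)} models")
    gtv = level_summary[level_summary.roi == "GTVnx"]
    for _, row in gtv.iterrows():
        print(f"  GTVnx {row.model}/{row.category}: "
              f"{row.pct_excellent:.1f}/{row.pct_good:.1f}/"
              f"{row.pct_moderate:.1f}/{row.pct_poor:.1f} % "
              f"(exc/good/mod/poor), mean CCC {row.mean_ccc:.2f} ± {row.sd_ccc:.2f}")
    exc = overlap[overlap.level == "excellent"]
    print(f"excellent-set overlap (mean Jaccard across ROIs): {exc.jaccard.mean():.2f}")
    print(f"subset report rows: {len(subset)} (21-feature curated list)")


if __name__ == "__main__":
    main()
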