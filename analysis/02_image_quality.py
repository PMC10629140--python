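"""Masked image-quality metrics for every (subject, ROI, model).

Reads the cohort manifest from step 01, computes MAE/RMSE/SSIM/PSNR on raw
HU inside the body and each ROI, and writes the per-record and mean +/- SD
summary tables under results/.
"""

from pathlib import Path

from sctradiomics.io import read_manifest
from sctradiomics.iqm import IqmConfig, evaluate_iqms, records_to_frame, summarize_iqms

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    cohort = read_manifest(ROOT / "scratch" / "cohort" / "manifest.json")
    records = evaluate_iqms(cohort, IqmConfig())
    df = records_to_frame(records)
    summary = summarize_iqms(records)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "iqm_records.csv", index=False)
    summary.to_csv(RESULTS / "iqm_summary.csv", index=False)
    print(f"{len(df)} IQM records "
          f"({df.subject_id.nunique()} subjects x {df.roi.nunique()} ROIs x "
          f"{df.model.nunique()} models)")
    body = summary[(summary.roi == "body")]
    for model in sorted(set(body.model)):
        sub = body[body.model == model].set_index("metric")
        print(f"  {model}: body MAE {sub.loc['mae','mean']:.1f} ± {sub.loc['mae','sd']:.1f} HU, "
              f"SSIM {sub.loc['ssim','mean']:.3f}, PSNR {sub.loc['psnr','mean']:.1f} dB")


if __name__ == "__main__":
    main()
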