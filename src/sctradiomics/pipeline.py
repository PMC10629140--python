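"""End-to-end evaluation: IQMs -> feature bank -> concordance analyses.

``evaluate_cohort`` is the single entry point used by the CLI, the analysis
scripts and the tests.  It returns plain pandas DataFrames keyed by stage so
every downstream consumer (CSV emission, figures, assertions) reads the
same objects.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .concordance import (
    LevelThresholds,
    ccc_table,
    mae_ccc_correlation,
    overlap_analysis,
    paired_ttest,
    records_to_frame as ccc_records_to_frame,
    subset_report,
    summarize_levels,
)
from .errors import DegenerateTestError, SctRadiomicsError
from .iqm import IqmConfig, evaluate_iqms, records_to_frame, summarize_iqms
from .radiomics import ExtractionConfig, extract_all, wavelet_decompose
from .volume import CohortManifest, validate_case

log = logging.getLogger("sctradiomics")


@dataclass
class PipelineConfig:
    iqm: IqmConfig = field(default_factory=IqmConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    thresholds: LevelThresholds = field(default_factory=LevelThresholds)
    feature_rois: tuple[str, ...] | None = None  # None = all ROIs except body
    subset_features: tuple[str, ...] = ()
    include_wavelet: bool = True


def extract_cohort_features(
    cohort: CohortManifest, config: PipelineConfig
) -> pd.DataFrame:
    """Feature table: one row per (subject, ROI, image), 837 columns.

    The wavelet decomposition is computed once per volume and shared across
    that volume's ROIs.
    """
    rois = (
        list(config.feature_rois)
        if config.feature_rois is not None
        else [r for r in cohort.roi_names if r != "body"]
    )
    images = ["real"] + cohort.model_names
    rows = []
    for case in cohort.cases:
        for img_name in images:
            vol = case.image(img_name)
            subbands = (
                wavelet_decompose(vol.values, config.extraction.wavelet)
                if config.include_wavelet
                else None
            )
            kwargs = {}
            if not config.include_wavelet:
                kwargs["images"] = ("original",)
            for roi in rois:
                fv = extract_all(
                    vol,
                    case.masks[roi],
                    config=config.extraction,
                    subbands=subbands,
                    **kwargs,
                )
                row = {"subject_id": case.subject_id, "roi": roi, "image": img_name}
                row.update(fv.values)
                if fv.flags:
                    log.warning(
                        "degenerate features for %s/%s/%s: %s",
                        case.subject_id,
                        roi,
                        img_name,
                        fv.flags,
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def _iqm_ttests(iqm_df: pd.DataFrame, models: list[str]) -> pd.DataFrame:
    """Paired t-test per (ROI x metric) between each model pair, across subjects."""
    rows = []
    for a, b in itertools.combinations(models, 2):
        for roi in sorted(set(iqm_df["roi"])):
            for metric in ("mae", "rmse", "ssim", "psnr"):
                va = iqm_df[(iqm_df["model"] == a) & (iqm_df["roi"] == roi)]
                vb = iqm_df[(iqm_df["model"] == b) & (iqm_df["roi"] == roi)]
                va = va.sort_values("subject_id")[metric].to_numpy()
                vb = vb.sort_values("subject_id")[metric].to_numpy()
                row = {"model_a": a, "model_b": b, "roi": roi, "metric": metric}
                try:
                    t, p, n = paired_ttest(va, vb)
                    row.update(t=t, p=p, n=n, significant=p < 0.05, note="")
                except (DegenerateTestError, ValueError) as exc:
                    row.update(t=np.nan, p=np.nan, n=len(va), significant=False, note=str(exc))
                rows.append(row)
    return pd.DataFrame(rows)


def _ccc_ttests(ccc_df: pd.DataFrame, models: list[str]) -> pd.DataFrame:
    """Paired t-test per (ROI x category) between model pairs, paired across features."""
    rows = []
    for a, b in itertools.combinations(models, 2):
        for (roi, cat), sub in ccc_df[ccc_df["model"].isin([a, b])].groupby(
            ["roi", "category"], sort=False
        ):
            pa = sub[sub["model"] == a].set_index("feature")["ccc"]
            pb = sub[sub["model"] == b].set_index("feature")["ccc"]
            common = pa.index.intersection(pb.index)
            row = {"model_a": a, "model_b": b, "roi": roi, "category": cat}
            try:
                t, p, n = paired_ttest(pa[common].to_numpy(), pb[common].to_numpy())
                row.update(t=t, p=p, n=n, significant=p < 0.05, note="")
            except (DegenerateTestError, ValueError) as exc:
                row.update(t=np.nan, p=np.nan, n=len(common), significant=False, note=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)


def evaluate_cohort(
    cohort: CohortManifest, config: PipelineConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Run the full evaluation; returns a dict of stage outputs.

    Keys: iqm_records, iqm_summary, features, ccc_records, level_summary,
    overlap, mae_ccc, iqm_ttests, ccc_ttests, (subset — when configured).
    """
    config = config or PipelineConfig()
    t0 = time.time()
    for case in cohort.cases:
        report = validate_case(case)
        if not report["valid"]:
            raise SctRadiomicsError(
                f"invalid case {case.subject_id}: {report['problems']}"
            )
    log.info("validated %d cases (%.1fs)", len(cohort.cases), time.time() - t0)

    stage = time.time()
    iqm_records = evaluate_iqms(cohort, config.iqm)
    iqm_df = records_to_frame(iqm_records)
    iqm_summary = summarize_iqms(iqm_records)
    log.info("IQMs: %d records (%.1fs)", len(iqm_df), time.time() - stage)

    stage = time.time()
    features = extract_cohort_features(cohort, config)
    log.info("features: %d rows (%.1fs)", len(features), time.time() - stage)

    stage = time.time()
    ccc_records = ccc_table(features, config.thresholds)
    ccc_df = ccc_records_to_frame(ccc_records)
    level_summary = summarize_levels(ccc_df)
    log.info("CCC: %d records (%.1fs)", len(ccc_df), time.time() - stage)

    overlaps = []
    models = cohort.model_names
    if len(models) >= 2:
        for a, b in itertools.combinations(models, 2):
            da = ccc_df[ccc_df["model"] == a]
            db = ccc_df[ccc_df["model"] == b]
            for level in ("excellent", "good"):
                ov = overlap_analysis(da, db, level)
                ov.insert(0, "model_a", a)
                ov.insert(1, "model_b", b)
                overlaps.append(ov)
    overlap = (
        pd.concat(overlaps, ignore_index=True) if overlaps else pd.DataFrame()
    )

    mae_ccc = mae_ccc_correlation(iqm_summary, level_summary)

    out = {
        "iqm_records": iqm_df,
        "iqm_summary": iqm_summary,
        "features": features,
        "ccc_records": ccc_df,
        "level_summary": level_summary,
        "overlap": overlap,
        "mae_ccc": mae_ccc,
        "iqm_ttests": _iqm_ttests(iqm_df, models),
        "ccc_ttests": _ccc_ttests(ccc_df, models),
    }
    if config.subset_features:
        out["subset"] = subset_report(ccc_df, list(config.subset_features))
    return out


def write_outputs(
    outputs: dict[str, pd.DataFrame],
    out_dir,
    provenance: dict | None = None,
) -> Path:
    """Write every stage table as CSV plus a provenance JSON.

    No multiple-testing correction is applied to any reported p-value; the
    provenance notes this so readers interpret significance flags per test.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in outputs.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    meta = {
        "package": "sctradiomics",
        "version": _pkg_version,
        "multiple_testing_correction": "none",
    }
    meta.update(provenance or {})
    (out_dir / "provenance.json").write_text(json.dumps(meta, indent=2, default=str))
    return out_dir
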