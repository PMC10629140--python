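"""Masked image-quality metrics: MAE, RMSE, PSNR and SSIM.

All four metrics are computed over an ROI mask on raw HU images (the units
used for reporting).  PSNR needs a peak constant and SSIM a data range;
neither is universal for CT, so both default to "auto" — the dynamic range
of the *real* image over the reference (body) mask — and the resolved value
is carried in each record so runs are auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.metrics import structural_similarity

from .errors import EmptyMaskError, GeometryError
from .volume import CohortManifest, ImageVolume, RoiMask, crop_to_mask

#: documented sentinel for PSNR of identical images (MSE = 0)
PSNR_PERFECT = math.inf


@dataclass
class IqmConfig:
    """Constants for PSNR and SSIM.

    ``psnr_max`` and ``ssim_data_range`` may be numeric (HU) or ``"auto"``,
    which resolves to the real image's (max - min) over the body mask of the
    subject being evaluated.
    """

    psnr_max: float | str = "auto"
    ssim_window: int = 7
    ssim_sigma: float = 1.5
    ssim_k1: float = 0.01
    ssim_k2: float = 0.03
    ssim_data_range: float | str = "auto"

    def __post_init__(self):
        if self.ssim_window < 3 or self.ssim_window % 2 == 0:
            raise ValueError("ssim_window must be odd and >= 3")
        if self.ssim_k1 <= 0 or self.ssim_k2 <= 0:
            raise ValueError("k1, k2 must be positive")
        for name in ("psnr_max", "ssim_data_range"):
            v = getattr(self, name)
            if v != "auto" and float(v) <= 0:
                raise ValueError(f"{name} must be positive or 'auto'")


@dataclass
class IqmRecord:
    subject_id: str
    roi_name: str
    model_name: str
    mae: float
    rmse: float
    ssim: float
    psnr: float
    psnr_max: float = float("nan")
    ssim_fallback: bool = False


def _masked_pair(real: ImageVolume, syn: ImageVolume, mask: RoiMask):
    if real.shape != syn.shape or real.shape != mask.shape:
        raise GeometryError(
            f"grid mismatch: real {real.shape}, syn {syn.shape}, mask {mask.shape}"
        )
    mask.require_nonempty()
    m = mask.values
    return real.values[m], syn.values[m]


def mae(real: ImageVolume, syn: ImageVolume, mask: RoiMask) -> float:
    """Mean absolute error over mask voxels (HU)."""
    a, b = _masked_pair(real, syn, mask)
    return float(np.mean(np.abs(a - b)))


def rmse(real: ImageVolume, syn: ImageVolume, mask: RoiMask) -> float:
    """Root mean squared error over mask voxels (HU)."""
    a, b = _masked_pair(real, syn, mask)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _resolve_peak(value, real: ImageVolume, reference_mask: RoiMask) -> float:
    if value == "auto":
        vals = real.values[reference_mask.values]
        if vals.size == 0:
            raise EmptyMaskError("reference mask for 'auto' peak is empty")
        rng = float(vals.max() - vals.min())
        if rng <= 0:
            raise GeometryError("real image is constant over the reference mask")
        return rng
    return float(value)


def psnr(
    real: ImageVolume,
    syn: ImageVolume,
    mask: RoiMask,
    config: IqmConfig | None = None,
    reference_mask: RoiMask | None = None,
) -> float:
    """Peak signal-to-noise ratio in dB: ``10 log10(peak^2 / MSE)``.

    With ``psnr_max="auto"`` the peak is the real image's dynamic range over
    ``reference_mask`` (the evaluation mask itself if none is given).
    Identical images return ``+inf``.
    """
    config = config or IqmConfig()
    a, b = _masked_pair(real, syn, mask)
    peak = _resolve_peak(config.psnr_max, real, reference_mask or mask)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return PSNR_PERFECT
    return float(10.0 * math.log10(peak**2 / mse))


def _global_ssim(a: np.ndarray, b: np.ndarray, data_range: float, k1: float, k2: float) -> float:
    # single-window SSIM over all mask voxels; used when the ROI bounding box
    # is smaller than the local window in some axis
    c1, c2 = (k1 * data_range) ** 2, (k2 * data_range) ** 2
    mu_a, mu_b = a.mean(), b.mean()
    va, vb = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return float(
        (2 * mu_a * mu_b + c1) * (2 * cov + c2)
        / ((mu_a**2 + mu_b**2 + c1) * (va + vb + c2))
    )


def ssim(
    real: ImageVolume,
    syn: ImageVolume,
    mask: RoiMask,
    config: IqmConfig | None = None,
    reference_mask: RoiMask | None = None,
    return_fallback: bool = False,
):
    """Mean of the local-window SSIM map over mask voxels.

    The map is computed on the mask's bounding box padded by the window
    half-width, with a Gaussian-weighted 3-D window.  ROIs whose bounding box
    is smaller than the window in any axis fall back to a single global
    window over the mask voxels (flagged when ``return_fallback``).
    """
    config = config or IqmConfig()
    a_full, b_full = _masked_pair(real, syn, mask)
    data_range = _resolve_peak(config.ssim_data_range, real, reference_mask or mask)
    half = config.ssim_window // 2
    fg = np.argwhere(mask.values)
    bbox = fg.max(axis=0) - fg.min(axis=0) + 1
    real_c, mask_c = crop_to_mask(real, mask, margin=half)
    syn_c, _ = crop_to_mask(syn, mask, margin=half)
    if int(bbox.min()) < config.ssim_window or min(real_c.shape) < config.ssim_window:
        value = _global_ssim(a_full, b_full, data_range, config.ssim_k1, config.ssim_k2)
        return (value, True) if return_fallback else value
    _, smap = structural_similarity(
        real_c.values,
        syn_c.values,
        win_size=config.ssim_window,
        gaussian_weights=True,
        sigma=config.ssim_sigma,
        use_sample_covariance=False,
        K1=config.ssim_k1,
        K2=config.ssim_k2,
        data_range=data_range,
        full=True,
    )
    value = float(smap[mask_c.values].mean())
    return (value, False) if return_fallback else value


def evaluate_case(case, config: IqmConfig, body_roi: str = "body") -> list[IqmRecord]:
    """All IQMs for one subject: every (ROI x model) pair.

    'auto' constants resolve against the body mask (or the first listed mask
    if no body mask exists) once per subject so all ROIs share one peak.
    """
    ref_mask = case.masks.get(body_roi) or next(iter(case.masks.values()))
    peak = _resolve_peak(config.psnr_max, case.real, ref_mask)
    data_range = _resolve_peak(config.ssim_data_range, case.real, ref_mask)
    resolved = replace(config, psnr_max=peak, ssim_data_range=data_range)
    records = []
    for model, syn in case.synthetic.items():
        for roi, mask in case.masks.items():
            s, fb = ssim(case.real, syn, mask, resolved, return_fallback=True)
            records.append(
                IqmRecord(
                    subject_id=case.subject_id,
                    roi_name=roi,
                    model_name=model,
                    mae=mae(case.real, syn, mask),
                    rmse=rmse(case.real, syn, mask),
                    ssim=s,
                    psnr=psnr(case.real, syn, mask, resolved),
                    psnr_max=peak,
                    ssim_fallback=fb,
                )
            )
    return records


def evaluate_iqms(cohort: CohortManifest, config: IqmConfig | None = None) -> list[IqmRecord]:
    """One IqmRecord per (subject x ROI x model) across the cohort."""
    config = config or IqmConfig()
    records = []
    for case in cohort.cases:
        try:
            records.extend(evaluate_case(case, config))
        except Exception as exc:
            raise type(exc)(f"[subject {case.subject_id}] {exc}") from exc
    return records


def records_to_frame(records: list[IqmRecord]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "roi": r.roi_name,
                "model": r.model_name,
                "mae": r.mae,
                "rmse": r.rmse,
                "ssim": r.ssim,
                "psnr": r.psnr,
                "psnr_max": r.psnr_max,
                "ssim_fallback": r.ssim_fallback,
            }
            for r in records
        ]
    )


def summarize_iqms(records: list[IqmRecord]):
    """Cohort mean +/- SD per (ROI x model x metric) — the Table-1 layout."""
    import pandas as pd

    df = records_to_frame(records)
    long = df.melt(
        id_vars=["subject_id", "roi", "model"],
        value_vars=["mae", "rmse", "ssim", "psnr"],
        var_name="metric",
    )
    out = (
        long.groupby(["roi", "model", "metric"], sort=False)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
        .reset_index()
    )
    return out
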