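"""Assembly of the full 837-feature vector for one (volume, ROI) pair.

Layout (deterministic order):

* ``original_firstorder_*``   — 18 features, category "first-order"
* ``original_{glcm,glrlm,glszm,gldm,ngtdm}_*`` — 75 features, category "texture"
* ``wavelet-{LLL..HHH}_{firstorder,...}_*`` — 93 x 8 = 744, category "wavelet"

Discretization is recomputed per image filter from that image's own masked
range (sub-band intensities are not HU), with one shared bin width.  Any
feature whose computation fails is recorded as a flagged 0.0 sentinel —
the vector always has full length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..volume import ImageVolume, RoiMask, crop_to_mask
from .discretize import discretize
from .firstorder import FIRSTORDER_NAMES, first_order_features
from .matrices import build_matrix_set
from .texturefeat import TEXTURE_NAMES, texture_features
from .wavelet import SUBBAND_ORDER, wavelet_decompose

IMAGE_FILTERS = ("original",) + tuple(f"wavelet-{b}" for b in SUBBAND_ORDER)

def _build_names() -> tuple[str, ...]:
    names = []
    for img in IMAGE_FILTERS:
        names.extend(f"{img}_firstorder_{n}" for n in FIRSTORDER_NAMES)
        names.extend(f"{img}_{n}" for n in TEXTURE_NAMES)
    return tuple(names)


#: the canonical 837 feature names in extraction order
FEATURE_NAMES: tuple[str, ...] = _build_names()
N_FEATURES = len(FEATURE_NAMES)  # 837


def feature_category(name: str) -> str:
    """Map a feature name to first-order / texture / wavelet."""
    if name.startswith("wavelet"):
        return "wavelet"
    if "_firstorder_" in name:
        return "first-order"
    return "texture"


@dataclass
class ExtractionConfig:
    bin_width: float = 25.0
    bin_anchor: str = "masked-min"
    wavelet: str = "coif1"
    glcm_distance: int = 1
    gldm_alpha: float = 0.0

    def metadata(self) -> dict:
        return {
            "bin_width": self.bin_width,
            "bin_anchor": self.bin_anchor,
            "wavelet": self.wavelet,
            "glcm_distance": self.glcm_distance,
            "gldm_alpha": self.gldm_alpha,
            "n_directions": 13,
            "connectivity": 26,
        }


@dataclass
class FeatureVector:
    """Ordered feature_name -> value map with per-feature failure flags."""

    values: dict[str, float]
    flags: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def categories(self) -> dict[str, str]:
        return {n: feature_category(n) for n in self.values}

    def as_series(self):
        import pandas as pd

        return pd.Series(self.values)


def _image_features(
    values: np.ndarray,
    mask: np.ndarray,
    voxel_volume: float,
    config: ExtractionConfig,
    prefix: str,
    out: dict[str, float],
    flags: dict[str, str],
    families: tuple[str, ...],
) -> None:
    disc = None
    try:
        disc = discretize(values, mask, config.bin_width, config.bin_anchor)
    except Exception as exc:
        for fam in families:
            names = FIRSTORDER_NAMES if fam == "firstorder" else ()
            flags[f"{prefix}:{fam}"] = f"discretization failed: {exc}"
    if "firstorder" in families:
        try:
            fo = first_order_features(values, mask, disc, voxel_volume)
            out.update({f"{prefix}_firstorder_{k}": v for k, v in fo.items()})
        except Exception as exc:
            out.update({f"{prefix}_firstorder_{k}": 0.0 for k in FIRSTORDER_NAMES})
            flags[f"{prefix}_firstorder"] = str(exc)
    if "texture" in families:
        try:
            mats = build_matrix_set(
                disc.levels, mask, disc.Ng, config.glcm_distance, config.gldm_alpha
            )
            out.update({f"{prefix}_{k}": v for k, v in texture_features(mats).items()})
        except Exception as exc:
            out.update({f"{prefix}_{k}": 0.0 for k in TEXTURE_NAMES})
            flags[f"{prefix}_texture"] = str(exc)


def extract_all(
    volume: ImageVolume,
    mask: RoiMask,
    bin_width: float | None = None,
    config: ExtractionConfig | None = None,
    subbands: dict[str, np.ndarray] | None = None,
    images: tuple[str, ...] = IMAGE_FILTERS,
    families: tuple[str, ...] = ("firstorder", "texture"),
) -> FeatureVector:
    """Extract the radiomic feature bank for one ROI.

    With default ``images`` and ``families`` the result has exactly 837
    entries.  ``subbands`` may carry precomputed full-grid sub-band images
    (one decomposition per volume shared across ROIs); otherwise the
    decomposition is computed here on the cropped ROI neighbourhood.
    Restricting ``images``/``families`` yields a correspondingly shorter
    vector (used for targeted analyses).
    """
    config = config or ExtractionConfig()
    if bin_width is not None:
        config = ExtractionConfig(
            bin_width=bin_width,
            bin_anchor=config.bin_anchor,
            wavelet=config.wavelet,
            glcm_distance=config.glcm_distance,
            gldm_alpha=config.gldm_alpha,
        )
    mask.require_nonempty()
    want_wavelet = any(img.startswith("wavelet") for img in images)
    # generous margin so the stationary transform sees real context and the
    # cropped grid is never smaller than the wavelet filter support
    margin = 8 if want_wavelet else 1
    vol_c, mask_c = crop_to_mask(volume, mask, margin=margin)
    m = mask_c.values
    out: dict[str, float] = {}
    flags: dict[str, str] = {}
    band_images: dict[str, np.ndarray] = {}
    if want_wavelet:
        if subbands is not None:
            # crop the precomputed full-grid sub-bands to the same window
            full_vol = volume
            fg = np.argwhere(mask.values)
            lo = np.maximum(fg.min(axis=0) - margin, 0)
            hi = np.minimum(fg.max(axis=0) + margin + 1, full_vol.shape)
            sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
            band_images = {b: np.asarray(arr)[sl] for b, arr in subbands.items()}
        else:
            band_images = wavelet_decompose(vol_c.values, config.wavelet)
    for img in images:
        if img == "original":
            _image_features(
                vol_c.values, m, volume.voxel_volume, config, "original", out, flags, families
            )
        else:
            band = img.split("-", 1)[1]
            _image_features(
                band_images[band], m, volume.voxel_volume, config, img, out, flags, families
            )
    # enforce canonical ordering
    ordered = {
        n: out[n] for n in FEATURE_NAMES if n in out
    }
    return FeatureVector(values=ordered, flags=flags)
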