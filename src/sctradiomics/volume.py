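"""Core in-memory containers for volumes, masks and paired cases.

Axis convention
---------------
All arrays are indexed ``(slice, row, column)`` — i.e. the first axis walks
through axial slices.  ``spacing`` is stored in millimetres per axis in the
same order.  No resampling is ever performed by this package: every volume
and mask of a case must already live on one shared grid (registration and
resampling are upstream concerns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateRangeError, EmptyMaskError, GeometryError

AXIS_ORDER = "zyx"

#: canonical ROI names used throughout the head-and-neck evaluation
STANDARD_ROIS = (
    "body",
    "GTVnx",
    "brainstem",
    "parotid_l",
    "parotid_r",
    "temporal_lobe_l",
    "temporal_lobe_r",
)


@dataclass
class ImageVolume:
    """A 3-D scalar grid (HU for CT; arbitrary units for derived images)."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = AXIS_ORDER

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise GeometryError(
                f"ImageVolume requires a 3-D array, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("ImageVolume contains non-finite voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        """Same grid metadata, new voxel values."""
        return ImageVolume(values, self.spacing, self.origin, self.axis_order)


@dataclass
class RoiMask:
    """Binary region-of-interest mask on the same grid as its parent volume.

    Any nonzero voxel is foreground.
    """

    values: np.ndarray
    roi_name: str = "roi"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise GeometryError(
                f"RoiMask requires a 3-D array, got shape {arr.shape}"
            )
        self.values = arr != 0
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def require_nonempty(self):
        if self.n_voxels == 0:
            raise EmptyMaskError(f"mask '{self.roi_name}' has no foreground voxels")


@dataclass
class PatientCase:
    """One subject: a real CT, named synthetic CTs, and named ROI masks.

    The same contour set applies to the real and every synthetic image, so a
    single mask per ROI is stored.
    """

    subject_id: str
    real: ImageVolume
    synthetic: dict[str, ImageVolume] = field(default_factory=dict)
    masks: dict[str, RoiMask] = field(default_factory=dict)

    @property
    def model_names(self) -> list[str]:
        return list(self.synthetic)

    @property
    def roi_names(self) -> list[str]:
        return list(self.masks)

    def image(self, name: str) -> ImageVolume:
        """Fetch 'real' or a synthetic model image by name."""
        if name == "real":
            return self.real
        return self.synthetic[name]


@dataclass
class CohortManifest:
    """An ordered cohort of cases with a shared ROI and model vocabulary."""

    cases: list[PatientCase]
    roi_names: list[str]
    model_names: list[str]

    def __post_init__(self):
        ids = [c.subject_id for c in self.cases]
        if len(set(ids)) != len(ids):
            raise GeometryError("subject_ids in a cohort must be unique")

    @property
    def subject_ids(self) -> list[str]:
        return [c.subject_id for c in self.cases]


def validate_case(case: PatientCase) -> dict:
    """Check grid agreement, mask non-emptiness and voxel finiteness.

    Always returns a report dict ``{"valid": bool, "problems": [str, ...]}``
    rather than raising, so a cohort sweep can collect every defect at once.
    """
    problems: list[str] = []
    ref_shape = case.real.shape
    ref_spacing = case.real.spacing
    if not np.all(np.isfinite(case.real.values)):
        problems.append("real volume has non-finite voxels")
    for name, vol in case.synthetic.items():
        if vol.shape != ref_shape:
            problems.append(
                f"synthetic '{name}' shape {vol.shape} != real shape {ref_shape}"
            )
        if vol.spacing != ref_spacing:
            problems.append(
                f"synthetic '{name}' spacing {vol.spacing} != real spacing {ref_spacing}"
            )
        if not np.all(np.isfinite(vol.values)):
            problems.append(f"synthetic '{name}' has non-finite voxels")
    for name, mask in case.masks.items():
        if mask.shape != ref_shape:
            problems.append(f"mask '{name}' shape {mask.shape} != real shape {ref_shape}")
        elif mask.n_voxels == 0:
            problems.append(f"mask '{name}' is empty")
    return {"valid": not problems, "subject_id": case.subject_id, "problems": problems}


def minmax_normalize(volume: ImageVolume) -> ImageVolume:
    """Rescale intensities linearly to [-1, 1].

    ``out = 2 * (x - min) / (max - min) - 1``.  Provided for parity with the
    preprocessing used before network training; the evaluation pipeline
    itself operates on raw HU.
    """
    x = volume.values
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise DegenerateRangeError("cannot min-max normalize a constant volume")
    return volume.with_values(2.0 * (x - lo) / (hi - lo) - 1.0)


def crop_to_mask(
    volume: ImageVolume, mask: RoiMask, margin: int = 0
) -> tuple[ImageVolume, RoiMask]:
    """Crop a volume and mask to the mask's bounding box plus ``margin``.

    The crop is clipped to the volume bounds; the multiset of masked voxel
    values is unchanged, so every mask-restricted statistic is invariant.
    """
    mask.require_nonempty()
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if volume.shape != mask.shape:
        raise GeometryError(
            f"volume shape {volume.shape} != mask shape {mask.shape}"
        )
    fg = np.argwhere(mask.values)
    lo = np.maximum(fg.min(axis=0) - margin, 0)
    hi = np.minimum(fg.max(axis=0) + margin + 1, volume.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return (
        volume.with_values(volume.values[sl]),
        RoiMask(mask.values[sl], mask.roi_name, mask.spacing),
    )
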