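"""Fixed-bin-width gray-level discretization.

Intensities inside the mask are mapped to integer levels 1..Ng with a
constant bin width (default 25 HU).  The default anchors bins at the masked
minimum, ``level(x) = floor((x - min) / w) + 1``, which makes every
discretization-based feature exactly invariant to adding a constant to the
image.  The alternative ``width-aligned`` anchor snaps the first bin edge
down to a multiple of the bin width (the convention of some extraction
tools); it sacrifices arbitrary-shift invariance for cross-image edge
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import EmptyMaskError

ANCHORS = ("masked-min", "width-aligned")


@dataclass
class DiscretizedVolume:
    """Integer gray levels on the masked grid.

    ``levels`` is 0 outside the mask and in 1..Ng inside.
    """

    levels: np.ndarray
    Ng: int
    bin_width: float
    bin_origin: float

    def masked_levels(self, mask: np.ndarray) -> np.ndarray:
        return self.levels[mask]


def discretize(
    values: np.ndarray,
    mask: np.ndarray,
    bin_width: float = 25.0,
    anchor: str = "masked-min",
) -> DiscretizedVolume:
    """Discretize ``values`` over ``mask`` with a fixed bin width.

    Parameters
    ----------
    values : 3-D float array (HU or sub-band intensities)
    mask : 3-D boolean array, at least one foreground voxel
    bin_width : width of each gray-level bin, > 0 (same units as values)
    anchor : "masked-min" (default) or "width-aligned"
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if anchor not in ANCHORS:
        raise ValueError(f"anchor must be one of {ANCHORS}")
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(values, dtype=np.float64)[mask]
    if vals.size == 0:
        raise EmptyMaskError("cannot discretize an empty mask")
    mn = float(vals.min())
    origin = mn if anchor == "masked-min" else mn - (mn % bin_width)
    levels = np.zeros(mask.shape, dtype=np.int64)
    inside = np.floor((np.asarray(values, dtype=np.float64)[mask] - origin) / bin_width).astype(np.int64) + 1
    # guard against floating round-down at the anchor itself
    inside = np.maximum(inside, 1)
    levels[mask] = inside
    ng = int(inside.max())
    return DiscretizedVolume(levels=levels, Ng=ng, bin_width=float(bin_width), bin_origin=origin)


def level_histogram(disc: DiscretizedVolume, mask: np.ndarray) -> np.ndarray:
    """Probability of each level 1..Ng inside the mask (sums to 1)."""
    lv = disc.masked_levels(np.asarray(mask, dtype=bool))
    counts = np.bincount(lv, minlength=disc.Ng + 1)[1:].astype(np.float64)
    return counts / counts.sum()
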