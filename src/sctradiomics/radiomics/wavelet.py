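"""Single-level undecimated 3-D wavelet decomposition.

The stationary (a trous) transform keeps every sub-band on the input grid,
so the ROI mask applies to each sub-band unchanged.  Default basis is
"coif1".  The stationary transform needs even axis lengths; odd axes are
edge-padded by one voxel and the pad is cropped off afterwards, so callers
never see a grid change.

Sub-band names use L (low-pass) / H (high-pass) per axis in
(slice, row, column) order: LLL is the smooth approximation, HHH the full
detail band.
"""

from __future__ import annotations

import numpy as np
import pywt

#: deterministic sub-band order used for feature naming
SUBBAND_ORDER = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

_KEY_FOR = {"L": "a", "H": "d"}  # pywt letters: a = approx, d = detail


def wavelet_decompose(values: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """Decompose a 3-D array into its 8 stationary-wavelet sub-bands.

    Returns ``{name: array}`` with every array on the input grid, names in
    :data:`SUBBAND_ORDER`.  Deterministic for fixed input.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("wavelet_decompose requires a 3-D array")
    wav = pywt.Wavelet(wavelet)
    if min(arr.shape) < wav.dec_len:
        raise ValueError(
            f"volume shape {arr.shape} smaller than the '{wavelet}' filter "
            f"support ({wav.dec_len})"
        )
    pad = [(0, n % 2) for n in arr.shape]
    padded = np.pad(arr, pad, mode="edge")
    coeffs = pywt.swtn(padded, wav, level=1, start_level=0)[0]
    crop = tuple(slice(0, n) for n in arr.shape)
    out = {}
    for name in SUBBAND_ORDER:
        key = "".join(_KEY_FOR[c] for c in name)
        out[name] = np.asarray(coeffs[key], dtype=np.float64)[crop]
    return out
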