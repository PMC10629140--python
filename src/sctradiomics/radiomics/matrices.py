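"""Construction of the five gray-level texture matrices.

All builders take an integer level volume (0 outside the mask, 1..Ng
inside), a boolean mask on the same grid, and Ng.  Conventions:

* 13 unique 3-D direction vectors at distance 1 for GLCM and GLRLM; each
  direction is processed separately (features are averaged downstream).
* GLCM matrices are symmetrized (counts + transpose).
* GLSZM zones, GLDM dependence neighbourhoods and NGTDM neighbourhoods use
  26-connectivity.
* GLDM dependence threshold alpha = 0; the dependence size of a voxel is
  1 + the number of neighbours with an equal level, so an isolated voxel
  has dependence 1.

Raw integer counts are returned; probability normalization happens in the
feature formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: the 13 unique 3-D offsets (one per opposite pair of the 26 neighbours)
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

#: all 26 neighbour offsets
NEIGHBOURS_26: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class TextureMatrixSet:
    """The five matrix families for one discretized ROI."""

    glcm: np.ndarray  # (13, Ng, Ng) symmetric counts per direction
    glrlm: np.ndarray  # (13, Ng, Nr) run counts per direction
    glszm: np.ndarray  # (Ng, Ns) zone counts
    gldm: np.ndarray  # (Ng, Nd) dependence counts
    ngtdm: np.ndarray  # (Ng, 3): count n_i, probability p_i, sum |i - A| s_i
    n_voxels: int


def _offset_slices(shape, off):
    src, dst = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def glcm_matrix(
    levels: np.ndarray, mask: np.ndarray, ng: int, distance: int = 1
) -> np.ndarray:
    """Symmetrized co-occurrence counts, shape (13, Ng, Ng)."""
    if distance < 1:
        raise ValueError("distance must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros((len(DIRECTIONS_3D), ng, ng), dtype=np.float64)
    for k, d in enumerate(DIRECTIONS_3D):
        off = tuple(distance * c for c in d)
        src, dst = _offset_slices(levels.shape, off)
        valid = mask[src] & mask[dst]
        i = levels[src][valid] - 1
        j = levels[dst][valid] - 1
        if i.size:
            counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng)
            out[k] = counts + counts.T  # symmetrization
    return out


def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, ng: int) -> np.ndarray:
    """Run-length counts per direction, shape (13, Ng, Nr).

    A run is a maximal set of collinear, consecutive masked voxels sharing
    one gray level; unmasked voxels break runs.  Nr is the longest run
    observed in any direction (at least 1).
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    lv = levels[mask]
    per_direction: list[tuple[np.ndarray, np.ndarray]] = []
    max_run = 1
    for d in DIRECTIONS_3D:
        dv = np.array(d)
        i0 = int(np.nonzero(dv)[0][0])
        t = coords[:, i0] * dv[i0]
        # line key: coordinates with the motion along the line projected out
        key = coords - np.outer(t, dv) * dv[i0]
        order = np.lexsort((t, key[:, 2], key[:, 1], key[:, 0]))
        ts, keys, lvs = t[order], key[order], lv[order]
        if len(ts) == 0:
            per_direction.append((np.array([], int), np.array([], int)))
            continue
        new_run = np.ones(len(ts), dtype=bool)
        same_line = np.all(keys[1:] == keys[:-1], axis=1)
        contiguous = ts[1:] == ts[:-1] + 1
        same_level = lvs[1:] == lvs[:-1]
        new_run[1:] = ~(same_line & contiguous & same_level)
        starts = np.flatnonzero(new_run)
        lengths = np.diff(np.append(starts, len(ts)))
        run_levels = lvs[starts]
        per_direction.append((run_levels, lengths))
        if lengths.size:
            max_run = max(max_run, int(lengths.max()))
    out = np.zeros((len(DIRECTIONS_3D), ng, max_run), dtype=np.float64)
    for k, (run_levels, lengths) in enumerate(per_direction):
        if run_levels.size:
            flat = (run_levels - 1) * max_run + (lengths - 1)
            out[k] = np.bincount(flat, minlength=ng * max_run).reshape(ng, max_run)
    return out


def glszm_matrix(levels: np.ndarray, mask: np.ndarray, ng: int) -> np.ndarray:
    """Size-zone counts, shape (Ng, Ns); zones are 26-connected."""
    mask = np.asarray(mask, dtype=bool)
    zone_levels: list[int] = []
    zone_sizes: list[int] = []
    present = np.unique(levels[mask])
    for g in present:
        lab, nlab = ndimage.label((levels == g) & mask, structure=_STRUCT_26)
        if nlab:
            sizes = np.bincount(lab.ravel())[1:]
            zone_levels.extend([int(g)] * nlab)
            zone_sizes.extend(int(s) for s in sizes)
    max_size = max(zone_sizes) if zone_sizes else 1
    out = np.zeros((ng, max_size), dtype=np.float64)
    for g, s in zip(zone_levels, zone_sizes):
        out[g - 1, s - 1] += 1
    return out


def gldm_matrix(
    levels: np.ndarray, mask: np.ndarray, ng: int, alpha: float = 0.0
) -> np.ndarray:
    """Dependence counts, shape (Ng, Nd).

    Column j (1-based) is dependence size j = 1 + number of 26-neighbours
    within the mask whose level differs from the centre by at most alpha.
    """
    mask = np.asarray(mask, dtype=bool)
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in NEIGHBOURS_26:
        src, dst = _offset_slices(levels.shape, off)
        ok = (
            mask[src]
            & mask[dst]
            & (np.abs(levels[src] - levels[dst]) <= alpha)
        )
        dep[dst] += ok
    sizes = dep[mask] + 1
    lv = levels[mask]
    nd = int(sizes.max())
    flat = (lv - 1) * nd + (sizes - 1)
    return (
        np.bincount(flat, minlength=ng * nd).reshape(ng, nd).astype(np.float64)
    )


def ngtdm_matrix(levels: np.ndarray, mask: np.ndarray, ng: int) -> np.ndarray:
    """Neighbourhood gray-tone difference table, shape (Ng, 3).

    Columns: n_i (count of valid voxels at level i), p_i = n_i / Nvp, and
    s_i = sum over those voxels of |i - mean level of masked neighbours|.
    Voxels with no masked neighbour are excluded from Nvp.
    """
    mask = np.asarray(mask, dtype=bool)
    nbr_sum = np.zeros(levels.shape, dtype=np.float64)
    nbr_cnt = np.zeros(levels.shape, dtype=np.int64)
    for off in NEIGHBOURS_26:
        src, dst = _offset_slices(levels.shape, off)
        ok = mask[src] & mask[dst]
        nbr_sum[dst] += np.where(ok, levels[src], 0)
        nbr_cnt[dst] += ok
    valid = mask & (nbr_cnt > 0)
    lv = levels[valid]
    diff = np.abs(lv - nbr_sum[valid] / nbr_cnt[valid])
    nvp = lv.size
    out = np.zeros((ng, 3), dtype=np.float64)
    if nvp:
        out[:, 0] = np.bincount(lv - 1, minlength=ng)
        out[:, 1] = out[:, 0] / nvp
        out[:, 2] = np.bincount(lv - 1, weights=diff, minlength=ng)
    return out


def build_matrix_set(
    levels: np.ndarray,
    mask: np.ndarray,
    ng: int,
    distance: int = 1,
    gldm_alpha: float = 0.0,
) -> TextureMatrixSet:
    mask = np.asarray(mask, dtype=bool)
    return TextureMatrixSet(
        glcm=glcm_matrix(levels, mask, ng, distance),
        glrlm=glrlm_matrix(levels, mask, ng),
        glszm=glszm_matrix(levels, mask, ng),
        gldm=gldm_matrix(levels, mask, ng, gldm_alpha),
        ngtdm=ngtdm_matrix(levels, mask, ng),
        n_voxels=int(mask.sum()),
    )
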