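"""The 75 texture features computed from the five matrix families.

GLCM (24) and GLRLM (16) are computed per direction and averaged over the
13 directions; GLSZM (16), GLDM (14) and NGTDM (5) come from single
matrices.  Degenerate denominators (constant regions, single gray level)
return documented sentinels — 0 for correlation/variance-type features,
1e6 for NGTDM Coarseness — so the feature vector never has holes.

Level indices i, j in the formulas are the integer gray values 1..Ng;
run lengths / zone sizes / dependence sizes are 1..N.
"""

from __future__ import annotations

import numpy as np

from .matrices import TextureMatrixSet

GLCM_NAMES = (
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "JointEnergy",
    "JointEntropy",
    "Imc1",
    "Imc2",
    "Idm",
    "Idmn",
    "Id",
    "Idn",
    "InverseVariance",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
    "MCC",
)

GLRLM_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

GLDM_NAMES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

TEXTURE_NAMES = (
    tuple(f"glcm_{n}" for n in GLCM_NAMES)
    + tuple(f"glrlm_{n}" for n in GLRLM_NAMES)
    + tuple(f"glszm_{n}" for n in GLSZM_NAMES)
    + tuple(f"gldm_{n}" for n in GLDM_NAMES)
    + tuple(f"ngtdm_{n}" for n in NGTDM_NAMES)
)

_EPS = np.finfo(np.float64).tiny


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _glcm_single(p: np.ndarray) -> dict[str, float]:
    """Features of one normalized symmetric GLCM (sums to 1)."""
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float(np.sum(i * px))
    uy = float(np.sum(i * py))
    sx = float(np.sqrt(np.sum((i - ux) ** 2 * px)))
    sy = float(np.sqrt(np.sum((i - uy) ** 2 * py)))
    # sum / difference distributions
    ksum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    kdiff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    sums = (ii + jj - 2).astype(int)
    diffs = np.abs(ii - jj).astype(int)
    np.add.at(p_sum, sums.ravel(), p.ravel())
    np.add.at(p_diff, diffs.ravel(), p.ravel())
    hx = float(-np.sum(_xlog2(px)))
    hy = float(-np.sum(_xlog2(py)))
    hxy = float(-np.sum(_xlog2(p)))
    pxy = np.outer(px, py)
    nzj = (p > 0) & (pxy > 0)
    hxy1 = float(-np.sum(p[nzj] * np.log2(pxy[nzj])))
    nz2 = pxy > 0
    hxy2 = float(-np.sum(pxy[nz2] * np.log2(pxy[nz2])))
    da = float(np.sum(kdiff * p_diff))
    autoc = float(np.sum(ii * jj * p))
    corr = 0.0 if sx * sy == 0 else float((autoc - ux * uy) / (sx * sy))
    imc1 = 0.0 if max(hx, hy) == 0 else float((hxy - hxy1) / max(hx, hy))
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    offdiag = diffs > 0
    mcc = _glcm_mcc(p, px, py)
    return {
        "Autocorrelation": autoc,
        "JointAverage": ux,
        "ClusterProminence": float(np.sum((ii + jj - ux - uy) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - ux - uy) ** 3 * p)),
        "ClusterTendency": float(np.sum((ii + jj - ux - uy) ** 2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-np.sum(_xlog2(p_diff))),
        "DifferenceVariance": float(np.sum((kdiff - da) ** 2 * p_diff)),
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + (ii - jj) ** 2 / ng**2))),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "InverseVariance": float(np.sum(p[offdiag] / (ii - jj)[offdiag] ** 2)),
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(ksum * p_sum)),
        "SumEntropy": float(-np.sum(_xlog2(p_sum))),
        "SumSquares": float(sx**2),
        "MCC": mcc,
    }


def _glcm_mcc(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    """Maximal correlation coefficient: sqrt of the 2nd-largest eigenvalue of Q."""
    present = px > 0
    if present.sum() < 2:
        return 1.0
    psub = p[np.ix_(present, present)]
    pxs = px[present]
    pys = py[present]
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
    q = (psub / pxs[:, None]) @ (psub.T / pys[:, None])
    ev = np.sort(np.abs(np.linalg.eigvals(q)))
    return float(np.sqrt(max(0.0, ev[-2].real)))


def glcm_features(glcm: np.ndarray) -> dict[str, float]:
    """Average the 24 single-matrix features over the 13 directions."""
    acc: dict[str, list[float]] = {n: [] for n in GLCM_NAMES}
    for k in range(glcm.shape[0]):
        total = glcm[k].sum()
        if total == 0:
            continue  # degenerate direction: no voxel pair
        single = _glcm_single(glcm[k] / total)
        for name, v in single.items():
            acc[name].append(v)
    return {
        n: (float(np.mean(vs)) if vs else 0.0) for n, vs in acc.items()
    }


def _size_family(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    """Shared formulas of the GLRLM/GLSZM family on one (Ng x Nsize) matrix.

    Returns values keyed by role; callers rename to family-specific names.
    """
    ng, ns = mat.shape
    i = np.arange(1, ng + 1, dtype=np.float64)
    j = np.arange(1, ns + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    nz = float(mat.sum())
    if nz == 0:
        return {k: 0.0 for k in (
            "small", "large", "gln", "glnn", "sn", "snn", "pct", "glv", "sv",
            "entropy", "lgl", "hgl", "small_lgl", "small_hgl", "large_lgl", "large_hgl",
        )}
    p = mat / nz
    mu_i = float(np.sum(ii * p))
    mu_j = float(np.sum(jj * p))
    margin_i = mat.sum(axis=1)
    margin_j = mat.sum(axis=0)
    return {
        "small": float(np.sum(mat / jj**2) / nz),
        "large": float(np.sum(mat * jj**2) / nz),
        "gln": float(np.sum(margin_i**2) / nz),
        "glnn": float(np.sum(margin_i**2) / nz**2),
        "sn": float(np.sum(margin_j**2) / nz),
        "snn": float(np.sum(margin_j**2) / nz**2),
        "pct": float(nz / n_voxels),
        "glv": float(np.sum((ii - mu_i) ** 2 * p)),
        "sv": float(np.sum((jj - mu_j) ** 2 * p)),
        "entropy": float(-np.sum(_xlog2(p))),
        "lgl": float(np.sum(mat / ii**2) / nz),
        "hgl": float(np.sum(mat * ii**2) / nz),
        "small_lgl": float(np.sum(mat / (ii**2 * jj**2)) / nz),
        "small_hgl": float(np.sum(mat * ii**2 / jj**2) / nz),
        "large_lgl": float(np.sum(mat * jj**2 / ii**2) / nz),
        "large_hgl": float(np.sum(mat * ii**2 * jj**2) / nz),
    }


_RUN_KEYS = (
    "small", "large", "gln", "glnn", "sn", "snn", "pct", "glv", "sv", "entropy",
    "lgl", "hgl", "small_lgl", "small_hgl", "large_lgl", "large_hgl",
)


def glrlm_features(glrlm: np.ndarray, n_voxels: int) -> dict[str, float]:
    """16 run-length features averaged over the 13 directions."""
    acc: dict[str, list[float]] = {k: [] for k in _RUN_KEYS}
    for k in range(glrlm.shape[0]):
        if glrlm[k].sum() == 0:
            continue
        vals = _size_family(glrlm[k], n_voxels)
        for key in _RUN_KEYS:
            acc[key].append(vals[key])
    mean = {k: (float(np.mean(v)) if v else 0.0) for k, v in acc.items()}
    return dict(zip(GLRLM_NAMES, (mean[k] for k in _RUN_KEYS)))


def glszm_features(glszm: np.ndarray, n_voxels: int) -> dict[str, float]:
    vals = _size_family(glszm, n_voxels)
    return dict(zip(GLSZM_NAMES, (vals[k] for k in _RUN_KEYS)))


def gldm_features(gldm: np.ndarray, n_voxels: int) -> dict[str, float]:
    """14 dependence features (no normalized gray-level non-uniformity)."""
    v = _size_family(gldm, n_voxels)
    return {
        "SmallDependenceEmphasis": v["small"],
        "LargeDependenceEmphasis": v["large"],
        "GrayLevelNonUniformity": v["gln"],
        "DependenceNonUniformity": v["sn"],
        "DependenceNonUniformityNormalized": v["snn"],
        "GrayLevelVariance": v["glv"],
        "DependenceVariance": v["sv"],
        "DependenceEntropy": v["entropy"],
        "LowGrayLevelEmphasis": v["lgl"],
        "HighGrayLevelEmphasis": v["hgl"],
        "SmallDependenceLowGrayLevelEmphasis": v["small_lgl"],
        "SmallDependenceHighGrayLevelEmphasis": v["small_hgl"],
        "LargeDependenceLowGrayLevelEmphasis": v["large_lgl"],
        "LargeDependenceHighGrayLevelEmphasis": v["large_hgl"],
    }


def ngtdm_features(ngtdm: np.ndarray) -> dict[str, float]:
    """Coarseness, Contrast, Busyness, Complexity, Strength."""
    n_i = ngtdm[:, 0]
    p_i = ngtdm[:, 1]
    s_i = ngtdm[:, 2]
    present = p_i > 0
    i = np.arange(1, ngtdm.shape[0] + 1, dtype=np.float64)
    nvp = float(n_i.sum())
    ngp = int(present.sum())
    ps = float(np.sum(p_i * s_i))
    coarseness = 1e6 if ps == 0 else float(1.0 / ps)
    if ngp > 1 and nvp > 0:
        ip = i[present]
        pp = p_i[present]
        contrast = float(
            np.sum(np.outer(pp, pp) * (ip[:, None] - ip[None, :]) ** 2)
            / (ngp * (ngp - 1))
            * (s_i.sum() / nvp)
        )
    else:
        contrast = 0.0
    if ngp > 0 and nvp > 0:
        ip = i[present]
        pp = p_i[present]
        sp = s_i[present]
        denom = float(np.sum(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :])))
        busyness = 0.0 if denom == 0 else float(ps / denom)
        pairsum = pp[:, None] + pp[None, :]
        complexity = float(
            np.sum(
                np.abs(ip[:, None] - ip[None, :])
                * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
                / pairsum
            )
            / nvp
        )
        ssum = float(s_i.sum())
        strength = (
            0.0
            if ssum == 0
            else float(np.sum(pairsum * (ip[:, None] - ip[None, :]) ** 2) / ssum)
        )
    else:
        busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


def texture_features(matrices: TextureMatrixSet) -> dict[str, float]:
    """All 75 texture features, keyed 'family_Feature'."""
    out: dict[str, float] = {}
    out.update({f"glcm_{k}": v for k, v in glcm_features(matrices.glcm).items()})
    out.update(
        {f"glrlm_{k}": v for k, v in glrlm_features(matrices.glrlm, matrices.n_voxels).items()}
    )
    out.update(
        {f"glszm_{k}": v for k, v in glszm_features(matrices.glszm, matrices.n_voxels).items()}
    )
    out.update(
        {f"gldm_{k}": v for k, v in gldm_features(matrices.gldm, matrices.n_voxels).items()}
    )
    out.update({f"ngtdm_{k}": v for k, v in ngtdm_features(matrices.ngtdm).items()})
    return out
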