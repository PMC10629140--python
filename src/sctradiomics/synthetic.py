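"""Seeded paired-phantom cohort generator.

Each phantom is a head-like HU volume: an ellipsoidal body of soft tissue
(~40 HU) wrapped in a bone shell, surrounded by air (~-1000 HU), with six
anatomical ROIs (GTVnx, brainstem, both parotids, both temporal lobes) plus
the body contour.  The tumor ROI is deliberately heterogeneous — by default
8% air pockets, 63% soft tissue and 29% bone, assigned by quantiles of a
smooth random field so the fractions are met almost exactly and the classes
are spatially coherent.

"Synthetic CT" images are produced by parametric degradation operators
(blur, bone remap, additive noise, optional boundary artifact) standing in
for two synthesis-model error styles: one that over-smooths and attenuates
bone, and one that is sharper but noisier with residual boundary structure.

Randomness: one master seed; per-subject, per-operator substreams come from
``numpy.random.SeedSequence(master_seed, spawn_key=(subject_index, op))``,
so adding a subject never perturbs earlier subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import GeometryError
from .volume import CohortManifest, ImageVolume, PatientCase, RoiMask


def _default_rois() -> dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]]:
    # name -> (center, radii) in voxel units on the default 64^3 grid
    return {
        "GTVnx": ((36.0, 38.0, 32.0), (6.0, 7.0, 7.0)),
        "brainstem": ((30.0, 26.0, 32.0), (5.0, 5.0, 5.0)),
        "parotid_l": ((38.0, 34.0, 17.0), (5.0, 5.0, 4.0)),
        "parotid_r": ((38.0, 34.0, 47.0), (5.0, 5.0, 4.0)),
        "temporal_lobe_l": ((24.0, 32.0, 18.0), (6.0, 6.0, 5.0)),
        "temporal_lobe_r": ((24.0, 32.0, 46.0), (6.0, 6.0, 5.0)),
    }


@dataclass
class PhantomSpec:
    """Geometry and tissue parameters of the head phantom."""

    grid: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    air_hu: float = -1000.0
    soft_hu: float = 40.0
    bone_hu: float = 700.0
    soft_texture_sd: float = 25.0  # smooth intra-tissue variation (HU)
    noise_sd: float = 10.0  # fine-grained acquisition noise (HU)
    subject_hu_jitter: float = 30.0  # per-subject shift of tissue means (HU)
    subject_geom_jitter: float = 1.5  # per-subject ROI center/radius jitter (voxels)
    body_radii: tuple[float, float, float] = (29.0, 28.0, 27.0)
    shell_thickness: float = 3.0  # bone shell (voxels)
    rois: dict = field(default_factory=_default_rois)
    gtv_composition: tuple[float, float, float] = (0.08, 0.63, 0.29)  # air/soft/bone
    gtv_air_hu: float = -900.0
    gtv_bone_hu: float = 500.0

    def __post_init__(self):
        frac = np.asarray(self.gtv_composition, dtype=float)
        if np.any(frac < 0) or abs(frac.sum() - 1.0) > 1e-9:
            raise ValueError("gtv_composition must be non-negative and sum to 1")


@dataclass
class DegradationSpec:
    """Parametric error model standing in for one synthesis network."""

    model_name: str
    blur_sigma: float = 0.0  # mm
    noise_sigma: float = 0.0  # HU
    bone_scale: float = 1.0  # multiplicative remap of bone voxels
    boundary_artifact: bool = False
    bone_threshold: float = 150.0  # HU, on the pre-degradation image
    boundary_strength: float = 40.0  # HU per unit normalized gradient

    def __post_init__(self):
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        if self.bone_scale <= 0:
            raise ValueError("bone_scale must be positive")


def default_degradations() -> tuple[DegradationSpec, DegradationSpec]:
    """The two stock degradation styles used for cross-model analyses.

    ``smoothnet`` over-smooths and strongly attenuates bone (supervised-
    style error); ``cyclesim`` is sharper but noisier, attenuates bone less,
    and retains boundary structure from the source modality.
    """
    return (
        DegradationSpec(
            "smoothnet", blur_sigma=1.2, noise_sigma=15.0, bone_scale=0.85
        ),
        DegradationSpec(
            "cyclesim",
            blur_sigma=0.5,
            noise_sigma=30.0,
            bone_scale=0.92,
            boundary_artifact=True,
        ),
    )


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _ellipsoid(shape, center, radii) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    ) <= 1.0


def _smooth_field(rng: np.random.Generator, shape, sigma_vox: float = 3.0) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_phantom(spec: PhantomSpec, seed) -> PatientCase:
    """One subject's real CT plus body and ROI masks (no synthetics yet).

    Deterministic for fixed (spec, seed).  Raises GeometryError if any ROI
    or the body cannot fit the grid.
    """
    rng = np.random.default_rng(_as_seedseq(seed))
    shape = tuple(int(n) for n in spec.grid)
    center = tuple((n - 1) / 2.0 for n in shape)

    for ax in range(3):
        if spec.body_radii[ax] >= shape[ax] / 2.0 - 1.0:
            raise GeometryError(
                f"body radius {spec.body_radii[ax]} does not fit grid axis {ax}"
            )

    # per-subject tissue means and geometry jitter
    soft_mu = spec.soft_hu + rng.normal(0, spec.subject_hu_jitter)
    bone_mu = spec.bone_hu + rng.normal(0, 3.0 * spec.subject_hu_jitter)
    body_radii = tuple(
        min(r + rng.normal(0, spec.subject_geom_jitter), shape[ax] / 2.0 - 1.0)
        for ax, r in enumerate(spec.body_radii)
    )

    body = _ellipsoid(shape, center, body_radii)
    inner = _ellipsoid(
        shape, center, tuple(r - spec.shell_thickness for r in body_radii)
    )
    shell = body & ~inner

    texture = _smooth_field(rng, shape) * spec.soft_texture_sd
    noise = rng.normal(0, spec.noise_sd, shape)

    vol = np.full(shape, spec.air_hu, dtype=np.float64)
    vol[inner] = soft_mu
    vol[shell] = bone_mu
    vol += texture * body  # intra-tissue variation only inside the body
    vol += noise

    masks: dict[str, RoiMask] = {"body": RoiMask(body, "body", spec.spacing)}
    for name, (c0, r0) in spec.rois.items():
        c = tuple(v + rng.normal(0, spec.subject_geom_jitter) for v in c0)
        r = tuple(
            max(1.5, v + rng.normal(0, 0.5 * spec.subject_geom_jitter)) for v in r0
        )
        for ax in range(3):
            if c[ax] - r[ax] < 0 or c[ax] + r[ax] > shape[ax] - 1:
                raise GeometryError(
                    f"ROI '{name}' (center {c}, radii {r}) does not fit grid {shape}"
                )
        roi = _ellipsoid(shape, c, r)
        if not np.all(inner[roi]):
            # keep organs strictly inside the soft-tissue compartment
            roi &= inner
        if roi.sum() == 0:
            raise GeometryError(f"ROI '{name}' is empty after clipping to the body")
        masks[name] = RoiMask(roi, name, spec.spacing)

    # heterogeneous tumor: quantile-partition a smooth field into air/soft/bone
    gtv = masks["GTVnx"].values
    n_gtv = int(gtv.sum())
    comp_field = _smooth_field(rng, shape, sigma_vox=1.5)[gtv]
    order = np.argsort(comp_field, kind="stable")
    f_air, f_soft, _ = spec.gtv_composition
    n_air = int(round(f_air * n_gtv))
    n_soft = int(round(f_soft * n_gtv))
    cls = np.full(n_gtv, 2, dtype=np.int8)  # bone
    cls[order[:n_air]] = 0  # air pockets
    cls[order[n_air : n_air + n_soft]] = 1  # soft tissue
    gtv_vals = vol[gtv]
    gtv_vals[cls == 0] = spec.gtv_air_hu + rng.normal(0, 30.0, int((cls == 0).sum()))
    gtv_vals[cls == 1] = soft_mu + rng.normal(0, spec.noise_sd, int((cls == 1).sum()))
    gtv_vals[cls == 2] = spec.gtv_bone_hu + rng.normal(
        0, 4.0 * spec.noise_sd, int((cls == 2).sum())
    )
    vol[gtv] = gtv_vals

    case = PatientCase(
        subject_id="phantom",
        real=ImageVolume(vol, spec.spacing),
        synthetic={},
        masks=masks,
    )
    return case


def gtv_class_fractions(case: PatientCase, spec: PhantomSpec) -> tuple[float, float, float]:
    """Measured (air, soft, bone) voxel fractions inside the tumor ROI."""
    gtv = case.masks["GTVnx"].values
    vals = case.real.values[gtv]
    air = float(np.mean(vals < -400))
    bone = float(np.mean(vals > 250))
    return air, 1.0 - air - bone, bone


def degrade(
    real: ImageVolume,
    masks: dict[str, RoiMask],
    spec: DegradationSpec,
    seed=0,
) -> ImageVolume:
    """Apply one degradation style to a real image.

    Order: Gaussian blur -> multiplicative bone remap (bone classified on
    the pre-degradation image at ``bone_threshold``) -> additive Gaussian
    noise -> optional boundary artifact (adds back a scaled gradient-
    magnitude map, emulating residual source-modality edges).  The
    degradation acts inside the body mask; surrounding air is untouched.
    Deterministic for fixed seed.
    """
    rng = np.random.default_rng(_as_seedseq(seed))
    x = real.values.copy()
    body = masks["body"].values if "body" in masks else np.ones(x.shape, bool)
    bone = (real.values > spec.bone_threshold) & body
    out = x.copy()
    if spec.blur_sigma > 0:
        sig_vox = tuple(spec.blur_sigma / s for s in real.spacing)
        out = ndimage.gaussian_filter(x, sig_vox)
    if spec.bone_scale != 1.0:
        out[bone] = out[bone] * spec.bone_scale
    if spec.noise_sigma > 0:
        out = out + rng.normal(0, spec.noise_sigma, x.shape) * body
    if spec.boundary_artifact:
        grad = np.sqrt(sum(np.gradient(real.values, axis=a) ** 2 for a in range(3)))
        gmax = grad.max()
        if gmax > 0:
            out = out + spec.boundary_strength * (grad / gmax) * body
    return real.with_values(out)


def generate_cohort(
    n_subjects: int,
    spec: PhantomSpec | None = None,
    degradations: tuple[DegradationSpec, ...] | None = None,
    master_seed: int = 0,
) -> CohortManifest:
    """A cohort of paired cases: real + one synthetic per degradation spec."""
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    spec = spec or PhantomSpec()
    degradations = degradations if degradations is not None else default_degradations()
    cases = []
    for k in range(n_subjects):
        sub_seed = np.random.SeedSequence(master_seed, spawn_key=(k, 0))
        case = generate_phantom(spec, sub_seed)
        case.subject_id = f"subj{k:03d}"
        for j, dspec in enumerate(degradations):
            dseed = np.random.SeedSequence(master_seed, spawn_key=(k, 1 + j))
            case.synthetic[dspec.model_name] = degrade(case.real, case.masks, dspec, dseed)
        cases.append(case)
    roi_names = ["body"] + list(spec.rois)
    return CohortManifest(cases, roi_names, [d.model_name for d in degradations])


def identity_degradations() -> tuple[DegradationSpec, ...]:
    """Zero-strength degradations: the synthetic images equal the real ones."""
    return (
        DegradationSpec("identityA"),
        DegradationSpec("identityB"),
    )


def noise_only(model_name: str, sigma: float) -> DegradationSpec:
    """Pure additive-noise degradation (used for calibration sweeps)."""
    return DegradationSpec(model_name, noise_sigma=sigma)


def analytic_ccc_fixture(
    n: int, sigma_x: float, sigma_e: float, seed=0, mu: float = 0.0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Paired samples with a known population CCC.

    x ~ Normal(mu, sigma_x^2), y = x + Normal(0, sigma_e^2); the population
    concordance is 2 sigma_x^2 / (2 sigma_x^2 + sigma_e^2).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if sigma_x < 0 or sigma_e < 0:
        raise ValueError("sigmas must be >= 0")
    rng = np.random.default_rng(_as_seedseq(seed))
    x = mu + rng.normal(0, sigma_x, n)
    y = x + rng.normal(0, sigma_e, n)
    denom = 2 * sigma_x**2 + sigma_e**2
    pop = 1.0 if denom == 0 else 2 * sigma_x**2 / denom
    return x, y, pop
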