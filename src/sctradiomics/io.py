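"""Volume/mask I/O (NIfTI, NRRD) and cohort manifests (JSON/YAML).

SimpleITK handles both on-disk formats.  SimpleITK stores spacing/origin in
``(x, y, z)`` order while its arrays come back ``(z, y, x)``; metadata is
reversed here so everything in memory follows the package's
``(slice, row, column)`` convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import yaml

from .errors import DimensionalityError, FormatError, GeometryError
from .volume import CohortManifest, ImageVolume, PatientCase, RoiMask

_SUPPORTED = (".nii", ".nii.gz", ".nrrd")


def _check_extension(path: Path):
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in _SUPPORTED):
        raise FormatError(f"unsupported volume format: {path.name} (use .nii/.nii.gz/.nrrd)")


def read_volume(path) -> ImageVolume:
    """Read a 3-D volume from NIfTI or NRRD."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    _check_extension(path)
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # SimpleITK raises RuntimeError on bad payloads
        raise FormatError(f"could not read {path}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 3:
        raise DimensionalityError(
            f"{path} holds a {arr.ndim}-D payload; a 3-D volume is required"
        )
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return ImageVolume(np.asarray(arr, dtype=np.float64), spacing, origin)


def write_volume(volume: ImageVolume, path) -> None:
    """Write a volume to NIfTI or NRRD (chosen by extension)."""
    path = Path(path)
    _check_extension(path)
    img = sitk.GetImageFromArray(volume.values)
    img.SetSpacing(tuple(reversed(volume.spacing)))
    img.SetOrigin(tuple(reversed(volume.origin)))
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))


def read_mask(path, roi_name: str) -> RoiMask:
    vol = read_volume(path)
    return RoiMask(vol.values, roi_name, vol.spacing)


def write_mask(mask: RoiMask, path) -> None:
    write_volume(
        ImageVolume(mask.values.astype(np.uint8), mask.spacing), path
    )


def read_manifest(path) -> CohortManifest:
    """Load a cohort manifest (JSON or YAML) and all volumes it references.

    Schema::

        {"cases": [{"subject_id": ..., "real": path,
                    "synthetic": {model: path}, "masks": {roi: path}}],
         "roi_names": [...], "model_names": [...]}

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    base = path.parent
    cases = []
    for entry in doc["cases"]:
        real = read_volume(base / entry["real"])
        synthetic = {m: read_volume(base / p) for m, p in entry["synthetic"].items()}
        masks = {r: read_mask(base / p, r) for r, p in entry["masks"].items()}
        cases.append(PatientCase(entry["subject_id"], real, synthetic, masks))
    roi_names = doc.get("roi_names") or sorted({r for c in cases for r in c.roi_names})
    model_names = doc.get("model_names") or sorted(
        {m for c in cases for m in c.model_names}
    )
    for c in cases:
        missing_roi = set(roi_names) - set(c.roi_names)
        missing_model = set(model_names) - set(c.model_names)
        if missing_roi or missing_model:
            raise GeometryError(
                f"case {c.subject_id} missing ROIs {sorted(missing_roi)} "
                f"or models {sorted(missing_model)}"
            )
    return CohortManifest(cases, list(roi_names), list(model_names))


def write_cohort(cohort: CohortManifest, out_dir) -> Path:
    """Write every volume/mask of a cohort as NIfTI plus a JSON manifest.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for case in cohort.cases:
        cdir = out_dir / case.subject_id
        entry = {
            "subject_id": case.subject_id,
            "real": f"{case.subject_id}/real.nii.gz",
            "synthetic": {},
            "masks": {},
        }
        write_volume(case.real, cdir / "real.nii.gz")
        for model, vol in case.synthetic.items():
            rel = f"{case.subject_id}/syn_{model}.nii.gz"
            write_volume(vol, out_dir / rel)
            entry["synthetic"][model] = rel
        for roi, mask in case.masks.items():
            rel = f"{case.subject_id}/mask_{roi}.nii.gz"
            write_mask(mask, out_dir / rel)
            entry["masks"][roi] = rel
        entries.append(entry)
    manifest = {
        "cases": entries,
        "roi_names": cohort.roi_names,
        "model_names": cohort.model_names,
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath
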