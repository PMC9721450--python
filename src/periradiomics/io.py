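"""File formats: images, masks, datasets, feature tables, configs.

Images are written as 16-bit PNG (or TIFF), masks as 8-bit 0/255 PNG;
NIfTI masks and DICOM images are read when given. A dataset directory
holds ``images/``, ``masks/`` and a ``metadata.csv`` manifest with one
row per (patient, view). Every derived output gets a JSON sidecar
naming the config hash and seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .phantom import LesionMask, MammogramImage, PhantomCase, PhantomConfig

__all__ = [
    "read_image", "write_image", "read_mask", "write_mask",
    "save_dataset", "load_dataset", "save_config", "load_config",
    "config_hash", "write_sidecar", "check_lineage",
]


def read_image(path) -> np.ndarray:
    """Read a 2D grayscale image: PNG/TIFF via imageio, DICOM via
    pydicom, NIfTI via nibabel."""
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith(".dcm"):
        import pydicom
        return pydicom.dcmread(path).pixel_array.astype(float)
    if ".nii" in suffix:
        import nibabel as nib
        return np.asarray(nib.load(path).dataobj, dtype=float).squeeze()
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse any accidental colour axis
        arr = arr[..., 0]
    return arr.astype(float)


def write_image(path, pixels) -> None:
    arr = np.clip(np.asarray(pixels), 0, 65535).astype(np.uint16)
    iio.imwrite(Path(path), arr)


def read_mask(path) -> np.ndarray:
    return read_image(path) > 0


def write_mask(path, mask) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

def save_dataset(cases: list[PhantomCase], outdir) -> Path:
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        img, mask = case.image, case.mask
        stem = f"{img.patient_id}_{img.view}"
        img_path = f"images/{stem}.png"
        mask_path = f"masks/{stem}_mask.png"
        write_image(outdir / img_path, img.pixels)
        write_mask(outdir / mask_path, mask.pixels)
        rows.append({
            "patient_id": img.patient_id, "view": img.view,
            "label": img.label, "spacing_mm": img.spacing_mm[0],
            "mass_diameter_mm": case.mass_diameter_mm,
            "image_path": img_path, "mask_path": mask_path,
        })
    pd.DataFrame(rows).to_csv(outdir / "metadata.csv", index=False)
    return outdir / "metadata.csv"


def load_dataset(directory) -> list[PhantomCase]:
    directory = Path(directory)
    meta = pd.read_csv(directory / "metadata.csv")
    cases = []
    for row in meta.itertuples():
        pixels = read_image(directory / row.image_path)
        mask = read_mask(directory / row.mask_path)
        image = MammogramImage(
            pixels=pixels, spacing_mm=(row.spacing_mm, row.spacing_mm),
            patient_id=str(row.patient_id), view=row.view,
            label=int(row.label))
        lesion = LesionMask(mask, f"{row.patient_id}_{row.view}")
        cases.append(PhantomCase(
            image, lesion, breast_support=None, body_support=None,
            mass_diameter_mm=float(getattr(row, "mass_diameter_mm", 0.0))))
    return cases


# ---------------------------------------------------------------------------
# configs and provenance
# ---------------------------------------------------------------------------

def save_config(config, path) -> None:
    data = asdict(config) if not isinstance(config, dict) else config
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_config(path, cls=PhantomConfig):
    data = yaml.safe_load(Path(path).read_text())
    for k, v in data.items():  # yaml reads tuples back as lists
        if isinstance(v, list):
            data[k] = tuple(v)
    return cls(**data)


def config_hash(config) -> str:
    data = asdict(config) if not isinstance(config, dict) else config
    canon = json.dumps(data, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_sidecar(path, *, config=None, seed=None, stage=None, extra=None):
    """JSON provenance sidecar next to an output file."""
    doc = {"stage": stage, "seed": seed}
    if config is not None:
        doc["config_hash"] = config_hash(config)
    if extra:
        doc.update(extra)
    side = Path(str(path) + ".meta.json")
    side.write_text(json.dumps(doc, indent=2, default=str))
    return side


def check_lineage(path, stage: str) -> None:
    """Raise a clear error when a prerequisite stage output is absent."""
    if not Path(path).exists():
        raise FileNotFoundError(
            f"missing {path}; run the '{stage}' stage first")
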