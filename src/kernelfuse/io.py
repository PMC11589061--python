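"""Readers and writers: NIfTI (canonical), DICOM (read-only), YAML configs.

NIfTI is the interchange format for synthetic and processed series; HU are
stored as signed 16-bit with unit scale by default (float32 is available for
exact round-trips of un-quantized data), with the pixel spacing and slice
thickness in the header zooms. DICOM stacks are read with the rescale
slope/intercept applied and slices sorted by position; DICOM writing is out
of scope.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np

from .image import CTImage

__all__ = ["read_series", "write_series", "read_dicom_stack", "load_yaml", "dump_yaml"]


def write_series(image: CTImage | list[CTImage], path, dtype: str = "int16") -> Path:
    """Write one slice (2D) or an aligned stack (3D) to NIfTI.

    ``dtype`` "int16" stores rounded HU at unit scale (the 16-bit signed
    range must contain all values); "float32" stores them exactly.
    """
    import nibabel as nib

    path = Path(path)
    images = [image] if isinstance(image, CTImage) else list(image)
    if any(im.shape != images[0].shape or im.spacing != images[0].spacing
           for im in images):
        raise ValueError("stack slices must share grid and spacing")
    data = np.stack([im.pixels for im in images], axis=-1)
    if dtype == "int16":
        if data.min() < -32768 or data.max() > 32767:
            raise ValueError("HU outside the signed 16-bit range")
        data = np.round(data).astype(np.int16)
    elif dtype == "float32":
        data = data.astype(np.float32)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    ref = images[0]
    affine = np.diag([ref.spacing, ref.spacing, ref.thickness, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((ref.spacing, ref.spacing, ref.thickness))
    nib.save(img, str(path))
    return path


def read_series(path, thickness: float | None = None) -> list[CTImage]:
    """Read a NIfTI file (or DICOM directory) back into a list of CTImages."""
    path = Path(path)
    if path.is_dir():
        return read_dicom_stack(path)
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 2:
        data = data[..., None]
    zooms = img.header.get_zooms()
    spacing = float(zooms[0])
    if abs(zooms[1] - spacing) > 1e-6:
        raise ValueError("anisotropic in-plane spacing is not supported")
    thick = thickness if thickness is not None else float(zooms[2]) if len(zooms) > 2 else 1.0
    return [CTImage(data[..., k], spacing=spacing, thickness=thick)
            for k in range(data.shape[-1])]


def read_dicom_stack(path) -> list[CTImage]:
    """Read a directory of DICOM slices, HU-rescaled and sorted by position."""
    import pydicom

    files = sorted(p for p in Path(path).iterdir() if p.suffix.lower() in (".dcm", ".ima", ""))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {path}")
    slices = []
    for f in files:
        ds = pydicom.dcmread(str(f))
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError(f"{f.name}: missing rescale slope/intercept tags")
        hu = ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope) + float(
            ds.RescaleIntercept)
        spacing = tuple(float(s) for s in ds.PixelSpacing)
        if abs(spacing[0] - spacing[1]) > 1e-6:
            raise ValueError(f"{f.name}: anisotropic pixel spacing unsupported")
        zpos = float(getattr(ds, "ImagePositionPatient", (0, 0, 0))[2])
        thick = float(getattr(ds, "SliceThickness", 1.0))
        slices.append((zpos, CTImage(hu, spacing=spacing[0], thickness=thick,
                                     provenance="clinical")))
    slices.sort(key=lambda t: t[0])
    spacings = {im.spacing for _, im in slices}
    if len(spacings) > 1:
        raise ValueError(f"inconsistent pixel spacing across the stack: {sorted(spacings)}")
    return [im for _, im in slices]


# ---------------------------------------------------------------------------
# YAML configuration


def dump_yaml(obj, path) -> None:
    """Serialize a dataclass (or dict) to a YAML document."""
    import yaml

    data = asdict(obj) if hasattr(obj, "__dataclass_fields__") else obj
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_yaml(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)
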