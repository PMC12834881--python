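"""Readers and writers for image stacks.

Two on-disk forms are supported:

* a DICOM series — one file per axial slice; read-only input in the
  pipeline sense, though a minimal writer is provided so synthetic stacks
  can be exported for third-party tools. HU values are recovered with the
  rescale slope/intercept, slices are sorted by slice location, and
  in-plane pixel spacing must agree across the series;
* a raw fixture — a little-endian float32 binary of the voxel array next
  to a JSON sidecar carrying shape, spacing and metadata. Round-trips are
  bit-exact at float32 precision and exact when written from float32 data.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .stack import ImageStack

__all__ = ["read_stack", "write_raw", "read_raw", "write_dicom_series", "read_dicom_series"]

logger = logging.getLogger(__name__)

_CT_STORAGE = "1.2.840.10008.5.1.4.1.1.2"


def write_raw(stack: ImageStack, path: str | Path) -> Path:
    """Write ``<path>.raw`` (float32, C order) and ``<path>.json`` sidecar."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".json" else path
    raw_path = base.with_suffix(".raw")
    voxels = stack.voxels.astype("<f4")
    raw_path.write_bytes(voxels.tobytes())
    sidecar = {
        "shape": list(voxels.shape),
        "dtype": "<f4",
        "pixel_spacing_mm": stack.pixel_spacing,
        "slice_thickness_mm": stack.slice_thickness,
        "meta": _jsonable(stack.meta),
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return base.with_suffix(".json")


def read_raw(path: str | Path) -> ImageStack:
    path = Path(path)
    base = path.with_suffix("")
    sidecar = json.loads(base.with_suffix(".json").read_text())
    shape = tuple(sidecar["shape"])
    voxels = np.frombuffer(
        base.with_suffix(".raw").read_bytes(), dtype=sidecar.get("dtype", "<f4")
    ).reshape(shape)
    return ImageStack(
        voxels.astype(np.float64),
        pixel_spacing=float(sidecar["pixel_spacing_mm"]),
        slice_thickness=float(sidecar.get("slice_thickness_mm", 1.0)),
        meta=dict(sidecar.get("meta", {})),
    )


def write_dicom_series(stack: ImageStack, directory: str | Path) -> list[Path]:
    """Write one CT-like DICOM file per slice with spacing and location set."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    intercept, slope = -1024.0, 1.0
    stored = np.clip(np.round(stack.voxels - intercept), 0, 65535).astype(np.uint16)
    paths = []
    for k in range(stack.n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = _CT_STORAGE
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = _CT_STORAGE
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = stack.voxels.shape[1:]
        ds.PixelSpacing = [f"{stack.pixel_spacing:.6f}"] * 2
        ds.SliceThickness = f"{stack.slice_thickness:.6f}"
        z = k * stack.slice_thickness
        ds.SliceLocation = f"{z:.6f}"
        ds.ImagePositionPatient = ["0", "0", f"{z:.6f}"]
        ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
        ds.RescaleIntercept = f"{intercept:.1f}"
        ds.RescaleSlope = f"{slope:.1f}"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = stored[k].tobytes()
        path = directory / f"slice_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def read_dicom_series(directory: str | Path) -> ImageStack:
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    datasets = [pydicom.dcmread(p) for p in files]

    def _location(ds) -> float:
        if getattr(ds, "ImagePositionPatient", None) is not None:
            return float(ds.ImagePositionPatient[2])
        if getattr(ds, "SliceLocation", None) is not None:
            return float(ds.SliceLocation)
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=_location)
    spacings = {tuple(np.round(np.asarray(ds.PixelSpacing, float), 6)) for ds in datasets}
    if len(spacings) > 1:
        raise ValueError(f"mixed pixel spacing across slices: {sorted(spacings)}")
    (spacing_rc,) = spacings
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        intercept_attr = getattr(ds, "RescaleIntercept", None)
        if intercept_attr is None:
            logger.warning("missing rescale tags; assuming identity rescale")
            intercept = 0.0
        else:
            intercept = float(intercept_attr)
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    thickness = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)
    return ImageStack(
        np.stack(slices),
        pixel_spacing=float(spacing_rc[0]),
        slice_thickness=thickness,
    )


def read_stack(path: str | Path) -> ImageStack:
    """Read an image stack from a DICOM series directory or a raw fixture."""
    path = Path(path)
    if path.is_dir():
        return read_dicom_series(path)
    if path.suffix in (".json", ".raw") or path.with_suffix(".json").exists():
        return read_raw(path)
    raise FileNotFoundError(f"cannot interpret {path} as a DICOM series or raw fixture")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
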