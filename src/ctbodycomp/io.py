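"""Readers and writers for the pipeline's on-disk formats.

DICOM in/out goes through pydicom with RescaleSlope/RescaleIntercept
honoured in both directions (HU are kept float in memory and rounded to
integers on write).  ROI polygons travel as JSON vertex lists in 0-based
(row, col) pixel coordinates, ordered, first != last, closure implicit.
Tabular results are plain CSV with a schema/config comment in row 1.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .phantom import PhantomTruth
from .segmentation import CTSlice, ROISet

SCHEMA = "ctbodycomp/1"


def read_dicom_slice(path: str | Path) -> CTSlice:
    """Load one axial slice, applying slope/intercept to obtain HU."""
    ds = pydicom.dcmread(str(path))
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = ds.pixel_array.astype(float) * slope + intercept
    spacing = tuple(float(v) for v in ds.PixelSpacing)
    return CTSlice(
        pixels=hu,
        pixel_spacing=spacing,  # DICOM PixelSpacing is (row, col)
        slice_thickness=float(ds.SliceThickness),
        patient_id=str(getattr(ds, "PatientID", "")),
        acquisition={"source": str(path)},
    )


def write_dicom_slice(ct: CTSlice, path: str | Path) -> None:
    """Write a monochrome CT slice; HU rounded to int16, intercept -1024."""
    intercept = -1024.0
    raw = np.round(ct.pixels - intercept).astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    # UID derived from content identity so a fixed seed reproduces the
    # bundle byte for byte
    meta.MediaStorageSOPInstanceUID = generate_uid(
        entropy_srcs=[ct.patient_id, str(ct.shape), str(ct.pixel_spacing)]
    )
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.PatientID = ct.patient_id
    ds.PatientName = ct.patient_id
    ds.Rows, ds.Columns = ct.shape
    ds.PixelSpacing = [str(ct.pixel_spacing[0]), str(ct.pixel_spacing[1])]
    ds.SliceThickness = str(ct.slice_thickness)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = "1"
    ds.RescaleIntercept = str(intercept)
    ds.PixelData = raw.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def write_slice_npz(ct: CTSlice, path: str | Path) -> None:
    """Plain compressed-array export of the float HU raster."""
    np.savez_compressed(
        str(path),
        pixels=ct.pixels,
        pixel_spacing=np.asarray(ct.pixel_spacing),
        slice_thickness=ct.slice_thickness,
    )


def read_slice_npz(path: str | Path) -> CTSlice:
    with np.load(str(path)) as z:
        return CTSlice(
            pixels=z["pixels"],
            pixel_spacing=tuple(z["pixel_spacing"]),
            slice_thickness=float(z["slice_thickness"]),
        )


def write_rois(rois: ROISet, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"schema": SCHEMA, **rois.as_dict()}, indent=1))


def read_rois(path: str | Path) -> ROISet:
    d = json.loads(Path(path).read_text())
    return ROISet(**{
        k: [tuple(v) for v in d[k]] for k in ("roi_a", "roi_b", "roi_c", "roi_d")
    })


def write_truth(truth: PhantomTruth, path: str | Path) -> None:
    d = {
        "schema": SCHEMA,
        "pixel_area_mm2": truth.pixel_area_mm2,
        "ma_hu": truth.ma_hu,
        "sat_quantifiable": truth.sat_quantifiable,
        "per_roi": {
            k: {
                "fat_pixels": v.fat_pixels,
                "fat_area_cm2": v.fat_area_cm2,
                "muscle_pixels": v.muscle_pixels,
                "muscle_area_cm2": v.muscle_area_cm2,
            }
            for k, v in truth.per_roi.items()
        },
    }
    Path(path).write_text(json.dumps(d, indent=1))


def write_csv_with_header(df, path: str | Path, config_hash: str) -> None:
    """CSV with a first-row comment carrying schema + config hash."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# schema={SCHEMA} config={config_hash}\n")
        df.to_csv(fh, index=False)


def read_csv_with_header(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, comment="#")
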