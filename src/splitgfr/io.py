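"""Readers and writers: the array-container study format, DICOM NM series,
and CSV tables.

The array container is a single NumPy ``.npz`` archive holding the frame
stack, the two time arrays, every ROI mask (keys ``mask_<role>``) and a
JSON sidecar string (key ``meta_json``) with the biometrics, injection,
plasma and truth fields.  Arrays round-trip bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    DynamicRenogram,
    InjectionRecord,
    PatientBiometrics,
    PlasmaStudy,
    RaterTable,
    RoiSet,
)

__all__ = [
    "StudyBundle",
    "save_study",
    "load_study",
    "read_dicom_renogram",
    "write_dicom_renogram",
    "read_rater_table_csv",
    "write_rater_table_csv",
]


@dataclasses.dataclass
class StudyBundle:
    """Everything one patient study carries, as read from a container."""

    renogram: DynamicRenogram
    rois: Optional[RoiSet] = None
    biometrics: Optional[PatientBiometrics] = None
    injection: Optional[InjectionRecord] = None
    plasma: Optional[PlasmaStudy] = None
    truth: Optional[dict] = None


def _meta_or_none(cls, d: Optional[dict]):
    return cls(**d) if d is not None else None


def save_study(
    path,
    renogram: DynamicRenogram,
    rois: Optional[RoiSet] = None,
    biometrics: Optional[PatientBiometrics] = None,
    injection: Optional[InjectionRecord] = None,
    plasma: Optional[PlasmaStudy] = None,
    truth: Optional[dict] = None,
) -> None:
    """Write a study to the single-archive container format."""
    arrays = {
        "frames": renogram.frames,
        "frame_start_s": renogram.frame_start_s,
        "frame_duration_s": renogram.frame_duration_s,
    }
    if rois is not None:
        for role, mask in rois.masks.items():
            arrays[f"mask_{role}"] = mask
    meta = {
        "detector": renogram.detector,
        "biometrics": dataclasses.asdict(biometrics) if biometrics else None,
        "injection": dataclasses.asdict(injection) if injection else None,
        "plasma": dataclasses.asdict(plasma) if plasma else None,
        "truth": truth,
    }
    arrays["meta_json"] = np.array(json.dumps(meta))
    np.savez_compressed(path, **arrays)


def load_study(path) -> StudyBundle:
    """Read a study container written by :func:`save_study`."""
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta_json"]))
        renogram = DynamicRenogram(
            frames=npz["frames"],
            frame_start_s=npz["frame_start_s"],
            frame_duration_s=npz["frame_duration_s"],
            detector=meta.get("detector", "posterior"),
        )
        masks = {
            key[len("mask_"):]: npz[key] for key in npz.files if key.startswith("mask_")
        }
    return StudyBundle(
        renogram=renogram,
        rois=RoiSet(masks=masks) if masks else None,
        biometrics=_meta_or_none(PatientBiometrics, meta.get("biometrics")),
        injection=_meta_or_none(InjectionRecord, meta.get("injection")),
        plasma=_meta_or_none(PlasmaStudy, meta.get("plasma")),
        truth=meta.get("truth"),
    )


# --------------------------------------------------------------------------
# DICOM nuclear-medicine multi-frame series


def read_dicom_renogram(path, detector: str = "posterior") -> DynamicRenogram:
    """Read a multi-frame dynamic NM series into a :class:`DynamicRenogram`.

    Frame durations come from the per-frame Frame Time Vector
    (0018,1065, ms) when present, else from a constant Frame Time
    (0018,1063); frame starts are the cumulative durations with t = 0 at
    the first frame.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    frames = ds.pixel_array
    if frames.ndim == 2:
        frames = frames[None]
    n = frames.shape[0]
    if "FrameTimeVector" in ds and len(ds.FrameTimeVector) >= n:
        durations = np.asarray(ds.FrameTimeVector[:n], dtype=float) / 1000.0
    elif "FrameTime" in ds:
        durations = np.full(n, float(ds.FrameTime) / 1000.0)
    else:
        raise ValueError("DICOM series carries no frame timing information")
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return DynamicRenogram(
        frames=frames.astype(np.int64),
        frame_start_s=starts,
        frame_duration_s=durations,
        detector=detector,
    )


def write_dicom_renogram(path, renogram: DynamicRenogram) -> None:
    """Write a renogram as a minimal multi-frame NM DICOM file.

    Intended for interchange and round-trip testing of synthetic studies,
    not as a full IOD implementation.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    frames = np.asarray(np.round(renogram.frames), dtype=np.uint16)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.20")  # NM Image
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "NM"
    ds.Rows, ds.Columns = frames.shape[1:]
    ds.NumberOfFrames = frames.shape[0]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.FrameTimeVector = [float(d) * 1000.0 for d in renogram.frame_duration_s]
    ds.PixelData = frames.tobytes()
    ds.save_as(path, enforce_file_format=True)


# --------------------------------------------------------------------------
# CSV tables


def read_rater_table_csv(path) -> RaterTable:
    """Rater table from CSV: rows are subjects, columns raters; an optional
    first column named ``subject`` carries subject identifiers."""
    df = pd.read_csv(path)
    if df.columns[0].lower() in ("subject", "subject_id"):
        subject_ids = df.iloc[:, 0].tolist()
        df = df.iloc[:, 1:]
    else:
        subject_ids = list(range(len(df)))
    return RaterTable(
        values=df.to_numpy(dtype=float),
        subject_ids=subject_ids,
        rater_ids=list(df.columns),
    )


def write_rater_table_csv(path, table: RaterTable) -> None:
    df = pd.DataFrame(table.values, columns=[str(r) for r in table.rater_ids])
    df.insert(0, "subject", list(table.subject_ids))
    df.to_csv(path, index=False)
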