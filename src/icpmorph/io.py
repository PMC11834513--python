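"""Readers and writers for ICP recordings and patient metadata.

Two on-disk signal formats are supported: plain CSV for small fixtures and
worked examples, and HDF5 for long recordings.  Pressure is always mm Hg;
time is seconds from an arbitrary epoch.  All downstream window logic uses
elapsed time from the first sample, so the absolute epoch never matters.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: minimum sampling rate (Hz) accepted without an override
MIN_FS = 100.0

#: relative tolerance on sample-spacing uniformity for CSV input
_UNIFORMITY_RTOL = 1e-4


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


class EmptyInputError(ValueError):
    """Raised when an input file contains no usable rows."""


@dataclass
class ICPRecording:
    """A regularly sampled intracranial-pressure time series.

    Parameters
    ----------
    patient_id : str
        Identifier linking the recording to the metadata table.
    fs : float
        Sampling rate in Hz.  Clinical-grade pulse analysis requires
        ``fs >= 100``; lower rates are accepted only with
        ``allow_low_fs=True`` and emit a warning.
    t0 : float
        Recording start time in seconds from an arbitrary epoch.
    samples : numpy.ndarray
        Pressure values in mm Hg, uniformly spaced at ``1/fs``.
    valid_mask : numpy.ndarray or None
        Optional per-sample boolean mask, ``True`` where the sample is
        usable.  ``None`` means all samples are usable.
    """

    patient_id: str
    fs: float
    samples: np.ndarray
    t0: float = 0.0
    valid_mask: np.ndarray | None = None
    allow_low_fs: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.fs < MIN_FS:
            if not self.allow_low_fs:
                raise ValueError(
                    f"sampling rate {self.fs} Hz is below the required "
                    f"{MIN_FS:g} Hz; pass allow_low_fs=True to override"
                )
            logger.warning(
                "recording %s sampled at %.3g Hz, below the recommended %g Hz",
                self.patient_id, self.fs, MIN_FS,
            )
        if self.valid_mask is not None:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.samples.shape:
                raise ValueError("valid_mask must match samples in length")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Elapsed time of each sample in seconds from the first sample."""
        return np.arange(self.samples.size) / self.fs

    def mask(self) -> np.ndarray:
        """Per-sample validity mask (all True when none was provided)."""
        if self.valid_mask is None:
            return np.ones(self.samples.size, dtype=bool)
        return self.valid_mask


@dataclass
class PatientMeta:
    """Clinical metadata for one patient.

    ``died6m`` is derived from the six-month GOSE score: GOSE 1 means the
    patient died (in-hospital death records map to GOSE 1 as well); GOSE 2-8
    means survival; a missing GOSE leaves the outcome unknown (``None``).
    """

    patient_id: str
    age: int
    rotterdam: int | None = None
    gose6m: int | None = None
    monitoring_modality: str = "unknown"
    dc_time: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.age <= 130):
            raise ValueError(f"age {self.age} outside [0, 130]")
        if self.rotterdam is not None and not (1 <= self.rotterdam <= 6):
            raise ValueError(f"Rotterdam score {self.rotterdam} outside 1-6")
        if self.gose6m is not None and not (1 <= self.gose6m <= 8):
            raise ValueError(f"GOSE {self.gose6m} outside 1-8")
        if self.monitoring_modality not in ("parenchymal", "evd", "unknown"):
            raise ValueError(
                f"unknown monitoring modality {self.monitoring_modality!r}"
            )

    @property
    def died6m(self) -> bool | None:
        if self.gose6m is None:
            return None
        return self.gose6m == 1


def read_recording(path: str | Path, format: str | None = None,
                   patient_id: str | None = None,
                   allow_low_fs: bool = False) -> ICPRecording:
    """Read an ICP recording from CSV or HDF5.

    CSV layout: header ``time_s,icp_mmhg`` with an optional third ``valid``
    column (0/1).  The sampling rate is inferred from the median time step
    and the spacing must be uniform to one part in 10^4.

    HDF5 layout: ``/patients/<id>/icp`` datasets with ``fs`` and ``t0``
    attributes on the patient group.  ``patient_id`` selects the group; when
    omitted, a file with exactly one patient group is read unambiguously.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "hdf5" if path.suffix in (".h5", ".hdf5") else "csv"
    if format == "csv":
        return _read_csv(path, patient_id or path.stem, allow_low_fs)
    if format == "hdf5":
        return _read_hdf5(path, patient_id, allow_low_fs)
    raise ValueError(f"unknown format {format!r}")


def _read_csv(path: Path, patient_id: str, allow_low_fs: bool) -> ICPRecording:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path} is empty") from exc
    if df.empty:
        raise EmptyInputError(f"{path} has a header but no rows")
    for col in ("time_s", "icp_mmhg"):
        if col not in df.columns:
            raise FormatError(f"{path} is missing required column {col!r}")
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"{path}: column {col!r} contains non-numeric data")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size >= 2:
        dt = np.diff(t)
        step = float(np.median(dt))
        if step <= 0:
            raise FormatError(f"{path}: time column is not strictly increasing")
        if np.max(np.abs(dt - step)) > _UNIFORMITY_RTOL * step:
            raise FormatError(
                f"{path}: non-uniform sampling (median step {step:g} s, "
                f"max deviation {np.max(np.abs(dt - step)):g} s)"
            )
        fs = 1.0 / step
    else:
        fs = MIN_FS  # a single sample carries no rate information
    mask = None
    if "valid" in df.columns:
        mask = df["valid"].to_numpy().astype(bool)
    return ICPRecording(patient_id=patient_id, fs=fs, t0=float(t[0]),
                        samples=df["icp_mmhg"].to_numpy(dtype=float),
                        valid_mask=mask, allow_low_fs=allow_low_fs)


def _read_hdf5(path: Path, patient_id: str | None,
               allow_low_fs: bool) -> ICPRecording:
    with h5py.File(path, "r") as f:
        if "patients" not in f:
            raise FormatError(f"{path}: no /patients group")
        group = f["patients"]
        ids = list(group.keys())
        if not ids:
            raise EmptyInputError(f"{path}: /patients group is empty")
        if patient_id is None:
            if len(ids) > 1:
                raise ValueError(
                    f"{path} holds {len(ids)} patients; pass patient_id"
                )
            patient_id = ids[0]
        if patient_id not in group:
            raise KeyError(f"patient {patient_id!r} not in {path}")
        g = group[patient_id]
        if "icp" not in g:
            raise FormatError(f"{path}: /patients/{patient_id} has no icp dataset")
        samples = g["icp"][:]
        fs = float(g.attrs["fs"])
        t0 = float(g.attrs.get("t0", 0.0))
        mask = g["valid"][:].astype(bool) if "valid" in g else None
    return ICPRecording(patient_id=patient_id, fs=fs, t0=t0, samples=samples,
                        valid_mask=mask, allow_low_fs=allow_low_fs)


def write_recording(rec: ICPRecording, path: str | Path,
                    format: str | None = None) -> None:
    """Write a recording in the CSV or HDF5 layout read by read_recording.

    HDF5 files are opened in append mode, so several patients can share one
    file; an existing group for the same patient is replaced.
    """
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix in (".h5", ".hdf5") else "csv"
    if format == "csv":
        t = rec.t0 + rec.times
        cols = {"time_s": t, "icp_mmhg": rec.samples}
        if rec.valid_mask is not None:
            cols["valid"] = rec.valid_mask.astype(int)
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")
    elif format == "hdf5":
        with h5py.File(path, "a") as f:
            patients = f.require_group("patients")
            if rec.patient_id in patients:
                del patients[rec.patient_id]
            g = patients.create_group(rec.patient_id)
            g.create_dataset("icp", data=rec.samples)
            if rec.valid_mask is not None:
                g.create_dataset("valid", data=rec.valid_mask.astype(np.uint8))
            g.attrs["fs"] = rec.fs
            g.attrs["t0"] = rec.t0
    else:
        raise ValueError(f"unknown format {format!r}")


_PATIENT_COLUMNS = ["patient_id", "age", "rotterdam", "gose6m",
                    "monitoring_modality", "dc_time"]


def read_patient_table(path: str | Path) -> list[PatientMeta]:
    """Read the patient metadata CSV (one PatientMeta per row).

    Missing Rotterdam scores, GOSE values and DC times are allowed and come
    back as ``None``; duplicate patient ids and GOSE values outside 1-8 are
    errors.
    """
    df = pd.read_csv(Path(path))
    missing = [c for c in _PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"patient table is missing columns {missing}")
    if df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient ids: {sorted(set(map(str, dups)))}")
    out = []
    for row in df.itertuples(index=False):
        out.append(PatientMeta(
            patient_id=str(row.patient_id),
            age=int(row.age),
            rotterdam=_opt_int(row.rotterdam),
            gose6m=_opt_int(row.gose6m),
            monitoring_modality=(str(row.monitoring_modality)
                                 if not _is_na(row.monitoring_modality)
                                 else "unknown"),
            dc_time=_opt_float(row.dc_time),
        ))
    return out


def write_patient_table(patients: Iterable[PatientMeta],
                        path: str | Path) -> None:
    rows = []
    for p in patients:
        rows.append({
            "patient_id": p.patient_id, "age": p.age,
            "rotterdam": p.rotterdam, "gose6m": p.gose6m,
            "monitoring_modality": p.monitoring_modality,
            "dc_time": p.dc_time,
        })
    pd.DataFrame(rows, columns=_PATIENT_COLUMNS).to_csv(path, index=False)


def patient_frame(patients: Sequence[PatientMeta]) -> pd.DataFrame:
    """Metadata as a DataFrame with the derived died6m column."""
    return pd.DataFrame([{
        "patient_id": p.patient_id, "age": p.age, "rotterdam": p.rotterdam,
        "gose6m": p.gose6m, "died6m": p.died6m,
        "monitoring_modality": p.monitoring_modality, "dc_time": p.dc_time,
    } for p in patients])


def _is_na(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def _opt_int(value) -> int | None:
    return None if _is_na(value) else int(value)


def _opt_float(value) -> float | None:
    return None if _is_na(value) else float(value)
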