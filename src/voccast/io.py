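"""Data model and on-disk interchange formats for GC-IMS spectra and sample metadata.

A GC-IMS run produces a dense two-dimensional intensity map indexed by gas
chromatography retention time (rows) and ion mobility drift time (columns).
Vendors ship these in proprietary binary containers; this package defines an
open interchange format instead — a headerless CSV matrix next to a JSON
sidecar carrying the axes and free-form metadata — and treats vendor
conversion as an upstream concern.

Axis *units* are carried as metadata only.  Every downstream stage (cropping,
background estimation, feature selection) works purely in index space, so
spectra from different instruments are comparable as long as their grids
align.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GCIMSSpectrum",
    "SampleRecord",
    "read_spectrum",
    "write_spectrum",
    "read_metadata_table",
    "write_metadata_table",
    "METADATA_COLUMNS",
]

SUBTYPES = ("CD", "UC", "IBDU")

METADATA_COLUMNS = ["patient_id", "sample_id", "seq_index", "fcp", "hbi", "sccai", "subtype"]


@dataclass
class GCIMSSpectrum:
    """One sample's GC-IMS intensity matrix plus axis metadata.

    Parameters
    ----------
    sample_id : str
        Opaque identifier; also names the on-disk files.
    intensities : ndarray of shape (n_retention, n_drift)
        Dense non-negative intensity matrix; rows follow the retention axis,
        columns the drift axis.
    retention_axis : ndarray
        Strictly increasing retention times (seconds).
    drift_axis : ndarray
        Strictly increasing drift times (milliseconds or RIP-relative units).
    meta : dict
        Free key/value map (instrument, run date, ...).
    """

    sample_id: str
    intensities: np.ndarray
    retention_axis: np.ndarray
    drift_axis: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.retention_axis = np.asarray(self.retention_axis, dtype=float)
        self.drift_axis = np.asarray(self.drift_axis, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        n_ret, n_drift = self.intensities.shape
        if n_ret != self.retention_axis.size:
            raise ValueError(
                f"row count {n_ret} != retention axis length {self.retention_axis.size}"
            )
        if n_drift != self.drift_axis.size:
            raise ValueError(
                f"column count {n_drift} != drift axis length {self.drift_axis.size}"
            )
        for name, axis in (("retention", self.retention_axis), ("drift", self.drift_axis)):
            if axis.size == 0:
                raise ValueError(f"{name} axis is empty")
            if not np.all(np.isfinite(axis)):
                raise ValueError(f"{name} axis contains non-finite values")
            if axis.size > 1 and not np.all(np.diff(axis) > 0):
                raise ValueError(f"{name} axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass
class SampleRecord:
    """Clinical metadata for one fecal sample.

    ``fcp`` is fecal calprotectin in mg/g; ``hbi`` (Harvey Bradshaw Index) is
    recorded for Crohn's disease only, ``sccai`` (Simple Clinical Colitis
    Activity Index) for ulcerative colitis / IBD-unclassified only.  Missing
    values are permitted at load time and only rejected when a label of the
    corresponding family is requested.
    """

    patient_id: str
    sample_id: str
    seq_index: int
    fcp: float | None = None
    hbi: int | None = None
    sccai: int | None = None
    subtype: str = "CD"

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}; expected one of {SUBTYPES}")
        if self.subtype == "CD" and self.sccai is not None:
            raise ValueError("SCCAI is only meaningful for UC/IBDU samples")
        if self.subtype in ("UC", "IBDU") and self.hbi is not None:
            raise ValueError("HBI is only meaningful for CD samples")
        if self.fcp is not None and (not math.isfinite(self.fcp) or self.fcp < 0):
            raise ValueError("fcp must be a finite non-negative value")
        for name in ("hbi", "sccai"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_spectrum(spectrum: GCIMSSpectrum, path: str | Path) -> Path:
    """Write ``spectrum`` as ``<path>`` (CSV matrix) plus a JSON sidecar.

    The matrix is written headerless, row-major, one retention row per line,
    with 17 significant digits so that float64 values round-trip bit-exactly.
    """
    path = Path(path)
    np.savetxt(path, spectrum.intensities, delimiter=",", fmt="%.17g")
    sidecar = {
        "sample_id": spectrum.sample_id,
        "retention_axis": spectrum.retention_axis.tolist(),
        "drift_axis": spectrum.drift_axis.tolist(),
        "meta": spectrum.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))
    return path


def read_spectrum(path: str | Path) -> GCIMSSpectrum:
    """Read a spectrum written by :func:`write_spectrum` and validate it."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    matrix = np.loadtxt(path, delimiter=",", ndmin=2)
    retention = np.asarray(sidecar["retention_axis"], dtype=float)
    # np.loadtxt cannot distinguish a single-column matrix from a single row
    if matrix.shape[0] == 1 and retention.size > 1 and matrix.size == retention.size:
        matrix = matrix.reshape(-1, 1)
    return GCIMSSpectrum(
        sample_id=sidecar["sample_id"],
        intensities=matrix,
        retention_axis=retention,
        drift_axis=sidecar["drift_axis"],
        meta=sidecar.get("meta", {}),
    )


def _opt_float(value) -> float | None:
    return None if pd.isna(value) else float(value)


def _opt_int(value) -> int | None:
    return None if pd.isna(value) else int(value)


def read_metadata_table(path: str | Path) -> list[SampleRecord]:
    """Read a per-sample clinical metadata CSV.

    Expected header: ``patient_id,sample_id,seq_index,fcp,hbi,sccai,subtype``;
    blank cells mean missing.  Raises on unknown subtype codes and on
    duplicate ``(patient_id, seq_index)`` pairs.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "sample_id": str, "subtype": str})
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["patient_id", "seq_index"])
    if dup.any():
        rows = df.loc[dup, ["patient_id", "seq_index"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate (patient_id, seq_index) rows: {rows}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SampleRecord(
                patient_id=row.patient_id,
                sample_id=row.sample_id,
                seq_index=int(row.seq_index),
                fcp=_opt_float(row.fcp),
                hbi=_opt_int(row.hbi),
                sccai=_opt_int(row.sccai),
                subtype=row.subtype,
            )
        )
    return records


def write_metadata_table(records: list[SampleRecord], path: str | Path) -> Path:
    """Write sample records to the metadata CSV format (blank = missing)."""
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "sample_id": r.sample_id,
                "seq_index": r.seq_index,
                "fcp": r.fcp,
                "hbi": r.hbi,
                "sccai": r.sccai,
                "subtype": r.subtype,
            }
            for r in records
        ],
        columns=METADATA_COLUMNS,
    )
    df.to_csv(path, index=False)
    return path
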