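"""Force-plate file reading, COP computation from force/moment channels, and
parameter-table output.

Two delimited-text dialects are supported: ``forces`` carries the six raw
Kistler channels (Fx, Fy, Fz in N; Mx, My, Mz in N·m) and ``cop`` carries
precomputed COP coordinates (copx, copy in mm).  Internal canonical units are
millimetres for COP displacement and seconds for time.
"""

from __future__ import annotations

import csv as _csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import EmptySignalError, FormatError, SamplingRateError

__all__ = [
    "SubjectMeta",
    "RawForceRecording",
    "CopRecording",
    "read_forceplate_csv",
    "cop_from_forces",
    "write_parameter_table",
]

_FORCE_COLUMNS = ("time", "Fx", "Fy", "Fz", "Mx", "My", "Mz")
_COP_COLUMNS = ("time", "copx", "copy")


@dataclass
class SubjectMeta:
    """Anthropometrics and labelling for one infant.

    height is the current height in cm, weight the current weight in grams;
    both are needed by height/weight parameter normalization.  group_label is
    the observational fidgety-movements classification when known.
    """

    id: str = "anonymous"
    height: float | None = None
    weight: float | None = None
    post_term_age: float | None = None
    group_label: Literal["normal_FM", "absent_FM", "unknown"] = "unknown"

    def __post_init__(self) -> None:
        if self.height is not None and not self.height > 0:
            raise ValueError(f"height must be positive, got {self.height}")
        if self.weight is not None and not self.weight > 0:
            raise ValueError(f"weight must be positive, got {self.weight}")


@dataclass
class RawForceRecording:
    """Raw six-channel force-plate recording (forces in N, moments in N·m)."""

    fs: float
    Fx: np.ndarray
    Fy: np.ndarray
    Fz: np.ndarray
    Mx: np.ndarray
    My: np.ndarray
    Mz: np.ndarray
    subject: SubjectMeta = field(default_factory=SubjectMeta)

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        channels = [self.Fx, self.Fy, self.Fz, self.Mx, self.My, self.Mz]
        for name, ch in zip("Fx Fy Fz Mx My Mz".split(), channels):
            arr = np.asarray(ch, dtype=float)
            setattr(self, name, arr)
        n = len(self.Fx)
        if n < 1:
            raise ValueError("channels must have length >= 1")
        if any(len(getattr(self, c)) != n for c in ("Fy", "Fz", "Mx", "My", "Mz")):
            raise ValueError("all six channels must have equal length")

    def __len__(self) -> int:
        return len(self.Fx)


@dataclass
class CopRecording:
    """COP coordinate time series: x medial–lateral, y caudo-cephalic (mm)."""

    fs: float
    x: np.ndarray
    y: np.ndarray
    valid_mask: np.ndarray | None = None
    subject: SubjectMeta = field(default_factory=SubjectMeta)

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")
        if self.valid_mask is None:
            self.valid_mask = np.ones(len(self.x), dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if len(self.valid_mask) != len(self.x):
                raise ValueError("valid_mask length must match x and y")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return len(self.x) / self.fs

    @property
    def valid_fraction(self) -> float:
        return float(np.mean(self.valid_mask)) if len(self.x) else 0.0


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        head = fh.readline()
    try:
        return _csv.Sniffer().sniff(head, delimiters=",\t;").delimiter
    except _csv.Error:
        return ","


def read_forceplate_csv(
    path: str | Path,
    dialect: Literal["forces", "cop"] = "cop",
    fs_declared: float = 50.0,
    subject: SubjectMeta | None = None,
) -> RawForceRecording | CopRecording:
    """Read a delimited force-plate export.

    The sampling rate is inferred from the median step of the ``time`` column
    and cross-checked against ``fs_declared`` within 1% relative tolerance.

    Parameters
    ----------
    path : file path
        CSV/TSV/semicolon-delimited text with a header row.
    dialect : {"forces", "cop"}
        ``forces`` expects columns time,Fx,Fy,Fz,Mx,My,Mz; ``cop`` expects
        time,copx,copy (COP in mm).
    fs_declared : float
        Nominal sampling rate in Hz (50 for the supine infant protocol).
    subject : SubjectMeta, optional
        Anthropometrics to attach to the returned recording.

    Raises
    ------
    FormatError
        Missing or non-numeric column.
    SamplingRateError
        Inferred rate differs from ``fs_declared`` by more than 1%.
    """
    path = Path(path)
    expected = _FORCE_COLUMNS if dialect == "forces" else _COP_COLUMNS
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    for col in expected:
        if col not in df.columns:
            raise FormatError(
                f"{path.name}: dialect {dialect!r} requires column {col!r}; "
                f"found {list(df.columns)}"
            )
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                raise FormatError(f"{path.name}: column {col!r} is not numeric")
            df[col] = coerced

    time = df["time"].to_numpy(dtype=float)
    if len(time) < 2:
        fs = float(fs_declared)
    else:
        step = float(np.median(np.diff(time)))
        if step <= 0:
            raise FormatError(f"{path.name}: time column is not increasing")
        fs = 1.0 / step
    if abs(fs - fs_declared) > 0.01 * fs_declared:
        raise SamplingRateError(
            f"{path.name}: inferred fs {fs:.4g} Hz differs from declared "
            f"{fs_declared:.4g} Hz by more than 1%"
        )

    subject = subject or SubjectMeta()
    if dialect == "forces":
        return RawForceRecording(
            fs=fs_declared,
            Fx=df["Fx"].to_numpy(float),
            Fy=df["Fy"].to_numpy(float),
            Fz=df["Fz"].to_numpy(float),
            Mx=df["Mx"].to_numpy(float),
            My=df["My"].to_numpy(float),
            Mz=df["Mz"].to_numpy(float),
            subject=subject,
        )
    return CopRecording(
        fs=fs_declared,
        x=df["copx"].to_numpy(float),
        y=df["copy"].to_numpy(float),
        subject=subject,
    )


def cop_from_forces(
    rec: RawForceRecording,
    plate_offset_z: float = 0.0,
    fz_min: float = 1.0,
) -> CopRecording:
    """Compute COP coordinates from raw force/moment channels.

    Standard plate mechanics with the measurement surface a distance
    ``plate_offset_z`` (m) above the sensor origin:

        COPx = -(My + Fx * z0) / Fz,   COPy = (Mx - Fy * z0) / Fz

    both in metres, converted to mm.  Samples where |Fz| < ``fz_min`` (N) are
    flagged invalid and held at the last valid COP value — masking preserves
    series length for the downstream trim and avoids inventing motion.

    Raises
    ------
    EmptySignalError
        If every sample is invalid.
    """
    if plate_offset_z < 0:
        raise ValueError("plate_offset_z must be >= 0")
    if not fz_min > 0:
        raise ValueError("fz_min must be > 0")

    fz = rec.Fz
    valid = np.abs(fz) >= fz_min
    if not valid.any():
        raise EmptySignalError("all samples have |Fz| below fz_min")

    with np.errstate(divide="ignore", invalid="ignore"):
        cop_x = -(rec.My + rec.Fx * plate_offset_z) / fz * 1000.0
        cop_y = (rec.Mx - rec.Fy * plate_offset_z) / fz * 1000.0

    # hold-last-valid: indices of the most recent valid sample at or before i
    idx = np.where(valid, np.arange(len(fz)), -1)
    idx = np.maximum.accumulate(idx)
    first_valid = int(np.argmax(valid))
    idx[idx < 0] = first_valid  # leading invalid run borrows the first valid sample
    return CopRecording(
        fs=rec.fs,
        x=cop_x[idx],
        y=cop_y[idx],
        valid_mask=valid,
        subject=rec.subject,
    )


def write_parameter_table(params: Sequence, path: str | Path) -> None:
    """Write one CSV row per recording, one column per (parameter, direction).

    Column order follows each parameter set's documented battery order (see
    :mod:`copsway.features`); floats are written at full ``repr`` precision so
    a read-back reproduces the values bit-for-bit.
    """
    params = list(params)
    if not params:
        raise ValueError("parameter list must be non-empty")
    columns = [f"{name}_{direction}" for name, direction in params[0].keys()]
    rows = []
    for p in params:
        row = {"subject_id": p.subject.id if p.subject else ""}
        for (name, direction), value in p.values.items():
            row[f"{name}_{direction}"] = repr(float(value))
        rows.append(row)
    df = pd.DataFrame(rows, columns=["subject_id", *columns])
    df.to_csv(path, index=False)


def read_parameter_table(path: str | Path) -> pd.DataFrame:
    """Read back a parameter table written by :func:`write_parameter_table`."""
    return pd.read_csv(path, float_precision="round_trip")
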