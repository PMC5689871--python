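"""Delivery-log reading/writing and x16 down-sampling into segments.

The on-disk format is fluqa's own documented binary layout (little-endian),
designed to mirror the content of TrueBeam-class trajectory logs: a fixed
header followed by fixed-size axis records sampled at a constant interval
(20 ms by default).  An adapter hook (:func:`register_log_reader`) lets a
vendor-format reader plug into :func:`read_log` by file suffix.

Header (20 bytes)::

    magic             4 bytes  b"FQLG"
    version           uint16   currently 1
    reserved          uint16   0
    n_records         uint32
    sampling_interval float64  seconds between records

Record (1040 bytes, 130 float64 fields)::

    time, couch_deg, gantry_deg, collimator_deg,
    jaws[4] (x1, x2, y1, y2; cm),
    bank_a[60], bank_b[60] (cm),
    cumulative_mu (MU, absolute), dose_rate (MU/s)

Down-sampling merges consecutive groups of ``factor`` records into one
:class:`DeliverySegment`: angles are combined by circular mean, jaws and
leaves by arithmetic mean, and the MU increment is the cumulative-MU
difference across the group, so total MU is conserved for any factor.  A
trailing partial group is merged the same way.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .exceptions import LogDataError, LogFormatError
from .geometry import (
    DEFAULT_SAD,
    BeamAngles,
    circular_mean_deg,
    normalize_angle_deg,
    source_position,
)

MAGIC = b"FQLG"
VERSION = 1
DEFAULT_SAMPLING_INTERVAL_S = 0.020
DEFAULT_DOWNSAMPLE_FACTOR = 16

_HEADER = struct.Struct("<4sHHId")

_RECORD_DTYPE = np.dtype(
    [
        ("time", "<f8"),
        ("couch", "<f8"),
        ("gantry", "<f8"),
        ("collimator", "<f8"),
        ("jaws", "<f8", (4,)),
        ("bank_a", "<f8", (60,)),
        ("bank_b", "<f8", (60,)),
        ("cumulative_mu", "<f8"),
        ("dose_rate", "<f8"),
    ]
)


@dataclass(frozen=True)
class LogRecord:
    """One fixed-interval machine-state sample during delivery."""

    time: float
    angles: BeamAngles
    jaws: tuple[float, float, float, float]
    bank_a: np.ndarray = field(repr=False)
    bank_b: np.ndarray = field(repr=False)
    cumulative_mu: float = 0.0
    dose_rate: float = 0.0


@dataclass(frozen=True)
class DeliverySegment:
    """Discretized integration element consumed by the fluence engine.

    Mean machine state over a short slice of delivery (one down-sampled log
    group, or one up-sampled control-point sub-interval) plus the MU delivered
    during it and the source position to use for inverse-square scaling.
    """

    angles: BeamAngles
    jaws: tuple[float, float, float, float]
    bank_a: np.ndarray = field(repr=False)
    bank_b: np.ndarray = field(repr=False)
    delta_mu: float = 0.0
    source: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.delta_mu < 0:
            raise ValueError(f"delta_mu must be >= 0, got {self.delta_mu:g}")


def _records_to_array(records: Sequence[LogRecord]) -> np.ndarray:
    arr = np.zeros(len(records), dtype=_RECORD_DTYPE)
    for i, r in enumerate(records):
        arr[i]["time"] = r.time
        arr[i]["couch"] = r.angles.couch_deg
        arr[i]["gantry"] = r.angles.gantry_deg
        arr[i]["collimator"] = r.angles.collimator_deg
        arr[i]["jaws"] = r.jaws
        arr[i]["bank_a"] = r.bank_a
        arr[i]["bank_b"] = r.bank_b
        arr[i]["cumulative_mu"] = r.cumulative_mu
        arr[i]["dose_rate"] = r.dose_rate
    return arr


def _array_to_records(arr: np.ndarray) -> list[LogRecord]:
    out = []
    for row in arr:
        out.append(
            LogRecord(
                time=float(row["time"]),
                angles=BeamAngles(
                    normalize_angle_deg(row["couch"]),
                    normalize_angle_deg(row["gantry"]),
                    normalize_angle_deg(row["collimator"]),
                ),
                jaws=tuple(float(v) for v in row["jaws"]),
                bank_a=np.array(row["bank_a"]),
                bank_b=np.array(row["bank_b"]),
                cumulative_mu=float(row["cumulative_mu"]),
                dose_rate=float(row["dose_rate"]),
            )
        )
    return out


def write_log(
    records: Sequence[LogRecord],
    path,
    sampling_interval_s: float = DEFAULT_SAMPLING_INTERVAL_S,
) -> None:
    """Write records to a fluqa binary log file (byte-exact re-readable)."""
    arr = _records_to_array(records)
    header = _HEADER.pack(MAGIC, VERSION, 0, len(records), sampling_interval_s)
    Path(path).write_bytes(header + arr.tobytes())


_VENDOR_READERS: dict[str, Callable] = {}


def register_log_reader(suffix: str, reader: Callable) -> None:
    """Register a vendor-format reader keyed by file suffix (e.g. ``".bin"``)."""
    _VENDOR_READERS[suffix.lower()] = reader


def read_log(path) -> list[LogRecord]:
    """Read a delivery-log file into validated records.

    Files whose suffix matches a registered vendor adapter are dispatched to
    it; everything else must be in the fluqa binary layout.  Raises
    :class:`~fluqa.exceptions.LogFormatError` on structural damage and
    :class:`~fluqa.exceptions.LogDataError` on non-monotone cumulative MU.
    """
    path = Path(path)
    reader = _VENDOR_READERS.get(path.suffix.lower())
    if reader is not None:
        return reader(path)
    blob = path.read_bytes()
    if len(blob) < _HEADER.size:
        raise LogFormatError(f"{path}: truncated header")
    magic, version, _, n_records, interval = _HEADER.unpack_from(blob)
    if magic != MAGIC:
        raise LogFormatError(f"{path}: bad magic {magic!r}")
    if version != VERSION:
        raise LogFormatError(f"{path}: unsupported version {version}")
    if n_records == 0:
        raise LogFormatError(f"{path}: empty record section")
    body = blob[_HEADER.size :]
    expected = n_records * _RECORD_DTYPE.itemsize
    if len(body) < expected:
        raise LogFormatError(
            f"{path}: truncated records ({len(body)} bytes, expected {expected})"
        )
    arr = np.frombuffer(body[:expected], dtype=_RECORD_DTYPE)
    if np.any(np.diff(arr["cumulative_mu"]) < 0):
        raise LogDataError(f"{path}: cumulative MU is not non-decreasing")
    return _array_to_records(arr)


def read_log_header(path) -> dict:
    """Parse just the header; used by ``fluqa log-info``.

    The equivalent angular resolution reported is
    ``mean gantry speed x sampling interval`` estimated from the records.
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < _HEADER.size or blob[:4] != MAGIC:
        raise LogFormatError(f"{path}: not a fluqa log file")
    magic, version, _, n_records, interval = _HEADER.unpack_from(blob)
    return {
        "version": version,
        "n_records": n_records,
        "sampling_interval_s": interval,
    }


def downsample_log(
    records: Sequence[LogRecord],
    factor: int = DEFAULT_DOWNSAMPLE_FACTOR,
    sad: float = DEFAULT_SAD,
) -> list[DeliverySegment]:
    """Merge consecutive groups of ``factor`` records into delivery segments.

    Cumulative MU is absolute (0 at beam-on), so the segments' MU increments
    telescope to ``cumulative_mu(last record)`` exactly; a log that begins
    mid-delivery must be re-based by the caller.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if not records:
        return []
    arr = _records_to_array(records)
    segments: list[DeliverySegment] = []
    prev_mu = 0.0
    for start in range(0, len(arr), factor):
        group = arr[start : start + factor]
        angles = BeamAngles(
            circular_mean_deg(group["couch"]),
            circular_mean_deg(group["gantry"]),
            circular_mean_deg(group["collimator"]),
        )
        end_mu = float(group["cumulative_mu"][-1])
        delta = end_mu - prev_mu
        prev_mu = end_mu
        segments.append(
            DeliverySegment(
                angles=angles,
                jaws=tuple(np.mean(group["jaws"], axis=0)),
                bank_a=np.mean(group["bank_a"], axis=0),
                bank_b=np.mean(group["bank_b"], axis=0),
                delta_mu=max(delta, 0.0),
                source=source_position(angles, sad),
            )
        )
    return segments
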