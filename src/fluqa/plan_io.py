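"""DICOM-RT plan reading/writing and control-point up-sampling.

A VMAT/IMRT plan is a list of :class:`Beam` objects, each an ordered sequence
of :class:`ControlPoint` machine states with non-decreasing cumulative
meterset weight.  DICOM stores lengths in mm and angles in [0, 360); both are
converted at this boundary (cm, signed degrees internally).

Control points sample the delivered trajectory far more coarsely than the
machine moves (typically 4 degrees of gantry per point), and the machine
interpolates all axes linearly in between.  :func:`upsample_beam` inserts
linearly interpolated sub-states so that consecutive segment centers differ
by at most ``step_deg`` of gantry (1 degree by default, which suppresses the
angular alias in the reconstructed volume), splitting each interval's MU
proportionally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import PlanFormatError
from .geometry import (
    DEFAULT_SAD,
    BeamAngles,
    normalize_angle_deg,
    source_position,
    unwrap_degrees,
)
from .log_io import DeliverySegment

DEFAULT_UPSAMPLE_STEP_DEG = 1.0


@dataclass(frozen=True)
class ControlPoint:
    """Planned machine state at one checkpoint of a beam."""

    index: int
    angles: BeamAngles
    jaws: tuple[float, float, float, float]
    bank_a: np.ndarray = field(repr=False)
    bank_b: np.ndarray = field(repr=False)
    cumulative_weight: float = 0.0


@dataclass(frozen=True)
class Beam:
    """One treatment beam: ordered control points plus its meterset."""

    beam_id: str
    sad: float
    total_mu: float
    control_points: tuple[ControlPoint, ...]
    machine_model: str = "Millennium120"

    def __post_init__(self):
        cps = tuple(self.control_points)
        if len(cps) < 2:
            raise PlanFormatError(f"beam {self.beam_id}: needs >= 2 control points")
        weights = np.array([cp.cumulative_weight for cp in cps])
        if weights[0] != 0.0:
            raise PlanFormatError(f"beam {self.beam_id}: first weight must be 0")
        if np.any(np.diff(weights) < 0):
            raise PlanFormatError(f"beam {self.beam_id}: weights must be non-decreasing")
        object.__setattr__(self, "control_points", cps)

    @property
    def final_weight(self) -> float:
        return self.control_points[-1].cumulative_weight


def delta_mu_sequence(beam: Beam) -> np.ndarray:
    """MU allocated to each control-point interval.

    ``delta_mu[k] = (w[k+1] - w[k]) / w[-1] * total_mu``; the sequence sums to
    the beam meterset exactly (last element absorbs rounding).
    """
    weights = np.array([cp.cumulative_weight for cp in beam.control_points])
    if beam.final_weight <= 0:
        raise PlanFormatError(f"beam {beam.beam_id}: final cumulative weight <= 0")
    delta = np.diff(weights) / beam.final_weight * beam.total_mu
    delta[-1] = beam.total_mu - delta[:-1].sum()
    return delta


def _interp_cp(a: ControlPoint, b: ControlPoint, f: float, gantry_track) -> ControlPoint:
    """State at fraction ``f`` of the interval [a, b], all axes linear."""
    ga, gb = gantry_track
    return ControlPoint(
        index=a.index,
        angles=BeamAngles(
            a.angles.couch_deg + f * normalize_angle_deg(b.angles.couch_deg - a.angles.couch_deg),
            ga + f * (gb - ga),
            a.angles.collimator_deg
            + f * normalize_angle_deg(b.angles.collimator_deg - a.angles.collimator_deg),
        ),
        jaws=tuple((1 - f) * np.asarray(a.jaws) + f * np.asarray(b.jaws)),
        bank_a=(1 - f) * a.bank_a + f * b.bank_a,
        bank_b=(1 - f) * a.bank_b + f * b.bank_b,
        cumulative_weight=(1 - f) * a.cumulative_weight + f * b.cumulative_weight,
    )


def _mean_segment(a: ControlPoint, b: ControlPoint, delta_mu: float, sad: float,
                  gantry_track) -> DeliverySegment:
    """Segment carrying the averaged endpoint state and the interval's MU.

    The source is the chord midpoint of the two endpoint source positions
    (the averaged-source rule), not the source at the averaged angles.
    """
    ga, gb = gantry_track
    mid = _interp_cp(a, b, 0.5, gantry_track)
    sa = source_position(BeamAngles(a.angles.couch_deg, ga, a.angles.collimator_deg), sad)
    sb = source_position(BeamAngles(b.angles.couch_deg, gb, b.angles.collimator_deg), sad)
    return DeliverySegment(
        angles=mid.angles,
        jaws=mid.jaws,
        bank_a=mid.bank_a,
        bank_b=mid.bank_b,
        delta_mu=max(float(delta_mu), 0.0),
        source=0.5 * (sa + sb),
    )


def upsample_beam(beam: Beam, step_deg: float = DEFAULT_UPSAMPLE_STEP_DEG) -> list[DeliverySegment]:
    """Up-sample control points into segments at <= ``step_deg`` gantry spacing.

    Each control-point interval is split into ``ceil(|dgantry| / step_deg)``
    equal sub-intervals (one, i.e. no splitting, for static-gantry intervals);
    every emitted segment carries the arithmetic mean of its sub-interval
    endpoint states, the proportional share of the interval's MU, and the
    averaged endpoint source position.  Total MU is conserved at any step.
    """
    if step_deg <= 0:
        raise ValueError("step_deg must be positive")
    cps = beam.control_points
    gantry = unwrap_degrees([cp.angles.gantry_deg for cp in cps])
    deltas = delta_mu_sequence(beam)
    segments: list[DeliverySegment] = []
    for k in range(len(cps) - 1):
        a, b = cps[k], cps[k + 1]
        span = abs(gantry[k + 1] - gantry[k])
        n_sub = max(1, math.ceil(span / step_deg - 1e-9))
        for j in range(n_sub):
            f0, f1 = j / n_sub, (j + 1) / n_sub
            sub_a = _interp_cp(a, b, f0, (gantry[k], gantry[k + 1]))
            sub_b = _interp_cp(a, b, f1, (gantry[k], gantry[k + 1]))
            track = (sub_a.angles.gantry_deg, sub_b.angles.gantry_deg)
            segments.append(_mean_segment(sub_a, sub_b, deltas[k] / n_sub, beam.sad, track))
    return segments


# ---------------------------------------------------------------------------
# DICOM I/O

_RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"


def read_rtplan(path) -> list[Beam]:
    """Read a DICOM RT Plan into one :class:`Beam` per treatment beam.

    Applies the DICOM sparse-control-point rule (parameters not restated at a
    control point are inherited from the last one that specified them),
    converts mm to cm, and pulls each beam's meterset from the Fraction Group
    when present (otherwise the meterset is 0 and must be set by the caller).
    """
    import pydicom

    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTPLAN" and getattr(ds, "SOPClassUID", "") != _RTPLAN_SOP_CLASS:
        raise PlanFormatError(f"{path}: not a DICOM RT Plan")
    metersets: dict[int, float] = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            if hasattr(rb, "BeamMeterset"):
                metersets[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)
    beams = []
    for bs in getattr(ds, "BeamSequence", []):
        beams.append(_read_beam(bs, metersets))
    if not beams:
        raise PlanFormatError(f"{path}: plan contains no beams")
    return beams


def _read_beam(bs, metersets: dict[int, float]) -> Beam:
    beam_number = int(getattr(bs, "BeamNumber", 0))
    sad = float(getattr(bs, "SourceAxisDistance", 10 * DEFAULT_SAD)) / 10.0
    has_mlc = any(
        getattr(bld, "RTBeamLimitingDeviceType", "") in ("MLCX", "MLCY")
        for bld in getattr(bs, "BeamLimitingDeviceSequence", [])
    )
    cps = []
    state = {"gantry": 0.0, "collimator": 0.0, "couch": 0.0,
             "jaws": None, "bank_a": None, "bank_b": None}
    for k, cp in enumerate(getattr(bs, "ControlPointSequence", [])):
        if hasattr(cp, "GantryAngle"):
            state["gantry"] = float(cp.GantryAngle)
        if hasattr(cp, "BeamLimitingDeviceAngle"):
            state["collimator"] = float(cp.BeamLimitingDeviceAngle)
        if hasattr(cp, "PatientSupportAngle"):
            state["couch"] = float(cp.PatientSupportAngle)
        for bldp in getattr(cp, "BeamLimitingDevicePositionSequence", []):
            kind = bldp.RTBeamLimitingDeviceType
            pos = np.array([float(v) for v in bldp.LeafJawPositions]) / 10.0
            if kind in ("X", "ASYMX"):
                x1, x2 = pos
                jaws = state["jaws"] or (0.0, 0.0, 0.0, 0.0)
                state["jaws"] = (x1, x2, jaws[2], jaws[3])
            elif kind in ("Y", "ASYMY"):
                y1, y2 = pos
                jaws = state["jaws"] or (0.0, 0.0, 0.0, 0.0)
                state["jaws"] = (jaws[0], jaws[1], y1, y2)
            elif kind == "MLCX":
                n = len(pos) // 2
                state["bank_a"] = pos[:n]
                state["bank_b"] = pos[n:]
        if not hasattr(cp, "CumulativeMetersetWeight") or cp.CumulativeMetersetWeight is None:
            raise PlanFormatError(f"beam {beam_number}: control point {k} lacks cumulative weight")
        if state["bank_a"] is None:
            if has_mlc:
                raise PlanFormatError(f"beam {beam_number}: MLC positions missing at first control point")
            raise PlanFormatError(f"beam {beam_number}: unsupported beam without MLC sequence")
        if state["jaws"] is None:
            raise PlanFormatError(f"beam {beam_number}: jaw positions missing at first control point")
        cps.append(
            ControlPoint(
                index=k,
                angles=BeamAngles(
                    normalize_angle_deg(state["couch"]),
                    normalize_angle_deg(state["gantry"]),
                    normalize_angle_deg(state["collimator"]),
                ),
                jaws=state["jaws"],
                bank_a=state["bank_a"].copy(),
                bank_b=state["bank_b"].copy(),
                cumulative_weight=float(cp.CumulativeMetersetWeight),
            )
        )
    return Beam(
        beam_id=str(getattr(bs, "BeamName", beam_number)),
        sad=sad,
        total_mu=metersets.get(beam_number, 0.0),
        control_points=tuple(cps),
        machine_model=str(getattr(bs, "TreatmentMachineName", "Millennium120")) or "Millennium120",
    )


def write_rtplan(beams: Sequence[Beam], path, patient_id: str = "FLUQA^SYNTH") -> None:
    """Write beams as a minimal but valid DICOM RT Plan (Explicit VR LE)."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTPLAN_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = pydicom.FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = _RTPLAN_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.PatientName = patient_id
    ds.PatientID = patient_id
    ds.RTPlanLabel = "FLUQA-SYNTH"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = 1
    fg.ReferencedBeamSequence = []
    ds.FractionGroupSequence = [fg]
    ds.BeamSequence = []

    for num, beam in enumerate(beams, start=1):
        rb = Dataset()
        rb.ReferencedBeamNumber = num
        rb.BeamMeterset = round(float(beam.total_mu), 6)
        fg.ReferencedBeamSequence.append(rb)

        bs = Dataset()
        bs.BeamNumber = num
        bs.BeamName = beam.beam_id
        bs.TreatmentMachineName = beam.machine_model
        bs.SourceAxisDistance = beam.sad * 10.0
        bs.FinalCumulativeMetersetWeight = round(float(beam.final_weight), 10)
        bs.NumberOfControlPoints = len(beam.control_points)

        mlc_bld = Dataset()
        mlc_bld.RTBeamLimitingDeviceType = "MLCX"
        mlc_bld.NumberOfLeafJawPairs = 60
        from .machine_model import get_layout, MILLENNIUM_120
        try:
            layout = get_layout(beam.machine_model)
        except KeyError:
            layout = MILLENNIUM_120
        mlc_bld.LeafPositionBoundaries = [float(v) * 10.0 for v in layout.boundaries]
        bs.BeamLimitingDeviceSequence = [mlc_bld]

        bs.ControlPointSequence = []
        for cp in beam.control_points:
            d = Dataset()
            d.ControlPointIndex = cp.index
            d.GantryAngle = round(cp.angles.gantry_deg % 360.0, 6)
            d.BeamLimitingDeviceAngle = round(cp.angles.collimator_deg % 360.0, 6)
            d.PatientSupportAngle = round(cp.angles.couch_deg % 360.0, 6)
            d.CumulativeMetersetWeight = round(float(cp.cumulative_weight), 10)
            d.BeamLimitingDevicePositionSequence = []
            for kind, pos in (
                ("ASYMX", [cp.jaws[0], cp.jaws[1]]),
                ("ASYMY", [cp.jaws[2], cp.jaws[3]]),
                ("MLCX", list(cp.bank_a) + list(cp.bank_b)),
            ):
                bld = Dataset()
                bld.RTBeamLimitingDeviceType = kind
                bld.LeafJawPositions = [round(float(v) * 10.0, 5) for v in pos]
                d.BeamLimitingDevicePositionSequence.append(bld)
            bs.ControlPointSequence.append(d)
        ds.BeamSequence.append(bs)

    ds.save_as(str(path), enforce_file_format=True)
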