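"""Beam-line coordinate frames, rotations, and divergent portal projection.

Conventions (room frame, origin at isocenter, lengths in cm, angles in degrees):

* ``+y`` is the beam direction at gantry 0, so the source sits at ``(0, -SAD, 0)``;
* ``+x`` is the X-jaw / MLC travel direction at all-zero angles;
* ``+z`` is the Y-jaw direction (couch long axis);
* the gantry rotates about the z axis, the couch about the y axis, and the
  collimator rotates in the 2D portal plane ``(u, w)``.

A room point ``r`` is mapped to the portal plane through isocenter by first
rotating it into the gantry-0/couch-0 beam frame, ``R_g(-beta) R_couch(-alpha) r``,
then applying the divergent projection ``u0 = x*SAD/(y+SAD)``,
``w0 = z*SAD/(y+SAD)``, and finally the in-plane collimator rotation
``R_col(theta)``.  All functions are total in the angles; the projection is
undefined for points at or upstream of the source plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .exceptions import BehindSourceError

#: default source-to-axis distance of a C-arm linac, cm
DEFAULT_SAD = 100.0

#: numerical guard for the "behind source" condition, cm
BEHIND_SOURCE_EPS = 1e-6


def normalize_angle_deg(angle: float) -> float:
    """Map an angle in degrees to the continuous signed range (-180, 180].

    DICOM stores machine angles in [0, 360); the signed representation keeps
    linear interpolation well behaved near the 0/360 seam.
    """
    a = math.fmod(float(angle), 360.0)
    if a > 180.0:
        a -= 360.0
    elif a <= -180.0:
        a += 360.0
    return a


def signed_delta_deg(start: float, end: float) -> float:
    """Shortest-arc signed difference ``end - start`` in (-180, 180]."""
    return normalize_angle_deg(end - start)


def unwrap_degrees(angles: Iterable[float]) -> np.ndarray:
    """Unwrap an angle sequence into a continuous track via shortest arcs.

    The first element anchors the track at its signed representation; each
    subsequent element adds the shortest-arc increment.  VMAT arcs routinely
    cross the 359 -> 1 degree seam, which naive interpolation would traverse
    the long way round.
    """
    angles = list(angles)
    if not angles:
        return np.empty(0)
    out = np.empty(len(angles))
    out[0] = normalize_angle_deg(angles[0])
    for i in range(1, len(angles)):
        out[i] = out[i - 1] + signed_delta_deg(angles[i - 1], angles[i])
    return out


def circular_mean_deg(angles: np.ndarray) -> float:
    """Mean of angles in degrees, computed on the unit circle."""
    rad = np.radians(np.asarray(angles, dtype=float))
    return normalize_angle_deg(
        math.degrees(math.atan2(np.mean(np.sin(rad)), np.mean(np.cos(rad))))
    )


@dataclass(frozen=True)
class BeamAngles:
    """Couch (alpha), gantry (beta) and collimator (theta) angles in degrees."""

    couch_deg: float = 0.0
    gantry_deg: float = 0.0
    collimator_deg: float = 0.0

    def normalized(self) -> "BeamAngles":
        """Angles mapped to the signed (-180, 180] representation."""
        return BeamAngles(
            normalize_angle_deg(self.couch_deg),
            normalize_angle_deg(self.gantry_deg),
            normalize_angle_deg(self.collimator_deg),
        )


def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def beam_frame_matrix(angles: BeamAngles) -> np.ndarray:
    """Rotation ``R_g(-beta) R_couch(-alpha)`` taking room points to the beam frame."""
    return _rot_z(-angles.gantry_deg) @ _rot_y(-angles.couch_deg)


def rotate_to_beam_frame(p, angles: BeamAngles) -> np.ndarray:
    """Express a room point in the gantry-0/couch-0 beam frame.

    The collimator rotation is intentionally not applied here; it acts
    in-plane on the projected portal coordinates (see :func:`project_to_portal`).
    """
    return beam_frame_matrix(angles) @ np.asarray(p, dtype=float)


def collimator_matrix_2d(collimator_deg: float) -> np.ndarray:
    """In-plane rotation applied to projected portal coordinates."""
    c = math.cos(math.radians(collimator_deg))
    s = math.sin(math.radians(collimator_deg))
    return np.array([[c, -s], [s, c]])


def project_to_portal(p, collimator_deg: float = 0.0, sad: float = DEFAULT_SAD):
    """Divergent projection of a beam-frame point onto the portal plane.

    Returns the portal coordinates ``(u, w)`` on the plane through isocenter,
    after the in-plane collimator rotation.  Raises
    :class:`~fluqa.exceptions.BehindSourceError` for points at or upstream of
    the source plane (``y <= -SAD``).
    """
    if sad <= 0:
        raise ValueError("SAD must be positive")
    x, y, z = np.asarray(p, dtype=float)
    denom = y + sad
    if denom <= BEHIND_SOURCE_EPS:
        raise BehindSourceError(
            f"point with y={y:.6g} cm is at or behind the source plane (SAD={sad:g})"
        )
    u0 = x * sad / denom
    w0 = z * sad / denom
    u, w = collimator_matrix_2d(collimator_deg) @ (u0, w0)
    return float(u), float(w)


def project_points(points: np.ndarray, angles: BeamAngles, sad: float = DEFAULT_SAD):
    """Vectorized room-to-portal projection for an ``(N, 3)`` point array.

    Returns ``(u, w, valid)`` where ``valid`` flags points strictly downstream
    of the source plane; ``u``/``w`` are NaN where invalid.
    """
    pb = np.asarray(points, dtype=float) @ beam_frame_matrix(angles).T
    denom = pb[:, 1] + sad
    valid = denom > BEHIND_SOURCE_EPS
    scale = np.where(valid, sad / np.where(valid, denom, 1.0), np.nan)
    u0 = pb[:, 0] * scale
    w0 = pb[:, 2] * scale
    rc = collimator_matrix_2d(angles.collimator_deg)
    u = rc[0, 0] * u0 + rc[0, 1] * w0
    w = rc[1, 0] * u0 + rc[1, 1] * w0
    return u, w, valid


def source_position(angles: BeamAngles, sad: float = DEFAULT_SAD) -> np.ndarray:
    """Room-frame position of the point source.

    At all-zero angles the source sits at ``(0, -SAD, 0)``; any rotation keeps
    it on the SAD sphere.
    """
    if sad <= 0:
        raise ValueError("SAD must be positive")
    return _rot_y(angles.couch_deg) @ _rot_z(angles.gantry_deg) @ np.array([0.0, -sad, 0.0])


def mean_source_position(a: BeamAngles, b: BeamAngles, sad: float = DEFAULT_SAD) -> np.ndarray:
    """Arithmetic mean of two source positions (the chord midpoint).

    Used for the averaged source of a control-point interval; for distinct
    angles it lies strictly inside the SAD sphere.
    """
    return 0.5 * (source_position(a, sad) + source_position(b, sad))
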