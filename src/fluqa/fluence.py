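"""3D primary-fluence reconstruction by forward projection (the 3DFC engine).

For every voxel center ``r`` and every delivery segment, the voxel is rotated
into the beam frame, divergently projected onto the portal plane, and tested
against the binary aperture mask; when inside, the segment contributes

    delta_MU * F(u, w) * SAD^2 / |r - s|^2

where ``F`` is the in-air beam profile (flat by default), ``s`` the segment's
source position, and the inverse-square factor scales the in-air intensity
with distance from the source.  Attenuation and scatter are deliberately not
modelled: the accumulated volume is the MU delivered "in air" to each point,
not dose.  Both the plan path (control points up-sampled to ~1 degree) and
the log path (records down-sampled x16) feed the same accumulation, so the
two reconstructions are directly comparable.

A gantry-collapsed composite 2D map (the 2DFC baseline) is also provided:
gantry and couch are forced to 0 and the map lives on the isocenter portal
plane, with no off-plane divergence scaling — which is exactly why it is
blind to gantry-angle delivery errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DegenerateGeometryError
from .geometry import DEFAULT_SAD, BeamAngles, collimator_matrix_2d, project_points
from .log_io import DeliverySegment, DEFAULT_DOWNSAMPLE_FACTOR, LogRecord, downsample_log
from .machine_model import MILLENNIUM_120, MLCLayout, aperture_from_state, aperture_mask, get_layout
from .plan_io import Beam, DEFAULT_UPSAMPLE_STEP_DEG, delta_mu_sequence, upsample_beam

DEFAULT_VOXEL_CM = 0.3
DEFAULT_MARGIN_CM = 1.0

_MIN_SOURCE_DIST_CM = 1e-3


@dataclass(frozen=True)
class GridSpec:
    """Isocenter-centered voxel grid: corner origin, isotropic spacing, dims."""

    origin: tuple[float, float, float]
    voxel_size: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must be >= 1 in every axis")

    def voxel_centers(self) -> np.ndarray:
        """All voxel centers as an ``(N, 3)`` array, x fastest-varying last axis."""
        ax = [self.origin[i] + (np.arange(self.dims[i]) + 0.5) * self.voxel_size
              for i in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def axis_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.dims[axis]) + 0.5) * self.voxel_size


@dataclass(frozen=True)
class PortalGrid:
    """2D pixel grid on the isocenter portal plane for composite maps."""

    origin: tuple[float, float]
    pixel_size: float
    dims: tuple[int, int]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        u = self.origin[0] + (np.arange(self.dims[0]) + 0.5) * self.pixel_size
        w = self.origin[1] + (np.arange(self.dims[1]) + 0.5) * self.pixel_size
        gu, gw = np.meshgrid(u, w, indexing="ij")
        return gu.ravel(), gw.ravel()


@dataclass
class FluenceVolume:
    """Accumulated 3D fluence (MU in air) on a :class:`GridSpec`."""

    grid: GridSpec
    values: np.ndarray = field(repr=False)
    provenance: dict = field(default_factory=dict)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.grid.voxel_size,) * 3


@dataclass
class FluenceMap:
    """Composite 2D fluence map on the isocenter portal plane."""

    grid: PortalGrid
    values: np.ndarray = field(repr=False)
    provenance: dict = field(default_factory=dict)

    @property
    def spacing(self) -> tuple[float, float]:
        return (self.grid.pixel_size,) * 2


class BeamProfile:
    """In-air 2D beam intensity profile ``F(u, w)``; flat (1.0) by default.

    Subclass or pass any callable ``(u, w) -> array`` for a measured radial
    profile; values must be positive within the maximum field.
    """

    def __call__(self, u: np.ndarray, w: np.ndarray) -> np.ndarray:
        return np.ones_like(np.asarray(u, dtype=float))


FLAT_PROFILE = BeamProfile()


def compute_volume_bounds(
    beams: Sequence[Beam],
    voxel_size: float = DEFAULT_VOXEL_CM,
    margin: float = DEFAULT_MARGIN_CM,
) -> GridSpec:
    """Cubic isocenter-centered grid covering the maximal jaw opening + margin.

    Half-extent = max over beams and control points of
    ``max(|x1|, |x2|, |y1|, |y2|)`` plus the margin, snapped up to a whole
    number of voxels.  An all-zero-jaw plan degenerates to a minimal 3-voxel
    grid.
    """
    if not beams:
        raise ValueError("need at least one beam")
    half = 0.0
    for beam in beams:
        for cp in beam.control_points:
            half = max(half, *(abs(v) for v in cp.jaws))
    if half == 0.0:
        n_half = 1.5  # minimal 3-voxel grid around the isocenter
    else:
        n_half = math.ceil((half + margin) / voxel_size - 1e-9)
    n = int(2 * n_half)
    origin = (-n_half * voxel_size,) * 3
    return GridSpec(origin=origin, voxel_size=voxel_size, dims=(n, n, n))


def _segment_aperture(seg: DeliverySegment):
    return aperture_from_state(seg.jaws, seg.bank_a, seg.bank_b)


def accumulate_fluence(
    segments: Sequence[DeliverySegment],
    grid: GridSpec,
    profile: BeamProfile | None = None,
    sad: float = DEFAULT_SAD,
    layout: MLCLayout = MILLENNIUM_120,
) -> FluenceVolume:
    """Accumulate MU-weighted, inverse-square-scaled aperture projections.

    The discrete realization of the fluence integral: every segment adds
    ``delta_MU * F * M * SAD^2/|r-s|^2`` to each voxel it covers.  Voxels
    never covered by any aperture remain exactly 0.
    """
    profile = profile or FLAT_PROFILE
    points = grid.voxel_centers()
    values = np.zeros(points.shape[0])
    for seg in segments:
        if seg.delta_mu == 0.0:
            continue
        u, w, valid = project_points(points, seg.angles, sad)
        ap = _segment_aperture(seg)
        mask = aperture_mask(u, w, ap, layout) & valid
        if not np.any(mask):
            continue
        src = seg.source
        d2 = np.sum((points[mask] - src) ** 2, axis=1)
        if np.any(d2 < _MIN_SOURCE_DIST_CM**2):
            raise DegenerateGeometryError("voxel coincides with the source position")
        values[mask] += seg.delta_mu * profile(u[mask], w[mask]) * sad**2 / d2
    return FluenceVolume(grid=grid, values=values.reshape(grid.dims))


def fluence_from_plan(
    beams: Sequence[Beam] | Beam,
    grid: GridSpec | None = None,
    profile: BeamProfile | None = None,
    step_deg: float = DEFAULT_UPSAMPLE_STEP_DEG,
) -> FluenceVolume:
    """Planned 3D fluence: up-sample each beam's control points and accumulate.

    Multiple beams/arcs are processed independently and summed.
    """
    beams = [beams] if isinstance(beams, Beam) else list(beams)
    if grid is None:
        grid = compute_volume_bounds(beams)
    total = np.zeros(grid.dims)
    ids = []
    for beam in beams:
        segs = upsample_beam(beam, step_deg=step_deg)
        layout = _beam_layout(beam)
        total += accumulate_fluence(segs, grid, profile, beam.sad, layout).values
        ids.append(beam.beam_id)
    return FluenceVolume(grid=grid, values=total,
                         provenance={"source": "plan", "beams": ids, "step_deg": step_deg})


def _beam_layout(beam: Beam) -> MLCLayout:
    try:
        return get_layout(beam.machine_model)
    except KeyError:
        return MILLENNIUM_120


def _as_record_groups(records) -> list[list[LogRecord]]:
    """Normalize one record sequence or a list of per-beam sequences."""
    if not records:
        return []
    if isinstance(records[0], LogRecord):
        return [list(records)]
    return [list(g) for g in records]


def fluence_from_log(
    records,
    grid: GridSpec,
    profile: BeamProfile | None = None,
    sad: float = DEFAULT_SAD,
    factor: int = DEFAULT_DOWNSAMPLE_FACTOR,
    layout: MLCLayout = MILLENNIUM_120,
) -> FluenceVolume:
    """Delivered 3D fluence from log records (down-sampled by ``factor``).

    ``records`` may be a single record sequence or a list of per-beam
    sequences (summed).  An empty log yields an all-zero volume.
    """
    total = np.zeros(grid.dims)
    for group in _as_record_groups(records):
        segs = downsample_log(group, factor=factor, sad=sad)
        total += accumulate_fluence(segs, grid, profile, sad, layout).values
    return FluenceVolume(grid=grid, values=total,
                         provenance={"source": "log", "factor": factor})


def compute_portal_bounds(
    beams: Sequence[Beam] | Beam,
    pixel_size: float = DEFAULT_VOXEL_CM,
    margin: float = DEFAULT_MARGIN_CM,
) -> PortalGrid:
    """Square portal-plane grid covering the maximal jaw opening + margin."""
    beams = [beams] if isinstance(beams, Beam) else list(beams)
    g = compute_volume_bounds(beams, voxel_size=pixel_size, margin=margin)
    return PortalGrid(origin=(g.origin[0], g.origin[2]), pixel_size=pixel_size,
                      dims=(g.dims[0], g.dims[2]))


def _composite_segments(source, sad: float, factor: int) -> tuple[list[DeliverySegment], MLCLayout]:
    """CP-interval (plan) or down-sampled (log) segments for the 2D composite.

    Plan control points are not angularly up-sampled here: with the gantry
    forced to 0 the up-sampling parameter is vacuous, and keeping the raw
    intervals makes the composite map bit-identical under gantry
    perturbations — the defining blindness of the 2DFC baseline.
    """
    if isinstance(source, Beam):
        source = [source]
    if source and isinstance(source[0], Beam):
        segs: list[DeliverySegment] = []
        for beam in source:
            deltas = delta_mu_sequence(beam)
            cps = beam.control_points
            for k in range(len(cps) - 1):
                a, b = cps[k], cps[k + 1]
                segs.append(DeliverySegment(
                    angles=BeamAngles(0.0, 0.0, 0.5 * (a.angles.collimator_deg
                                                       + b.angles.collimator_deg)),
                    jaws=tuple(0.5 * (np.asarray(a.jaws) + np.asarray(b.jaws))),
                    bank_a=0.5 * (a.bank_a + b.bank_a),
                    bank_b=0.5 * (a.bank_b + b.bank_b),
                    delta_mu=max(float(deltas[k]), 0.0),
                    source=np.array([0.0, -sad, 0.0]),
                ))
        return segs, _beam_layout(source[0])
    segs = []
    for group in _as_record_groups(source):
        for s in downsample_log(group, factor=factor, sad=sad):
            segs.append(DeliverySegment(
                angles=BeamAngles(0.0, 0.0, s.angles.collimator_deg),
                jaws=s.jaws, bank_a=s.bank_a, bank_b=s.bank_b,
                delta_mu=s.delta_mu, source=np.array([0.0, -sad, 0.0]),
            ))
    return segs, MILLENNIUM_120


def composite_2d_fluence(
    source,
    portal_grid: PortalGrid | None = None,
    profile: BeamProfile | None = None,
    sad: float = DEFAULT_SAD,
    factor: int = DEFAULT_DOWNSAMPLE_FACTOR,
) -> FluenceMap:
    """Composite 2D fluence with gantry (and couch) fixed at 0 (2DFC baseline).

    ``source`` is a beam, a beam list, or log records.  Pixels lie on the
    isocenter portal plane where the divergence scale is exactly 1, so each
    segment simply adds ``delta_MU * F * M``; gantry-angle changes cannot
    affect the result.
    """
    profile = profile or FLAT_PROFILE
    segs, layout = _composite_segments(source, sad, factor)
    if portal_grid is None:
        if not (isinstance(source, Beam) or (source and isinstance(source[0], Beam))):
            raise ValueError("portal_grid is required for log input")
        portal_grid = compute_portal_bounds(source)
    gu, gw = portal_grid.pixel_centers()
    values = np.zeros(gu.shape[0])
    for seg in segs:
        if seg.delta_mu == 0.0:
            continue
        rc = collimator_matrix_2d(seg.angles.collimator_deg)
        u = rc[0, 0] * gu + rc[0, 1] * gw
        w = rc[1, 0] * gu + rc[1, 1] * gw
        mask = aperture_mask(u, w, _segment_aperture(seg), layout)
        values[mask] += seg.delta_mu * profile(u[mask], w[mask])
    return FluenceMap(grid=portal_grid, values=values.reshape(portal_grid.dims))


# ---------------------------------------------------------------------------
# volume export

def export_volume(volume: FluenceVolume, path) -> None:
    """Write a fluence volume as NRRD with spacing and origin metadata (cm)."""
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.T))
    img.SetSpacing((volume.grid.voxel_size,) * 3)
    center_origin = tuple(volume.grid.origin[i] + 0.5 * volume.grid.voxel_size
                          for i in range(3))
    img.SetOrigin(center_origin)
    sitk.WriteImage(img, str(path))


def load_volume(path) -> FluenceVolume:
    """Read a volume written by :func:`export_volume` (lossless round-trip)."""
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).T
    sx, sy, sz = img.GetSpacing()
    if not (abs(sx - sy) < 1e-12 and abs(sy - sz) < 1e-12):
        raise ValueError("fluqa volumes are isotropic; anisotropic NRRD given")
    ox, oy, oz = img.GetOrigin()
    grid = GridSpec(origin=(ox - 0.5 * sx, oy - 0.5 * sx, oz - 0.5 * sx),
                    voxel_size=sx, dims=values.shape)
    return FluenceVolume(grid=grid, values=values)
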