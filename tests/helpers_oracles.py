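"""Deliberately slow, independent reference implementations used as oracles.

Everything here is written from the governing formulas with plain Python/
NumPy — explicit rotation matrices, closed-form leaf lookup, exhaustive
neighborhood enumeration — and shares no computational code with the
production package (only its data containers are consumed).
"""

import math

import numpy as np
from scipy.interpolate import RegularGridInterpolator


def _rz(deg):
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


def _ry(deg):
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, 0, s], [0, 1.0, 0], [-s, 0, c]])


def _leaf_number(w):
    """Closed-form Millennium-120 leaf-pair number; 0 when out of field."""
    if not -20.0 <= w < 20.0:
        return 0
    upsilon = int(math.floor((w + 20.0) / 0.5)) + 1
    if upsilon <= 20:
        return (upsilon - 1) // 2 + 1
    if upsilon <= 60:
        return upsilon - 10
    return (upsilon - 61) // 2 + 51


def brute_segment_fluence(points, values, state, sad):
    """Add one delivery state's contribution to ``values`` (in place).

    ``state`` is a dict with couch/gantry/collimator (deg), jaws (4, cm),
    bank_a/bank_b (60, cm), delta_mu, and source (3, cm).
    """
    if state["delta_mu"] == 0.0:
        return
    rot = _rz(-state["gantry"]) @ _ry(-state["couch"])
    th = math.radians(state["collimator"])
    ct, st = math.cos(th), math.sin(th)
    x1, x2, y1, y2 = state["jaws"]
    bank_a, bank_b = state["bank_a"], state["bank_b"]
    src = np.asarray(state["source"], dtype=float)
    for i, p in enumerate(points):
        bx, by, bz = rot @ p
        denom = by + sad
        if denom <= 1e-6:
            continue
        u0 = bx * sad / denom
        w0 = bz * sad / denom
        u = ct * u0 - st * w0
        w = st * u0 + ct * w0
        if not (x1 <= u < x2 and y1 <= w < y2):
            continue
        num = _leaf_number(w)
        if num == 0:
            continue
        if not (bank_a[num - 1] <= u < bank_b[num - 1]):
            continue
        d2 = float(np.sum((p - src) ** 2))
        values[i] += state["delta_mu"] * sad**2 / d2


def brute_fluence_from_records(records, grid, sad=100.0):
    """Per-record (factor-1) fluence accumulation, one state per log record.

    The MU increment of record ``i`` is the cumulative-MU step from record
    ``i - 1`` (from absolute zero for the first record), mirroring factor-1
    grouping of an absolute-MU log.
    """
    points = grid.voxel_centers()
    values = np.zeros(points.shape[0])
    prev = 0.0
    for rec in records:
        src = _ry(rec.angles.couch_deg) @ _rz(rec.angles.gantry_deg) @ np.array([0.0, -sad, 0.0])
        state = {
            "couch": rec.angles.couch_deg,
            "gantry": rec.angles.gantry_deg,
            "collimator": rec.angles.collimator_deg,
            "jaws": rec.jaws,
            "bank_a": rec.bank_a,
            "bank_b": rec.bank_b,
            "delta_mu": max(rec.cumulative_mu - prev, 0.0),
            "source": src,
        }
        prev = rec.cumulative_mu
        brute_segment_fluence(points, values, state, sad)
    return values.reshape(grid.dims)


def brute_fluence_from_segments(segments, grid, sad=100.0):
    """Brute per-voxel accumulation over prepared delivery segments."""
    points = grid.voxel_centers()
    values = np.zeros(points.shape[0])
    for seg in segments:
        state = {
            "couch": seg.angles.couch_deg,
            "gantry": seg.angles.gantry_deg,
            "collimator": seg.angles.collimator_deg,
            "jaws": seg.jaws,
            "bank_a": seg.bank_a,
            "bank_b": seg.bank_b,
            "delta_mu": seg.delta_mu,
            "source": seg.source,
        }
        brute_segment_fluence(points, values, state, sad)
    return values.reshape(grid.dims)


def brute_gamma(ref, ev, spacing, pct=3.0, dta_cm=0.3, cutoff=0.10,
                radius_factor=3.0, subdivisions=3):
    """Exhaustive gamma: per-voxel minimum over the full sub-voxel lattice.

    Same mathematical definition as the production search (1/subdivisions-
    voxel offsets out to radius_factor x DTA, linear interpolation of the
    evaluated distribution, candidates outside the volume excluded), but
    enumerated exhaustively per voxel with no early exit and independent
    interpolation code.  Returns (gamma_map, fail_mask, eval_mask).
    """
    ref = np.asarray(ref, dtype=float)
    ev = np.asarray(ev, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    max_ref = ref.max()
    tol = pct / 100.0 * max_ref
    radius = radius_factor * dta_cm

    axes = [np.arange(n) for n in ref.shape]
    interp = RegularGridInterpolator(axes, ev, method="linear",
                                     bounds_error=False, fill_value=np.nan)

    per_axis = []
    for s in spacing:
        step = s / subdivisions
        n = int(math.floor(radius / step + 1e-12))
        per_axis.append(np.arange(-n, n + 1) * step)
    mesh = np.meshgrid(*per_axis, indexing="ij")
    offsets = np.stack([m.ravel() for m in mesh], axis=1)
    d2 = np.sum(offsets**2, axis=1)
    offsets = offsets[d2 <= radius**2 + 1e-12]
    d2 = d2[d2 <= radius**2 + 1e-12]
    dist_pen = d2 / dta_cm**2

    eval_mask = ref >= cutoff * max_ref
    gamma_map = np.zeros_like(ref)
    for idx in np.argwhere(eval_mask):
        coords = idx + offsets / spacing
        vals = interp(coords)
        with np.errstate(invalid="ignore"):
            g2 = (vals - ref[tuple(idx)]) ** 2 / tol**2 + dist_pen
        gamma_map[tuple(idx)] = math.sqrt(np.nanmin(g2))
    fail_mask = eval_mask & (gamma_map > 1.0 + 1e-9)
    return gamma_map, fail_mask, eval_mask
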