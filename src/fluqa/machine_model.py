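"""MLC leaf geometry and the binary aperture mask.

The default layout is the Varian Millennium 120: 60 opposed leaf pairs
stacked along ``w``, the outer 10 pairs on each side 1.0 cm wide and the
central 40 pairs 0.5 cm wide, spanning -20 to +20 cm at the isocenter plane.
Leaf and jaw positions are interpreted at the isocenter plane (already
divergence-scaled), matching DICOM-RT semantics.

A portal point ``(u, w)`` is inside the aperture when it lies within the X and
Y jaw openings and between the two leaf tips of the pair addressed by ``w``.
All edges use the half-open convention ``[lower, upper)`` so that points
exactly on a boundary are resolved deterministically.  The mask is binary —
the reduction of fluence for small apertures caused by the shadowed
distributed source is deliberately not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ApertureError

#: maximum leaf-tip travel from the axis, cm at isocenter
LEAF_TRAVEL_CM = 20.0

#: tolerance for bank-crossing validation, cm
BANK_CROSS_TOL = 1e-4


def _millennium120_boundaries() -> np.ndarray:
    widths = np.concatenate([np.full(10, 1.0), np.full(40, 0.5), np.full(10, 1.0)])
    return np.concatenate([[-20.0], -20.0 + np.cumsum(widths)])


@dataclass(frozen=True)
class MLCLayout:
    """Leaf-pair geometry: 61 strictly increasing edge coordinates along w."""

    name: str
    boundaries: np.ndarray = field(repr=False)

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("boundaries must be a 1D sequence of >= 2 edges")
        if not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_pairs(self) -> int:
        return self.boundaries.size - 1

    def leaf_widths(self) -> np.ndarray:
        return np.diff(self.boundaries)

    def pair_index(self, w) -> np.ndarray:
        """1-based leaf-pair number(s) for portal coordinate(s) ``w``.

        Vectorized boundary-table lookup with half-open intervals
        ``[b[i], b[i+1])``; returns 0 for out-of-field points.
        """
        w = np.asarray(w, dtype=float)
        idx = np.searchsorted(self.boundaries, w, side="right")
        out = np.where((idx >= 1) & (idx <= self.n_pairs), idx, 0)
        return out if out.ndim else int(out)


MILLENNIUM_120 = MLCLayout("Millennium120", _millennium120_boundaries())

_REGISTRY: dict[str, MLCLayout] = {
    MILLENNIUM_120.name: MILLENNIUM_120,
    # long-form alias; the short name fits the 16-char DICOM SH value limit
    "Varian_Millennium_120": MILLENNIUM_120,
}


def get_layout(name: str) -> MLCLayout:
    """Look up a registered MLC layout by machine model name."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown MLC layout {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None


def register_layout(layout: MLCLayout) -> None:
    _REGISTRY[layout.name] = layout


def load_layout(path, name: str | None = None) -> MLCLayout:
    """Load a custom layout from a plain-text file of 61 boundary values (cm)."""
    path = Path(path)
    values = np.array(
        [float(tok) for tok in path.read_text().split() if not tok.startswith("#")]
    )
    layout = MLCLayout(name or path.stem, values)
    register_layout(layout)
    return layout


def leaf_index(w: float) -> int:
    """Millennium-120 leaf-pair number for portal coordinate ``w``.

    Closed form: the 0.5 cm sub-slot index is ``upsilon = int((w+20)/0.5) + 1``
    in [1, 80]; the outer slots map two-to-one onto the 1 cm leaves::

        L = int((upsilon-1)/2) + 1    for upsilon in [1, 20]
        L = upsilon - 10              for upsilon in [21, 60]
        L = int((upsilon-61)/2) + 51  for upsilon in [61, 80]

    Raises ``ValueError`` out of field (|w| >= 20).  Equivalent to
    ``MILLENNIUM_120.pair_index(w)`` (property-tested).
    """
    if not -LEAF_TRAVEL_CM <= w < LEAF_TRAVEL_CM:
        raise ValueError(f"w={w:g} cm is outside the leaf bank (|w| >= 20)")
    upsilon = int(math.floor((w + 20.0) / 0.5)) + 1
    if 1 <= upsilon <= 20:
        return (upsilon - 1) // 2 + 1
    if 21 <= upsilon <= 60:
        return upsilon - 10
    return (upsilon - 61) // 2 + 51


@dataclass(frozen=True)
class Aperture:
    """Jaw edges plus one leaf-tip position per bank, cm at isocenter.

    ``bank_a`` is the left (negative-u) bank; a closed pair has
    ``bank_a[i] == bank_b[i]`` (a zero gap admits no points under the
    half-open convention).
    """

    x1: float
    x2: float
    y1: float
    y2: float
    bank_a: np.ndarray = field(repr=False)
    bank_b: np.ndarray = field(repr=False)


def aperture_from_state(jaws, bank_a, bank_b, n_pairs: int = 60) -> Aperture:
    """Build a validated :class:`Aperture` from raw jaw and leaf values.

    ``jaws`` is ``(x1, x2, y1, y2)``.  Banks are normalized so that ``bank_a``
    is the smaller-u bank; crossings beyond tolerance and tips outside the
    leaf travel range are rejected.
    """
    x1, x2, y1, y2 = (float(v) for v in jaws)
    if x1 > x2 or y1 > y2:
        raise ApertureError(f"jaw edges not ordered: x=({x1},{x2}), y=({y1},{y2})")
    a = np.asarray(bank_a, dtype=float).copy()
    b = np.asarray(bank_b, dtype=float).copy()
    if a.shape != (n_pairs,) or b.shape != (n_pairs,):
        raise ApertureError(f"expected {n_pairs} leaf positions per bank")
    cross = a - b
    if np.any(cross > BANK_CROSS_TOL):
        i = int(np.argmax(cross))
        raise ApertureError(
            f"leaf pair {i + 1} crossed: A={a[i]:g} > B={b[i]:g} cm"
        )
    # within tolerance, snap touching pairs closed
    touching = cross > 0
    if np.any(touching):
        mid = 0.5 * (a[touching] + b[touching])
        a[touching] = mid
        b[touching] = mid
    if np.any(np.abs(a) > LEAF_TRAVEL_CM) or np.any(np.abs(b) > LEAF_TRAVEL_CM):
        raise ApertureError("leaf tip outside +/-20 cm travel range")
    return Aperture(x1, x2, y1, y2, a, b)


def aperture_mask(u, w, ap: Aperture, layout: MLCLayout = MILLENNIUM_120) -> np.ndarray:
    """Binary aperture mask M for portal coordinates ``u``, ``w`` (vectorized).

    True where the point is inside both jaw openings and strictly between the
    leaf tips of its pair; False out of field.  NaN coordinates map to False.
    """
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    with np.errstate(invalid="ignore"):
        inside_jaws = (u >= ap.x1) & (u < ap.x2) & (w >= ap.y1) & (w < ap.y2)
        pair = layout.pair_index(np.where(np.isnan(w), layout.boundaries[0] - 1.0, w))
        in_field = pair > 0
        idx = np.where(in_field, pair - 1, 0)
        between = (u >= ap.bank_a[idx]) & (u < ap.bank_b[idx])
    return inside_jaws & in_field & between


def in_aperture(p, ap: Aperture, layout: MLCLayout = MILLENNIUM_120) -> bool:
    """Scalar aperture-mask value for a portal point ``p = (u, w)``."""
    u, w = p
    return bool(aperture_mask(np.array([u]), np.array([w]), ap, layout)[0])
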