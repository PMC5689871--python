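"""Synthetic VMAT/IMRT plans and matched delivery logs for testing and demos.

The generator emulates the delivery conditions the method targets: single- or
multi-arc VMAT plans with 91 control points per 360-degree arc (4 degrees per
control point) delivered in about two minutes, so a matched trajectory log at
20 ms sampling holds on the order of 6000 records per arc.  Leaf patterns
range from a plain open field to a seeded sliding-window modulation, a
smoothed random-leaf pattern, and a "closed-junction" pattern that parks
closed leaf pairs inside the jaw-defined field (the classic step-and-shoot
planning error this QA class is meant to catch).

A matched log traces the plan's linear inter-control-point trajectories at a
constant dose rate.  With ``noise=None`` (or all-zero noise) the log is an
exact delivery: its reconstructed fluence matches the plan's within
discretization tolerance and yields 0% failing rates in both QA tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import BeamAngles
from .log_io import DEFAULT_SAMPLING_INTERVAL_S, LogRecord
from .machine_model import MILLENNIUM_120
from .plan_io import Beam, ControlPoint

PATTERNS = ("open", "sliding-window", "random-leaf", "closed-junction")


@dataclass(frozen=True)
class PlanRecipe:
    """Parameters of a synthetic VMAT plan.

    ``field_size_cm`` is the square jaw opening; ``total_mu`` is split evenly
    across arcs.  All randomness (random-leaf pattern, modulation phases) is
    driven by ``seed``.
    """

    n_arcs: int = 1
    cps_per_arc: int = 91
    arc_span_deg: float = 360.0
    total_mu: float = 600.0
    field_size_cm: float = 10.0
    pattern: str = "sliding-window"
    collimator_deg: float = 0.0
    couch_deg: float = 0.0
    sad: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.cps_per_arc < 2:
            raise ValueError("cps_per_arc must be >= 2")
        if self.total_mu <= 0:
            raise ValueError("total_mu must be positive")
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; choose from {PATTERNS}")
        if not 0 < self.field_size_cm <= 40:
            raise ValueError("field_size_cm must be in (0, 40]")


@dataclass(frozen=True)
class LogNoise:
    """Zero-mean Gaussian tracking-noise standard deviations per axis."""

    gantry_deg: float = 0.0
    collimator_deg: float = 0.0
    couch_deg: float = 0.0
    jaw_cm: float = 0.0
    mlc_cm: float = 0.0
    mu: float = 0.0

    def any(self) -> bool:
        return any(v > 0 for v in
                   (self.gantry_deg, self.collimator_deg, self.couch_deg,
                    self.jaw_cm, self.mlc_cm, self.mu))


def _contributing_pairs(jaws, layout=MILLENNIUM_120) -> np.ndarray:
    """Boolean mask of leaf pairs whose width interval overlaps the Y jaws."""
    lo, hi = jaws[2], jaws[3]
    lower = layout.boundaries[:-1]
    upper = layout.boundaries[1:]
    return (upper > lo) & (lower < hi)


def _leaf_pattern(recipe: PlanRecipe, frac: float, rng: np.random.Generator,
                  walk_state: np.ndarray | None):
    """Bank positions for one control point at arc fraction ``frac``."""
    half = recipe.field_size_cm / 2.0
    layout = MILLENNIUM_120
    n = layout.n_pairs
    bank_a = np.full(n, -half)
    bank_b = np.full(n, half)
    inside = _contributing_pairs((-half, half, -half, half), layout)
    centers = 0.5 * (layout.boundaries[:-1] + layout.boundaries[1:])

    if recipe.pattern == "open":
        pass
    elif recipe.pattern in ("sliding-window", "closed-junction"):
        # seeded per-pair phases make the window sweep spatially modulated
        phase_rng = np.random.default_rng(recipe.seed)
        phases = phase_rng.uniform(0, 2 * np.pi, n)
        gap = max(0.25 * recipe.field_size_cm, 0.6)
        amp = half - gap / 2.0
        c = amp * np.sin(2 * np.pi * frac + phases + centers / 8.0)
        bank_a = np.clip(c - gap / 2.0, -half, half)
        bank_b = np.clip(c + gap / 2.0, -half, half)
        if recipe.pattern == "closed-junction":
            # park two adjacent central pairs closed inside the open field
            junction = np.where(inside)[0]
            mid = junction[len(junction) // 2]
            bank_a[mid : mid + 2] = 0.0
            bank_b[mid : mid + 2] = 0.0
    elif recipe.pattern == "random-leaf":
        step = 0.15 * recipe.field_size_cm
        walk_state += rng.uniform(-step, step, walk_state.shape)
        walk_state[:] = np.clip(walk_state, -half * 0.8, half * 0.8)
        gap = max(0.2 * recipe.field_size_cm, 0.5)
        bank_a = np.clip(walk_state[0] - gap / 2.0 - np.abs(walk_state[2]), -half, half)
        bank_b = np.clip(walk_state[1] + gap / 2.0 + np.abs(walk_state[3]), -half, half)
        crossed = bank_a > bank_b
        mid_pos = 0.5 * (bank_a + bank_b)
        bank_a[crossed] = mid_pos[crossed]
        bank_b[crossed] = mid_pos[crossed]

    # pairs fully outside the Y jaws are parked closed at the field edge
    bank_a[~inside] = -half
    bank_b[~inside] = -half
    return bank_a, bank_b


def generate_synthetic_plan(recipe: PlanRecipe) -> list[Beam]:
    """Deterministic synthetic plan satisfying all plan invariants.

    Arcs alternate rotation direction (as clinical multi-arc plans do) and
    share the meterset evenly.  Cumulative weights are spaced evenly from 0
    to 1 over each arc's control points.
    """
    rng = np.random.default_rng(recipe.seed)
    half = recipe.field_size_cm / 2.0
    jaws = (-half, half, -half, half)
    beams = []
    for arc in range(recipe.n_arcs):
        n_cp = recipe.cps_per_arc
        direction = 1 if arc % 2 == 0 else -1
        start = 180.0 if direction == 1 else 180.0 + recipe.arc_span_deg
        walk = rng.uniform(-half / 2, half / 2, (4, MILLENNIUM_120.n_pairs))
        cps = []
        for k in range(n_cp):
            frac = k / (n_cp - 1)
            gantry = start + direction * recipe.arc_span_deg * frac
            bank_a, bank_b = _leaf_pattern(recipe, frac, rng, walk)
            cps.append(ControlPoint(
                index=k,
                angles=BeamAngles(recipe.couch_deg, gantry % 360.0,
                                  recipe.collimator_deg),
                jaws=jaws,
                bank_a=bank_a,
                bank_b=bank_b,
                cumulative_weight=frac,
            ))
        beams.append(Beam(
            beam_id=f"synth-arc-{arc + 1}",
            sad=recipe.sad,
            total_mu=recipe.total_mu / recipe.n_arcs,
            control_points=tuple(cps),
        ))
    return beams


def generate_matched_log(
    beams,
    duration_s: float = 120.0,
    noise: LogNoise | None = None,
    dt: float = DEFAULT_SAMPLING_INTERVAL_S,
    seed: int = 0,
):
    """Trajectory-log records tracing the plan at constant dose rate.

    For a single :class:`Beam` returns one record list; for a beam sequence
    returns a list of per-beam record lists (down-sampling groups must not
    straddle the gantry jump between arcs).  ``duration_s`` applies per beam.
    Records are spaced ``dt`` apart with cumulative MU rising linearly from 0
    to the beam meterset, and all axes linearly interpolated between control
    points at the matching meterset fraction — exactly the machine's stated
    interpolation behaviour.  Optional zero-mean Gaussian tracking noise is
    added per axis.
    """
    single = isinstance(beams, Beam)
    beam_list = [beams] if single else list(beams)
    noise = noise or LogNoise()
    rng = np.random.default_rng(seed)
    logs = []
    for beam in beam_list:
        logs.append(_one_beam_log(beam, duration_s, noise, dt, rng))
    return logs[0] if single else logs


def _one_beam_log(beam: Beam, duration_s: float, noise: LogNoise, dt: float,
                  rng: np.random.Generator) -> list[LogRecord]:
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    from .geometry import unwrap_degrees
    from .plan_io import _interp_cp

    cps = beam.control_points
    weights = np.array([cp.cumulative_weight for cp in cps]) / beam.final_weight
    gantry_track = unwrap_degrees([cp.angles.gantry_deg for cp in cps])
    n = max(2, round(duration_s / dt))
    dose_rate = beam.total_mu / duration_s
    records = []
    for i in range(n):
        t = i * dt
        mu_frac = i / (n - 1)
        k = min(int(np.searchsorted(weights, mu_frac, side="right")) - 1, len(cps) - 2)
        k = max(k, 0)
        span = weights[k + 1] - weights[k]
        f = 0.0 if span <= 0 else (mu_frac - weights[k]) / span
        state = _interp_cp(cps[k], cps[k + 1], min(f, 1.0),
                           (gantry_track[k], gantry_track[k + 1]))
        g = state.angles.gantry_deg + rng.normal(0, noise.gantry_deg) if noise.gantry_deg else state.angles.gantry_deg
        c = state.angles.collimator_deg + (rng.normal(0, noise.collimator_deg) if noise.collimator_deg else 0.0)
        s = state.angles.couch_deg + (rng.normal(0, noise.couch_deg) if noise.couch_deg else 0.0)
        jaws = np.asarray(state.jaws, dtype=float)
        if noise.jaw_cm:
            jaws = jaws + rng.normal(0, noise.jaw_cm, 4)
        bank_a, bank_b = state.bank_a, state.bank_b
        if noise.mlc_cm:
            bank_a = bank_a + rng.normal(0, noise.mlc_cm, bank_a.shape)
            bank_b = bank_b + rng.normal(0, noise.mlc_cm, bank_b.shape)
            crossed = bank_a > bank_b
            mid = 0.5 * (bank_a + bank_b)
            bank_a = np.where(crossed, mid, bank_a)
            bank_b = np.where(crossed, mid, bank_b)
        cum = beam.total_mu * mu_frac
        if noise.mu and 0 < i < n - 1:
            cum = float(np.clip(cum + rng.normal(0, noise.mu), 0.0, beam.total_mu))
        records.append(LogRecord(
            time=t,
            angles=BeamAngles(s, g % 360.0, c),
            jaws=tuple(jaws),
            bank_a=np.asarray(bank_a),
            bank_b=np.asarray(bank_b),
            cumulative_mu=cum,
            dose_rate=dose_rate,
        ))
    # noise on cumulative MU must not break monotonicity
    if noise.mu:
        cms = np.maximum.accumulate([r.cumulative_mu for r in records])
        records = [LogRecord(r.time, r.angles, r.jaws, r.bank_a, r.bank_b,
                             float(cm), r.dose_rate)
                   for r, cm in zip(records, cms)]
    return records


def interrupted_delivery(records: list[LogRecord], delivered_fraction: float = 0.9) -> list[LogRecord]:
    """Truncate a log to the first ``delivered_fraction`` of its records.

    Emulates a delivery interruption (beam-off partway through the arc); the
    reconstructed fluence then misses the tail of the plan.
    """
    if not 0 < delivered_fraction <= 1:
        raise ValueError("delivered_fraction must be in (0, 1]")
    return records[: max(1, int(len(records) * delivered_fraction))]
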