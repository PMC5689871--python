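"""Delivery-error injection, sensitivity sweeps, and passing-rate correlation.

Five error families are modelled, matching the TG-142-style tolerances of a
clinical C-arm linac:

========== =========== ============== =======================
error      tolerance   within regime  outside regime
========== =========== ============== =======================
gantry     1 degree    uniform        uniform in [1, 2] deg
MU         1 MU        uniform        uniform in [1, 2] MU
jaw        1 mm        uniform        uniform in [1, 2] mm
collimator 1 degree    uniform        uniform in [1, 2] deg
MLC        2 mm        Gaussian       uniform in [2, 3] mm
========== =========== ============== =======================

Within-tolerance draws are magnitudes in [0, tolerance] with random sign
(Gaussian for MLC: sigma = tolerance/2, truncated at the tolerance); the
outside regime uses the uniform magnitude ranges above, signed.  Errors are
injected into plans, per control point; MLC shifts touch only leaves that
actually contribute (open pairs inside the Y-jaw window), in either
direction, and bank crossings caused by a shift are clamped closed.

The sensitivity sweep scales one unit-magnitude draw per replicate across
all requested error levels (common random numbers), so the mean failing-rate
curve rises monotonically without Monte-Carlo jitter between levels.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np

from .compare import TestCriteria, gamma_analysis_3d, intensity_difference_test
from .exceptions import UndefinedCorrelationError
from .fluence import (
    FluenceMap,
    FluenceVolume,
    composite_2d_fluence,
    compute_portal_bounds,
    compute_volume_bounds,
    fluence_from_plan,
)
from .geometry import BeamAngles
from .machine_model import LEAF_TRAVEL_CM, MILLENNIUM_120
from .plan_io import Beam, ControlPoint, delta_mu_sequence
from .synthetic import _contributing_pairs

ERROR_TYPES = ("gantry", "MU", "jaw", "collimator", "MLC")

#: machine tolerance per error family (deg | MU | cm)
TOLERANCES = {"gantry": 1.0, "MU": 1.0, "jaw": 0.1, "collimator": 1.0, "MLC": 0.2}

#: out-of-tolerance magnitude ranges (deg | MU | cm)
OUTSIDE_RANGES = {
    "gantry": (1.0, 2.0),
    "MU": (1.0, 2.0),
    "jaw": (0.1, 0.2),
    "collimator": (1.0, 2.0),
    "MLC": (0.2, 0.3),
}

DEFAULT_DISTRIBUTIONS = {
    "gantry": "uniform", "MU": "uniform", "jaw": "uniform",
    "collimator": "uniform", "MLC": "gaussian",
}


@dataclass(frozen=True)
class ErrorSpec:
    """One error family with its magnitude bounds and distribution."""

    error_type: str
    low: float
    high: float
    distribution: str | None = None
    per_control_point: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.error_type not in ERROR_TYPES:
            raise ValueError(f"unknown error_type {self.error_type!r}; choose from {ERROR_TYPES}")
        if self.low < 0 or self.high < self.low:
            raise ValueError("need 0 <= low <= high")
        dist = self.distribution or DEFAULT_DISTRIBUTIONS[self.error_type]
        if dist not in ("uniform", "gaussian"):
            raise ValueError(f"unknown distribution {dist!r}")
        object.__setattr__(self, "distribution", dist)

    @classmethod
    def within_tolerance(cls, error_type: str, seed: int = 0, scale: float = 1.0) -> "ErrorSpec":
        """Magnitudes in [0, scale x tolerance], family-default distribution."""
        return cls(error_type, 0.0, scale * TOLERANCES[error_type], seed=seed)

    @classmethod
    def outside_tolerance(cls, error_type: str, seed: int = 0) -> "ErrorSpec":
        """Out-of-tolerance regime: signed uniform in the published ranges."""
        low, high = OUTSIDE_RANGES[error_type]
        return cls(error_type, low, high, distribution="uniform", seed=seed)


def _draw_signed(rng: np.random.Generator, spec: ErrorSpec, size) -> np.ndarray:
    """Signed error draws honoring the spec's distribution and bounds."""
    if spec.high == 0.0:
        return np.zeros(size)
    sign = rng.choice([-1.0, 1.0], size=size)
    if spec.distribution == "uniform":
        mag = rng.uniform(spec.low, spec.high, size=size)
        return sign * mag
    # truncated Gaussian magnitudes: sigma = high/2, redraw beyond the bound
    sigma = spec.high / 2.0
    draws = rng.normal(0.0, sigma, size=size)
    bad = np.abs(draws) > spec.high
    while np.any(bad):
        draws[bad] = rng.normal(0.0, sigma, size=int(bad.sum()))
        bad = np.abs(draws) > spec.high
    if spec.low > 0:
        draws = np.sign(draws) * np.clip(np.abs(draws), spec.low, spec.high)
    return draws


def inject_errors(beams: Sequence[Beam] | Beam, spec: ErrorSpec) -> list[Beam]:
    """Return a deep-copied plan with the spec's errors added per control point.

    Only the targeted axis changes; everything else is untouched.  The result
    is bit-identical for identical spec + seed.
    """
    single = isinstance(beams, Beam)
    beam_list = [beams] if single else list(beams)
    rng = np.random.default_rng(spec.seed)
    out = [_inject_beam(beam, spec, rng) for beam in beam_list]
    return out[0] if single else out


def _inject_beam(beam: Beam, spec: ErrorSpec, rng: np.random.Generator) -> Beam:
    cps = [copy.deepcopy(cp) for cp in beam.control_points]
    n = len(cps)
    total_mu = beam.total_mu

    if spec.error_type == "gantry":
        errs = _draw_signed(rng, spec, n)
        cps = [dc_replace(cp, angles=BeamAngles(
            cp.angles.couch_deg, cp.angles.gantry_deg + e, cp.angles.collimator_deg))
            for cp, e in zip(cps, errs)]
    elif spec.error_type == "collimator":
        errs = _draw_signed(rng, spec, n)
        cps = [dc_replace(cp, angles=BeamAngles(
            cp.angles.couch_deg, cp.angles.gantry_deg, cp.angles.collimator_deg + e))
            for cp, e in zip(cps, errs)]
    elif spec.error_type == "jaw":
        errs = _draw_signed(rng, spec, (n, 4))
        cps = [dc_replace(cp, jaws=tuple(np.asarray(cp.jaws) + e))
               for cp, e in zip(cps, errs)]
    elif spec.error_type == "MU":
        # perturb the per-interval meterset increments, then rebuild weights
        deltas = delta_mu_sequence(beam)
        errs = _draw_signed(rng, spec, n - 1)
        new_deltas = np.maximum(deltas + errs, 0.0)
        total_mu = float(new_deltas.sum())
        cum = np.concatenate([[0.0], np.cumsum(new_deltas)])
        final = cum[-1] if cum[-1] > 0 else 1.0
        cps = [dc_replace(cp, cumulative_weight=float(c / final))
               for cp, c in zip(cps, cum)]
    elif spec.error_type == "MLC":
        for i, cp in enumerate(cps):
            contributing = _contributing_pairs(cp.jaws) & (cp.bank_b - cp.bank_a > 1e-6)
            m = int(contributing.sum())
            if m == 0:
                continue
            ea = _draw_signed(rng, spec, m)
            eb = _draw_signed(rng, spec, m)
            bank_a = cp.bank_a.copy()
            bank_b = cp.bank_b.copy()
            bank_a[contributing] += ea
            bank_b[contributing] += eb
            np.clip(bank_a, -LEAF_TRAVEL_CM, LEAF_TRAVEL_CM, out=bank_a)
            np.clip(bank_b, -LEAF_TRAVEL_CM, LEAF_TRAVEL_CM, out=bank_b)
            crossed = bank_a > bank_b
            mid = 0.5 * (bank_a + bank_b)
            bank_a[crossed] = mid[crossed]
            bank_b[crossed] = mid[crossed]
            cps[i] = dc_replace(cp, bank_a=bank_a, bank_b=bank_b)

    return Beam(beam_id=beam.beam_id, sad=beam.sad, total_mu=total_mu,
                control_points=tuple(cps), machine_model=beam.machine_model)


@dataclass
class SensitivityCurve:
    """Mean failing rates vs normalized error level for one error family."""

    error_type: str
    levels_pct: np.ndarray
    f_intensity_3d: np.ndarray
    f_gamma_3d: np.ndarray
    f_intensity_2d: np.ndarray | None = None
    f_gamma_2d: np.ndarray | None = None


def _scaled_injection(beams, error_type, unit_spec_seed, magnitude):
    """Inject errors with magnitudes scaled to ``magnitude`` x tolerance,
    reusing the same underlying draws (common random numbers)."""
    spec = ErrorSpec(error_type, 0.0, magnitude * TOLERANCES[error_type],
                     seed=unit_spec_seed)
    return inject_errors(beams, spec)


def sensitivity_sweep(
    beams: Sequence[Beam],
    error_types: Sequence[str] = ERROR_TYPES,
    levels_pct: Sequence[float] = (25.0, 50.0, 100.0, 150.0, 200.0),
    n_reps: int = 10,
    seed: int = 0,
    criteria: TestCriteria | None = None,
    voxel_size: float = 0.3,
    step_deg: float = 1.0,
    include_2d: bool = True,
) -> dict[str, SensitivityCurve]:
    """Failing rates of 3DFC (and optionally 2DFC) vs normalized error level.

    Levels are percentages of each family's tolerance.  The reference is the
    unmodified plan's own fluence; each replicate reuses one seeded draw
    across all levels so the mean curves are monotone up to the physics, not
    the sampling.
    """
    criteria = criteria or TestCriteria()
    levels = np.asarray(sorted(levels_pct), dtype=float)
    grid = compute_volume_bounds(beams, voxel_size=voxel_size)
    ref3d = fluence_from_plan(beams, grid, step_deg=step_deg)
    portal = compute_portal_bounds(beams, pixel_size=voxel_size)
    ref2d = composite_2d_fluence(beams, portal) if include_2d else None
    ss = np.random.SeedSequence(seed)
    curves: dict[str, SensitivityCurve] = {}
    for error_type in error_types:
        rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_reps)]
        fi3 = np.zeros((n_reps, levels.size))
        fg3 = np.zeros((n_reps, levels.size))
        fi2 = np.zeros((n_reps, levels.size))
        fg2 = np.zeros((n_reps, levels.size))
        for r, rep_seed in enumerate(rep_seeds):
            for li, level in enumerate(levels):
                if level == 0:
                    continue
                modified = _scaled_injection(beams, error_type, rep_seed, level / 100.0)
                ev3 = fluence_from_plan(modified, grid, step_deg=step_deg)
                _, fi3[r, li] = intensity_difference_test(ref3d, ev3, criteria)
                _, fg3[r, li] = gamma_analysis_3d(ref3d, ev3, criteria)
                if include_2d:
                    ev2 = composite_2d_fluence(modified, portal)
                    _, fi2[r, li] = intensity_difference_test(ref2d, ev2, criteria)
                    _, fg2[r, li] = gamma_analysis_3d(ref2d, ev2, criteria)
        curves[error_type] = SensitivityCurve(
            error_type=error_type,
            levels_pct=levels,
            f_intensity_3d=fi3.mean(axis=0),
            f_gamma_3d=fg3.mean(axis=0),
            f_intensity_2d=fi2.mean(axis=0) if include_2d else None,
            f_gamma_2d=fg2.mean(axis=0) if include_2d else None,
        )
    return curves


def correlate_passing_rates(group_a: Sequence[float], group_b: Sequence[float]):
    """Pearson r plus Spearman rho (average ranks on ties) with two-sided p.

    Raises :class:`~fluqa.exceptions.UndefinedCorrelationError` when either
    sample has zero variance.
    """
    from scipy import stats

    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need two equal-length 1D samples with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("zero variance in one of the samples")
    pearson = stats.pearsonr(a, b)
    spearman = stats.spearmanr(a, b)
    return float(pearson.statistic), float(spearman.statistic), float(spearman.pvalue)
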