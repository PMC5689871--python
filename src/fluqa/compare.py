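"""QA verdicts: intensity-difference test, gamma analysis, and reports.

Both tests use global normalization to the maximum of the reference (plan)
volume.  Voxels below 10% of that maximum are excluded from analysis, and
the failing rate denominator is the number of voxels above that cutoff.

* Difference test: a voxel fails when ``|eval - ref| >= diff_pct% of max``.
* Gamma: for every evaluated reference voxel,
  ``gamma = min over the search neighborhood of
  sqrt(dose_diff^2 / tol^2 + dist^2 / dta^2)``;
  a voxel fails when ``gamma > 1`` (gamma of exactly 1 passes).  The search
  covers a radius of 3 x DTA with sub-voxel refinement on a 1/3-voxel
  lattice via trilinear interpolation of the evaluated volume.

Because the gamma dose term at zero offset equals the difference-test ratio,
every voxel passing the difference test passes gamma: ``F_gamma <= F_I`` for
matched criteria, structurally.

The clinic-style action level is a 5% failing rate on the 3%/3 mm gamma:
above it the verdict is "investigate", otherwise "pass".
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .exceptions import GridMismatchError
from .fluence import FluenceMap, FluenceVolume

_GAMMA_TIE_EPS = 1e-9


@dataclass(frozen=True)
class TestCriteria:
    """Acceptance criteria for the two comparison tests.

    Percentages are of the reference maximum (global normalization); the DTA
    is in mm.  The action level applies to the gamma failing rate.
    """

    __test__ = False  # keep pytest from collecting this as a test class

    diff_pct: float = 3.0
    gamma_pct: float = 3.0
    gamma_dta_mm: float = 3.0
    low_cutoff_fraction: float = 0.10
    action_level_fraction: float = 0.05

    def __post_init__(self):
        if min(self.diff_pct, self.gamma_pct, self.gamma_dta_mm,
               self.low_cutoff_fraction, self.action_level_fraction) <= 0:
            raise ValueError("all criteria must be strictly positive")
        if self.low_cutoff_fraction >= 1:
            raise ValueError("low_cutoff_fraction must be < 1")


@dataclass
class ComparisonResult:
    """Per-voxel maps plus summary failing rates and the QA verdict."""

    criteria: TestCriteria
    diff_map: np.ndarray = field(repr=False)
    gamma_map: np.ndarray = field(repr=False)
    f_intensity: float = 0.0
    f_gamma: float = 0.0
    mean_abs_error_mu: float = 0.0
    sd_abs_error_mu: float = 0.0
    max_abs_error_mu: float = 0.0
    evaluated_voxel_count: int = 0
    verdict: str = "pass"

    def summary_dict(self) -> dict:
        d = asdict(self)
        d.pop("diff_map")
        d.pop("gamma_map")
        d["criteria"] = asdict(self.criteria)
        return d


def _unpack(volume, spacing=None):
    if isinstance(volume, (FluenceVolume, FluenceMap)):
        return np.asarray(volume.values, dtype=float), volume.spacing
    if spacing is None:
        raise ValueError("spacing is required for raw-array input")
    arr = np.asarray(volume, dtype=float)
    return arr, tuple(spacing if np.ndim(spacing) else [spacing] * arr.ndim)


def _check_grids(reference, evaluated):
    if isinstance(reference, (FluenceVolume, FluenceMap)) and isinstance(
        evaluated, (FluenceVolume, FluenceMap)
    ):
        if reference.grid != evaluated.grid:
            raise GridMismatchError("reference and evaluated volumes use different grids")


def _prepare(reference, evaluated, criteria, spacing=None):
    _check_grids(reference, evaluated)
    ref, ref_spacing = _unpack(reference, spacing)
    ev, _ = _unpack(evaluated, spacing)
    if ref.shape != ev.shape:
        raise GridMismatchError(
            f"shape mismatch: reference {ref.shape} vs evaluated {ev.shape}"
        )
    max_ref = float(ref.max(initial=0.0))
    if max_ref <= 0:
        raise ValueError("reference volume is all zero; nothing to evaluate")
    evaluated_mask = ref >= criteria.low_cutoff_fraction * max_ref
    return ref, ev, ref_spacing, max_ref, evaluated_mask


def intensity_difference_test(reference, evaluated, criteria: TestCriteria | None = None,
                              spacing=None):
    """Global intensity-difference test.

    Returns ``(diff_map, f_intensity)``: the signed per-voxel difference
    (evaluated - reference, MU) and the fraction of above-cutoff voxels whose
    absolute difference reaches ``diff_pct`` % of the reference maximum.
    """
    criteria = criteria or TestCriteria()
    ref, ev, _, max_ref, mask = _prepare(reference, evaluated, criteria, spacing)
    diff = ev - ref
    tol = criteria.diff_pct / 100.0 * max_ref
    failing = mask & (np.abs(diff) >= tol - _GAMMA_TIE_EPS * max_ref)
    n_eval = int(mask.sum())
    return diff, float(failing.sum() / n_eval) if n_eval else 0.0


def gamma_analysis_3d(reference, evaluated, criteria: TestCriteria | None = None,
                      spacing=None, search_radius_factor: float = 3.0,
                      subdivisions: int = 3):
    """Global gamma analysis with distance-to-agreement search.

    Works on 3D volumes and 2D composite maps alike.  Returns
    ``(gamma_map, f_gamma)``; the gamma map is 0 outside the evaluated
    (above-cutoff) region.  The neighborhood search runs over a
    ``1/subdivisions``-voxel offset lattice out to
    ``search_radius_factor x DTA``, interpolating the evaluated volume
    (tri)linearly, with early exit once no voxel can improve.
    """
    criteria = criteria or TestCriteria()
    ref, ev, spacing_cm, max_ref, mask = _prepare(reference, evaluated, criteria, spacing)
    dose_tol = criteria.gamma_pct / 100.0 * max_ref
    dta_cm = criteria.gamma_dta_mm / 10.0
    radius = search_radius_factor * dta_cm
    ndim = ref.ndim

    idx = np.argwhere(mask).astype(float)  # (M, ndim) voxel indices
    gamma2 = ((ev[mask] - ref[mask]) / dose_tol) ** 2
    ref_vals = ref[mask]

    # offset lattice in cm, sorted by distance, zero offset excluded
    steps = []
    for s in spacing_cm:
        n = int(math.ceil(radius / (s / subdivisions) - 1e-12))
        steps.append(np.arange(-n, n + 1) * (s / subdivisions))
    offsets = np.array(list(itertools.product(*steps)))
    dist2 = np.sum(offsets**2, axis=1)
    keep = (dist2 > 0) & (dist2 <= radius**2 + 1e-12)
    offsets, dist2 = offsets[keep], dist2[keep]
    order = np.argsort(dist2)
    offsets, dist2 = offsets[order], dist2[order]

    active = np.arange(idx.shape[0])
    shape = np.array(ref.shape)
    spacing_arr = np.array(spacing_cm)
    for off, d2 in zip(offsets, dist2):
        dist_pen = d2 / dta_cm**2
        still = gamma2[active] > dist_pen + _GAMMA_TIE_EPS
        active = active[still]
        if active.size == 0:
            break
        coords = idx[active] + off / spacing_arr
        inside = np.all((coords >= 0) & (coords <= shape - 1), axis=1)
        if not np.any(inside):
            continue
        sel = active[inside]
        interp = map_coordinates(ev, idx[sel].T + (off / spacing_arr)[:, None],
                                 order=1, mode="nearest")
        cand = ((interp - ref[tuple(idx[sel].astype(int).T)]) / dose_tol) ** 2 + dist_pen
        gamma2[sel] = np.minimum(gamma2[sel], cand)

    gamma_map = np.zeros_like(ref)
    gamma_map[mask] = np.sqrt(gamma2)
    failing = gamma2 > 1.0 + _GAMMA_TIE_EPS
    n_eval = int(mask.sum())
    return gamma_map, float(failing.sum() / n_eval) if n_eval else 0.0


def compare_volumes(reference, evaluated, criteria: TestCriteria | None = None,
                    spacing=None) -> ComparisonResult:
    """Run both tests and assemble the full comparison result with verdict."""
    criteria = criteria or TestCriteria()
    ref, ev, _, max_ref, mask = _prepare(reference, evaluated, criteria, spacing)
    diff_map, f_i = intensity_difference_test(reference, evaluated, criteria, spacing)
    gamma_map, f_g = gamma_analysis_3d(reference, evaluated, criteria, spacing)
    abs_err = np.abs(diff_map[mask])
    return ComparisonResult(
        criteria=criteria,
        diff_map=diff_map,
        gamma_map=gamma_map,
        f_intensity=f_i,
        f_gamma=f_g,
        mean_abs_error_mu=float(abs_err.mean()) if abs_err.size else 0.0,
        sd_abs_error_mu=float(abs_err.std()) if abs_err.size else 0.0,
        max_abs_error_mu=float(abs_err.max()) if abs_err.size else 0.0,
        evaluated_voxel_count=int(mask.sum()),
        verdict="investigate" if f_g > criteria.action_level_fraction else "pass",
    )


def qa_report(plan_volume, log_volume, criteria: TestCriteria | None = None,
              path=None, slice_images: bool = False) -> dict:
    """Machine-readable delivery-QA report (plan = reference, log = evaluated).

    Optionally writes the report as JSON and, with ``slice_images``, saves
    orthogonal mid-plane slices of the plan, log, and difference volumes as
    PNG next to it.
    """
    result = compare_volumes(plan_volume, log_volume, criteria)
    report = {
        "reference": getattr(plan_volume, "provenance", {}) or {"source": "plan"},
        "evaluated": getattr(log_volume, "provenance", {}) or {"source": "log"},
        **result.summary_dict(),
    }
    if path is not None:
        path = Path(path)
        path.write_text(json.dumps(report, indent=2))
        if slice_images:
            _write_slice_images(plan_volume, log_volume, result, path)
    return report


def load_report(path) -> dict:
    return json.loads(Path(path).read_text())


def _write_slice_images(plan_volume, log_volume, result: ComparisonResult, report_path: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vol_p = np.asarray(plan_volume.values)
    vol_l = np.asarray(log_volume.values)
    diff = result.diff_map
    if vol_p.ndim != 3:
        return
    mids = [s // 2 for s in vol_p.shape]
    rows = [("plan", vol_p), ("log", vol_l), ("difference", diff)]
    views = [("axial", lambda v: v[:, :, mids[2]].T),
             ("coronal", lambda v: v[:, mids[1], :].T),
             ("sagittal", lambda v: v[mids[0], :, :].T)]
    fig, axes = plt.subplots(3, 3, figsize=(9, 9))
    for i, (rname, vol) in enumerate(rows):
        for j, (vname, cut) in enumerate(views):
            ax = axes[i][j]
            im = ax.imshow(cut(vol), origin="lower",
                           cmap="RdBu_r" if rname == "difference" else "viridis")
            ax.set_title(f"{rname} {vname}", fontsize=8)
            ax.axis("off")
            fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(report_path.with_suffix(".png"), dpi=110)
    plt.close(fig)
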