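"""Bootstrapped biomarker z-trajectories along an amyloid-burden proxy.

Each biomarker's reference-standardized z-score is modelled as a function
of a proxy of disease progression — amyloid-PET Centiloids, or the CSF
Abeta42/40 ratio with its axis inverted so that progression runs from high
to low ratio.  The trajectory is the pointwise mean over bootstrap
resamples of a robust locally weighted regression fit, evaluated on the
grid of proxy values observed in the original sample; abnormality onset is
the first grid location where the mean trajectory reaches a z threshold
(1.5 or 2 SD above the reference mean), linearly interpolated between
bracketing grid points and never extrapolated beyond the observed range.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import config as cfg
from . import schema
from .smoothing import rlowess_smooth

log = logging.getLogger(__name__)


@dataclass
class TrajectoryModel:
    """Mean bootstrap trajectory with its percentile envelope.

    ``grid`` is stored in the analysis direction (ascending progression);
    when ``axis_inverted`` the original proxy values are the negated grid.
    """

    proxy: str
    biomarker: str
    grid: np.ndarray
    mean_z: np.ndarray
    envelope_low: np.ndarray
    envelope_high: np.ndarray
    n_boot: int
    span_points: int
    axis_inverted: bool = False
    single_fit: np.ndarray | None = None
    replicate_curves: np.ndarray | None = None

    def grid_proxy_units(self) -> np.ndarray:
        """Grid back on the original proxy scale (for reporting)."""
        return -self.grid if self.axis_inverted else self.grid

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "proxy_value": self.grid_proxy_units(),
            "mean_z": self.mean_z,
            "envelope_low": self.envelope_low,
            "envelope_high": self.envelope_high,
        })


@dataclass
class CrossingResult:
    """Proxy value at which the mean trajectory first reaches a z threshold."""

    biomarker: str
    threshold_z: float
    crossing_proxy: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    n_replicates_crossing: int = 0


def _first_crossing(grid: np.ndarray, curve: np.ndarray,
                    threshold: float) -> float | None:
    idx = np.flatnonzero(curve >= threshold)
    if idx.size == 0:
        return None
    i = idx[0]
    if i == 0:
        return float(grid[0])
    x0, x1 = grid[i - 1], grid[i]
    y0, y1 = curve[i - 1], curve[i]
    if y1 == y0:
        return float(x1)
    return float(x0 + (threshold - y0) * (x1 - x0) / (y1 - y0))


def bootstrap_trajectory(proxy, z, n_boot: int = cfg.N_BOOT,
                         span_points: int = cfg.SPAN_POINTS,
                         seed=None, invert: bool = False,
                         resample: bool = True,
                         keep_replicates: bool = True,
                         proxy_name: str = "proxy",
                         biomarker: str = "biomarker") -> TrajectoryModel:
    """Fit the bootstrap-mean z-trajectory of one biomarker.

    Each replicate resamples the complete (proxy, z) pairs with
    replacement, sorts by proxy, smooths with the robust local regression,
    averages fitted values over tied proxy values and linearly interpolates
    onto the grid of original proxy values.  ``resample=False`` disables
    the bootstrap (single pass over the original sample, degenerate
    envelope).  Deterministic given ``seed``.

    A span larger than the available sample is clamped to n with a logged
    warning (the span is an observation count; small proxy subsets cannot
    support the full default span).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    p = np.asarray(proxy, dtype=float)
    v = np.asarray(z, dtype=float)
    ok = np.isfinite(p) & np.isfinite(v)
    p, v = p[ok], v[ok]
    if invert:
        p = -p
    n = p.size
    if span_points > n:
        log.warning("span %d exceeds n=%d for %s on %s: clamping span to n",
                    span_points, n, biomarker, proxy_name)
        warnings.warn(f"span clamped from {span_points} to n={n}",
                      stacklevel=2)
        span_points = n
    order = np.argsort(p, kind="stable")
    xs, vs = p[order], v[order]
    grid = np.unique(xs)

    if not resample:
        fit = rlowess_smooth(xs, vs, span_points)
        curve = _aggregate_to_grid(xs, fit, grid)
        curves = curve[None, :]
    else:
        rng = np.random.default_rng(seed)
        curves = np.empty((n_boot, grid.size))
        for b in range(n_boot):
            idx = np.sort(rng.integers(0, n, n))
            fit = rlowess_smooth(xs[idx], vs[idx], span_points)
            curves[b] = _aggregate_to_grid(xs[idx], fit, grid)

    mean_z = curves.mean(axis=0)
    lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
    single = rlowess_smooth(xs, vs, span_points)
    return TrajectoryModel(
        proxy=proxy_name, biomarker=biomarker, grid=grid, mean_z=mean_z,
        envelope_low=lo, envelope_high=hi, n_boot=curves.shape[0],
        span_points=span_points, axis_inverted=invert,
        single_fit=_aggregate_to_grid(xs, single, grid),
        replicate_curves=curves if keep_replicates else None)


def _aggregate_to_grid(xb: np.ndarray, fit: np.ndarray,
                       grid: np.ndarray) -> np.ndarray:
    """Average fitted values over tied abscissae, then interpolate to grid."""
    ux, starts = np.unique(xb, return_index=True)
    sums = np.add.reduceat(fit, starts)
    counts = np.diff(np.append(starts, xb.size))
    return np.interp(grid, ux, sums / counts)


def crossing_point(model: TrajectoryModel, threshold_z: float) -> CrossingResult:
    """Locate where the mean trajectory first reaches ``threshold_z``.

    Returns an explicit no-crossing result when the trajectory never
    reaches the threshold within the observed proxy range.  The bootstrap
    CI is the percentile interval of per-replicate crossings (replicates
    that never cross are excluded and counted).
    """
    if threshold_z <= 0:
        raise ValueError("threshold_z must be positive")
    xc = _first_crossing(model.grid, model.mean_z, threshold_z)

    ci_low = ci_high = None
    n_cross = 0
    if model.replicate_curves is not None and model.replicate_curves.shape[0] > 1:
        reps = [_first_crossing(model.grid, c, threshold_z)
                for c in model.replicate_curves]
        vals = np.array([r for r in reps if r is not None])
        n_cross = vals.size
        if vals.size >= 2:
            lo, hi = np.percentile(vals, [2.5, 97.5])
            if model.axis_inverted:
                lo, hi = -hi, -lo
            ci_low, ci_high = float(lo), float(hi)

    if xc is not None and model.axis_inverted:
        xc = -xc
    return CrossingResult(model.biomarker, threshold_z, xc,
                          ci_low, ci_high, n_cross)


def trajectory_panel(pre: pd.DataFrame, proxy: str = schema.CENTILOIDS,
                     n_boot: int = cfg.N_BOOT,
                     span_points: int = cfg.SPAN_POINTS,
                     seed=None,
                     thresholds=cfg.ABNORMALITY_THRESHOLDS,
                     biomarkers: tuple[str, ...] = schema.PLASMA_COLUMNS,
                     ) -> tuple[dict[str, TrajectoryModel], pd.DataFrame]:
    """Trajectories and crossing table for every plasma biomarker.

    ``pre`` is a preprocessed cohort (``<col>__z`` columns present).  When
    the proxy is the CSF ratio the axis is inverted so progression runs
    toward lower ratios.  Each biomarker's z is oriented by its pathologic
    direction (the Abeta42/40 ratio falls with pathology), so "abnormal"
    is always z above +threshold.  Per-biomarker child seeds derive from
    ``seed``.
    """
    invert = proxy == schema.CSF_AB4240
    models: dict[str, TrajectoryModel] = {}
    rows = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(biomarkers))
    for child, col in zip(children, biomarkers):
        direction = schema.biomarker_info(col).direction
        model = bootstrap_trajectory(
            pre[proxy], direction * pre[f"{col}__z"], n_boot=n_boot,
            span_points=span_points, seed=child, invert=invert,
            proxy_name=proxy, biomarker=col)
        models[col] = model
        for t in thresholds:
            res = crossing_point(model, t)
            rows.append({
                "biomarker": col, "proxy": proxy, "threshold_z": t,
                "crossing_proxy": res.crossing_proxy,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "n_replicates_crossing": res.n_replicates_crossing,
            })
    return models, pd.DataFrame(rows)


def inverted_proxy_trajectory(pre: pd.DataFrame, biomarker: str,
                              n_boot: int = cfg.N_BOOT,
                              span_points: int = cfg.SPAN_POINTS,
                              seed=None) -> TrajectoryModel:
    """Trajectory against the CSF Abeta42/40 ratio, axis inverted."""
    return bootstrap_trajectory(
        pre[schema.CSF_AB4240], pre[f"{biomarker}__z"], n_boot=n_boot,
        span_points=span_points, seed=seed, invert=True,
        proxy_name=schema.CSF_AB4240, biomarker=biomarker)
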