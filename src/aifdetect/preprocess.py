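"""Three-stage curve-exclusion cascade applied before clustering.

Arterial voxels are a small minority of a perfusion slice.  Before
clustering, candidate time-concentration curves are thinned by:

1. an area filter — the ``p_auc`` fraction of curves with the smallest
   areas under the curve are excluded (tissue curves have small areas);
2. a roughness filter — the ``p_rough`` fraction of the survivors with the
   largest integrated squared second derivative are excluded (pulsation and
   motion artifacts);
3. a partial-volume filter — each survivor's first passage is fitted to a
   gamma-variate; curves whose steady-state-to-first-passage-area ratio
   falls outside the pool mean +/- ``ratio_tolerance`` are excluded.

Exclusion counts use the floor of fraction x pool size; ties are broken by
ascending curve index (the lower index is removed first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .phantom import CurveSet, GammaVariateParams, SamplingGrid, gamma_variate

__all__ = [
    "FilterConfig",
    "FilterReport",
    "GammaFitError",
    "GammaVariateFit",
    "auc_filter",
    "roughness",
    "roughness_filter",
    "fit_gamma_variate",
    "steady_state_pve_filter",
    "run_filter_cascade",
]


@dataclass(frozen=True)
class FilterConfig:
    p_auc: float = 0.90
    p_rough: float = 0.25
    ss_threshold: float = 0.30      # steady state starts below this fraction of peak
    ss_length: int = 10             # time points integrated for the steady state
    ratio_tolerance: float = 0.20   # acceptance band: mean ratio +/- this fraction
    ss_window_mode: str = "include_start"  # or "after_start" (off-by-one reading)

    def __post_init__(self) -> None:
        for name in ("p_auc", "p_rough", "ss_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.ss_length < 1:
            raise ValueError("ss_length must be >= 1")
        if self.ratio_tolerance < 0:
            raise ValueError("ratio_tolerance must be non-negative")
        if self.ss_window_mode not in ("include_start", "after_start"):
            raise ValueError("unknown ss_window_mode")


@dataclass
class FilterReport:
    """Per-stage survivor indices and per-curve diagnostics."""

    stage_retained: dict[str, list[int]] = field(default_factory=dict)
    auc: np.ndarray | None = None
    rough: dict[int, float] = field(default_factory=dict)
    ratios: dict[int, float] = field(default_factory=dict)
    mean_ratio: float | None = None
    excluded: dict[int, str] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.stage_retained.items()}


def _values_times(curves, grid):
    if isinstance(curves, CurveSet):
        return curves.values, curves.grid.times
    if grid is None:
        raise ValueError("grid required when curves is a raw matrix")
    values = np.atleast_2d(np.asarray(curves, dtype=float))
    times = grid.times if isinstance(grid, SamplingGrid) else np.asarray(grid, dtype=float)
    return values, times


def auc_filter(curves, p_auc: float = 0.90, grid=None):
    """Remove the ``floor(p_auc * n)`` curves with the smallest trapezoidal
    areas; returns (retained indices ascending, per-curve AUC array)."""
    values, times = _values_times(curves, grid)
    n = values.shape[0]
    if n == 0:
        raise ValueError("empty curve set")
    aucs = np.trapezoid(values, times, axis=1)
    n_remove = int(np.floor(p_auc * n))
    order = np.argsort(aucs, kind="stable")  # ties: lower index removed first
    retained = np.sort(order[n_remove:])
    return retained, aucs


def roughness(curve: np.ndarray, grid) -> float:
    """Integrated squared second derivative (discrete central differences,
    trapezoid rule over interior samples).  Zero for any affine curve."""
    times = grid.times if isinstance(grid, SamplingGrid) else np.asarray(grid, dtype=float)
    curve = np.asarray(curve, dtype=float)
    if curve.size < 3:
        raise ValueError("roughness needs at least 3 samples")
    dt = times[1] - times[0]
    d2 = (curve[2:] - 2.0 * curve[1:-1] + curve[:-2]) / dt**2
    return float(np.trapezoid(d2**2, times[1:-1]))


def roughness_filter(curves, retained: np.ndarray, p_rough: float = 0.25, grid=None):
    """Remove the ``floor(p_rough * m)`` roughest of the ``m`` survivors;
    returns (retained indices, {index: roughness})."""
    values, times = _values_times(curves, grid)
    retained = np.asarray(retained, dtype=int)
    if retained.size == 0:
        raise ValueError("empty survivor set")
    rough = np.array([roughness(values[i], times) for i in retained])
    n_remove = int(np.floor(p_rough * retained.size))
    # roughest removed; ties among equals: lower curve index removed first
    order = np.argsort(-rough, kind="stable")
    keep = np.sort(retained[order[n_remove:]])
    return keep, dict(zip(retained.tolist(), rough.tolist()))


class GammaFitError(RuntimeError):
    """First-passage gamma-variate fit failed to converge."""


@dataclass
class GammaVariateFit:
    params: GammaVariateParams
    fitted: np.ndarray        # fitted first passage on the full grid
    auc_first: float          # analytic first-passage area
    window: tuple[int, int]   # fitted sample range [start, stop)


def _gv_model(t, t0, alpha, beta, scale):
    x = t - t0
    out = np.zeros_like(t)
    pos = x > 0
    out[pos] = scale * x[pos] ** alpha * np.exp(-x[pos] / beta)
    return out


def fit_gamma_variate(curve: np.ndarray, grid, ss_threshold: float = 0.30) -> GammaVariateFit:
    """Fit the first bolus passage to a gamma-variate by nonlinear least
    squares.

    The fitted window runs from just before the bolus arrival (first sample
    above 10 % of the peak) to the first post-peak sample below
    ``ss_threshold`` of the peak.  The first-passage area is the analytic
    ``scale * Gamma(alpha+1) * beta**(alpha+1)``.
    """
    times = grid.times if isinstance(grid, SamplingGrid) else np.asarray(grid, dtype=float)
    curve = np.asarray(curve, dtype=float)
    pv = curve.max()
    if pv <= 0:
        raise GammaFitError("curve has no positive peak")
    ipk = int(curve.argmax())
    above = np.nonzero(curve > 0.10 * pv)[0]
    ia = int(above[0])
    start = max(0, ia - 2)
    below = np.nonzero(curve[ipk:] < ss_threshold * pv)[0]
    stop = ipk + int(below[0]) + 1 if below.size else curve.size
    tw, cw = times[start:stop], curve[start:stop]
    if tw.size < 5:
        raise GammaFitError("too few samples in the first-passage window")

    # initialization: t0 from the 10 %-of-peak crossing, alpha/beta from a
    # log-linearization of the rising limb, amplitude from the peak
    t0_init = times[ia - 1] if ia > 0 else max(times[0] - (times[1] - times[0]), 0.0)
    rise = np.arange(ia, ipk + 1)
    alpha0, beta0 = 3.0, (times[1] - times[0])
    x = times[rise] - t0_init
    good = (x > 0) & (curve[rise] > 0)
    if good.sum() >= 3:
        X = np.column_stack([np.ones(good.sum()), np.log(x[good]), -x[good]])
        coef, *_ = np.linalg.lstsq(X, np.log(curve[rise][good]), rcond=None)
        if 0.05 < coef[1] < 50 and coef[2] > 1e-6:
            alpha0, beta0 = float(coef[1]), float(1.0 / coef[2])
    scale0 = pv / ((alpha0 * beta0) ** alpha0 * np.exp(-alpha0))

    lo = [0.0, 0.05, 1e-3, 1e-12]
    hi = [times[ipk], 50.0, 1e3, np.inf]
    p0 = [float(np.clip(t0_init, lo[0], hi[0] * 0.999)),
          float(np.clip(alpha0, lo[1], hi[1])),
          float(np.clip(beta0, lo[2], hi[2])),
          float(max(scale0, 1e-10))]
    try:
        popt, _ = optimize.curve_fit(_gv_model, tw, cw, p0=p0,
                                     bounds=(lo, hi), maxfev=5000)
    except (RuntimeError, ValueError) as exc:
        raise GammaFitError(f"gamma-variate fit did not converge: {exc}") from exc
    t0, alpha, beta, scale = (float(v) for v in popt)
    params = GammaVariateParams(t0=t0, alpha=alpha, beta=beta, scale=scale)
    fitted = gamma_variate(times, params)
    # a "converged" fit that does not describe the first passage is a failure
    rel_resid = np.linalg.norm(fitted[start:stop] - cw) / np.linalg.norm(cw)
    if rel_resid > 0.5:
        raise GammaFitError(f"gamma-variate fit rejected (relative residual "
                            f"{rel_resid:.2f} over the first-passage window)")
    auc_first = float(scale * special.gamma(alpha + 1.0) * beta ** (alpha + 1.0))
    return GammaVariateFit(params=params, fitted=fitted, auc_first=auc_first,
                           window=(start, stop))


def _steady_state_window(curve: np.ndarray, cfg: FilterConfig) -> np.ndarray:
    """Sample indices of the steady-state integration window, or raise."""
    pv = curve.max()
    ipk = int(curve.argmax())
    below = np.nonzero(curve[ipk:] < cfg.ss_threshold * pv)[0]
    if below.size == 0:
        raise ValueError("no post-peak sample below the steady-state threshold")
    start = ipk + int(below[0])
    if cfg.ss_window_mode == "after_start":
        start += 1
    stop = start + cfg.ss_length
    if stop > curve.size:
        raise ValueError("steady-state window exceeds the grid")
    return np.arange(start, stop)


def steady_state_pve_filter(curves, retained: np.ndarray, cfg: FilterConfig, grid=None):
    """Partial-volume filter: keep curves whose SS/AUC_first ratio lies within
    the pool mean +/- ``ratio_tolerance`` * mean.

    SS is the trapezoidal integral over ``ss_length`` samples starting at
    the first post-peak sample below ``ss_threshold`` of the maximum;
    AUC_first is the analytic area of the fitted gamma-variate first
    passage.  Curves that cannot be fitted, or whose steady-state window
    exceeds the grid, are excluded with a logged reason and do not enter
    the ratio pool.  Returns (retained indices, ratios, mean ratio,
    {index: exclusion reason}).
    """
    values, times = _values_times(curves, grid)
    retained = np.asarray(retained, dtype=int)
    if retained.size == 0:
        raise ValueError("empty survivor set")
    ratios: dict[int, float] = {}
    excluded: dict[int, str] = {}
    for i in retained:
        c = values[i]
        try:
            fit = fit_gamma_variate(c, times, ss_threshold=cfg.ss_threshold)
            win = _steady_state_window(c, cfg)
        except (GammaFitError, ValueError) as exc:
            excluded[int(i)] = str(exc)
            continue
        ss = float(np.trapezoid(c[win], times[win]))
        ratios[int(i)] = ss / fit.auc_first
    if not ratios:
        raise ValueError("no curve survived gamma-variate fitting")
    mean_ratio = float(np.mean(list(ratios.values())))
    if np.isinf(cfg.ratio_tolerance):
        keep = np.array(sorted(ratios), dtype=int)
    else:
        band = cfg.ratio_tolerance * abs(mean_ratio)
        keep = np.array(sorted(i for i, r in ratios.items()
                               if abs(r - mean_ratio) <= band), dtype=int)
        for i in sorted(set(ratios) - set(keep.tolist())):
            excluded[i] = "SS/AUC_first ratio outside acceptance band"
    return keep, ratios, mean_ratio, excluded


def run_filter_cascade(curves, cfg: FilterConfig | None = None, grid=None):
    """Apply the three filters in order; returns (retained indices, report).

    Survivor sets are nested: each stage filters the previous stage's
    survivors.
    """
    cfg = cfg or FilterConfig()
    report = FilterReport()
    values, times = _values_times(curves, grid)
    report.stage_retained["input"] = list(range(values.shape[0]))
    r1, aucs = auc_filter(values, cfg.p_auc, times)
    report.auc = aucs
    report.stage_retained["auc"] = r1.tolist()
    r2, rough = roughness_filter(values, r1, cfg.p_rough, times)
    report.rough = rough
    report.stage_retained["roughness"] = r2.tolist()
    r3, ratios, mean_ratio, excluded = steady_state_pve_filter(values, r2, cfg, times)
    report.ratios = ratios
    report.mean_ratio = mean_ratio
    report.excluded = excluded
    report.stage_retained["pve"] = r3.tolist()
    return r3, report
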