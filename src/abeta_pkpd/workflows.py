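"""End-user workflows built on the turnover model.

Three analyses recur in Aβ-lowering programs:

* **Regimen prediction** — once (kout, Imax, IC50, gamma) are estimated
  from one study, the response to any other regimen is the re-integration
  of three separable components: the new exposure time course, the
  intrinsic exposure-Rgen relationship, and the compartment's turnover
  rate.
* **Hysteresis diagnostics** — because the effect lags the exposure,
  plotting Aβ lowering against the concurrent concentration traces a loop
  rather than a curve. The signed (shoelace) loop area and the lag between
  exposure peak and effect nadir quantify the delay; a memoryless
  concentration-effect relationship gives zero area.
* **Intrinsic-curve comparison** — Rgen(C) contains no turnover term, so
  fits from compartments with very different kinetics (brain vs CSF)
  should overlay on the Rgen scale; the comparison is restricted to each
  curve's 0-50% lowering band, where preclinical data are informative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimation import FitResult
from .turnover import Trajectory, TurnoverParams, rgen, simulate_trajectory

__all__ = [
    "LoopSummary",
    "CurveComparison",
    "predict_regimen",
    "hysteresis_loop",
    "compare_intrinsic_curves",
]


@dataclass(frozen=True)
class LoopSummary:
    """Signed-area summary of a concentration-effect hysteresis loop.

    ``area`` is the shoelace area of the time-ordered polygon in
    (concentration, % lowering) coordinates; counterclockwise traversal is
    positive, which is the orientation an indirect-response delay produces.
    ``lag_h`` is effect-nadir time minus exposure-peak time.
    """

    area: float
    orientation: str          # "counterclockwise" | "clockwise" | "none"
    nadir_time_h: float
    peak_time_h: float
    lag_h: float


@dataclass(frozen=True)
class CurveComparison:
    """Band-limited agreement between intrinsic exposure-Rgen curves."""

    conc_grid: np.ndarray
    rgen_curves: np.ndarray   # shape (n_fits, n_grid)
    band_mask: np.ndarray     # grid points inside every curve's 0-50% band
    max_abs_diff: float
    rms_diff: float
    band_empty: bool


def _fit_params(fit) -> TurnoverParams:
    return fit.params if isinstance(fit, FitResult) else fit


def predict_regimen(fit: FitResult, new_drive, times, *, force: bool = False,
                    method: str = "lsoda", **sim_kwargs) -> Trajectory:
    """Predict the Aβ time course for a new regimen from a completed fit.

    Simulates the turnover model with the fitted parameters under
    ``new_drive``. Refuses a fit flagged as non-converged unless
    ``force=True``.
    """
    if isinstance(fit, FitResult) and not fit.success and not force:
        raise ValueError(
            "fit did not converge; pass force=True to predict from it anyway")
    return simulate_trajectory(_fit_params(fit), new_drive, times,
                               method=method, **sim_kwargs)


def hysteresis_loop(concs, effect_pct, times=None, *,
                    area_tol: float | None = None) -> LoopSummary:
    """Summarize the loop traced by effect vs concurrent concentration.

    ``concs`` and ``effect_pct`` (Aβ as % of control) must be sampled at
    the same time points, already in time order (pass ``times`` to have the
    ordering checked). The polygon is closed from the last point back to
    the first and its shoelace area computed on the
    (concentration, 100 - effect_pct) plane. ``area_tol`` defaults to
    1e-9 x (concentration range x lowering range); below it the orientation
    is "none".
    """
    c = np.asarray(concs, dtype=float)
    e = np.asarray(effect_pct, dtype=float)
    if c.shape != e.shape or c.ndim != 1:
        raise ValueError("concs and effect_pct must be 1-D arrays of equal length")
    if c.size < 4:
        raise ValueError("need at least 4 time points covering onset and offset")
    if times is None:
        t = np.arange(c.size, dtype=float)
    else:
        t = np.asarray(times, dtype=float)
        if t.shape != c.shape:
            raise ValueError("times must match concs in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")

    lowering = 100.0 - e
    x, y = c, lowering
    area = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    if area_tol is None:
        scale = max(np.ptp(x), 1e-300) * max(np.ptp(y), 1e-300)
        area_tol = 1e-9 * scale
    if abs(area) <= area_tol:
        orientation = "none"
    else:
        orientation = "counterclockwise" if area > 0 else "clockwise"

    nadir_time = float(t[int(np.argmax(lowering))])
    peak_time = float(t[int(np.argmax(c))])
    return LoopSummary(area=area, orientation=orientation,
                       nadir_time_h=nadir_time, peak_time_h=peak_time,
                       lag_h=nadir_time - peak_time)


def compare_intrinsic_curves(fits, *, n_grid: int = 200,
                             lowering_band: tuple[float, float] = (0.0, 50.0),
                             conc_range: tuple[float, float] | None = None,
                             ) -> CurveComparison:
    """Overlay intrinsic exposure-Rgen curves from two or more fits.

    Evaluates Rgen for every fit on a shared log-spaced concentration grid
    (default: ic50/100 of the smallest-ic50 fit to 100 x ic50 of the
    largest) and reports the maximum and RMS absolute differences between
    curves, restricted to grid points lying inside *every* curve's own
    lowering band (default 0-50% lowering, i.e. Rgen in [0.5, 1]). All
    fits must share a concentration unit. Curves differing only in kout
    are identical here: the intrinsic relationship is turnover-free.
    """
    params = [_fit_params(f) for f in fits]
    if len(params) < 2:
        raise ValueError("need at least two fits to compare")
    if conc_range is None:
        ic50s = [p.ic50 for p in params]
        conc_range = (min(ic50s) / 100.0, max(ic50s) * 100.0)
    grid = np.geomspace(conc_range[0], conc_range[1], n_grid)
    curves = np.vstack([np.asarray(rgen(p, grid)) for p in params])

    lo, hi = lowering_band
    lowering = 100.0 * (1.0 - curves)
    band = np.all((lowering >= lo) & (lowering <= hi), axis=0)
    empty = not bool(band.any())
    if empty:
        max_diff = rms = float("nan")
    else:
        sub = curves[:, band]
        diffs = np.abs(sub[:, None, :] - sub[None, :, :])
        max_diff = float(diffs.max())
        iu = np.triu_indices(len(params), k=1)
        rms = float(np.sqrt(np.mean(diffs[iu] ** 2)))
    return CurveComparison(conc_grid=grid, rgen_curves=curves, band_mask=band,
                           max_abs_diff=max_diff, rms_diff=rms, band_empty=empty)
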