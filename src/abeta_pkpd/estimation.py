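"""Vehicle normalization and turnover-parameter estimation.

Preclinical Aβ studies in rodents use destructive sampling: each animal
contributes a single terminal measurement, and every sampling time has its
own concurrent vehicle group. To remove non-specific (handling, assay,
circadian) effects, treated absolute Aβ levels are expressed as percentages
of the mean of the concurrent vehicle animals in the same
(time, compartment, analyte) stratum, and the normalized time courses are
fit with the turnover model to estimate kout, Imax, IC50 and gamma.

Fitting is naive-pooled nonlinear least squares (every normalized
observation treated as independent), with smooth bound-respecting
parameter transforms — log(kout), log(ic50), log(gamma), logit(imax) — a
small multistart, and asymptotic standard errors from the Jacobian at the
optimum. Case-resampling bootstrap over animals within strata provides
empirical confidence intervals.

Raw study data is a pandas DataFrame with columns
``animal_id, group, dose, route, time_h, compartment, analyte, value``;
normalized data additionally carries ``pct_of_control``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import lmfit
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .turnover import TurnoverParams, simulate_trajectory

__all__ = [
    "RAW_COLUMNS",
    "NormalizationError",
    "UnidentifiableError",
    "FitSpec",
    "FitResult",
    "BootstrapResult",
    "normalize_to_vehicle",
    "fit_turnover",
    "fit_strata",
    "bootstrap_uncertainty",
    "read_raw_csv",
]

RAW_COLUMNS = ("animal_id", "group", "dose", "route", "time_h",
               "compartment", "analyte", "value")

_PARAM_NAMES = ("kout", "imax", "ic50", "gamma")


class NormalizationError(ValueError):
    """A treated stratum lacks a concurrent vehicle group (or its mean is 0)."""


class UnidentifiableError(ValueError):
    """The dataset carries no information about one or more parameters."""


def read_raw_csv(path) -> pd.DataFrame:
    """Read raw study data CSV and validate its schema."""
    df = pd.read_csv(path)
    return validate_raw(df)


def validate_raw(raw: pd.DataFrame) -> pd.DataFrame:
    missing = set(RAW_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"raw study data missing columns: {sorted(missing)}")
    if (raw["value"] < 0).any():
        raise ValueError("raw Aβ values must be >= 0")
    return raw


def normalize_to_vehicle(raw: pd.DataFrame) -> pd.DataFrame:
    """Express each observation as percent of the concurrent vehicle mean.

    Vehicle animals are the ``dose == 0`` records. Within every
    (time_h, compartment, analyte) stratum containing treated records there
    must be at least one concurrent vehicle record; the treated and vehicle
    values are divided by the stratum's vehicle mean and scaled to percent.
    Vehicle records are retained (normalized like the rest) because they
    carry the residual-variance information.

    Normalization is idempotent: renormalizing a dataset whose vehicle
    means are already 100 leaves it unchanged.
    """
    raw = validate_raw(raw)
    strata = ["time_h", "compartment", "analyte"]
    veh = raw[raw["dose"] == 0]
    veh_mean = veh.groupby(strata)["value"].mean()

    out = raw.copy()
    keys = pd.MultiIndex.from_frame(out[strata])
    have = keys.isin(veh_mean.index)
    if not have.all():
        bad = sorted(set(map(tuple, out.loc[~have, strata].itertuples(index=False))))
        raise NormalizationError(
            "no concurrent vehicle group for strata (time_h, compartment, analyte): "
            f"{bad}")
    means = veh_mean.loc[keys].to_numpy()
    if np.any(means <= 0):
        bad = sorted(set(map(tuple, out.loc[means <= 0, strata].itertuples(index=False))))
        raise NormalizationError(f"vehicle mean is zero in strata: {bad}")
    out["pct_of_control"] = 100.0 * out["value"].to_numpy() / means
    return out


@dataclass(frozen=True)
class FitSpec:
    """Everything the optimizer needs besides the data.

    ``init`` holds starting values on the natural scale; ``vary`` flags
    which parameters are estimated (fix gamma and/or imax by setting the
    flag False and the value in ``init``); ``bounds`` are natural-scale box
    constraints applied on the transformed scale. ``loss`` selects additive
    residuals on the percent scale (default) or on log(percent).
    ``drive_key`` names the column identifying dose groups (each treated
    group needs an entry in the drives mapping passed to the fitter).
    """

    init: Mapping[str, float] = field(
        default_factory=lambda: {"kout": 0.5, "imax": 0.9, "ic50": 1.0, "gamma": 1.0})
    vary: Mapping[str, bool] = field(
        default_factory=lambda: {"kout": True, "imax": True, "ic50": True, "gamma": True})
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"kout": (1e-3, 50.0), "imax": (1e-4, 1.0),
                                 "ic50": (1e-6, 1e6), "gamma": (0.1, 10.0)})
    loss: str = "percent"
    drive_key: str = "dose"
    n_restarts: int = 5
    jitter_sd: float = 0.3
    restart_seed: int = 0
    sim_method: str = "expstep"
    sim_dt: float = 0.02

    def __post_init__(self) -> None:
        if self.loss not in ("percent", "log"):
            raise ValueError(f"unknown loss {self.loss!r}")
        # partial mappings are merged over the defaults
        defaults = type(self).__dataclass_fields__
        init = {**defaults["init"].default_factory(), **dict(self.init)}
        vary = {**defaults["vary"].default_factory(), **dict(self.vary)}
        bounds = {**defaults["bounds"].default_factory(), **dict(self.bounds)}
        object.__setattr__(self, "init", init)
        object.__setattr__(self, "vary", vary)
        object.__setattr__(self, "bounds", bounds)
        lo, hi = bounds["imax"]
        if hi > 1:
            raise ValueError("imax upper bound cannot exceed 1")
        for name in _PARAM_NAMES:
            b_lo, b_hi = bounds[name]
            if vary.get(name, True) and not (b_lo <= init[name] <= b_hi):
                raise ValueError(f"initial {name}={init[name]} outside bounds {bounds[name]}")

    def params(self) -> TurnoverParams:
        return TurnoverParams(**{k: float(self.init[k]) for k in _PARAM_NAMES})


@dataclass(frozen=True)
class FitResult:
    """Estimates, uncertainties and diagnostics from one turnover fit."""

    params: TurnoverParams
    stderr: dict
    ci95: dict
    success: bool
    status: str               # "converged" | "not_converged" | "at_bounds"
    message: str
    ssr: float
    rmse: float
    n_obs: int
    n_free: int
    multimodal: bool
    spec: FitSpec

    @property
    def kin(self) -> float:
        return self.params.kin

    def to_dict(self) -> dict:
        return {
            "estimates": {"kout": self.params.kout, "imax": self.params.imax,
                          "ic50": self.params.ic50, "gamma": self.params.gamma,
                          "kin": self.kin},
            "stderr": self.stderr,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "success": self.success, "status": self.status,
            "message": self.message, "ssr": self.ssr, "rmse": self.rmse,
            "n_obs": self.n_obs, "n_free": self.n_free,
            "multimodal": self.multimodal,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# parameter transforms: unconstrained internally within transformed box bounds
_TRANSFORMS = {
    "kout": (np.log, np.exp),
    "ic50": (np.log, np.exp),
    "gamma": (np.log, np.exp),
    "imax": (lambda x: logit(np.clip(x, 1e-12, 1 - 1e-12)), expit),
}


def _to_internal(name: str, value: float) -> float:
    return float(_TRANSFORMS[name][0](value))


def _to_natural(name: str, value: float) -> float:
    return float(_TRANSFORMS[name][1](value))


def _natural_params(lm_params: lmfit.Parameters, fixed: Mapping[str, float]) -> TurnoverParams:
    vals = dict(fixed)
    for name in _PARAM_NAMES:
        key = f"t_{name}"
        if key in lm_params:
            vals[name] = _to_natural(name, lm_params[key].value)
    return TurnoverParams(**vals)


def _single_stratum(data: pd.DataFrame) -> tuple[str, str]:
    strata = data[["compartment", "analyte"]].drop_duplicates()
    if len(strata) != 1:
        raise ValueError(
            "fit_turnover fits one (compartment, analyte) stratum at a time; "
            f"got {len(strata)} strata — subset the data or use fit_strata()")
    return tuple(strata.iloc[0])


def _group_predictions(p: TurnoverParams, groups, spec: FitSpec) -> np.ndarray:
    """Model percent-of-control prediction for each observation.

    ``groups`` is a list of (times_per_record, unique_times, drive); vehicle
    groups carry drive=None and predict exactly 100.
    """
    preds = []
    for rec_times, uniq, drive in groups:
        if drive is None:
            preds.append(np.full(rec_times.size, 100.0))
            continue
        grid = uniq if uniq[0] == 0 else np.concatenate(([0.0], uniq))
        traj = simulate_trajectory(p, drive, grid, method=spec.sim_method,
                                   dt=spec.sim_dt)
        lookup = dict(zip(traj.times, traj.abeta_pct))
        preds.append(np.array([lookup[t] for t in rec_times]))
    return np.concatenate(preds)


def _prepare_groups(data: pd.DataFrame, drives: Mapping, spec: FitSpec):
    """Split observations by dose group, pairing each with its drive."""
    obs, groups = [], []
    for key, sub in data.groupby(spec.drive_key, sort=True):
        rec_times = sub["time_h"].to_numpy(dtype=float)
        uniq = np.unique(rec_times)
        if (sub["dose"] == 0).all():
            drive = None
        else:
            try:
                drive = drives[key]
            except KeyError:
                raise KeyError(f"no drive supplied for treated group {key!r}") from None
        obs.append(sub["pct_of_control"].to_numpy(dtype=float))
        groups.append((rec_times, uniq, drive))
    return np.concatenate(obs), groups


def _residual(lm_params, obs, groups, fixed, spec):
    p = _natural_params(lm_params, fixed)
    pred = _group_predictions(p, groups, spec)
    if spec.loss == "log":
        return np.log(np.maximum(obs, 1e-9)) - np.log(np.maximum(pred, 1e-9))
    return obs - pred


def _build_lm_params(spec: FitSpec) -> tuple[lmfit.Parameters, dict]:
    lm = lmfit.Parameters()
    fixed = {}
    for name in _PARAM_NAMES:
        val = float(spec.init[name])
        if spec.vary.get(name, True):
            lo, hi = spec.bounds[name]
            lm.add(f"t_{name}", value=_to_internal(name, val),
                   min=_to_internal(name, lo), max=_to_internal(name, hi))
        else:
            fixed[name] = val
    return lm, fixed


def fit_turnover(data: pd.DataFrame, drives: Mapping, spec: FitSpec | None = None,
                 ) -> FitResult:
    """Estimate (kout, imax, ic50, gamma) from one stratum of normalized data.

    Minimizes the chosen loss between observed percent-of-control values and
    turnover-model predictions, pooled across all dose groups simultaneously.
    ``drives`` maps each treated group key (by default the dose level) to a
    concentration drive callable. Runs ``spec.n_restarts`` jittered restarts
    from the initial values (deterministic sub-seeds) and keeps the best;
    flags apparent multimodality when two near-tied optima disagree on
    parameters.

    Raises
    ------
    UnidentifiableError
        If there are no treated observations, or fewer than two distinct
        treated sampling times while kinetic parameters are free.
    """
    spec = spec or FitSpec()
    if "pct_of_control" not in data.columns:
        raise ValueError("data must be normalized first (missing pct_of_control)")
    _single_stratum(data)
    treated = data[data["dose"] > 0]
    if treated.empty:
        raise UnidentifiableError("no treated observations: parameters are unidentifiable")
    if treated["time_h"].nunique() < 2 and spec.vary.get("kout", True):
        raise UnidentifiableError(
            "kout is unidentifiable from a single treated sampling time; "
            "fix kout or add time points")

    obs, groups = _prepare_groups(data, drives, spec)
    lm0, fixed = _build_lm_params(spec)
    if not lm0:
        raise UnidentifiableError("all parameters fixed: nothing to estimate")

    rng = np.random.default_rng(spec.restart_seed)
    candidates = []
    for k in range(max(spec.n_restarts, 1)):
        lm = lm0.copy()
        if k > 0:
            for par in lm.values():
                jit = rng.normal(0.0, spec.jitter_sd)
                par.value = float(np.clip(par.value + jit, par.min, par.max))
        try:
            res = lmfit.minimize(_residual, lm, args=(obs, groups, fixed, spec),
                                 method="least_squares")
            candidates.append(res)
        except Exception as exc:  # optimizer blow-up on a bad restart: keep going
            warnings.warn(f"restart {k} failed: {exc}")
    if not candidates:
        raise RuntimeError("all optimizer restarts failed")

    candidates.sort(key=lambda r: float(np.sum(np.asarray(r.residual) ** 2)))
    best = candidates[0]
    best_p = _natural_params(best.params, fixed)

    multimodal = False
    if len(candidates) > 1:
        ssr0 = float(np.sum(np.asarray(best.residual) ** 2))
        ssr1 = float(np.sum(np.asarray(candidates[1].residual) ** 2))
        p1 = _natural_params(candidates[1].params, fixed)
        if ssr0 > 0 and (ssr1 - ssr0) / ssr0 < 0.01:
            for name in _PARAM_NAMES:
                v0, v1 = getattr(best_p, name), getattr(p1, name)
                if abs(v1 - v0) > 0.10 * abs(v0):
                    multimodal = True

    stderr: dict[str, float | None] = {}
    ci95: dict[str, tuple[float, float]] = {}
    at_bounds = False
    for name in _PARAM_NAMES:
        key = f"t_{name}"
        if key not in best.params:
            stderr[name] = None
            ci95[name] = (float(spec.init[name]), float(spec.init[name]))
            continue
        par = best.params[key]
        margin = 1e-6 * max(abs(par.max - par.min), 1.0)
        if par.value <= par.min + margin or par.value >= par.max - margin:
            at_bounds = True
        nat = getattr(best_p, name)
        if par.stderr is not None and np.isfinite(par.stderr):
            lo = _to_natural(name, par.value - 1.959964 * par.stderr)
            hi = _to_natural(name, par.value + 1.959964 * par.stderr)
            # delta method: d(natural)/d(internal) at the optimum
            if name == "imax":
                deriv = nat * (1.0 - nat)
            else:
                deriv = nat
            stderr[name] = abs(deriv) * par.stderr
            ci95[name] = (min(lo, hi), max(lo, hi))
        else:
            stderr[name] = None
            ci95[name] = (nat, nat)

    ssr = float(np.sum(np.asarray(best.residual) ** 2))
    n_free = len(best.params)
    converged = bool(best.success)
    if not converged:
        status = "not_converged"
        warnings.warn(f"optimizer did not converge: {best.message}")
    elif at_bounds:
        status = "at_bounds"
        warnings.warn("one or more estimates pinned at bounds")
    else:
        status = "converged"

    return FitResult(params=best_p, stderr=stderr, ci95=ci95,
                     success=converged, status=status, message=str(best.message),
                     ssr=ssr, rmse=float(np.sqrt(ssr / max(obs.size - n_free, 1))),
                     n_obs=int(obs.size), n_free=n_free,
                     multimodal=multimodal, spec=spec)


def fit_strata(data: pd.DataFrame, drives: Mapping, spec: FitSpec | None = None,
               ) -> dict[tuple[str, str], FitResult]:
    """Fit every (compartment, analyte) stratum independently."""
    out = {}
    for key, sub in data.groupby(["compartment", "analyte"], sort=True):
        out[tuple(key)] = fit_turnover(sub.reset_index(drop=True), drives, spec)
    return out


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap replicates and percentile confidence intervals."""

    samples: pd.DataFrame          # one row per successful bootstrap fit
    ci: dict                       # param -> (lo, hi)
    level: float
    n_boot: int
    n_failed: int

    def to_dict(self) -> dict:
        return {"ci": {k: list(v) for k, v in self.ci.items()},
                "level": self.level, "n_boot": self.n_boot,
                "n_failed": self.n_failed}


def bootstrap_uncertainty(raw: pd.DataFrame, drives: Mapping, spec: FitSpec,
                          n_boot: int = 200, seed: int = 0, *,
                          level: float = 0.90,
                          warm_start: FitResult | None = None) -> BootstrapResult:
    """Case-resampling bootstrap over animals within strata.

    Animals are resampled with replacement within each
    (dose, compartment, analyte) group of the *raw* data — animals in a
    dose group are exchangeable before their terminal-time assignment, and
    resampling at this level (rather than within dose x time cells of a
    handful of animals each) keeps the bootstrap distribution from
    understating the sampling variance. Vehicle variability propagates
    through re-normalization of every resample. Percentile intervals at
    ``level`` are returned; reproducible under a fixed ``seed``. Resamples
    that lose all treated records or a concurrent vehicle stratum are
    redrawn.
    """
    if n_boot < 50:
        warnings.warn(f"n_boot={n_boot} is small; percentile CIs will be noisy")
    raw = validate_raw(raw)
    if warm_start is not None:
        spec = replace(spec, init={"kout": warm_start.params.kout,
                                   "imax": warm_start.params.imax,
                                   "ic50": warm_start.params.ic50,
                                   "gamma": warm_start.params.gamma},
                       n_restarts=1)
    rng = np.random.default_rng(seed)
    blocks = [sub for _, sub in raw.groupby(["dose", "compartment", "analyte"],
                                            sort=True)]

    rows, n_failed = [], 0
    for _ in range(n_boot):
        norm = None
        for _attempt in range(20):
            parts = []
            for sub in blocks:
                idx = rng.integers(0, len(sub), size=len(sub))
                parts.append(sub.iloc[idx])
            boot = pd.concat(parts, ignore_index=True)
            if not (boot["dose"] > 0).any():
                continue
            try:
                norm = normalize_to_vehicle(boot)
                break
            except NormalizationError:
                continue
        if norm is None:
            n_failed += 1
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_turnover(norm, drives, spec)
            rows.append({"kout": fit.params.kout, "imax": fit.params.imax,
                         "ic50": fit.params.ic50, "gamma": fit.params.gamma})
        except (UnidentifiableError, RuntimeError):
            n_failed += 1
    samples = pd.DataFrame(rows)
    alpha = (1.0 - level) / 2.0
    ci = {}
    for name in _PARAM_NAMES:
        if samples.empty:
            ci[name] = (np.nan, np.nan)
        else:
            ci[name] = (float(samples[name].quantile(alpha)),
                        float(samples[name].quantile(1 - alpha)))
    return BootstrapResult(samples=samples, ci=ci, level=level,
                           n_boot=n_boot, n_failed=n_failed)
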