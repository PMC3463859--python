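"""Drug concentration-time drives.

The turnover model is agnostic about where its driving concentration comes
from: in practice it may be plasma, brain, or CSF drug concentration,
whichever was measured. This module provides the two drive flavors the rest
of the package consumes:

* a minimal parametric one-compartment model with first-order absorption
  and elimination (the Bateman function), sufficient to emulate oral or
  subcutaneous dosing in synthetic studies, and
* tabulated concentration-time profiles with linear or log-linear
  interpolation, for observed PK data.

Every drive is a callable ``c(t)`` accepting scalars or arrays of time in
hours and returning non-negative concentrations. Concentration units are
whatever the caller uses; IC50 in the PD model inherits them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "OneCmtParams",
    "ConcTable",
    "ConstantProfile",
    "PeriodicProfile",
    "SummedDoseProfile",
    "bateman_concentration",
    "tabulated_concentration",
    "read_conc_table_csv",
    "write_conc_table_csv",
]


@dataclass(frozen=True)
class OneCmtParams:
    """One-compartment first-order absorption/elimination PK parameters.

    Parameters
    ----------
    dose : float
        Administered dose per kg body weight (e.g. mg/kg).
    f_abs : float
        Bioavailable fraction, in (0, 1].
    ka : float
        First-order absorption rate constant, 1/h.
    ke : float
        First-order elimination rate constant, 1/h.
    vd : float
        Apparent volume of distribution per kg (e.g. L/kg).
    """

    dose: float
    f_abs: float
    ka: float
    ke: float
    vd: float

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")
        if not (0 < self.f_abs <= 1):
            raise ValueError(f"f_abs must be in (0, 1], got {self.f_abs}")
        for name in ("ka", "ke", "vd"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")

    def with_dose(self, dose: float) -> "OneCmtParams":
        """Same kinetics at a different dose (linear PK)."""
        return replace(self, dose=dose)

    @property
    def auc(self) -> float:
        """Area under the curve from 0 to infinity, f*dose/(vd*ke)."""
        return self.f_abs * self.dose / (self.vd * self.ke)

    @property
    def tmax(self) -> float:
        """Time of peak concentration, ln(ka/ke)/(ka-ke); 1/ke if ka == ke."""
        if self.ka == self.ke:
            return 1.0 / self.ke
        return float(np.log(self.ka / self.ke) / (self.ka - self.ke))

    def __call__(self, t):
        return bateman_concentration(self, t)


def bateman_concentration(pk: OneCmtParams, t):
    """Concentration of a one-compartment model with first-order absorption.

    C(t) = f*dose*ka / (vd*(ka-ke)) * (exp(-ke*t) - exp(-ka*t)); the
    ka -> ke limit is f*dose*ka/vd * t * exp(-ke*t). C(0) = 0.

    Parameters
    ----------
    pk : OneCmtParams
    t : float or array_like
        Time since dosing, h; must be >= 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    ka, ke = pk.ka, pk.ke
    scale = pk.f_abs * pk.dose * ka / pk.vd
    # relative tolerance guards the removable singularity at ka == ke
    if abs(ka - ke) <= 1e-9 * ke:
        c = scale * t * np.exp(-ke * t)
    else:
        c = scale / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
    c = np.maximum(c, 0.0)  # clip roundoff negatives near t=0
    return c if c.ndim else float(c)


@dataclass(frozen=True)
class ConcTable:
    """Tabulated concentration-time profile with an explicit interpolation rule.

    ``interp`` is ``"linear"`` or ``"log-linear"``. The log-linear rule
    interpolates exp(linear in log C) between nodes and falls back to linear
    interpolation across any segment touching a zero concentration.
    Extrapolation beyond the table is disabled unless ``extrapolate=True``,
    in which case queries before the first node return the first value and
    queries after the last node decay log-linearly along the last segment
    (or hold the last value if that segment is flat or contains a zero).
    """

    times: np.ndarray
    concs: np.ndarray
    interp: str = "linear"
    extrapolate: bool = False

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        concs = np.asarray(self.concs, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concs", concs)
        if times.ndim != 1 or times.shape != concs.shape:
            raise ValueError("times and concs must be 1-D arrays of equal length")
        if times.size < 2:
            raise ValueError("a ConcTable needs at least two nodes")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(concs < 0):
            raise ValueError("concentrations must be >= 0")
        if self.interp not in ("linear", "log-linear"):
            raise ValueError(f"unknown interpolation rule {self.interp!r}")

    def __call__(self, t):
        return tabulated_concentration(self, t)


def tabulated_concentration(tab: ConcTable, t):
    """Interpolate a ConcTable at time ``t`` per the table's rule.

    Node queries return the node value exactly. Out-of-range queries raise
    unless the table enables extrapolation.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    times, concs = tab.times, tab.concs
    lo, hi = times[0], times[-1]
    if not tab.extrapolate and (np.any(t_arr < lo) or np.any(t_arr > hi)):
        raise ValueError(
            f"query time outside table range [{lo}, {hi}] and extrapolation is disabled"
        )

    out = np.empty_like(t_arr)
    inside = (t_arr >= lo) & (t_arr <= hi)
    ti = np.clip(t_arr[inside], lo, hi)
    idx = np.clip(np.searchsorted(times, ti, side="right") - 1, 0, times.size - 2)
    t0, t1 = times[idx], times[idx + 1]
    c0, c1 = concs[idx], concs[idx + 1]
    w = (ti - t0) / (t1 - t0)
    lin = c0 + w * (c1 - c0)
    if tab.interp == "log-linear":
        ok = (c0 > 0) & (c1 > 0)
        with np.errstate(divide="ignore"):
            loglin = np.exp(np.log(np.where(ok, c0, 1.0)) * (1 - w)
                            + np.log(np.where(ok, c1, 1.0)) * w)
        vals = np.where(ok, loglin, lin)
    else:
        vals = lin
    at_node = np.isin(ti, times)
    if np.any(at_node):
        node_idx = np.searchsorted(times, ti[at_node])
        vals = np.array(vals)
        vals[at_node] = concs[node_idx]
    out[inside] = vals

    before = t_arr < lo
    after = t_arr > hi
    if np.any(before):
        out[before] = concs[0]
    if np.any(after):
        c_last, c_prev = concs[-1], concs[-2]
        if c_last > 0 and c_prev > 0 and c_prev != c_last:
            # terminal log-linear decay continues the last segment's slope
            kz = np.log(c_prev / c_last) / (times[-1] - times[-2])
            out[after] = c_last * np.exp(-kz * (t_arr[after] - hi))
        else:
            out[after] = c_last
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class ConstantProfile:
    """A constant-concentration drive, c(t) = c for all t."""

    c: float

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("concentration must be >= 0")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.c)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PeriodicProfile:
    """Wrap a base drive into an exactly periodic drive of the given period.

    c(t) = base(t mod period). Models the periodic steady-state limit of a
    repeated-dosing regimen.
    """

    base: object
    period: float

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be > 0")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.asarray(self.base(np.mod(t, self.period)), dtype=float)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SummedDoseProfile:
    """Superposition of repeated identical doses at a fixed interval.

    c(t) = sum over doses k with k*interval <= t of base(t - k*interval),
    for ``n_doses`` doses starting at t=0. Linear PK is assumed.
    """

    base: object
    interval: float
    n_doses: int

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for k in range(self.n_doses):
            tk = t - k * self.interval
            m = tk >= 0
            if np.any(m):
                out[m] += np.asarray(self.base(tk[m]), dtype=float)
        return float(out) if out.ndim == 0 else out


def read_conc_table_csv(path, interp: str = "linear", extrapolate: bool = False) -> ConcTable:
    """Read a ConcTable from CSV with columns ``time_h, conc``."""
    df = pd.read_csv(path)
    missing = {"time_h", "conc"} - set(df.columns)
    if missing:
        raise ValueError(f"concentration table CSV missing columns: {sorted(missing)}")
    return ConcTable(df["time_h"].to_numpy(), df["conc"].to_numpy(),
                     interp=interp, extrapolate=extrapolate)


def write_conc_table_csv(tab: ConcTable, path) -> None:
    pd.DataFrame({"time_h": tab.times, "conc": tab.concs}).to_csv(path, index=False)
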