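"""Allometric scaling of the CSF Aβ turnover rate constant across species.

Across mouse, rat, monkey, dog, and human, the CSF Aβ40 turnover rate
constant kout falls with body weight following a power law,
kout = a * BW^b with a ≈ 0.415 1/h and b ≈ -0.36 — small, fast-turnover
species respond and wash out quickly while large species show blunted
biomarker time courses. The fit is ordinary least squares of log(kout) on
log(BW), the standard allometric regression.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesKoutPoint",
    "AllometryFit",
    "fit_power_law",
    "predict_kout",
    "read_points_csv",
    "write_points_csv",
]


@dataclass(frozen=True)
class SpeciesKoutPoint:
    """One species' body weight and CSF Aβ turnover rate constant."""

    species: str
    bw_kg: float
    kout_per_h: float

    def __post_init__(self) -> None:
        if self.bw_kg <= 0:
            raise ValueError(f"body weight must be > 0, got {self.bw_kg}")
        if self.kout_per_h <= 0:
            raise ValueError(f"kout must be > 0, got {self.kout_per_h}")


@dataclass(frozen=True)
class AllometryFit:
    """Power-law fit kout = a * BW^b.

    ``coefficient`` is kout at BW = 1 kg (1/h); ``exponent`` is
    dimensionless; ``r_squared`` is the goodness of fit on the log-log
    scale; ``n`` the number of points.
    """

    coefficient: float
    exponent: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("coefficient must be > 0")
        if self.n < 2:
            raise ValueError("need at least 2 points")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def fit_power_law(points: Sequence[SpeciesKoutPoint] | Iterable[SpeciesKoutPoint]) -> AllometryFit:
    """Fit kout = a * BW^b by OLS of log(kout) on log(BW).

    Exactly recovers (a, b) on noiseless power-law data. Requires at least
    two points with distinct body weights.
    """
    pts = list(points)
    if len(pts) < 2:
        raise ValueError("power-law fit needs at least 2 points")
    bw = np.array([p.bw_kg for p in pts], dtype=float)
    ko = np.array([p.kout_per_h for p in pts], dtype=float)
    if np.unique(bw).size < 2:
        raise ValueError("power-law fit needs at least 2 distinct body weights")
    x, y = np.log(bw), np.log(ko)
    design = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return AllometryFit(coefficient=float(np.exp(beta[0])), exponent=float(beta[1]),
                        r_squared=r2, n=len(pts))


def predict_kout(fit: AllometryFit, bw_kg) -> float | np.ndarray:
    """Predicted kout (1/h) at body weight ``bw_kg`` (kg): a * BW^b."""
    bw = np.asarray(bw_kg, dtype=float)
    if np.any(bw <= 0):
        raise ValueError("body weight must be > 0")
    out = fit.coefficient * bw ** fit.exponent
    return float(out) if out.ndim == 0 else out


def read_points_csv(path) -> list[SpeciesKoutPoint]:
    """Read (species, bw_kg, kout_per_h) rows from CSV."""
    df = pd.read_csv(path)
    missing = {"species", "bw_kg", "kout_per_h"} - set(df.columns)
    if missing:
        raise ValueError(f"allometry CSV missing columns: {sorted(missing)}")
    return [SpeciesKoutPoint(str(r.species), float(r.bw_kg), float(r.kout_per_h))
            for r in df.itertuples(index=False)]


def write_points_csv(points: Sequence[SpeciesKoutPoint], path) -> None:
    pd.DataFrame([asdict(p) for p in points]).to_csv(path, index=False)
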