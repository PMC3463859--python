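"""Synthetic preclinical Aβ study generator.

No raw animal dataset accompanies the turnover analyses this package
implements, so testing every stage end to end requires a generative twin:
studies drawn from the same indirect-response model the estimator assumes,
with the design features of real rodent programs — destructive sampling
(one terminal observation per animal), per-time-point concurrent vehicle
groups, two compartments (brain, CSF) with distinct turnover rates,
dose ladders like 1/3/10/30/100 mg/kg, and cross-species turnover following
the allometric power law.

Observation model (the source studies publish none): each animal draws a
lognormal between-animal baseline (mean-preserving, default CV 20%), the
model predicts its percent-of-control at its sampling time, and a
multiplicative lognormal assay error (plus an optional additive floor) is
applied to the absolute value. Defaults are placeholders for unpublished
study magnitudes, chosen to be realistic for plate-based Aβ immunoassays.

Seeding: a master seed spawns one deterministic sub-stream per animal keyed
by (dose, time index, animal index, compartment/analyte), so adding a dose
group to a design does not shuffle the draws of existing animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allometry import SpeciesKoutPoint
from .turnover import TurnoverParams, simulate_trajectory

__all__ = [
    "StudyDesign",
    "TruthConfig",
    "generate_study",
    "generate_multispecies_kout",
]


@dataclass(frozen=True)
class StudyDesign:
    """Layout of a synthetic animal study.

    ``doses`` must include the vehicle (0); ``times`` are sampling times in
    hours; ``n_per_group`` animals are measured at every dose x time cell;
    each animal contributes one terminal sample per listed
    (compartment, analyte) stratum (destructive sampling — the rodent
    default). ``destructive=False`` switches to repeated sampling: one
    cohort per dose is followed across all times with a shared baseline,
    emulating serial CSF collection in large species.
    """

    species: str = "mouse"
    bw_kg: float = 0.025
    doses: Sequence[float] = (0.0, 3.0, 10.0, 30.0)
    route: str = "po"
    times: Sequence[float] = (1.0, 3.0, 7.0, 24.0)
    n_per_group: int = 4
    strata: Sequence[tuple[str, str]] = (("brain", "Abeta42"), ("CSF", "Abeta40"))
    destructive: bool = True

    def __post_init__(self) -> None:
        if 0.0 not in tuple(self.doses):
            raise ValueError("design must include a vehicle group (dose 0)")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if any(t < 0 for t in self.times):
            raise ValueError("sampling times must be >= 0")
        if self.bw_kg <= 0:
            raise ValueError("body weight must be > 0")


@dataclass(frozen=True)
class TruthConfig:
    """Generating truth for one synthetic study.

    ``params`` maps (compartment, analyte) to TurnoverParams; ``drives``
    maps each nonzero dose to its concentration drive (use
    ``OneCmtParams.with_dose`` for linear PK across a ladder);
    ``baseline_mean`` maps strata to absolute Aβ means (pg/g tissue for
    brain, pg/mL for CSF); ``baseline_cv`` is the between-animal lognormal
    CV, ``noise_cv`` the multiplicative assay CV, ``noise_floor`` an
    additive half-normal floor in absolute units (0 disables it).
    """

    params: Mapping[tuple[str, str], TurnoverParams]
    drives: Mapping[float, object]
    baseline_mean: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {("brain", "Abeta42"): 2000.0, ("CSF", "Abeta40"): 1500.0})
    baseline_cv: float = 0.20
    noise_cv: float = 0.10
    noise_floor: float = 0.0
    sim_method: str = "lsoda"

    def __post_init__(self) -> None:
        if self.baseline_cv < 0 or self.noise_cv < 0 or self.noise_floor < 0:
            raise ValueError("CVs and noise floor must be >= 0")


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 multiplicative lognormal factor with the given CV."""
    if cv == 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def _animal_rng(seed: int, dose: float, t_idx: int, animal_idx: int) -> np.random.Generator:
    dose_key = int(round(dose * 1e6))
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(dose_key, t_idx, animal_idx)))


def _pct_curves(design: StudyDesign, truth: TruthConfig):
    """Model percent-of-control at each design time, per dose and stratum."""
    times = np.asarray(sorted(set(design.times)), dtype=float)
    grid = times if times[0] == 0 else np.concatenate(([0.0], times))
    curves: dict[tuple[float, tuple[str, str]], dict[float, float]] = {}
    for dose in design.doses:
        for stratum in design.strata:
            p = truth.params[stratum]
            if dose == 0:
                curves[(dose, stratum)] = {t: 100.0 for t in times}
                continue
            try:
                drive = truth.drives[dose]
            except KeyError:
                raise KeyError(f"no drive configured for dose {dose}") from None
            traj = simulate_trajectory(p, drive, grid, method=truth.sim_method)
            curves[(dose, stratum)] = dict(zip(traj.times, traj.abeta_pct))
    return times, curves


def generate_study(design: StudyDesign, truth: TruthConfig, seed: int = 0) -> pd.DataFrame:
    """Simulate one study; returns raw data in the estimation CSV schema.

    Every (dose, time) cell gets ``n_per_group`` animals; each animal is
    measured once per stratum. Record count is
    len(doses) x len(times) x n_per_group x len(strata). The same seed
    reproduces the dataset exactly.
    """
    times, curves = _pct_curves(design, truth)
    rows = []
    for dose in design.doses:
        group = "vehicle" if dose == 0 else f"{dose:g}mpk"
        if design.destructive:
            for t_idx, t in enumerate(times):
                for i in range(design.n_per_group):
                    rng = _animal_rng(seed, dose, t_idx, i)
                    animal = f"{design.species}-{group}-t{t_idx}-a{i}"
                    rows.extend(_measure(animal, group, dose, t, design, truth,
                                         curves, rng))
        else:
            # repeated sampling: one cohort per dose, shared baseline across times
            for i in range(design.n_per_group):
                rng = _animal_rng(seed, dose, 0, i)
                animal = f"{design.species}-{group}-a{i}"
                baselines = {s: truth.baseline_mean[s] * _lognormal_factor(rng, truth.baseline_cv)
                             for s in design.strata}
                for t in times:
                    rows.extend(_measure(animal, group, dose, t, design, truth,
                                         curves, rng, baselines=baselines))
    return pd.DataFrame(rows, columns=["animal_id", "group", "dose", "route",
                                       "time_h", "compartment", "analyte", "value"])


def _measure(animal, group, dose, t, design, truth, curves, rng, baselines=None):
    rows = []
    for stratum in design.strata:
        comp, analyte = stratum
        if baselines is None:
            base = truth.baseline_mean[stratum] * _lognormal_factor(rng, truth.baseline_cv)
        else:
            base = baselines[stratum]
        pct = curves[(dose, stratum)][t]
        value = base * pct / 100.0 * _lognormal_factor(rng, truth.noise_cv)
        if truth.noise_floor > 0:
            value += abs(rng.normal(0.0, truth.noise_floor))
        rows.append({"animal_id": animal, "group": group, "dose": dose,
                     "route": design.route, "time_h": float(t),
                     "compartment": comp, "analyte": analyte,
                     "value": float(value)})
    return rows


def generate_multispecies_kout(a: float, b: float,
                               species: Sequence[tuple[str, float]],
                               noise_sd: float = 0.0,
                               seed: int = 0) -> list[SpeciesKoutPoint]:
    """Draw per-species kout values around the allometric law.

    kout_i = a * BW_i^b * exp(eps_i), eps_i ~ Normal(0, noise_sd^2);
    noise_sd = 0 gives exact power-law points.
    """
    if a <= 0:
        raise ValueError("coefficient a must be > 0")
    rng = np.random.default_rng(seed)
    pts = []
    for label, bw in species:
        if bw <= 0:
            raise ValueError(f"body weight must be > 0 for {label!r}")
        eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        pts.append(SpeciesKoutPoint(label, float(bw), float(a * bw ** b * np.exp(eps))))
    return pts
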