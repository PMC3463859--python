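"""YAML config loading for study designs, truths, PK drives and fit specs.

The CLI (and any scripted pipeline) describes a run with small YAML
documents; this module converts them into the package's dataclasses.
Schemas are deliberately flat:

study design::

    species: mouse
    bw_kg: 0.025
    doses: [0, 3, 10, 30]
    route: po
    times: [1, 3, 7, 24]
    n_per_group: 4
    strata: [[brain, Abeta42], [CSF, Abeta40]]

truth::

    params:
      brain/Abeta42: {kout: 0.49, imax: 1.0, ic50: 100.0, gamma: 1.0}
      CSF/Abeta40:   {kout: 1.42, imax: 1.0, ic50: 100.0, gamma: 1.0}
    pk: {dose: 1.0, f_abs: 0.8, ka: 1.0, ke: 0.25, vd: 2.0}   # dose rescaled per group
    baseline_mean: {brain/Abeta42: 2000.0, CSF/Abeta40: 1500.0}
    baseline_cv: 0.20
    noise_cv: 0.10

fit spec keys mirror :class:`abeta_pkpd.estimation.FitSpec`.
"""

from __future__ import annotations

import yaml

from .estimation import FitSpec
from .pk import OneCmtParams
from .synthetic import StudyDesign, TruthConfig
from .turnover import TurnoverParams

__all__ = [
    "load_yaml",
    "turnover_params_from_dict",
    "onecmt_from_dict",
    "study_design_from_dict",
    "truth_from_dict",
    "fitspec_from_dict",
]


def load_yaml(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a YAML mapping at top level")
    return doc


def _stratum_key(key) -> tuple[str, str]:
    if isinstance(key, str):
        comp, _, analyte = key.partition("/")
        if not analyte:
            raise ValueError(f"stratum key {key!r} must look like 'compartment/analyte'")
        return comp, analyte
    comp, analyte = key
    return str(comp), str(analyte)


def turnover_params_from_dict(d: dict) -> TurnoverParams:
    return TurnoverParams(**{k: float(v) for k, v in d.items()})


def onecmt_from_dict(d: dict) -> OneCmtParams:
    return OneCmtParams(**{k: float(v) for k, v in d.items()})


def study_design_from_dict(d: dict) -> StudyDesign:
    kwargs = dict(d)
    if "strata" in kwargs:
        kwargs["strata"] = tuple(_stratum_key(s) for s in kwargs["strata"])
    for key in ("doses", "times"):
        if key in kwargs:
            kwargs[key] = tuple(float(v) for v in kwargs[key])
    return StudyDesign(**kwargs)


def truth_from_dict(d: dict, doses=None) -> TruthConfig:
    params = {_stratum_key(k): turnover_params_from_dict(v)
              for k, v in d["params"].items()}
    if "pk" in d:
        if doses is None:
            raise ValueError("a parametric 'pk' truth needs the design's dose list")
        template = onecmt_from_dict(d["pk"])
        drives = {float(dose): template.with_dose(float(dose))
                  for dose in doses if dose != 0}
    else:
        raise ValueError("truth config needs a 'pk' block (tabulated drives are "
                         "supplied programmatically)")
    kwargs = {}
    if "baseline_mean" in d:
        kwargs["baseline_mean"] = {_stratum_key(k): float(v)
                                   for k, v in d["baseline_mean"].items()}
    for key in ("baseline_cv", "noise_cv", "noise_floor"):
        if key in d:
            kwargs[key] = float(d[key])
    return TruthConfig(params=params, drives=drives, **kwargs)


def fitspec_from_dict(d: dict) -> FitSpec:
    kwargs = dict(d)
    if "bounds" in kwargs:
        kwargs["bounds"] = {k: tuple(map(float, v)) for k, v in kwargs["bounds"].items()}
    return FitSpec(**kwargs)
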