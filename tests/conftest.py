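import numpy as np
import pytest

from abeta_pkpd import OneCmtParams, StudyDesign, TruthConfig, TurnoverParams

# mouse compartment turnover rates: brain Abeta42 is ~3x slower than CSF Abeta40
MOUSE_BRAIN_KOUT = 0.49
MOUSE_CSF_KOUT = 1.42
ALLOMETRIC_A = 0.415
ALLOMETRIC_B = -0.36


@pytest.fixture
def csf_params() -> TurnoverParams:
    return TurnoverParams(kout=MOUSE_CSF_KOUT, imax=1.0, ic50=0.5, gamma=1.0)


@pytest.fixture
def brain_params() -> TurnoverParams:
    return TurnoverParams(kout=MOUSE_BRAIN_KOUT, imax=1.0, ic50=0.5, gamma=1.0)


@pytest.fixture
def fast_pk() -> OneCmtParams:
    """Rapid absorption/elimination drive: washout reveals turnover."""
    return OneCmtParams(dose=1.0, f_abs=0.8, ka=3.0, ke=1.0, vd=2.0)


@pytest.fixture
def slow_pk() -> OneCmtParams:
    """Slower oral-like drive."""
    return OneCmtParams(dose=1.0, f_abs=0.8, ka=1.0, ke=0.25, vd=2.0)


def make_time_course_design(strata=(("CSF", "Abeta40"),), n_per_group=4,
                            doses=(0.0, 1.0, 3.0, 10.0)) -> StudyDesign:
    """Time-course design sampling onset and washout across a dose ladder."""
    return StudyDesign(doses=doses, times=(0.5, 1, 2, 3, 5, 8, 12),
                       n_per_group=n_per_group, strata=strata)


def make_truth(pk: OneCmtParams, params_by_stratum, doses,
               baseline_cv=0.0, noise_cv=0.0) -> TruthConfig:
    baselines = {("brain", "Abeta42"): 2000.0, ("CSF", "Abeta40"): 1500.0}
    return TruthConfig(
        params=params_by_stratum,
        drives={d: pk.with_dose(d) for d in doses if d != 0},
        baseline_mean={s: baselines.get(s, 1000.0) for s in params_by_stratum},
        baseline_cv=baseline_cv, noise_cv=noise_cv)


@pytest.fixture
def time_grid():
    return np.linspace(0.0, 24.0, 97)


from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("repro", derandomize=True)
_hyp_settings.load_profile("repro")
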