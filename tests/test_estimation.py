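"""Vehicle normalization and turnover-parameter estimation."""

import warnings

import numpy as np
import pandas as pd
import pytest

from abeta_pkpd import (FitSpec, NormalizationError, TurnoverParams,
                        UnidentifiableError, bootstrap_uncertainty,
                        fit_strata, fit_turnover, normalize_to_vehicle)
from abeta_pkpd.estimation import read_raw_csv, validate_raw
from abeta_pkpd.synthetic import generate_study

from conftest import (MOUSE_BRAIN_KOUT, MOUSE_CSF_KOUT, make_time_course_design,
                      make_truth)


def _rec(animal, dose, time, value, compartment="CSF", analyte="Abeta40"):
    return {"animal_id": animal, "group": "vehicle" if dose == 0 else f"{dose}mpk",
            "dose": dose, "route": "po", "time_h": time,
            "compartment": compartment, "analyte": analyte, "value": value}


class TestNormalizeToVehicle:
    def test_treated_equal_to_vehicle_mean_gives_100(self):
        raw = pd.DataFrame([_rec("v1", 0, 3.0, 5.0), _rec("t1", 10, 3.0, 5.0)])
        norm = normalize_to_vehicle(raw)
        assert norm.loc[norm.dose == 10, "pct_of_control"].item() == pytest.approx(100.0)

    def test_percent_of_vehicle_mean(self):
        raw = pd.DataFrame([_rec("v1", 0, 3.0, 4.0), _rec("v2", 0, 3.0, 6.0),
                            _rec("t1", 10, 3.0, 2.5)])
        norm = normalize_to_vehicle(raw)
        assert norm.loc[norm.dose == 10, "pct_of_control"].item() == pytest.approx(50.0)

    def test_missing_concurrent_vehicle_names_stratum(self):
        raw = pd.DataFrame([_rec("v1", 0, 3.0, 5.0), _rec("t1", 10, 7.0, 2.5)])
        with pytest.raises(NormalizationError, match=r"7\.0.*CSF.*Abeta40"):
            normalize_to_vehicle(raw)

    def test_zero_vehicle_mean_rejected(self):
        raw = pd.DataFrame([_rec("v1", 0, 3.0, 0.0), _rec("t1", 10, 3.0, 2.5)])
        with pytest.raises(NormalizationError, match="zero"):
            normalize_to_vehicle(raw)

    def test_idempotent_when_vehicle_mean_is_100(self):
        raw = pd.DataFrame([_rec("v1", 0, 3.0, 90.0), _rec("v2", 0, 3.0, 110.0),
                            _rec("t1", 10, 3.0, 55.0)])
        once = normalize_to_vehicle(raw)
        again = normalize_to_vehicle(once.assign(value=once["pct_of_control"]))
        np.testing.assert_allclose(again["pct_of_control"], once["pct_of_control"])

    def test_vehicle_records_retained_and_mean_100(self):
        raw = pd.DataFrame([_rec("v1", 0, 3.0, 4.0), _rec("v2", 0, 3.0, 6.0),
                            _rec("t1", 10, 3.0, 2.5)])
        norm = normalize_to_vehicle(raw)
        veh = norm[norm.dose == 0]
        assert len(veh) == 2
        assert veh["pct_of_control"].mean() == pytest.approx(100.0)

    def test_schema_validation(self):
        with pytest.raises(ValueError, match="missing columns"):
            validate_raw(pd.DataFrame({"animal_id": ["a"]}))


@pytest.fixture(scope="module")
def noiseless_csf_study(request):
    """Noiseless synthetic CSF study with the fast mouse CSF turnover."""
    from conftest import make_time_course_design, make_truth
    from abeta_pkpd import OneCmtParams
    pk = OneCmtParams(dose=1.0, f_abs=0.8, ka=3.0, ke=1.0, vd=2.0)
    truth_p = TurnoverParams(kout=MOUSE_CSF_KOUT, imax=1.0, ic50=0.5, gamma=1.0)
    design = make_time_course_design()
    truth = make_truth(pk, {("CSF", "Abeta40"): truth_p}, design.doses)
    raw = generate_study(design, truth, seed=11)
    return raw, truth, truth_p


class TestFitTurnover:
    def test_noiseless_recovery_all_free_parameters(self, noiseless_csf_study):
        raw, truth, truth_p = noiseless_csf_study
        norm = normalize_to_vehicle(raw)
        spec = FitSpec(init={"kout": 0.6, "imax": 0.8, "ic50": 0.2, "gamma": 1.3})
        fit = fit_turnover(norm, truth.drives, spec)
        assert fit.status in ("converged", "at_bounds")  # imax sits at its cap of 1
        for name in ("kout", "imax", "ic50", "gamma"):
            est, true = getattr(fit.params, name), getattr(truth_p, name)
            assert est == pytest.approx(true, rel=0.01), name
        assert fit.kin == pytest.approx(100 * fit.params.kout)

    def test_vehicle_only_dataset_unidentifiable(self):
        raw = pd.DataFrame([_rec(f"v{i}", 0, t, 5.0)
                            for i in range(3) for t in (1.0, 3.0)])
        norm = normalize_to_vehicle(raw)
        with pytest.raises(UnidentifiableError):
            fit_turnover(norm, {}, FitSpec())

    def test_single_time_point_design_rejected_for_free_kout(self):
        raw = pd.DataFrame([_rec("v1", 0, 3.0, 5.0), _rec("t1", 10, 3.0, 2.5),
                            _rec("t2", 30, 3.0, 1.5)])
        norm = normalize_to_vehicle(raw)
        with pytest.raises(UnidentifiableError, match="single"):
            fit_turnover(norm, {10: None, 30: None}, FitSpec())

    def test_estimates_invariant_to_record_order_and_ids(self, noiseless_csf_study):
        raw, truth, _ = noiseless_csf_study
        spec = FitSpec(init={"kout": 0.6, "imax": 0.8, "ic50": 0.2, "gamma": 1.3})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_turnover(normalize_to_vehicle(raw), truth.drives, spec)
            shuffled = raw.sample(frac=1.0, random_state=4).reset_index(drop=True)
            shuffled["animal_id"] = [f"relabeled-{i}" for i in range(len(shuffled))]
            b = fit_turnover(normalize_to_vehicle(shuffled), truth.drives, spec)
        assert b.params.kout == pytest.approx(a.params.kout, rel=1e-6)
        assert b.params.ic50 == pytest.approx(a.params.ic50, rel=1e-6)

    def test_unnormalized_data_rejected(self, noiseless_csf_study):
        raw, truth, _ = noiseless_csf_study
        with pytest.raises(ValueError, match="normalized"):
            fit_turnover(raw, truth.drives, FitSpec())

    def test_missing_drive_for_treated_group(self, noiseless_csf_study):
        raw, truth, _ = noiseless_csf_study
        norm = normalize_to_vehicle(raw)
        with pytest.raises(KeyError, match="drive"):
            fit_turnover(norm, {}, FitSpec())

    def test_multi_stratum_data_rejected_by_single_fit(self, fast_pk):
        design = make_time_course_design(
            strata=(("brain", "Abeta42"), ("CSF", "Abeta40")), n_per_group=1)
        truth = make_truth(fast_pk, {
            ("brain", "Abeta42"): TurnoverParams(kout=MOUSE_BRAIN_KOUT, ic50=0.5),
            ("CSF", "Abeta40"): TurnoverParams(kout=MOUSE_CSF_KOUT, ic50=0.5)},
            design.doses)
        norm = normalize_to_vehicle(generate_study(design, truth, seed=2))
        with pytest.raises(ValueError, match="stratum"):
            fit_turnover(norm, truth.drives, FitSpec())

    def test_fit_strata_recovers_both_compartments(self, fast_pk):
        design = make_time_course_design(
            strata=(("brain", "Abeta42"), ("CSF", "Abeta40")), n_per_group=2)
        truth = make_truth(fast_pk, {
            ("brain", "Abeta42"): TurnoverParams(kout=MOUSE_BRAIN_KOUT, ic50=0.5),
            ("CSF", "Abeta40"): TurnoverParams(kout=MOUSE_CSF_KOUT, ic50=0.5)},
            design.doses)
        norm = normalize_to_vehicle(generate_study(design, truth, seed=3))
        spec = FitSpec(init={"kout": 0.8, "imax": 1.0, "ic50": 0.3, "gamma": 1.0},
                       vary={"imax": False, "gamma": False})
        fits = fit_strata(norm, truth.drives, spec)
        assert fits[("brain", "Abeta42")].params.kout == pytest.approx(
            MOUSE_BRAIN_KOUT, rel=0.01)
        assert fits[("CSF", "Abeta40")].params.kout == pytest.approx(
            MOUSE_CSF_KOUT, rel=0.01)

    def test_raw_csv_round_trip(self, noiseless_csf_study, tmp_path):
        raw, _, _ = noiseless_csf_study
        path = tmp_path / "raw.csv"
        raw.to_csv(path, index=False)
        back = read_raw_csv(path)
        assert len(back) == len(raw)
        np.testing.assert_allclose(back["value"], raw["value"])


@pytest.fixture(scope="module")
def noisy_study():
    from abeta_pkpd import OneCmtParams
    pk = OneCmtParams(dose=1.0, f_abs=0.8, ka=3.0, ke=1.0, vd=2.0)
    truth_p = TurnoverParams(kout=MOUSE_CSF_KOUT, imax=1.0, ic50=0.5, gamma=1.0)
    design = make_time_course_design()
    truth = make_truth(pk, {("CSF", "Abeta40"): truth_p}, design.doses,
                       noise_cv=0.10)
    raw = generate_study(design, truth, seed=21)
    spec = FitSpec(init={"kout": 1.0, "imax": 1.0, "ic50": 0.3, "gamma": 1.0},
                   vary={"imax": False, "gamma": False}, sim_dt=0.05)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_turnover(normalize_to_vehicle(raw), truth.drives, spec)
    return raw, truth, spec, fit


class TestBootstrap:
    def test_deterministic_under_seed(self, noisy_study):
        raw, truth, spec, fit = noisy_study
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = bootstrap_uncertainty(raw, truth.drives, spec, n_boot=30, seed=9,
                                      warm_start=fit)
            b = bootstrap_uncertainty(raw, truth.drives, spec, n_boot=30, seed=9,
                                      warm_start=fit)
        assert a.ci == b.ci

    def test_ci_contains_point_estimate_and_shrinks_with_n(self, fast_pk):
        truth_p = TurnoverParams(kout=MOUSE_CSF_KOUT, imax=1.0, ic50=0.5, gamma=1.0)
        spec = FitSpec(init={"kout": 1.0, "imax": 1.0, "ic50": 0.3, "gamma": 1.0},
                       vary={"imax": False, "gamma": False}, sim_dt=0.05)
        widths = {}
        for n in (4, 16):
            design = make_time_course_design(n_per_group=n)
            truth = make_truth(fast_pk, {("CSF", "Abeta40"): truth_p},
                               design.doses, noise_cv=0.10)
            raw = generate_study(design, truth, seed=31)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_turnover(normalize_to_vehicle(raw), truth.drives, spec)
                boot = bootstrap_uncertainty(raw, truth.drives, spec, n_boot=60,
                                             seed=5, warm_start=fit)
            lo, hi = boot.ci["kout"]
            assert lo <= fit.params.kout <= hi
            widths[n] = hi - lo
        assert widths[16] < widths[4]

    def test_small_n_boot_warns(self, noisy_study):
        raw, truth, spec, fit = noisy_study
        with pytest.warns(UserWarning, match="n_boot"):
            bootstrap_uncertainty(raw, truth.drives, spec, n_boot=5, seed=1,
                                  warm_start=fit)
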