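import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardiovar import doseresp as dr

GRID = (0.1, 1.0, 10.0, 100.0)


def make_params_wells(donors, endpoint="bpm", vehicle_values=(10.0, 12.0, 14.0)):
    """Minimal params/wells frames: per donor, vehicle wells plus treated
    wells holding given (conc, value) pairs."""
    prows, wrows = [], []
    i = 0
    for donor, treated in donors.items():
        for v in vehicle_values:
            i += 1
            wid = f"w{i:03d}"
            prows.append({"well_id": wid, endpoint: v, "quiescent": False})
            wrows.append({
                "well_id": wid, "donor_id": donor, "plate_id": "p1",
                "treatment": "vehicle", "compound": "", "conc_uM": None,
            })
        for conc, value in treated:
            i += 1
            wid = f"w{i:03d}"
            prows.append({"well_id": wid, endpoint: value, "quiescent": False})
            wrows.append({
                "well_id": wid, "donor_id": donor, "plate_id": "p1",
                "treatment": "ISO", "compound": "ISO", "conc_uM": conc,
            })
    return pd.DataFrame(prows), pd.DataFrame(wrows)


def exact_table(form, donor_params, concs=GRID, scale=1.0, noise=0.0, seed=0, reps=4):
    """Response table generated exactly from a model form."""
    rng = np.random.default_rng(seed)
    rows = []
    for donor, p in donor_params.items():
        for x in concs:
            if form == "ISO_EMAX":
                mu = dr.iso_emax_mean(np.asarray(x), p)
            elif form == "CIS_LOG_EMAX":
                mu = np.exp(dr.cis_log_emax_mean(np.asarray(x), p))
            else:
                mu = dr.pro2_mean(np.asarray(x), p, scale)
            for _ in range(reps):
                y = float(mu)
                if noise:
                    y = y + rng.normal(0, noise) if form != "CIS_LOG_EMAX" else y * np.exp(rng.normal(0, noise))
                rows.append({
                    "donor_id": donor, "well_id": f"{donor}-{x}-{_}",
                    "plate_id": "p1", "treatment": form, "compound": "X",
                    "concentration": x, "endpoint_name": "y",
                    "normalized_value": y, "quiescent": False,
                })
    return pd.DataFrame(rows)


SPECS = {
    "ISO_EMAX": dr.ModelSpec(form="ISO_EMAX", endpoint="bpm"),
    "CIS_LOG_EMAX": dr.ModelSpec(form="CIS_LOG_EMAX", endpoint="decay_rise_ratio"),
    "PRO2": dr.ModelSpec(form="PRO2", endpoint="bpm"),
}


class TestNormalize:
    def test_simple_arithmetic(self):
        params, wells = make_params_wells({"D1": [(1.0, 18.0)]})
        tab = dr.normalize_to_control(params, wells, "bpm")
        treated = tab[tab["compound"].notna()]
        assert treated["normalized_value"].iloc[0] == pytest.approx(18.0 / 12.0)

    def test_all_vehicle_medians_are_one(self):
        params, wells = make_params_wells({"D1": [], "D2": []})
        tab = dr.normalize_to_control(params, wells, "bpm")
        med = tab.groupby("donor_id")["normalized_value"].median()
        assert np.allclose(med, 1.0)

    def test_idempotent(self):
        params, wells = make_params_wells({"D1": [(1.0, 18.0), (10.0, 24.0)]})
        tab = dr.normalize_to_control(params, wells, "bpm")
        params2 = params.copy()
        params2["bpm"] = tab.set_index("well_id").loc[params2["well_id"], "normalized_value"].values
        tab2 = dr.normalize_to_control(params2, wells, "bpm")
        pd.testing.assert_series_equal(
            tab.set_index("well_id")["normalized_value"],
            tab2.set_index("well_id")["normalized_value"],
        )

    def test_missing_vehicle_names_donor(self):
        params, wells = make_params_wells({"D7": [(1.0, 18.0)]})
        wells.loc[wells["treatment"].eq("vehicle"), "treatment"] = "media"
        with pytest.raises(ValueError, match="D7"):
            dr.normalize_to_control(params, wells, "bpm")


class TestDropRule:
    @staticmethod
    def _table(compound, concs=GRID):
        return pd.DataFrame({
            "donor_id": "D1",
            "compound": compound,
            "concentration": list(concs),
            "normalized_value": 1.0,
            "quiescent": False,
        })

    def test_inotropes_lose_top_concentration(self):
        for compound in ("ISO", "PRO"):
            out = dr.apply_drop_rule(self._table(compound), compound)
            assert 100.0 not in out["concentration"].values
            assert len(out) == 3

    def test_cis_keeps_all_concentrations(self):
        out = dr.apply_drop_rule(self._table("CIS"), "CIS")
        assert len(out) == 4

    def test_noop_without_top_group(self):
        out = dr.apply_drop_rule(self._table("ISO", (0.1, 1.0, 10.0)), "ISO")
        assert len(out) == 3

    def test_unknown_compound_rejected(self):
        with pytest.raises(ValueError):
            dr.apply_drop_rule(self._table("ISO"), "XYZ")


class TestFitModel:
    @pytest.mark.parametrize(
        "form,params",
        [
            ("ISO_EMAX", {"D1": 2.2, "D2": 1.6}),
            ("CIS_LOG_EMAX", {"D1": 2.6881, "D2": 1.2}),
            ("PRO2", {"D1": np.log(0.538), "D2": np.log(5.0)}),
        ],
    )
    def test_noiseless_recovery_to_machine_precision(self, form, params):
        tab = exact_table(form, params)
        fit = dr.fit_model(SPECS[form], tab, method="two_stage")
        for donor, truth in params.items():
            assert fit.donor_params()[donor] == pytest.approx(truth, abs=1e-6)
        if form == "PRO2":
            assert fit.fixed_effects["scale"] == pytest.approx(1.0, abs=1e-6)

    def test_pro2_midpoint_is_half(self):
        assert dr.pro2_mean(np.asarray(0.538), np.log(0.538), 1.0) == pytest.approx(0.5)

    def test_cis_null_effect_curve_is_flat_one(self):
        tab = exact_table("CIS_LOG_EMAX", {"D1": 1.0, "D2": 1.0})
        fit = dr.fit_model(SPECS["CIS_LOG_EMAX"], tab)
        change = dr.predict_change_at(fit, 1.0)
        assert np.allclose(change, 0.0, atol=1e-8)

    @pytest.mark.parametrize("form,params", [
        ("ISO_EMAX", {f"D{i}": b for i, b in enumerate([1.5, 1.8, 2.0, 2.2])}),
        ("PRO2", {f"D{i}": p for i, p in enumerate([-0.6, 0.2, 1.0, 2.0])}),
    ])
    def test_two_stage_and_laplace_agree_at_low_noise(self, form, params):
        tab = exact_table(form, params, noise=0.01, seed=3, reps=6)
        ts = dr.fit_model(SPECS[form], tab, method="two_stage")
        la = dr.fit_model(SPECS[form], tab, method="laplace")
        re = SPECS[form].random_effect
        assert la.fixed_effects[re] == pytest.approx(ts.fixed_effects[re], abs=0.02)
        np.testing.assert_allclose(
            la.donor_params().values, ts.donor_params().values, atol=0.05
        )

    def test_change_prediction_bias_small_at_default_noise(self):
        # per-donor percent change at 1 uM, default residual noise level
        rng_bias = []
        for seed in range(30):
            tab = exact_table("ISO_EMAX", {"D1": 2.0}, noise=0.06, seed=seed, reps=8)
            fit = dr.fit_model(SPECS["ISO_EMAX"], tab)
            rng_bias.append(dr.predict_change_at(fit, 1.0)["D1"])
        truth = 100.0 * (dr.iso_emax_mean(np.asarray(1.0), 2.0) - 1.0)
        assert np.mean(rng_bias) == pytest.approx(truth, rel=0.05)

    def test_donor_with_single_concentration_rejected(self):
        tab = exact_table("ISO_EMAX", {"D1": 2.0}, concs=(1.0,))
        with pytest.raises(ValueError, match="D1"):
            dr.fit_model(SPECS["ISO_EMAX"], tab)

    def test_unknown_method_rejected(self):
        tab = exact_table("ISO_EMAX", {"D1": 2.0})
        with pytest.raises(ValueError):
            dr.fit_model(SPECS["ISO_EMAX"], tab, method="bayes")

    def test_quiescent_wells_are_excluded_and_logged(self):
        tab = exact_table("ISO_EMAX", {"D1": 2.0})
        tab.loc[tab.index[:3], "quiescent"] = True
        fit = dr.fit_model(SPECS["ISO_EMAX"], tab)
        assert fit.dropped["quiescent_wells"] == 3


class TestPredictChange:
    def test_closed_form_calibration_points(self):
        # solved from the model forms at the calibrated extremes
        assert dr.iso_emax_mean(np.asarray(1.0), 2.2012) == pytest.approx(2.2, abs=1e-4)
        tab = exact_table("ISO_EMAX", {"D1": 2.2012})
        fit = dr.fit_model(SPECS["ISO_EMAX"], tab)
        assert dr.predict_change_at(fit, 1.0)["D1"] == pytest.approx(120.0, abs=0.05)

        tab = exact_table("CIS_LOG_EMAX", {"D1": 2.6881})
        fit = dr.fit_model(SPECS["CIS_LOG_EMAX"], tab)
        assert dr.predict_change_at(fit, 1.0)["D1"] == pytest.approx(440.0, abs=0.5)

        tab = exact_table("PRO2", {"D1": np.log(0.538)})
        fit = dr.fit_model(SPECS["PRO2"], tab)
        assert dr.predict_change_at(fit, 1.0)["D1"] == pytest.approx(-65.0, abs=0.05)
        tab = exact_table("PRO2", {"D1": np.log(13.3)})
        fit = dr.fit_model(SPECS["PRO2"], tab)
        assert dr.predict_change_at(fit, 1.0)["D1"] == pytest.approx(-7.0, abs=0.05)

    def test_change_vanishes_at_zero_dose(self):
        tab = exact_table("ISO_EMAX", {"D1": 2.2})
        fit = dr.fit_model(SPECS["ISO_EMAX"], tab)
        assert dr.predict_change_at(fit, 1e-9)["D1"] == pytest.approx(0.0, abs=0.01)

    def test_nonpositive_concentration_rejected(self):
        tab = exact_table("ISO_EMAX", {"D1": 2.2})
        fit = dr.fit_model(SPECS["ISO_EMAX"], tab)
        with pytest.raises(ValueError):
            dr.predict_change_at(fit, 0.0)

    @given(st.floats(min_value=1.01, max_value=3.0))
    @settings(max_examples=20, deadline=None)
    def test_model_shape_invariants(self, B):
        xs = np.geomspace(1e-3, 1e3, 40)
        assert np.all(np.diff(dr.iso_emax_mean(xs, B)) > 0)
        assert np.all(np.exp(dr.cis_log_emax_mean(xs, B)) >= 1.0)
        assert np.all(np.diff(dr.pro2_mean(xs, np.log(B), 1.0)) < 0)


class TestSummarizeVariability:
    def test_two_donor_arithmetic(self):
        tab = exact_table("ISO_EMAX", {"D1": 1.5005, "D2": 2.2012})
        fit = dr.fit_model(SPECS["ISO_EMAX"], tab)
        s = dr.summarize_variability(fit, 1.0)
        assert s.minimum == pytest.approx(50.0, abs=0.1)
        assert s.maximum == pytest.approx(120.0, abs=0.1)
        assert s.median == pytest.approx(85.0, abs=0.1)
        assert s.minimum <= s.median <= s.maximum

    def test_single_donor_rejected(self):
        tab = exact_table("ISO_EMAX", {"D1": 2.0})
        fit = dr.fit_model(SPECS["ISO_EMAX"], tab)
        with pytest.raises(ValueError):
            dr.summarize_variability(fit)
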