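import numpy as np
import pandas as pd
import pytest

from impscore.registry import RegistryError
from impscore.simulate import hazard
from impscore.wadp import (
    TMR_FLOOR,
    BlendWeights,
    DerivationError,
    SeverityTable,
    blend_tdp,
    compute_tmr,
    derive_wadp,
    fit_component_model,
    lookup_tmr,
    optimize_blend_weights,
    simplex_grid,
)

from conftest import make_patient


def cohort_with_code_outcomes(spec):
    """One single-injury patient per (code, died) event given {predot: (n, d)}."""
    patients = []
    for predot, (n, d) in spec.items():
        for i in range(n):
            patients.append(
                make_patient(
                    pid=f"{predot}_{i}", codes=(f"{predot}.3",), died=i < d
                )
            )
    return patients


class TestComputeTMR:
    def test_smoothing_rules(self):
        patients = cohort_with_code_outcomes(
            {"110000": (100, 5), "210000": (3, 3), "310000": (50, 0)}
        )
        tab = compute_tmr(patients)
        assert tab.loc["110000", "tmr"] == pytest.approx(0.05)  # raw rate
        assert tab.loc["210000", "tmr"] == pytest.approx(0.75)  # add-a-survivor
        assert tab.loc["310000", "tmr"] == pytest.approx(0.008 * 0.618)  # floor
        assert tab.loc["310000", "tmr"] == pytest.approx(0.004944)

    def test_patient_counted_once_per_code(self):
        p = make_patient(pid="X", codes=("110000.3", "110000.2"), died=True)
        q = make_patient(pid="Y", codes=("110000.3",), died=False)
        tab = compute_tmr([p, q])
        assert tab.loc["110000", "n_patients"] == 2
        assert tab.loc["110000", "tmr"] == pytest.approx(0.5)

    def test_all_rates_strictly_interior(self):
        patients = cohort_with_code_outcomes(
            {"110000": (5, 0), "210000": (1, 1), "310000": (4, 2)}
        )
        tab = compute_tmr(patients)
        assert ((tab["tmr"] > 0) & (tab["tmr"] < 1)).all()

    def test_unknown_code_lookup_raises(self):
        tab = compute_tmr(cohort_with_code_outcomes({"110000": (4, 1)}))
        assert lookup_tmr(tab, "110000") == pytest.approx(0.25)
        with pytest.raises(DerivationError):
            lookup_tmr(tab, "999999")


class TestBlend:
    def test_identity_weight(self):
        w = BlendWeights(1, 0, 0)
        p = np.array([0.1, 0.9])
        assert np.allclose(blend_tdp(p, p * 0 + 0.5, p * 0 + 0.5, w), p)

    def test_convexity_fixed_point(self):
        p = np.full(4, 0.3)
        for w in simplex_grid(0.5):
            assert np.allclose(blend_tdp(p, p, p, w), 0.3)

    def test_stated_arithmetic(self):
        out = blend_tdp(
            np.array([0.1]), np.array([0.5]), np.array([0.2]),
            BlendWeights(0.5, 0.3, 0.2),
        )
        assert out[0] == pytest.approx(0.24)

    def test_missing_gcs_renormalizes(self):
        out = blend_tdp(
            np.array([0.2]), np.array([np.nan]), np.array([0.4]),
            BlendWeights(0.25, 0.5, 0.25),
        )
        assert out[0] == pytest.approx(0.3)  # (0.25*0.2 + 0.25*0.4)/0.5

    def test_all_weight_on_missing_component_raises(self):
        with pytest.raises(DerivationError):
            blend_tdp(
                np.array([0.2]), np.array([np.nan]), np.array([0.4]),
                BlendWeights(0, 1, 0),
            )

    def test_off_simplex_weights_rejected(self):
        with pytest.raises(RegistryError):
            BlendWeights(0.5, 0.5, 0.5)


class TestOptimizeBlendWeights:
    def test_grid_enumeration_step_half(self):
        grid = simplex_grid(0.5)
        assert len(grid) == 6
        assert {(w.w_tmr, w.w_gcs, w.w_br) for w in grid} == {
            (1, 0, 0), (0.5, 0.5, 0), (0.5, 0, 0.5),
            (0, 1, 0), (0, 0.5, 0.5), (0, 0, 1),
        }

    def test_informative_component_wins(self, rng):
        n = 4000
        p_true = rng.uniform(0.01, 0.9, n)
        died = rng.random(n) < p_true
        p_gcs = rng.uniform(0.01, 0.9, n)
        p_br = rng.uniform(0.01, 0.9, n)
        winner, grid = optimize_blend_weights(
            p_true, p_gcs, p_br, died.astype(float), grid_step=0.25, seed=0
        )
        # independent exhaustive evaluation of the same grid
        best = grid.sort_values(
            ["auc", "w_tmr", "w_gcs"], ascending=False, kind="mergesort"
        ).iloc[0]
        assert (winner.w_tmr, winner.w_gcs, winner.w_br) == (
            best["w_tmr"], best["w_gcs"], best["w_br"],
        )
        assert winner.w_tmr == 1.0

    def test_tie_breaks_toward_tmr(self, rng):
        n = 200
        p = rng.uniform(0.1, 0.9, n)
        died = (rng.random(n) < 0.3).astype(float)
        # all three components identical -> every grid point ties
        winner, _ = optimize_blend_weights(p, p, p, died, grid_step=0.5, seed=1)
        assert (winner.w_tmr, winner.w_gcs, winner.w_br) == (1, 0, 0)

    def test_empty_grid_rejected(self):
        with pytest.raises(RegistryError):
            simplex_grid(0)


class TestDeriveWADP:
    def _patients_with_tdp(self, code_carriers):
        """code_carriers: {predot: [tdp,...]}; returns (patients, tdp array)."""
        patients, tdps = [], []
        i = 0
        for predot, values in code_carriers.items():
            for v in values:
                patients.append(
                    make_patient(pid=f"p{i}", codes=(f"{predot}.2",))
                )
                tdps.append(v)
                i += 1
        return patients, np.array(tdps)

    def test_top3_mean_identity_transform(self):
        patients, tdp = self._patients_with_tdp({"110000": [0.1, 0.2, 0.3, 0.4]})
        tab = derive_wadp(patients, tdp, transform="identity")
        assert tab.loc["110000", "wadp"] == pytest.approx(np.mean([0.4, 0.3, 0.2]))
        assert tab.loc["110000", "n_support"] == 4

    def test_fewer_than_three_carriers(self):
        patients, tdp = self._patients_with_tdp({"110000": [0.5]})
        tab = derive_wadp(patients, tdp, transform="identity")
        assert tab.loc["110000", "wadp"] == pytest.approx(0.5)

    def test_default_transform_matches_hazard_scale(self):
        patients, tdp = self._patients_with_tdp({"110000": [0.975], "210000": [0.008]})
        tab = derive_wadp(patients, tdp)
        assert tab.loc["110000", "wadp"] == pytest.approx(3.6889, abs=1e-3)
        assert tab.loc["210000", "wadp"] == pytest.approx(0.008032, abs=1e-5)

    def test_top_weights_option(self):
        patients, tdp = self._patients_with_tdp({"110000": [0.1, 0.2, 0.4]})
        tab = derive_wadp(
            patients, tdp, transform="identity", top_weights=(0.5, 0.3, 0.2)
        )
        assert tab.loc["110000", "wadp"] == pytest.approx(
            0.5 * 0.4 + 0.3 * 0.2 + 0.2 * 0.1
        )

    def test_monotone_in_contributing_tdp(self, rng):
        codes = [f"{rng.integers(1,10)}{i:05d}" for i in range(30)]
        patients = [
            make_patient(
                pid=f"p{i}",
                codes=tuple(
                    f"{c}.2" for c in rng.choice(codes, rng.integers(1, 5), replace=False)
                ),
            )
            for i in range(200)
        ]
        tdp = rng.uniform(0.01, 0.9, 200)
        base = derive_wadp(patients, tdp)
        bumped = tdp.copy()
        bumped[17] = min(0.99, bumped[17] + 0.05)
        after = derive_wadp(patients, bumped)
        carried = {inj.code.predot for inj in patients[17].injuries}
        joined = base["wadp"].to_frame("before").join(after["wadp"].rename("after"))
        assert (joined["after"] >= joined["before"] - 1e-12)[list(carried)].all()
        others = joined.drop(index=list(carried))
        assert np.allclose(others["before"], others["after"])

    def test_nan_tdp_rejected(self):
        patients, tdp = self._patients_with_tdp({"110000": [0.5, 0.2]})
        tdp[0] = np.nan
        with pytest.raises(DerivationError):
            derive_wadp(patients, tdp)


class TestComponentModels:
    def test_intercept_only_predicts_sample_rate(self, rng):
        from impscore.models import MortalityModel

        y = (rng.random(2000) < 0.025).astype(float)
        model = MortalityModel(y, pd.DataFrame(index=range(2000)), kind="imp")
        res = model.fit()
        preds = res.predict(pd.DataFrame(index=range(5)))
        assert np.allclose(preds, y.mean(), atol=1e-5)

    def test_predictions_strictly_in_unit_interval(self, small_splits, derived_small):
        derivation, _, _ = small_splits
        for name, cm in derived_small.components.items():
            if cm is None:
                continue
            p = cm.predict(derivation, derived_small.tmr_table)
            p = p[~np.isnan(p)]
            assert ((p > 0) & (p < 1)).all()

    def test_gcs_model_fitted_on_observed_only(self, small_splits, derived_small):
        derivation, _, _ = small_splits
        cm = derived_small.components["gcs"]
        p = cm.predict(derivation)
        missing = np.array([pt.gcs is None for pt in derivation])
        assert np.isnan(p[missing]).all()
        assert not np.isnan(p[~missing]).any()

    def test_constant_outcome_rejected(self):
        patients = [make_patient(pid=f"p{i}", died=False) for i in range(50)]
        with pytest.raises(DerivationError, match="constant"):
            fit_component_model("br", patients, min_hospital_n=1)

    def test_slope_recovery_on_known_logistic_law(self, rng):
        """Outcome generated from a logistic law on the max-TMR logit."""
        from impscore.wadp import _logit, _patient_tmr_covariate

        tmr_vals = rng.uniform(0.005, 0.6, 40)
        codes = [f"{rng.integers(1,10)}{i:05d}" for i in range(40)]
        tab = pd.DataFrame(
            {"n_patients": 100, "n_deaths": 1, "tmr": tmr_vals},
            index=pd.Index(codes, name="predot"),
        )
        n = 30_000
        patients = []
        for i in range(n):
            k = rng.integers(1, 4)
            cs = rng.choice(codes, k, replace=False)
            patients.append(
                make_patient(
                    pid=f"p{i}",
                    codes=tuple(f"{c}.2" for c in cs),
                    hospital=f"H{rng.integers(0, 4)}",
                )
            )
        x = _patient_tmr_covariate(patients, tab, "max-logit")
        true_slope, true_icpt = 0.8, -1.5
        died = rng.random(n) < 1 / (1 + np.exp(-(true_icpt + true_slope * x)))
        patients = [
            make_patient(
                pid=p.patient_id,
                codes=tuple(f"{inj.code.predot}.2" for inj in p.injuries),
                hospital=p.hospital_id,
                died=bool(d),
            )
            for p, d in zip(patients, died)
        ]
        cm = fit_component_model("tmr", patients, tmr_table=tab, min_hospital_n=1)
        assert cm.params["tmr_score"] == pytest.approx(true_slope, rel=0.10)


class TestSeverityTable:
    def test_fallback_for_unseen_code(self):
        tab = SeverityTable(
            pd.DataFrame({"wadp": [0.5]}, index=pd.Index(["110000"], name="predot"))
        )
        assert tab.lookup("110000") == 0.5
        assert tab.lookup("999999") == pytest.approx(float(hazard(TMR_FLOOR)), abs=1e-9)

    def test_csv_roundtrip(self, tmp_path):
        df = pd.DataFrame(
            {"wadp": [0.25, 1.5], "n_support": [10, 3]},
            index=pd.Index(["110000", "920000"], name="predot"),
        )
        path = tmp_path / "wadp.csv"
        SeverityTable(df).to_csv(path)
        back = SeverityTable.from_csv(path)
        assert back.lookup("920000") == pytest.approx(1.5)
        assert len(back) == 2


class TestDeriverEndToEnd:
    def test_summary_and_tables(self, derived_small):
        res = derived_small
        assert len(res.wadp_table) > 0
        assert (res.wadp_table["wadp"] >= 0).all()
        assert np.isfinite(res.wadp_table["wadp"]).all()
        assert res.tdp["tdp"].between(0, 1, inclusive="neither").all()
        text = res.summary()
        assert "blend weights" in text and "WADP range" in text

    def test_patient_anchor_mode(self, small_splits):
        from impscore.wadp import DerivationConfig, WADPDeriver

        derivation, _, _ = small_splits
        res = WADPDeriver(
            derivation, config=DerivationConfig(anchor="patient", grid_step=0.5)
        ).fit()
        assert (res.wadp_table["wadp"] >= 0).all()
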