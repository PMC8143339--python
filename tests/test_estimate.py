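"""Estimation-layer tests: objective arithmetic, stage fits, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest

import conapkpd as cp
from conapkpd.estimate import PD_PARAMETER_NAMES, estimate_cv

from conftest import perturbed


def drug_table(times_h, doses, values):
    n = len(times_h)
    return pd.DataFrame({
        "group": ["g"] * n, "animal_id": [f"a{i}" for i in range(n)],
        "dose_mg_per_kg": doses, "time_h": times_h, "analyte": ["GRMS55"] * n,
        "value": values, "unit": ["mg/L"] * n, "cona": [False] * n,
    })


class TestWLSObjective:
    def test_zero_for_exact_data(self, ref_params):
        t = np.array([0.25, 0.5, 1.0])
        table = drug_table(t, [50.0] * 3, cp.pk_concentration(t, 50.0, ref_params.pk))
        assert cp.wls_objective(ref_params, table) == pytest.approx(0.0, abs=1e-20)

    def test_single_observation_hand_value(self, ref_params):
        """y=2, yhat=1: weight 1/yhat^2 = 1, objective (2-1)^2 = 1."""
        t = 0.693147  # chosen so the model prediction is ~1 after dose scaling
        yhat = cp.pk_concentration(t, 50.0, ref_params.pk)
        table = drug_table([t], [50.0], [yhat + 1.0])
        assert cp.wls_objective(ref_params, table) == pytest.approx(1.0 / yhat**2, rel=1e-12)

    def test_three_point_hand_sum(self, ref_params):
        t = np.array([0.25, 0.5, 1.0])
        yhat = cp.pk_concentration(t, 50.0, ref_params.pk)
        y = yhat * np.array([1.1, 0.9, 1.3])
        table = drug_table(t, [50.0] * 3, y)
        expected = float(np.sum((y - yhat) ** 2 / yhat**2))
        assert cp.wls_objective(ref_params, table) == pytest.approx(expected, rel=1e-12)

    def test_weight_exponent_zero_is_ordinary_ls(self, ref_params):
        t = np.array([0.25, 0.5, 1.0])
        yhat = cp.pk_concentration(t, 50.0, ref_params.pk)
        y = yhat + np.array([0.5, -0.25, 0.1])
        table = drug_table(t, [50.0] * 3, y)
        expected = float(np.sum((y - yhat) ** 2))
        assert cp.wls_objective(ref_params, table, weight_exponent=0.0) == pytest.approx(
            expected, rel=1e-12)


class TestInformationCriteria:
    def test_unit_mean_square(self):
        aic, bic = cp.information_criteria(10.0, 10, 3)  # WSS = n -> ln term 0
        assert aic == pytest.approx(6.0)
        assert bic == pytest.approx(3 * math.log(10))

    def test_hand_case(self):
        aic, bic = cp.information_criteria(5.0, 10, 2)
        base = 10 * math.log(0.5)
        assert aic == pytest.approx(base + 4)
        assert bic == pytest.approx(base + 2 * math.log(10))

    def test_parameter_penalty_is_monotone(self):
        aic2, bic2 = cp.information_criteria(5.0, 20, 2)
        aic3, bic3 = cp.information_criteria(5.0, 20, 3)
        assert aic3 > aic2 and bic3 > bic2

    def test_degenerate_counts_rejected(self):
        with pytest.raises(cp.DomainError):
            cp.information_criteria(5.0, 3, 3)


class TestFitPK:
    def test_noiseless_recovery_within_one_percent(self, ref_params, noiseless_table):
        fit = cp.fit_pk(noiseless_table)
        assert fit.converged
        assert fit.estimates["Vd_F"] == pytest.approx(1.81, rel=0.01)
        assert fit.estimates["ka"] == pytest.approx(1.49, rel=0.01)
        assert fit.estimates["ke"] == pytest.approx(4.59, rel=0.01)

    def test_scale_invariance_of_rate_constants(self, ref_params):
        t = np.array([5, 15, 30, 60, 90, 120]) / 60.0
        base = drug_table(np.tile(t, 2), np.repeat([50.0, 100.0], 6),
                          np.concatenate([cp.pk_concentration(t, d, ref_params.pk)
                                          for d in (50.0, 100.0)]))
        doubled = base.copy()
        doubled["dose_mg_per_kg"] *= 2
        doubled["value"] *= 2
        fit1, fit2 = cp.fit_pk(base), cp.fit_pk(doubled)
        assert fit2.estimates["ka"] == pytest.approx(fit1.estimates["ka"], rel=1e-4)
        assert fit2.estimates["ke"] == pytest.approx(fit1.estimates["ke"], rel=1e-4)

    def test_single_time_point_unidentifiable(self, ref_params):
        table = drug_table([0.5] * 4, [50.0] * 4, [3.0, 3.1, 2.9, 3.0])
        with pytest.raises(cp.IdentifiabilityError):
            cp.fit_pk(table)

    def test_refit_from_optimum_is_idempotent(self, noiseless_table):
        fit = cp.fit_pk(noiseless_table)
        refit = cp.fit_pk(noiseless_table, init=fit.estimates)
        for name, value in fit.estimates.items():
            assert refit.estimates[name] == pytest.approx(value, rel=1e-6)

    def test_duplicate_observations_leave_estimates_unchanged(self, ref_params):
        t = np.array([5, 15, 30, 60, 90, 120]) / 60.0
        c = cp.pk_concentration(t, 50.0, ref_params.pk)
        single = drug_table(t, [50.0] * 6, c)
        double = drug_table(np.tile(t, 2), [50.0] * 12, np.tile(c, 2))
        fit1, fit2 = cp.fit_pk(single), cp.fit_pk(double)
        for name in fit1.estimates:
            assert fit2.estimates[name] == pytest.approx(fit1.estimates[name], rel=1e-6)


class TestFitPD:
    def test_control_only_flags_ic50(self, ref_params, noiseless_table):
        """Without a treated group the drug-potency parameters are undetermined,
        but the turnover/stimulation parameters are still recovered."""
        control = noiseless_table[noiseless_table["group"].isin(["control", "healthy"])]
        truth = ref_params.to_dict()
        init = perturbed(truth, PD_PARAMETER_NAMES, factor=1.3)
        fit = cp.fit_pd(control, ref_params.pk, cp.baselines_from_table(noiseless_table),
                        init=init)
        assert set(fit.unidentifiable) == {"IC50_TNFa", "IC50_IFNg", "IC50_IL6"}
        for name in ("tau", "kout_TNFa", "kout_IFNg", "kout_IL6", "S_TNFa", "S_IFNg", "S_IL6"):
            assert fit.estimates[name] == pytest.approx(truth[name], rel=0.01), name
        assert all(n not in fit.estimates for n in fit.unidentifiable)

    def test_missing_baselines_rejected(self, ref_params, noiseless_table):
        with pytest.raises(cp.SchemaError):
            cp.fit_pd(noiseless_table, ref_params.pk, {"R0_TNFa": 10.0})


class TestFitDisease:
    def test_no_challenge_flags_stimulation(self, ref_params, noiseless_table):
        healthy_only = noiseless_table[noiseless_table["group"] == "healthy"]
        fit = cp.fit_disease(healthy_only, ref_params)
        assert set(fit.unidentifiable) == {
            "S_ALT_TNFa", "S_ALT_IFNg", "S_AST_TNFa", "S_AST_IFNg"}

    def test_alpha_beta_fixed_not_estimated(self, ref_params, noiseless_table):
        fit = cp.fit_disease(noiseless_table, ref_params,
                             init={"kout_ALT": 0.12, "kout_AST": 0.1})
        assert "alpha" in fit.fixed and "beta" in fit.fixed
        assert "alpha" not in fit.estimates and "beta" not in fit.estimates


class TestPrecision:
    def test_noiseless_cv_near_zero(self, noiseless_table):
        fit = cp.fit_pk(noiseless_table)
        for name, cv in fit.cv_percent.items():
            assert cv is not None and cv < 1e-2, name

    def test_cv_shrinks_with_replicates(self, ref_params):
        """Asymptotic CV% scales like 1/sqrt(n) in the replicate count."""
        t = np.array([5, 15, 30, 60, 90, 120]) / 60.0
        c = cp.pk_concentration(t, 50.0, ref_params.pk)
        rng = np.random.default_rng(11)
        cvs = {}
        for reps in (2, 8):
            times = np.tile(t, reps)
            values = np.tile(c, reps) * np.exp(rng.normal(0, 0.1, 6 * reps))
            fit = cp.fit_pk(drug_table(times, [50.0] * 6 * reps, values))
            cvs[reps] = fit.cv_percent["ka"]
        assert cvs[8] < cvs[2]
        assert cvs[8] == pytest.approx(cvs[2] / 2, rel=0.6)  # ~1/sqrt(4)

    def test_estimate_cv_matches_fit_reported(self, noiseless_table, ref_params):
        rng = np.random.default_rng(5)
        noisy = cp.generate_study(cp.StudyDesign(), ref_params, noise_cv=0.1, seed=9)
        fit = cp.fit_pk(noisy)
        recomputed = estimate_cv(fit)
        for name in fit.estimates:
            assert recomputed[name] == pytest.approx(fit.cv_percent[name], rel=0.05)


def test_fit_result_json_round_trip(tmp_path, noiseless_table):
    fit = cp.fit_pk(noiseless_table)
    path = tmp_path / "fit.json"
    fit.to_json(path)
    loaded = cp.FitResult.from_json(path)
    assert loaded.estimates == pytest.approx(fit.estimates)
    assert loaded.n_obs == fit.n_obs and loaded.converged == fit.converged
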