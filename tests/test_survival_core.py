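import numpy as np
import pytest

from survrp.survival_core import (
    ClinicalRecord,
    ConvergenceError,
    SurvivalDataset,
    breslow_cumulative_hazard,
    clean_clinical,
    cox_log_partial_likelihood,
    fit_cox_ph,
    martingale_residuals,
)
from survrp.synthetic_data import SyntheticSpec, generate_cohort


class TestCleanClinical:
    @pytest.mark.parametrize(
        "rec, kept, reason",
        [
            (ClinicalRecord("a", 100, 100, "deceased"), True, None),
            (ClinicalRecord("b", 100, 90, "deceased"), False, "day_mismatch"),
            (ClinicalRecord("c", None, None, "deceased"), False, "deceased_missing_days"),
            (ClinicalRecord("d", 50, None, "alive"), True, None),
            (ClinicalRecord("e", None, None, "alive"), False, "no_day_information"),
        ],
    )
    def test_keep_drop_rules(self, rec, kept, reason):
        kept_ids, dropped = clean_clinical([rec])
        if kept:
            assert kept_ids == [rec.sample_id] and not dropped
        else:
            assert not kept_ids and dropped == [(rec.sample_id, reason)]

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError, match="no clinical records"):
            clean_clinical([])


class TestBreslowHazard:
    def test_two_events_hand_computation(self, two_subject_constant):
        # beta = 0 (constant covariate): H0(1) = 1/2, H0(2) = 1/2 + 1 = 3/2
        data = two_subject_constant([1.0, 2.0], [1, 1])
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_cox_ph(data)
        assert fit.beta[0] == 0.0
        H0 = breslow_cumulative_hazard(fit, data)
        assert H0(1.0) == pytest.approx(0.5)
        assert H0(2.0) == pytest.approx(1.5)
        assert H0(0.5) == 0.0  # zero before the first event

    def test_single_subject_at_risk_gets_unit_increment(self, two_subject_constant):
        # B censored before A's event: risk set at t=1 is {A} alone -> H0(1)=1
        data = two_subject_constant([1.0, 0.5], [1, 0])
        with pytest.warns(UserWarning):
            fit = fit_cox_ph(data)
        assert fit.baseline_cumhaz(1.0) == pytest.approx(1.0)

    def test_nondecreasing_step_function(self, small_cohort):
        data, _ = small_cohort
        fit = fit_cox_ph(data, data.gene_names[:4])
        grid = np.linspace(0, data.time.max() * 1.2, 300)
        vals = fit.baseline_cumhaz(grid)
        assert np.all(np.diff(vals) >= 0)
        assert fit.baseline_cumhaz(0.0) == 0.0


class TestMartingaleResiduals:
    def test_event_and_censored_pair(self, two_subject_constant):
        # A event at t=1, B censored at t=2: H0(1)=H0(2)=1/2 -> (+0.5, -0.5)
        data = two_subject_constant([1.0, 2.0], [1, 0])
        with pytest.warns(UserWarning):
            fit = fit_cox_ph(data)
        res = martingale_residuals(fit, data)
        assert res == pytest.approx([0.5, -0.5])
        assert res.sum() == pytest.approx(0.0, abs=1e-12)

    def test_censored_before_first_event_has_zero_residual(self, two_subject_constant):
        data = two_subject_constant([2.0, 1.0], [1, 0])
        with pytest.warns(UserWarning):
            fit = fit_cox_ph(data)
        res = martingale_residuals(fit, data)
        assert res[1] == 0.0  # delta=0 and H0(1)=0

    def test_bounded_above_and_centered(self, small_cohort):
        data, _ = small_cohort
        for genes in (data.gene_names[:1], data.gene_names[:10]):
            fit = fit_cox_ph(data, genes)
            res = martingale_residuals(fit, data)
            assert np.all(res <= 1.0 + 1e-12)
            assert abs(res.sum()) < 1e-6 * data.n


class TestFitCoxPH:
    def test_all_censored_is_an_error(self):
        rng = np.random.default_rng(0)
        data = SurvivalDataset(
            [f"s{i}" for i in range(10)], np.arange(1.0, 11.0),
            np.zeros(10, int), rng.standard_normal((10, 2)), ["g1", "g2"],
        )
        with pytest.raises(ValueError, match="no events"):
            fit_cox_ph(data)

    def test_more_covariates_than_events_rejected(self):
        rng = np.random.default_rng(1)
        data = SurvivalDataset(
            [f"s{i}" for i in range(10)], np.arange(1.0, 11.0),
            np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0]),
            rng.standard_normal((10, 5)), [f"g{j}" for j in range(5)],
        )
        with pytest.raises(ValueError, match="covariates"):
            fit_cox_ph(data, data.gene_names[:4])  # 4 free params, 3 events

    def test_monotone_likelihood_raises_naming_covariate(self):
        n = 30
        t = np.arange(1.0, n + 1)
        X = (-t + 0.001 * np.random.default_rng(0).standard_normal(n))[:, None]
        data = SurvivalDataset([f"s{i}" for i in range(n)], t, np.ones(n, int), X, ["bad_gene"])
        with pytest.raises(ConvergenceError, match="bad_gene"):
            fit_cox_ph(data)

    def test_efron_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        data, _ = generate_cohort(SyntheticSpec(n=80, p=3, beta=(0.8, -0.4, 0.0), seed=5))
        fit = fit_cox_ph(data, ties="efron")
        df = pd.DataFrame(data.X, columns=data.gene_names)
        df["T"], df["E"] = data.time, data.status
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        assert fit.beta == pytest.approx(cph.params_.values, abs=1e-5)
        assert fit.log_partial_likelihood == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_parameter_recovery_known_coefficients(self):
        ok = 0
        for seed in range(10):
            data, truth = generate_cohort(
                SyntheticSpec(n=500, p=2, beta=(1.0, -0.5), block_rho=0.0, seed=seed)
            )
            fit = fit_cox_ph(data)
            ok += bool(np.all(np.abs(fit.beta - truth.beta_true) <= 3 * fit.se))
        assert ok >= 9

    def test_log_partial_likelihood_recorded_at_optimum(self, small_cohort):
        data, _ = small_cohort
        genes = data.gene_names[:3]
        fit = fit_cox_ph(data, genes)
        idx = data.gene_index(genes)
        ll = cox_log_partial_likelihood(fit.beta, data.X[:, idx], data.time, data.status)
        assert fit.log_partial_likelihood == pytest.approx(ll)
        # nudging beta never increases the partial likelihood
        for j in range(len(genes)):
            for d in (-0.05, 0.05):
                b = fit.beta.copy()
                b[j] += d
                assert cox_log_partial_likelihood(b, data.X[:, idx], data.time, data.status) <= ll + 1e-9
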