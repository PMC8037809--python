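"""QSAR model: prediction, MLR rebuild, elimination, cross-validation, AD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bbbperm import (
    InsufficientDataError,
    LogBBRegression,
    QSARSimSpec,
    TrainingTable,
    ValidationError,
    applicability_domain,
    backward_eliminate,
    cross_validate_lto,
    delta_logp,
    fit_mlr,
    predict_logbb,
    predict_logbb_biomimetic,
    published_model,
    simulate_qsar_table,
)
from bbbperm.qsar import QSARModel, best_subset_by_alpha
from bbbperm.retention import LinearFitResult, LogkwResult


class TestDeltaLogP:
    @pytest.mark.parametrize(
        "logpow,logpcw,expected",
        [(5.2, 4.029, 1.171), (-3.7, -24.704, 21.004), (1.5, 1.5, 0.0)],
    )
    def test_values(self, logpow, logpcw, expected):
        assert delta_logp(logpow, logpcw) == pytest.approx(expected, abs=1e-12)


class TestPredict:
    def test_published_coefficients(self):
        m = published_model()
        assert (m.intercept, m.coef_dlogp, m.coef_lipophilicity, m.coef_e) == (
            -0.114, -0.098, 0.278, 0.218,
        )

    def test_intercept_only_input(self):
        assert predict_logbb(published_model(), 0, 0, 0) == pytest.approx(-0.114, abs=1e-15)

    def test_unit_inputs(self):
        assert predict_logbb(published_model(), 1, 1, 1) == pytest.approx(0.284, abs=1e-12)

    def test_zero_model(self):
        assert predict_logbb(QSARModel(0, 0, 0, 0), 3.1, -2.2, 0.7) == 0.0

    @given(
        dlogp=st.floats(-25, 25), lip=st.floats(-10, 10), e=st.floats(0, 10),
    )
    def test_affine_map_matches_hand_arithmetic(self, dlogp, lip, e):
        got = predict_logbb(published_model(), dlogp, lip, e)
        expected = -0.114 - 0.098 * dlogp + 0.278 * lip + 0.218 * e
        assert got == pytest.approx(expected, abs=1e-12)


class TestBiomimeticSubstitution:
    def _logkw(self, value, system):
        fit = LinearFitResult(slope=-3.0, intercept=value, r_squared=1.0,
                              residual_sd=0.0, n_points=4)
        return LogkwResult("x", system, value, fit)

    def test_chol_substitution_value(self):
        out = predict_logbb_biomimetic(published_model(), 1.171, self._logkw(2.0, "CHOL"), 1.0)
        # -0.114 - 0.098*1.171 + 0.278*2.0 + 0.218*1.0
        assert out.value == pytest.approx(0.545242, abs=1e-12)
        assert out.label == "logBB-CHOL"

    def test_zero_logkw_drops_lipophilicity_term(self):
        out = predict_logbb_biomimetic(published_model(), 1.0, self._logkw(0.0, "BMC"), 2.0)
        assert out.value == pytest.approx(-0.114 - 0.098 + 0.436, abs=1e-12)

    def test_labels_differ_only_by_system(self):
        a = predict_logbb_biomimetic(published_model(), 1.0, self._logkw(1.5, "IAM"), 1.0)
        b = predict_logbb_biomimetic(published_model(), 1.0, self._logkw(1.5, "CHOL"), 1.0)
        assert a.value == b.value and a.label != b.label


class TestFitMLR:
    def test_noiseless_recovery_is_exact(self):
        table = simulate_qsar_table(QSARSimSpec(noise_sd=0.0, seed=11))
        m = fit_mlr(table)
        assert m.intercept == pytest.approx(-0.114, abs=1e-9)
        assert m.coef_dlogp == pytest.approx(-0.098, abs=1e-9)
        assert m.coef_lipophilicity == pytest.approx(0.278, abs=1e-9)
        assert m.coef_e == pytest.approx(0.218, abs=1e-9)
        assert m.diagnostics.r_squared == pytest.approx(100.0, abs=1e-9)
        assert m.diagnostics.r_squared_pred == pytest.approx(100.0, abs=1e-9)

    def test_constant_response_gives_flat_model(self):
        table = simulate_qsar_table(QSARSimSpec(noise_sd=0.0, beta_true=(0.7, 0, 0, 0), seed=2))
        m = fit_mlr(table)
        assert m.intercept == pytest.approx(0.7, abs=1e-9)
        for c in (m.coef_dlogp, m.coef_lipophilicity, m.coef_e):
            assert c == pytest.approx(0.0, abs=1e-9)

    def test_underdetermined_rejected(self):
        df = simulate_qsar_table(QSARSimSpec(seed=1)).data.iloc[:3].assign(split="train")
        with pytest.raises(InsufficientDataError):
            fit_mlr(TrainingTable(df))

    def test_missing_cells_rejected(self):
        df = simulate_qsar_table(QSARSimSpec(seed=1)).data.copy()
        df.loc[0, "e"] = np.nan
        with pytest.raises(ValidationError):
            TrainingTable(df)

    def test_results_summary_mentions_fit_quality(self):
        res = LogBBRegression(simulate_qsar_table(QSARSimSpec(seed=3))).fit()
        text = res.summary()
        assert "R²" in text and "n_train = 30" in text


class TestBackwardElimination:
    def test_noiseless_full_signal_removes_nothing(self):
        table = simulate_qsar_table(QSARSimSpec(noise_sd=0.0, seed=4))
        m_be = backward_eliminate(table, alpha=0.10)
        m_ols = fit_mlr(table)
        assert m_be.coef_dlogp == pytest.approx(m_ols.coef_dlogp, abs=1e-12)
        assert m_be.ad_state.columns == ("dlogp", "lipophilicity", "e")

    def test_planted_null_descriptor_removed(self):
        spec = QSARSimSpec(noise_sd=0.05, beta_true=(-0.114, 0.0, 0.278, 0.218), seed=8)
        m = backward_eliminate(simulate_qsar_table(spec), alpha=0.05)
        assert m.coef_dlogp == 0.0
        assert m.coef_lipophilicity != 0.0 and m.coef_e != 0.0

    def test_pure_noise_response_collapses_to_intercept(self):
        import warnings

        removed_all = 0
        n_seeds = 40
        for seed in range(n_seeds):
            spec = QSARSimSpec(noise_sd=1.0, beta_true=(0.2, 0.0, 0.0, 0.0), seed=seed)
            table = simulate_qsar_table(spec)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = backward_eliminate(table, alpha=0.10)
            if (m.coef_dlogp, m.coef_lipophilicity, m.coef_e) == (0.0, 0.0, 0.0):
                removed_all += 1
        assert removed_all > n_seeds / 2

    def test_matches_exhaustive_subset_oracle(self):
        """Greedy elimination lands on the same subset as the exhaustive
        all-significant oracle when signal and null descriptors separate."""
        for seed in range(10):
            spec = QSARSimSpec(noise_sd=0.05, beta_true=(-0.114, 0.0, 0.278, 0.218), seed=seed)
            table = simulate_qsar_table(spec)
            m = backward_eliminate(table, alpha=0.01)
            retained = tuple(
                p for p, c in zip(
                    ("dlogp", "lipophilicity", "e"),
                    (m.coef_dlogp, m.coef_lipophilicity, m.coef_e),
                )
                if c != 0.0
            )
            assert retained == best_subset_by_alpha(table, alpha=0.01)


class TestCrossValidation:
    def test_noiseless_data_gives_zero_press(self):
        table = simulate_qsar_table(QSARSimSpec(noise_sd=0.0, seed=5))
        rmsecv, r2cv, press = cross_validate_lto(table, seed=0)
        assert press == pytest.approx(0.0, abs=1e-18)
        assert rmsecv == pytest.approx(0.0, abs=1e-9)
        assert r2cv == pytest.approx(100.0, abs=1e-9)

    def test_thirty_rows_make_three_folds(self):
        table = simulate_qsar_table(QSARSimSpec(seed=6))
        assert table.n_train == 30
        # PRESS accounting: recompute fold-wise residuals independently
        rng = np.random.default_rng(123)
        order = rng.permutation(30)
        train = table.train.reset_index(drop=True)
        X = np.column_stack([np.ones(30), train[["dlogp", "lipophilicity", "e"]].to_numpy()])
        y = train["logbb"].to_numpy()
        press_manual = 0.0
        folds = [order[0:10], order[10:20], order[20:30]]
        assert sorted(len(f) for f in folds) == [10, 10, 10]
        for f in folds:
            mask = np.ones(30, bool)
            mask[f] = False
            beta, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
            press_manual += float(((y[f] - X[f] @ beta) ** 2).sum())
        _, _, press = cross_validate_lto(table, seed=123)
        assert press == pytest.approx(press_manual, rel=1e-12)

    def test_small_table_rejected(self):
        df = simulate_qsar_table(QSARSimSpec(seed=1)).data.iloc[:10].assign(split="train")
        with pytest.raises(InsufficientDataError):
            cross_validate_lto(TrainingTable(df), seed=0)

    def test_r2cv_below_r2_on_noisy_data(self):
        """Out-of-fold prediction cannot beat the training fit on average."""
        diffs = []
        for seed in range(20):
            table = simulate_qsar_table(QSARSimSpec(seed=seed))
            m = fit_mlr(table)
            _, r2cv, _ = cross_validate_lto(table, seed=seed)
            diffs.append(m.diagnostics.r_squared - r2cv)
        assert np.mean(diffs) > 0


class TestApplicabilityDomain:
    def test_leverage_identities(self):
        m = fit_mlr(simulate_qsar_table(QSARSimSpec(seed=9)))
        lev = m.ad_state.training_leverages
        p = len(m.ad_state.columns)
        assert lev.sum() == pytest.approx(p + 1, abs=1e-9)
        assert lev.mean() == pytest.approx((p + 1) / m.n_train, abs=1e-12)

    def test_centroid_is_inside_with_minimal_leverage(self):
        table = simulate_qsar_table(QSARSimSpec(seed=9))
        m = fit_mlr(table)
        train = table.train
        centroid = {c: train[c].mean() for c in ("dlogp", "lipophilicity", "e")}
        h, inside = applicability_domain(m, centroid)
        assert inside
        assert h == pytest.approx(1.0 / m.n_train, abs=1e-12)  # minimum possible

    def test_far_query_is_outside(self):
        table = simulate_qsar_table(QSARSimSpec(seed=9))
        m = fit_mlr(table)
        train = table.train
        far = {c: train[c].mean() + 10 * (train[c].max() - train[c].min())
               for c in ("dlogp", "lipophilicity", "e")}
        h, inside = applicability_domain(m, far)
        assert not inside and h > m.ad_state.leverage_threshold

    def test_missing_ad_state_directs_to_refit(self):
        with pytest.raises(Exception, match="refit"):
            applicability_domain(published_model(), {"dlogp": 1, "lipophilicity": 1, "e": 1})

    def test_hat_computation_matches_direct_formula(self):
        table = simulate_qsar_table(QSARSimSpec(seed=10))
        m = fit_mlr(table)
        train = table.train
        X = np.column_stack([np.ones(len(train)), train[["dlogp", "lipophilicity", "e"]].to_numpy()])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        np.testing.assert_allclose(m.ad_state.training_leverages, np.diag(H), atol=1e-10)
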