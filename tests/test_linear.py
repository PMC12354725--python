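"""Linear PTML models: fitting, selection, cross-validation, published
equations."""

import numpy as np
import pandas as pd
import pytest

from ptml.errors import ConfigError, ContractError, SingularityError
from ptml.linear import (
    expert_guided_selection,
    fit_mlr,
    forward_stepwise,
    leave_group_out_cv,
    loo_cv,
    predict,
    published_model,
)


def _toy_features(n=60, n_terms=4, seed=0):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        rng.normal(size=(n, n_terms)), columns=[f"t{i}" for i in range(n_terms)]
    )
    frame.insert(0, "reference", rng.normal(70, 10, size=n))
    frame.index = pd.Index([f"r{i}" for i in range(n)], name="reaction_id")
    return frame


class TestFitMlr:
    def test_recovers_noise_free_planted_coefficients(self):
        frame = _toy_features()
        y = 3.0 + 0.9 * frame["reference"] + 2.0 * frame["t0"] - 1.5 * frame["t2"]
        model, diag = fit_mlr(frame, y)
        assert model.a0 == pytest.approx(3.0, abs=1e-6)
        assert model.a1 == pytest.approx(0.9, abs=1e-6)
        assert model.b["t0"] == pytest.approx(2.0, abs=1e-6)
        assert model.b["t1"] == pytest.approx(0.0, abs=1e-6)
        assert model.b["t2"] == pytest.approx(-1.5, abs=1e-6)
        assert diag.rmse == pytest.approx(0.0, abs=1e-8)

    def test_self_reference_yields(self):
        frame = _toy_features()
        model, _ = fit_mlr(frame, frame["reference"])
        assert model.a1 == pytest.approx(1.0, abs=1e-8)
        assert model.a0 == pytest.approx(0.0, abs=1e-6)
        assert all(abs(c) < 1e-8 for c in model.b.values())

    def test_saturated_fit_interpolates(self):
        frame = _toy_features(n=3, n_terms=1)
        y = pd.Series([10.0, 20.0, 30.0], index=frame.index)
        model, diag = fit_mlr(frame, y)
        assert diag.residuals.abs().max() < 1e-8

    def test_rank_deficiency_lists_collinear_terms(self):
        frame = _toy_features()
        frame["t3"] = 2.0 * frame["t1"]
        with pytest.raises(SingularityError):
            fit_mlr(frame, frame["reference"])

    def test_residuals_orthogonal_to_design(self):
        frame = _toy_features(seed=4)
        rng = np.random.default_rng(1)
        y = 1.0 + 0.5 * frame["reference"] + rng.normal(0, 5, len(frame))
        model, diag = fit_mlr(frame, pd.Series(y, index=frame.index))
        X = np.column_stack([np.ones(len(frame)), frame.to_numpy()])
        dots = X.T @ diag.residuals.to_numpy()
        assert np.all(np.abs(dots) < 1e-8 * max(1.0, np.abs(X).max()) * len(frame))


class TestPredictPublished:
    def _row(self, model, reference=0.0, **terms):
        data = {"reference": [reference], **{t: [terms.get(t, 0.0)] for t in model.b}}
        return pd.DataFrame(data)

    def test_zero_perturbation_baseline(self):
        m6 = published_model("eq6")
        assert predict(m6, self._row(m6)).iloc[0] == pytest.approx(1.7555)
        m5 = published_model("eq5")
        assert predict(m5, self._row(m5)).iloc[0] == pytest.approx(2.0103)

    def test_reference_slope_span(self):
        m6 = published_model("eq6")
        d = predict(m6, self._row(m6, reference=1.0)) - predict(m6, self._row(m6))
        assert d.iloc[0] == pytest.approx(0.9731)

    def test_temperature_term_contribution(self):
        m6 = published_model("eq6")
        d = predict(m6, self._row(m6, dV30=1.0)) - predict(m6, self._row(m6))
        assert d.iloc[0] == pytest.approx(1.0987)

    def test_coefficient_counts_and_intercepts(self):
        m5, m6 = published_model("eq5"), published_model("eq6")
        assert len(m5.b) == len(m6.b) == 8
        assert m5.a0 == 2.0103 and m5.a1 == 0.9749
        assert m6.a0 == 1.7555 and m6.a1 == 0.9731
        assert list(m5.b) == list(m6.b)  # same printed term order
        with pytest.raises(ConfigError):
            published_model("eq9")

    def test_missing_column_is_a_contract_error(self):
        m6 = published_model("eq6")
        row = self._row(m6).drop(columns=["dV30"])
        with pytest.raises(ContractError, match="dV30"):
            predict(m6, row)


class TestForwardStepwise:
    def test_planted_signal_selected_first(self):
        frame = _toy_features(n=200, seed=2)
        rng = np.random.default_rng(3)
        y = 0.2 * frame["reference"] + 6.0 * frame["t2"] + rng.normal(0, 0.5, 200)
        selected = forward_stepwise(frame, pd.Series(y, index=frame.index))
        assert selected[0] == "t2"

    def test_pure_noise_with_strict_entry_selects_nothing(self):
        frame = _toy_features(n=120, seed=5)
        rng = np.random.default_rng(6)
        y = pd.Series(rng.normal(size=120), index=frame.index)
        assert forward_stepwise(frame, y, enter_p=1e-6) == []

    def test_max_steps_bounds_selection(self):
        frame = _toy_features(n=100, seed=7)
        rng = np.random.default_rng(8)
        y = pd.Series(
            frame.drop(columns="reference").sum(axis=1) + rng.normal(0, 0.1, 100),
            index=frame.index,
        )
        assert len(forward_stepwise(frame, y, max_steps=1)) <= 1

    def test_unbounded_entry_selects_all_and_matches_full_fit(self):
        frame = _toy_features(n=80, seed=9)
        rng = np.random.default_rng(10)
        y = pd.Series(rng.normal(70, 5, 80), index=frame.index)
        selected = forward_stepwise(frame, y, max_steps=4, enter_p=np.inf)
        assert sorted(selected) == ["t0", "t1", "t2", "t3"]
        m_sel, _ = fit_mlr(frame, y, terms=selected)
        m_all, _ = fit_mlr(frame, y)
        for t in m_all.b:
            assert m_sel.b[t] == pytest.approx(m_all.b[t], rel=1e-9, abs=1e-12)


class TestExpertGuidedSelection:
    @pytest.mark.parametrize(
        "base,forced,expected",
        [
            (["t1"], ["t2"], ["t1", "t2"]),
            (["t1", "t2"], ["t2"], ["t1", "t2"]),
            ([], ["t3", "t4"], ["t3", "t4"]),
        ],
    )
    def test_union_preserving_order(self, base, forced, expected):
        assert expert_guided_selection(base, forced) == expected

    def test_unknown_forced_term_rejected(self):
        with pytest.raises(ConfigError, match="ghost"):
            expert_guided_selection(["t1"], ["ghost"], known_terms=["t1", "t2"])


class TestCrossValidation:
    def test_loo_residuals_vanish_on_exact_linear_data(self):
        frame = _toy_features(n=20, n_terms=2, seed=11)
        y = 5.0 + 0.8 * frame["reference"] + 2.0 * frame["t0"]
        report = loo_cv(frame, y)
        assert report.residuals.abs().max() < 1e-6
        assert report.skipped == []

    def test_loo_flags_a_planted_outlier(self):
        frame = _toy_features(n=30, n_terms=2, seed=12)
        y = (5.0 + 0.8 * frame["reference"] + 2.0 * frame["t0"]).copy()
        y.iloc[13] += 60.0
        report = loo_cv(frame, y)
        assert report.relative_errors.idxmax() == frame.index[13]

    def test_loo_minimal_case_fits_every_fold(self):
        frame = _toy_features(n=3, n_terms=0, seed=13)
        y = pd.Series([10.0, 30.0, 50.0], index=frame.index)
        report = loo_cv(frame, y)
        assert report.predictions.notna().sum() == 3

    def test_leave_group_out_improves_fit_on_two_regime_data(self):
        frame = _toy_features(n=120, n_terms=2, seed=14)
        rng = np.random.default_rng(15)
        groups = pd.Series(
            ["odd" if i % 5 == 0 else "main" for i in range(120)], index=frame.index
        )
        y = 2.0 + 0.9 * frame["reference"] + 3.0 * frame["t0"] + rng.normal(0, 1, 120)
        # the "odd" group follows a different generating model
        y[groups == "odd"] = rng.normal(50, 30, int((groups == "odd").sum()))
        y = pd.Series(y, index=frame.index)
        _, full = fit_mlr(frame, y)
        reduced = leave_group_out_cv(frame, y, groups, "odd")
        assert reduced.diagnostics.R > full.R
        assert reduced.excluded == int((groups == "odd").sum())

    def test_excluding_an_absent_group_changes_nothing(self):
        frame = _toy_features(n=40, n_terms=2, seed=16)
        y = pd.Series(
            np.random.default_rng(17).normal(70, 8, 40), index=frame.index
        )
        groups = pd.Series(["g"] * 40, index=frame.index)
        full_model, _ = fit_mlr(frame, y)
        reduced = leave_group_out_cv(frame, y, groups, "nonexistent")
        assert reduced.excluded == 0
        assert reduced.model.a0 == pytest.approx(full_model.a0)
        assert reduced.model.b == pytest.approx(full_model.b)
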