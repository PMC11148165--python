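"""Dysbiosis-index prediction, feature selection, fitting, evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dysbiome.dysbiosis import (
    DysbiosisIndexModel,
    evaluate_accuracy,
    fit_mlr,
    predict,
    predict_table,
    select_features,
    stratified_split,
    top_taxa,
)
from dysbiome.io import load_paper_model

ALL_MODELS = [load_paper_model(c) for c in ("oral", "lung", "gut")]


def brute_force_probs(model, f):
    """Direct evaluation of the closed-form equations (no log-sum-exp)."""
    x = np.exp(model.b1[0] + model.b1[1:] @ f)
    y = np.exp(model.b2[0] + model.b2[1:] @ f)
    return np.array([1.0, x, y]) / (1.0 + x + y)


class TestPredict:
    def test_oral_model_zero_features(self):
        """All-zero features: X = e^3.639385, Y = e^15.535322 → Low."""
        m = load_paper_model("oral")
        pred = predict(m, np.zeros(len(m.feature_names)))
        x, y = np.exp(3.639385), np.exp(15.535322)
        assert pred.p_low == pytest.approx(y / (1 + x + y), abs=1e-12)
        assert pred.p_low > 0.9999
        assert pred.label == "Low"

    def test_lung_model_shannon_four(self):
        m = load_paper_model("lung")
        f = pd.Series(0.0, index=m.feature_names)
        f["ShannonIndex"] = 4.0
        pred = predict(m, f)
        assert pred.p_high == pytest.approx(0.839, abs=0.001)
        assert pred.label == "High"

    @pytest.mark.parametrize("model", ALL_MODELS, ids=lambda m: m.compartment)
    def test_matches_brute_force_on_random_inputs(self, model):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            f = rng.uniform(-5, 5, len(model.feature_names))
            if "ShannonIndex" in model.feature_names:
                f[model.feature_names.index("ShannonIndex")] = rng.uniform(0, 5)
            pred = predict(model, f)
            expected = brute_force_probs(model, f)
            np.testing.assert_allclose(
                [pred.p_high, pred.p_intermediate, pred.p_low], expected, atol=1e-12
            )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_probabilities_normalize(self, seed):
        rng = np.random.default_rng(seed)
        model = ALL_MODELS[seed % 3]
        f = rng.uniform(-5, 5, len(model.feature_names))
        pred = predict(model, f)
        assert pred.p_high + pred.p_intermediate + pred.p_low == pytest.approx(1.0, abs=1e-12)
        assert min(pred.p_high, pred.p_intermediate, pred.p_low) >= 0

    def test_overflow_safe(self):
        model = DysbiosisIndexModel(
            compartment="lung", feature_names=["f"], b1=[0.0, 500.0], b2=[0.0, 400.0]
        )
        pred = predict(model, np.array([3.0]))
        assert pred.p_intermediate == pytest.approx(1.0)
        assert np.isfinite(pred.p_low)

    def test_feature_order_free_when_named(self):
        m = load_paper_model("gut")
        f = pd.Series(np.linspace(-1, 1, len(m.feature_names)), index=m.feature_names)
        shuffled = f.sample(frac=1, random_state=4)
        a, b = predict(m, f), predict(m, shuffled)
        assert (a.p_high, a.p_low) == (b.p_high, b.p_low)

    def test_missing_feature_is_error_unless_flagged(self):
        m = load_paper_model("gut")
        partial = pd.Series({"Blautia": 1.0})
        with pytest.raises(KeyError, match="missing"):
            predict(m, partial)
        pred = predict(m, partial, fill_missing=True)
        assert np.isfinite(pred.p_low)

    def test_nan_feature_rejected(self):
        m = load_paper_model("oral")
        f = np.zeros(len(m.feature_names))
        f[0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            predict(m, f)

    def test_monotone_in_low_leaning_feature(self):
        """Raising a feature with b2 > b1 > 0 never decreases P(L)/P(H)."""
        model = DysbiosisIndexModel(
            compartment="lung", feature_names=["f"], b1=[0.1, 0.5], b2=[0.2, 1.5]
        )
        ratios = []
        for v in np.linspace(-3, 3, 13):
            p = predict(model, np.array([v]))
            ratios.append(p.p_low / p.p_high)
        assert np.all(np.diff(ratios) >= 0)


class TestStratifiedSplit:
    def test_reproducible_and_stratified(self):
        labels = np.array(["High"] * 50 + ["Intermediate"] * 30 + ["Low"] * 20)
        tr1, te1 = stratified_split(labels, 0.2, seed=5)
        tr2, te2 = stratified_split(labels, 0.2, seed=5)
        np.testing.assert_array_equal(te1, te2)
        assert len(te1) == 20
        counts = pd.Series(labels[te1]).value_counts()
        assert counts["High"] == 10 and counts["Low"] == 4
        assert set(tr1) | set(te1) == set(range(100))
        assert not set(tr1) & set(te1)


def _labeled_features(n=240, seed=0):
    """Three classes separated along two informative features, plus noise."""
    rng = np.random.default_rng(seed)
    labels = np.array(["High", "Intermediate", "Low"])[rng.integers(0, 3, n)]
    shift = {"High": 0.0, "Intermediate": 2.0, "Low": 4.0}
    informative = np.array([shift[c] for c in labels])
    X = pd.DataFrame(
        {
            "sep1": informative + rng.normal(0, 0.5, n),
            "sep2": -informative + rng.normal(0, 0.7, n),
            **{f"noise{j}": rng.normal(0, 1, n) for j in range(20)},
        }
    )
    return X, labels


class TestSelectFeatures:
    def test_separating_feature_always_kept_noise_dropped(self):
        X, labels = _labeled_features(seed=1)
        selected = select_features(X, labels, seed=2)
        assert "sep1" in selected
        noise_kept = [f for f in selected if f.startswith("noise")]
        assert len(noise_kept) <= 1  # each noise feature excluded w.h.p.

    def test_fixed_seed_deterministic(self):
        X, labels = _labeled_features(seed=3)
        assert select_features(X, labels, seed=4) == select_features(X, labels, seed=4)

    def test_degenerate_labels_rejected(self):
        X, _ = _labeled_features(seed=5)
        with pytest.raises(ValueError, match="degenerate"):
            select_features(X, np.array(["Low"] * len(X)), seed=0)

    def test_ci_test_alternative_finds_informative(self):
        X, labels = _labeled_features(seed=6)
        selected = select_features(X, labels, method="ci_tests", alpha=0.01)
        assert "sep1" in selected or "sep2" in selected
        assert len([f for f in selected if f.startswith("noise")]) <= 2


class TestFitMLR:
    def test_single_class_rejected(self):
        X = pd.DataFrame({"f": np.arange(30.0)})
        with pytest.raises(ValueError, match="three classes"):
            fit_mlr(X, np.array(["High"] * 30))

    def test_collinear_design_named(self):
        rng = np.random.default_rng(0)
        labels = np.array(["High", "Intermediate", "Low"] * 20)
        f = rng.normal(size=60)
        X = pd.DataFrame({"a": f, "b": 2 * f})
        with pytest.raises(ValueError, match="collinear.*'b'|collinear.*'a'"):
            fit_mlr(X, labels)

    def test_coefficient_recovery(self):
        """Simulate from known coefficients; estimates land within 3 Wald SE."""
        rng = np.random.default_rng(8)
        n = 2000
        f = rng.normal(0, 1, (n, 2))
        b1_true = np.array([0.5, 1.0, -0.5])
        b2_true = np.array([-0.5, -1.0, 1.5])
        eta1 = b1_true[0] + f @ b1_true[1:]
        eta2 = b2_true[0] + f @ b2_true[1:]
        denom = 1 + np.exp(eta1) + np.exp(eta2)
        u = rng.random(n)
        p_high, p_int = 1 / denom, np.exp(eta1) / denom
        labels = np.where(u < p_high, "High", np.where(u < p_high + p_int, "Intermediate", "Low"))
        X = pd.DataFrame(f, columns=["f1", "f2"])
        model = fit_mlr(X, labels)
        se_rough = 3 * 0.15  # generous Wald band at n=2000
        np.testing.assert_allclose(model.b1, b1_true, atol=se_rough)
        np.testing.assert_allclose(model.b2, b2_true, atol=se_rough)

    def test_uninformative_features_reproduce_class_frequencies(self):
        rng = np.random.default_rng(9)
        n = 600
        labels = np.array(["High"] * 300 + ["Intermediate"] * 200 + ["Low"] * 100)
        X = pd.DataFrame({"noise": rng.normal(0, 1, n) * 1e-8})
        model = fit_mlr(X, labels)
        pred = predict(model, np.array([0.0]))
        assert pred.p_high == pytest.approx(0.5, abs=0.02)
        assert pred.p_intermediate == pytest.approx(1 / 3, abs=0.02)
        assert pred.p_low == pytest.approx(1 / 6, abs=0.02)

    def test_separable_data_triggers_ridge_refit(self):
        labels = np.array(["High"] * 20 + ["Intermediate"] * 20 + ["Low"] * 20)
        X = pd.DataFrame({"f": np.r_[np.zeros(20), np.ones(20), 2 * np.ones(20)]
                          + np.linspace(0, 0.01, 60)})
        model = fit_mlr(X, labels)
        assert model.ridge_refit
        assert np.all(np.isfinite(model.b1)) and np.all(np.isfinite(model.b2))


class TestEvaluateAccuracy:
    def test_all_correct_and_all_wrong(self):
        model = DysbiosisIndexModel(
            compartment="lung", feature_names=["f"], b1=[0.0, 10.0], b2=[0.0, 20.0]
        )
        X = pd.DataFrame({"f": [-10.0, 10.0]}, index=["s1", "s2"])
        acc, ci, confusion = evaluate_accuracy(model, X, np.array(["High", "Low"]))
        assert acc == 1.0 and ci[1] == 1.0
        acc2, ci2, _ = evaluate_accuracy(model, X, np.array(["Low", "High"]))
        assert acc2 == 0.0 and ci2[0] == 0.0

    def test_empty_test_set_rejected(self):
        model = DysbiosisIndexModel(
            compartment="lung", feature_names=["f"], b1=[0.0, 1.0], b2=[0.0, 1.0]
        )
        with pytest.raises(ValueError, match="empty"):
            evaluate_accuracy(model, pd.DataFrame({"f": []}), np.array([]))


def test_top_taxa_ranked_by_mean_relative_abundance(separated_fixture):
    table, _, _ = separated_fixture
    top5 = top_taxa(table, n=5)
    mean_rel = table.relative_abundance().mean(axis=0)
    expected = [table.taxon_ids[j] for j in np.argsort(-mean_rel)[:5]]
    assert top5 == expected


def test_predict_table_labels_match_scalar_predict():
    m = load_paper_model("oral")
    rng = np.random.default_rng(2)
    X = pd.DataFrame(
        rng.uniform(-3, 3, (5, len(m.feature_names))),
        columns=m.feature_names,
        index=[f"s{i}" for i in range(5)],
    )
    frame = predict_table(m, X)
    for sid in X.index:
        assert frame.loc[sid, "label"] == predict(m, X.loc[sid]).label
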