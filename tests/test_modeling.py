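import numpy as np
import pandas as pd
import pytest

from dynrad.modeling import (
    SignatureModel,
    build_signature,
    compare_auc,
    delong_ci,
    delong_test,
    evaluate,
    f_test_screen,
    icc_2way_random_single,
    icc_filter,
    lasso_select,
    rank_auc,
    standardize,
)
from oracles import bf_auc


def _reader_frames(rng, n=40, p=12, noise=0.0):
    """Feature matrices for a two-reader repeat design with shared truth."""
    truth = rng.normal(0, 3, (n, p))
    mk = lambda s: pd.DataFrame(truth + rng.normal(0, s, (n, p)),
                                columns=[f"f{i}" for i in range(p)])
    return mk(noise if noise else 1e-9), mk(noise if noise else 0), mk(noise if noise else 0)


class TestICC:
    def test_perfect_repeat_gives_icc_one(self, rng):
        a = pd.DataFrame(rng.normal(0, 2, (20, 5)))
        table = icc_filter(a, a.copy(), a.copy(), threshold=0.8)
        np.testing.assert_allclose(table["intra_observer_icc"], 1.0, atol=1e-12)
        assert table["passed"].all()

    def test_independent_noise_fails(self, rng):
        n = 40
        cols = [f"f{i}" for i in range(8)]
        mk = lambda: pd.DataFrame(rng.normal(0, 1, (n, 8)), columns=cols)
        table = icc_filter(mk(), mk(), mk())
        assert np.abs(table["intra_observer_icc"]).max() < 0.6
        assert not table["passed"].any()

    def test_matches_pingouin_two_way_random_single(self, rng):
        pg = pytest.importorskip("pingouin")
        scores = rng.normal(0, 1, (15, 2)) + rng.normal(0, 2, (15, 1))
        ours = icc_2way_random_single(scores)[0]
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(15), 2),
            "rater": np.tile([0, 1], 15),
            "score": scores.ravel(),
        })
        ref = pg.intraclass_corr(df, "subject", "rater", "score")
        # absolute-agreement single-rater ICC: labelled ICC2 or ICC(A,1)
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = ref.loc[mask, "ICC"].iloc[0]
        assert ours == pytest.approx(icc2, abs=1e-10)

    def test_zero_between_subject_variance_fails(self):
        a = pd.DataFrame(np.ones((10, 3)))
        table = icc_filter(a, a.copy(), a.copy())
        assert not table["passed"].any()


class TestStandardize:
    def test_training_columns_zero_mean_unit_sd(self, rng):
        tr = pd.DataFrame(rng.normal(5, 3, (30, 4)))
        out = standardize(tr, tr)
        np.testing.assert_allclose(out.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(ddof=0), 1.0, atol=1e-12)

    def test_validation_not_recentred(self, rng):
        tr = pd.DataFrame(rng.normal(0, 1, (50, 3)))
        va = pd.DataFrame(rng.normal(2, 1, (50, 3)))
        out = standardize(tr, va)
        assert np.all(out.mean() > 1.0)  # shifted cohort stays shifted

    def test_constant_training_columns_dropped(self, rng):
        tr = pd.DataFrame({"a": rng.normal(0, 1, 20), "b": np.ones(20)})
        with pytest.warns(UserWarning, match="constant"):
            out = standardize(tr, tr)
        assert list(out.columns) == ["a"]


class TestFScreen:
    def test_uninformative_feature_dropped_informative_kept(self, rng):
        n = 60
        y = np.array([0, 1] * (n // 2))
        X = pd.DataFrame({
            "null": rng.normal(0, 1, n),
            "signal": y * 3.0 + rng.normal(0, 0.5, n),
            "flat": np.zeros(n),
        })
        kept = f_test_screen(X, y)
        assert "signal" in kept and "null" not in kept and "flat" not in kept

    def test_requires_two_per_class(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            f_test_screen(X, np.array([0, 0, 1]))


class TestLasso:
    def test_recovers_single_predictive_feature(self, rng):
        n = 300
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(rng.normal(0, 1, (n, 10)),
                         columns=[f"noise{i}" for i in range(10)])
        X["signal"] = y + rng.normal(0, 0.3, n)
        Z = standardize(X, X)
        sel = lasso_select(Z, y, cv_folds=3, cv_repeats=2, seed=0)
        assert "signal" in sel

    def test_deterministic_under_seed(self, rng):
        n = 120
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(rng.normal(0, 1, (n, 15)))
        X.columns = [f"f{i}" for i in range(15)]
        X["f0"] += y
        Z = standardize(X, X)
        assert lasso_select(Z, y, 3, 2, seed=5) == lasso_select(Z, y, 3, 2, seed=5)


class TestAUC:
    def test_perfect_scores(self):
        y = np.array([0, 1, 0, 1])
        assert rank_auc(y, y.astype(float)) == 1.0

    def test_toy_list_matches_pair_counting(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.4, 0.35, 0.8])
        assert rank_auc(y, s) == pytest.approx(bf_auc(y, s))
        assert rank_auc(y, s) == pytest.approx(0.75)

    def test_matches_pair_counting_with_ties(self, rng):
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        s = rng.integers(0, 5, 30).astype(float)  # heavy ties
        assert rank_auc(y, s) == pytest.approx(bf_auc(y, s), abs=1e-12)

    def test_random_scores_near_half(self, rng):
        y = rng.integers(0, 2, 2000)
        s = rng.normal(0, 1, 2000)
        assert rank_auc(y, s) == pytest.approx(0.5, abs=0.03)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            rank_auc(np.zeros(5, dtype=int), np.arange(5.0))

    def test_delong_ci_brackets_auc(self, rng):
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        s = y + rng.normal(0, 1, 200)
        auc, lo, hi = delong_ci(y, s)
        assert lo < auc < hi
        assert 0 <= lo and hi <= 1


class TestCompareAUC:
    def test_identical_scores_p_one(self, rng):
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.normal(0, 1, 50)
        assert compare_auc(s, s, y) == 1.0

    def test_antisymmetric_z(self, rng):
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        a, b = y + rng.normal(0, 1, 80), rng.normal(0, 1, 80)
        z1, _ = delong_test(a, b, y)
        z2, _ = delong_test(b, a, y)
        assert z1 == pytest.approx(-z2, rel=1e-12)

    def test_detects_informative_vs_noise(self, rng):
        y = rng.integers(0, 2, 500)
        y[:2] = [0, 1]
        informative = y + rng.normal(0, 0.7, 500)
        noise = rng.normal(0, 1, 500)
        assert compare_auc(informative, noise, y) < 0.05


class TestSignature:
    def _toy(self, rng, n=150, p=20):
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(rng.normal(0, 1, (n, p)),
                         columns=[f"f{i}" for i in range(p)])
        X["f0"] += 1.5 * y
        X["f1"] -= 1.0 * y
        return X, y

    def test_build_and_evaluate(self, rng):
        X, y = self._toy(rng)
        model = build_signature(X, y, "SR", cv_folds=3, cv_repeats=2, seed=1)
        assert {"f0", "f1"} & set(model.feature_names)
        rep = evaluate(model, X, y)
        assert rep.auc > 0.8
        assert 0 < model.threshold < 1
        assert rep.roc["tpr"].is_monotonic_increasing

    def test_json_roundtrip(self, rng, tmp_path):
        X, y = self._toy(rng)
        model = build_signature(X, y, "DR", cv_folds=3, cv_repeats=2, seed=1)
        model.to_json(tmp_path / "m.json")
        clone = SignatureModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(model.predict_proba(X), clone.predict_proba(X))

    def test_nan_inputs_handled_by_training_medians(self, rng):
        X, y = self._toy(rng)
        X.iloc[::7, 0] = np.nan
        model = build_signature(X, y, "SR", cv_folds=3, cv_repeats=2, seed=1)
        assert np.isfinite(model.predict_proba(X)).all()

    def test_transform_independent_of_validation_labels(self, rng):
        X, y = self._toy(rng)
        model = build_signature(X, y, "SR", cv_folds=3, cv_repeats=2, seed=1)
        Xv = pd.DataFrame(rng.normal(0, 1, (30, 20)), columns=X.columns)
        np.testing.assert_array_equal(model.transform(Xv), model.transform(Xv))
        # the frozen transform uses no labels at all by construction
        assert set(model.provenance) >= {"alpha", "seed"}
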