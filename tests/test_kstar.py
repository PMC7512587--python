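import numpy as np
import pandas as pd
import pytest

from kstable.errors import KStarError
from kstable.kstar import (
    KStarClassifier,
    KStarConfig,
    effective_count,
    numeric_scale_solve,
    symbolic_transform_prob,
)

from .conftest import mixed_matrix, numeric_matrix


class TestSymbolicTransformProb:
    FREQS = {chr(65 + i): 0.05 for i in range(20)}  # uniform over 20 symbols

    def test_s_zero_is_identity(self):
        assert symbolic_transform_prob("A", "A", 0.0, self.FREQS) == 1.0
        assert symbolic_transform_prob("A", "B", 0.0, self.FREQS) == 0.0

    def test_s_one_is_memoryless(self):
        assert symbolic_transform_prob("A", "B", 1.0, self.FREQS) == pytest.approx(0.05)
        assert symbolic_transform_prob("A", "A", 1.0, self.FREQS) == pytest.approx(0.05)

    def test_half_stop_hand_values_and_normalization(self):
        assert symbolic_transform_prob("A", "A", 0.5, self.FREQS) == pytest.approx(0.525)
        assert symbolic_transform_prob("A", "B", 0.5, self.FREQS) == pytest.approx(0.025)
        total = sum(symbolic_transform_prob("A", b, 0.5, self.FREQS)
                    for b in self.FREQS)
        assert total == pytest.approx(1.0)

    def test_invalid_s(self):
        with pytest.raises(KStarError):
            symbolic_transform_prob("A", "B", 1.5, self.FREQS)


class TestNumericScaleSolve:
    def test_blend_zero_concentrates_on_nearest(self):
        t = np.array([0.0, 1.0, 2.0, 5.0])
        x0 = numeric_scale_solve(0.1, t, blend=0.0)
        w = np.exp(-np.abs(t - 0.1) / x0)
        assert effective_count(w) == pytest.approx(1.0, abs=1e-3)

    def test_blend_hundred_is_uniform(self):
        t = np.array([0.0, 1.0, 2.0, 5.0])
        x0 = numeric_scale_solve(0.1, t, blend=100.0)
        w = np.exp(-np.abs(t - 0.1) / x0)
        assert effective_count(w) == pytest.approx(4.0, abs=1e-3)

    @pytest.mark.parametrize("blend", [10.0, 50.0, 90.0])
    def test_plug_back_reproduces_target_count(self, blend):
        t = np.array([0.3, -1.2, 0.8, 2.5, 0.31])
        x0 = numeric_scale_solve(0.0, t, blend=blend, tol=1e-8)
        w = np.exp(-np.abs(t) / x0)
        d = np.abs(t)
        n_lo = float((d == d.min()).sum())
        target = n_lo + (blend / 100.0) * (len(t) - n_lo)
        assert effective_count(w) == pytest.approx(target, abs=1e-4)

    def test_all_equal_training_values(self):
        assert numeric_scale_solve(1.0, [2.0, 2.0, 2.0], blend=50.0) > 0

    def test_empty_training_rejected(self):
        with pytest.raises(KStarError):
            numeric_scale_solve(0.0, [], blend=20.0)


def _training(seed=0, n=30):
    rng = np.random.default_rng(seed)
    y = np.where(rng.random(n) < 0.3, "positive", "negative")
    x = np.where(y == "positive", 3.0, -3.0) + rng.normal(0, 0.5, n)
    z = rng.normal(size=n)
    return numeric_matrix({"x": x, "z": z}, y)


class TestFitPredict:
    def test_lazy_fit_stores_instances(self):
        m = _training(n=10)
        clf = KStarClassifier().fit(m)
        assert clf.n_instances == 10
        assert clf.classes_ == ("negative", "positive")

    def test_empty_matrix_rejected(self):
        m = _training(n=5).take([])
        with pytest.raises(KStarError):
            KStarClassifier().fit(m)

    def test_refit_is_deterministic(self):
        m = _training()
        q = m.frame.iloc[:5]
        p1 = KStarClassifier().fit(m).predict_proba(q)
        p2 = KStarClassifier().fit(m).predict_proba(q)
        pd.testing.assert_frame_equal(p1, p2)

    def test_single_class_always_predicted(self):
        m = numeric_matrix({"x": [0.0, 1.0, 2.0]}, ["positive"] * 3)
        clf = KStarClassifier().fit(m)
        assert (clf.predict(pd.DataFrame({"x": [5.0, -5.0]})) == "positive").all()

    def test_single_training_instance_identical_to_query(self):
        m = numeric_matrix({"x": [1.5]}, ["positive"])
        p = KStarClassifier().fit(m).predict_proba(pd.DataFrame({"x": [1.5]}))
        assert p["positive"].iloc[0] == pytest.approx(1.0)

    def test_mirror_symmetric_instances_split_evenly(self):
        m = numeric_matrix({"x": [-1.0, 1.0], "z": [2.0, -2.0]},
                           ["positive", "negative"])
        p = KStarClassifier().fit(m).predict_proba(
            pd.DataFrame({"x": [0.0], "z": [0.0]}))
        assert p.iloc[0].tolist() == pytest.approx([0.5, 0.5])

    def test_probabilities_sum_to_one(self):
        m = _training(seed=3)
        p = KStarClassifier().fit(m).predict_proba(m.frame.iloc[:8]).to_numpy()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert (p >= 0).all()

    def test_invariant_to_training_row_order(self):
        m = _training(seed=4)
        perm = np.random.default_rng(0).permutation(len(m))
        q = pd.DataFrame({"x": [0.2, -0.7], "z": [0.1, 1.0]})
        p1 = KStarClassifier().fit(m).predict_proba(q).to_numpy()
        p2 = KStarClassifier().fit(m.take(perm)).predict_proba(q).to_numpy()
        np.testing.assert_allclose(p1, p2, atol=1e-9)

    def test_schema_mismatch_rejected(self):
        clf = KStarClassifier().fit(_training())
        with pytest.raises(KStarError, match="schema"):
            clf.predict_proba(pd.DataFrame({"x": [0.0]}))

    def test_mixed_symbolic_features_supported(self):
        m = mixed_matrix({"x": [0.0, 1.0, 2.0, 3.0]},
                         {"aa": ["A", "A", "G", "G"]},
                         ["positive", "positive", "negative", "negative"])
        clf = KStarClassifier().fit(m)
        q = pd.DataFrame({"x": [0.5], "aa": np.array(["A"], dtype=object)})
        p = clf.predict_proba(q)
        assert p["positive"].iloc[0] > 0.5


class TestBlendLimits:
    def test_blend_100_returns_class_priors(self):
        m = _training(seed=5, n=40)
        clf = KStarClassifier(KStarConfig(blend=100.0)).fit(m)
        p = clf.predict_proba(m.frame.iloc[:6]).to_numpy()
        priors = np.array([np.mean(m.target == c) for c in clf.classes_])
        kl = np.sum(priors * np.log(priors / p), axis=1)
        assert np.abs(kl).max() < 1e-6

    def test_blend_0_is_nearest_neighbour(self):
        m = numeric_matrix({"x": [0.0, 10.0]}, ["negative", "positive"])
        clf = KStarClassifier(KStarConfig(blend=0.0)).fit(m)
        p = clf.predict_proba(pd.DataFrame({"x": [9.0]}))
        assert p["positive"].iloc[0] == pytest.approx(1.0)

    def test_kl_to_priors_shrinks_as_blend_grows(self):
        m = _training(seed=6, n=40)
        q = m.frame.iloc[:10]
        priors = None
        kls = []
        for blend in (20.0, 60.0, 95.0):
            clf = KStarClassifier(KStarConfig(blend=blend)).fit(m)
            p = clf.predict_proba(q).to_numpy()
            priors = np.array([np.mean(m.target == c) for c in clf.classes_])
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(priors > 0, priors * np.log(priors / p), 0.0)
            kls.append(float(np.mean(terms.sum(axis=1))))
        assert kls[0] > kls[1] > kls[2] >= 0


class TestPredictTieRule:
    def test_exact_tie_goes_to_negative(self):
        m = numeric_matrix({"x": [-1.0, 1.0]}, ["positive", "negative"])
        clf = KStarClassifier().fit(m)
        assert clf.predict(pd.DataFrame({"x": [0.0]}))[0] == "negative"

    def test_clear_majority_wins(self):
        m = numeric_matrix({"x": [0.0, 5.0]}, ["positive", "negative"])
        assert KStarClassifier().fit(m).predict(
            pd.DataFrame({"x": [0.4]}))[0] == "positive"


class TestLeaveOneOutSmoke:
    def test_wide_margin_data_classified_reliably(self):
        rng = np.random.default_rng(7)
        n = 30
        y = np.array(["positive"] * 15 + ["negative"] * 15, dtype=object)
        x = np.where(y == "positive", 5.0, -5.0) + rng.normal(0, 0.3, n)
        z = rng.normal(size=n)
        m = numeric_matrix({"x": x, "z": z}, y)
        correct = 0
        for i in range(n):
            rest = [j for j in range(n) if j != i]
            clf = KStarClassifier(KStarConfig(blend=20.0)).fit(m.take(rest))
            correct += clf.predict(m.frame.iloc[[i]])[0] == y[i]
        assert correct / n >= 0.95


class TestPersistence:
    def test_save_load_reproduces_predictions(self, tmp_path):
        m = mixed_matrix({"x": [0.1, 1.7, -0.3, 2.2]},
                         {"aa": ["A", "G", "A", "L"]},
                         ["positive", "negative", "positive", "negative"])
        clf = KStarClassifier(KStarConfig(blend=35.0)).fit(m)
        q = pd.DataFrame({"x": [0.5, 2.0],
                          "aa": np.array(["G", "A"], dtype=object)})
        before = clf.predict_proba(q)
        path = tmp_path / "model.json"
        clf.save(path)
        after = KStarClassifier.load(path).predict_proba(q)
        pd.testing.assert_frame_equal(before, after)
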