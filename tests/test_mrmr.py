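import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kstable.errors import KStableError
from kstable.mrmr import (
    DiscretizationScheme,
    chi2_statistic,
    chisquared_rank,
    discretize,
    entropy_bits,
    infogain_rank,
    mrmr_rank,
    mrmr_score,
    mutual_information,
    redundancy,
    relevance,
)

from .conftest import numeric_matrix


def mi_brute(x, y) -> float:
    """Exhaustive joint-table plug-in MI (independent oracle)."""
    x, y = list(x), list(y)
    n = len(x)
    total = 0.0
    for vx in set(x):
        for vy in set(y):
            pxy = sum(1 for a, b in zip(x, y) if a == vx and b == vy) / n
            if pxy == 0:
                continue
            px = x.count(vx) / n
            py = y.count(vy) / n
            total += pxy * math.log2(pxy / (px * py))
    return total


class TestDiscretize:
    def test_constant_vector_is_middle_state(self):
        assert (discretize([5.0] * 7) == 1).all()

    def test_three_point_spread(self):
        # mu = 0, sigma = sqrt(200/3) < 10: each value lands in its own state.
        assert discretize([-10.0, 0.0, 10.0]).tolist() == [0, 1, 2]

    def test_symbolic_passthrough(self):
        x = np.array(["A", "G", "A"], dtype=object)
        assert (discretize(x) == x).all()

    def test_equal_frequency_bins(self):
        states = discretize(np.arange(12.0),
                            DiscretizationScheme("equal_frequency", bins=3))
        assert sorted(np.bincount(states)) == [4, 4, 4]

    def test_invalid_bins(self):
        with pytest.raises(KStableError):
            DiscretizationScheme(bins=1)


class TestMutualInformation:
    def test_identical_balanced_binary_is_one_bit(self):
        x = [0, 1] * 6
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_constant_is_zero(self):
        assert mutual_information([1] * 8, [0, 1] * 4) == pytest.approx(0.0)

    def test_length_mismatch(self):
        with pytest.raises(KStableError):
            mutual_information([0, 1], [0, 1, 2])

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_joint_table(self, data):
        n = data.draw(st.integers(2, 12))
        x = data.draw(st.lists(st.integers(0, 2), min_size=n, max_size=n))
        y = data.draw(st.lists(st.integers(0, 2), min_size=n, max_size=n))
        assert mutual_information(x, y) == pytest.approx(mi_brute(x, y), abs=1e-9)
        assert mutual_information(x, y) == pytest.approx(
            mutual_information(y, x), abs=1e-12)

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_bounded_by_marginal_entropies(self, data):
        n = data.draw(st.integers(2, 15))
        x = data.draw(st.lists(st.integers(0, 3), min_size=n, max_size=n))
        y = data.draw(st.lists(st.integers(0, 3), min_size=n, max_size=n))
        mi = mutual_information(x, y)
        assert -1e-12 <= mi <= min(entropy_bits(x), entropy_bits(y)) + 1e-9


class TestSetLevelQuantities:
    def test_relevance_is_mean_mi(self):
        t = [0, 1, 0, 1]
        f1, f2 = [0, 1, 0, 1], [0, 0, 1, 1]
        expected = (mutual_information(f1, t) + mutual_information(f2, t)) / 2
        assert relevance([f1, f2], t) == pytest.approx(expected)

    def test_relevance_empty_set_errors(self):
        with pytest.raises(KStableError):
            relevance([], [0, 1])

    def test_redundancy_singleton_is_entropy(self):
        f = [0, 0, 1, 1]
        assert redundancy([f]) == pytest.approx(entropy_bits(f))

    def test_redundancy_two_independent_balanced(self):
        # 4-term sum: 2 self-informations of 1 bit + 2 zero cross terms, / 4.
        f1, f2 = [0, 0, 1, 1], [0, 1, 0, 1]
        assert redundancy([f1, f2]) == pytest.approx(0.5)

    def test_redundancy_duplicated_pair(self):
        f = [0, 0, 1, 1]
        assert redundancy([f, f]) == pytest.approx(entropy_bits(f))

    @pytest.mark.parametrize(
        "D,R,expected", [(0.6, 0.3, 2.0), (0.0, 0.5, 0.0), (0.4, 0.0, math.inf)]
    )
    def test_quotient_score(self, D, R, expected):
        assert mrmr_score(D, R) == expected


def brute_force_greedy(cols: dict, target, n: int) -> list[str]:
    """Step-by-step recomputation of every candidate's quotient (oracle)."""
    rel = {nm: mi_brute(list(c), list(target)) for nm, c in cols.items()}
    selected: list[str] = []
    while len(selected) < n:
        scored = []
        for nm in cols:
            if nm in selected:
                continue
            if not selected:
                mean_red = 0.0
            else:
                mean_red = np.mean(
                    [mi_brute(list(cols[nm]), list(cols[s])) for s in selected]
                )
            score = math.inf if mean_red == 0 else rel[nm] / mean_red
            scored.append((-score, -rel[nm], nm))
        scored.sort()
        selected.append(scored[0][2])
    return selected


class TestMrmrRank:
    def _matrix(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        y = np.where(rng.random(n) < 0.5, "positive", "negative")
        signal = np.where(y == "positive", 1.0, -1.0) + rng.normal(0, 0.1, n)
        cols = {"signal": signal}
        for i in range(4):
            cols[f"noise{i}"] = rng.normal(size=n)
        return numeric_matrix(cols, y)

    def test_planted_feature_ranked_first(self):
        r = mrmr_rank(self._matrix(), n=3)
        assert r.names[0] == "signal"

    def test_n1_equals_argmax_relevance(self):
        m = self._matrix(seed=1)
        assert mrmr_rank(m, 1).names == infogain_rank(m, 1).names

    def test_column_order_invariance(self):
        m = self._matrix(seed=2)
        shuffled = m.select(tuple(reversed(m.feature_names)))
        assert mrmr_rank(m, 5).names == mrmr_rank(shuffled, 5).names

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_greedy_trace_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        y = np.where(rng.random(n) < 0.5, "positive", "negative")
        cols = {f"f{i}": rng.integers(0, 3, size=n) for i in range(6)}
        cols["f0"] = np.where(y == "positive", 2, 0) + rng.integers(0, 2, n)
        m = numeric_matrix({k: v.astype(float) for k, v in cols.items()}, y)
        # Discretize identically for the oracle (mean-sigma on the same data).
        disc = {k: tuple(discretize(v.astype(float))) for k, v in cols.items()}
        expected = brute_force_greedy(disc, tuple(y), 6)
        assert list(mrmr_rank(m, 6).names) == expected

    def test_invalid_n(self):
        with pytest.raises(KStableError):
            mrmr_rank(self._matrix(), n=0)
        with pytest.raises(KStableError):
            mrmr_rank(self._matrix(), n=99)


class TestBaselineRankers:
    def test_label_copy_tops_both(self):
        rng = np.random.default_rng(3)
        n = 50
        y = np.where(rng.random(n) < 0.4, "positive", "negative")
        cols = {"copy": np.where(y == "positive", 10.0, -10.0),
                "noise": rng.normal(size=n)}
        m = numeric_matrix(cols, y)
        assert infogain_rank(m, 2).names[0] == "copy"
        assert chisquared_rank(m, 2).names[0] == "copy"

    def test_chi2_balanced_independence_is_zero(self):
        x = ["a"] * 50 + ["b"] * 50
        y = (["p"] * 25 + ["n"] * 25) * 2
        assert chi2_statistic(x, y) == pytest.approx(0.0)

    def test_chi2_matches_hand_formula(self):
        # 2x2 table: [[30, 10], [20, 40]]; expected under independence and
        # sum (O-E)^2/E computed by hand.
        x = ["a"] * 40 + ["b"] * 60
        y = ["p"] * 30 + ["n"] * 10 + ["p"] * 20 + ["n"] * 40
        obs = np.array([[10.0, 30.0], [40.0, 20.0]])
        total = obs.sum()
        exp = np.outer(obs.sum(1), obs.sum(0)) / total
        hand = ((obs - exp) ** 2 / exp).sum()
        assert chi2_statistic(x, y) == pytest.approx(hand)

    def test_mrmr_first_equals_infogain_first(self):
        rng = np.random.default_rng(9)
        n = 40
        y = np.where(rng.random(n) < 0.5, "positive", "negative")
        cols = {f"f{i}": rng.normal(size=n) for i in range(5)}
        m = numeric_matrix(cols, y)
        assert mrmr_rank(m, 3).names[0] == infogain_rank(m, 1).names[0]


def test_ranking_tsv_serialization(tmp_path):
    rng = np.random.default_rng(5)
    y = np.where(rng.random(30) < 0.5, "positive", "negative")
    m = numeric_matrix({"a": rng.normal(size=30), "b": rng.normal(size=30)}, y)
    r = mrmr_rank(m, 2)
    buf = io.StringIO()
    r.to_tsv(buf)
    lines = buf.getvalue().strip().split("\n")
    assert lines[0].split("\t") == ["rank", "feature", "relevance_bits",
                                    "redundancy_bits", "score"]
    assert len(lines) == 3
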