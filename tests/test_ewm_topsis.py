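import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wneval import ewm_topsis
from wneval.trial_data import IndicatorTable


def make_table(values, directions=None, columns=None) -> IndicatorTable:
    df = pd.DataFrame(values, columns=columns)
    df.index = [f"o{i}" for i in range(len(df))]
    if directions is None:
        directions = {c: "benefit" for c in df.columns}
    return IndicatorTable(df, directions)


def brute_force_evaluate(x, directions, variant="weights-linear"):
    """Loop-based oracle written straight from the scoring equations."""
    m, n = len(x), len(x[0])
    z = [[0.0] * n for _ in range(m)]
    for j in range(n):
        col = [x[i][j] for i in range(m)]
        lo, hi = min(col), max(col)
        for i in range(m):
            if directions[j] == "benefit":
                z[i][j] = (x[i][j] - lo) / (hi - lo)
            else:
                z[i][j] = (hi - x[i][j]) / (hi - lo)
    e = []
    for j in range(n):
        s = sum(z[i][j] for i in range(m))
        acc = 0.0
        for i in range(m):
            p = z[i][j] / s
            if p > 0:
                acc += p * math.log(p)
        e.append(-acc / math.log(m))
    util = [1 - ej for ej in e]
    w = [u / sum(util) for u in util]
    zp = [max(z[i][j] for i in range(m)) for j in range(n)]
    zm = [min(z[i][j] for i in range(m)) for j in range(n)]
    dp, dm = [], []
    for i in range(m):
        if variant == "weights-linear":
            dp.append(math.sqrt(sum(w[j] * (z[i][j] - zp[j]) ** 2 for j in range(n))))
            dm.append(math.sqrt(sum(w[j] * (z[i][j] - zm[j]) ** 2 for j in range(n))))
        else:
            dp.append(math.sqrt(sum((w[j] * z[i][j] - w[j] * zp[j]) ** 2 for j in range(n))))
            dm.append(math.sqrt(sum((w[j] * z[i][j] - w[j] * zm[j]) ** 2 for j in range(n))))
    T = [dm[i] / (dm[i] + dp[i]) for i in range(m)]
    return e, w, dp, dm, T


class TestStandardize:
    def test_benefit_column(self):
        t = make_table({"A": [2.0, 4, 6]})
        z = ewm_topsis.standardize(t).z
        assert z["A"].tolist() == [0.0, 0.5, 1.0]

    def test_cost_column(self):
        t = make_table({"A": [2.0, 4, 6]}, {"A": "cost"})
        z = ewm_topsis.standardize(t).z
        assert z["A"].tolist() == [1.0, 0.5, 0.0]

    def test_constant_column_errors_by_default(self):
        t = make_table({"A": [5.0, 5, 5], "B": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="constant indicator"):
            ewm_topsis.standardize(t)

    def test_constant_column_drop_policy(self):
        t = make_table({"A": [5.0, 5, 5], "B": [1.0, 2, 3]})
        std = ewm_topsis.standardize(t, constant_policy="drop")
        assert list(std.z.columns) == ["B"]

    def test_every_column_attains_both_extremes(self, table_2022):
        z = ewm_topsis.standardize(table_2022).z
        assert (z.min(axis=0) == 0).all()
        assert (z.max(axis=0) == 1).all()
        assert ((z >= 0) & (z <= 1)).all().all()


class TestEntropy:
    def test_uniform_is_maximal(self):
        assert ewm_topsis.entropy(np.full(9, 1 / 9)) == pytest.approx(1.0)

    def test_one_hot_is_zero(self):
        p = np.zeros(9)
        p[3] = 1.0
        assert ewm_topsis.entropy(p) == 0.0

    def test_negative_proportion_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ewm_topsis.entropy(np.array([1.2, -0.2]))

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ewm_topsis.entropy(np.array([0.5, 0.4]))

    def test_proportions_columns_sum_to_one(self, table_2022):
        std = ewm_topsis.standardize(table_2022)
        P = ewm_topsis.proportions(std.z)
        assert np.allclose(P.sum(axis=0), 1.0, atol=1e-12)


class TestEntropyWeights:
    def test_equal_entropies_share_equally(self):
        w = ewm_topsis.entropy_weights(np.array([0.5, 0.5]), index=["A", "B"])
        assert w.weights.tolist() == [0.5, 0.5]

    def test_fully_uninformative_column_gets_nothing(self):
        w = ewm_topsis.entropy_weights(np.array([1.0, 0.0]), index=["A", "B"])
        assert w.weights.tolist() == [0.0, 1.0]

    def test_all_uninformative_rejected(self):
        with pytest.raises(ValueError, match="no discriminating"):
            ewm_topsis.entropy_weights(np.array([1.0, 1.0]))

    def test_weights_always_sum_to_one(self, table_2022, table_2023):
        for t in (table_2022, table_2023):
            w, _ = ewm_topsis.evaluate(t)
            assert w.weights.sum() == pytest.approx(1.0, abs=1e-12)
            assert w.utility.equals(1 - w.entropy)


class TestIdealsDistancesCloseness:
    def test_min_max_ideals_are_unit_vectors(self, table_2022):
        std = ewm_topsis.standardize(table_2022)
        zp, zm = ewm_topsis.ideal_solutions(std)
        assert (zp == 1.0).all()
        assert (zm == 0.0).all()

    def test_object_at_positive_ideal_has_zero_distance(self):
        z = pd.DataFrame({"A": [1.0, 0.0], "B": [1.0, 0.0]}, index=["top", "bot"])
        w = pd.Series([0.6, 0.4], index=["A", "B"])
        dp, dm = ewm_topsis.distances(z, w, z.max(), z.min())
        assert dp["top"] == 0.0
        assert dm["bot"] == 0.0

    def test_unknown_variant_rejected(self, table_2022):
        with pytest.raises(ValueError, match="unknown distance variant"):
            ewm_topsis.evaluate(table_2022, variant="bogus")

    def test_closeness_limits(self):
        dp = pd.Series([0.0, 0.3])
        dm = pd.Series([0.5, 0.3])
        T = ewm_topsis.closeness(dp, dm)
        assert T.tolist() == [1.0, 0.5]

    def test_degenerate_object_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ewm_topsis.closeness(pd.Series([0.0]), pd.Series([0.0]))

    def test_distances_bounded_by_one_under_linear_weights(self, table_2022):
        _, r = ewm_topsis.evaluate(table_2022)
        assert ((r.d_plus >= 0) & (r.d_plus <= 1)).all()
        assert ((r.d_minus >= 0) & (r.d_minus <= 1)).all()


class TestRank:
    def test_descending_order(self):
        T = pd.Series([0.2, 0.9, 0.5])
        assert ewm_topsis.rank(T).tolist() == [3, 1, 2]

    def test_ties_follow_input_order(self):
        T = pd.Series([0.5, 0.5, 0.5])
        assert ewm_topsis.rank(T).tolist() == [1, 2, 3]

    def test_ranks_are_a_permutation(self, table_2023):
        _, r = ewm_topsis.evaluate(table_2023)
        assert sorted(r.rank) == list(range(1, 10))


class TestOracleEquivalence:
    @pytest.mark.parametrize("variant", ["weights-linear", "literal"])
    def test_random_matrices_match_loop_oracle(self, variant):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            x = rng.uniform(1.0, 50.0, size=(4, 3))
            dirs = rng.choice(["benefit", "cost"], size=3).tolist()
            t = make_table(x, {f"c{j}": dirs[j] for j in range(3)},
                           columns=[f"c{j}" for j in range(3)])
            w, r = ewm_topsis.evaluate(t, variant=variant)
            e_o, w_o, dp_o, dm_o, T_o = brute_force_evaluate(
                x.tolist(), dirs, variant
            )
            assert np.allclose(w.entropy, e_o, atol=1e-10)
            assert np.allclose(w.weights, w_o, atol=1e-10)
            assert np.allclose(r.d_plus, dp_o, atol=1e-10)
            assert np.allclose(r.d_minus, dm_o, atol=1e-10)
            assert np.allclose(r.closeness, T_o, atol=1e-10)


class TestInvariances:
    @given(scale=st.floats(0.01, 100), shift=st.floats(-50, 50))
    @settings(max_examples=25, deadline=None)
    def test_increasing_affine_transform_changes_nothing(self, scale, shift):
        rng = np.random.default_rng(5)
        x = rng.uniform(1.0, 50.0, size=(5, 3))
        t = make_table(x.copy(), columns=list("ABC"))
        w0, r0 = ewm_topsis.evaluate(t)
        x2 = x.copy()
        x2[:, 1] = scale * x2[:, 1] + shift
        t2 = make_table(x2, columns=list("ABC"))
        w1, r1 = ewm_topsis.evaluate(t2)
        assert np.allclose(w0.weights, w1.weights, atol=1e-9)
        assert np.allclose(r0.closeness, r1.closeness, atol=1e-9)
        assert (r0.rank == r1.rank).all()

    def test_raising_benefit_value_raises_closeness(self):
        """With weights held fixed, a strictly interior improvement in a
        benefit indicator strictly increases that object's closeness."""
        x = np.array([[10.0, 5.0], [20.0, 8.0], [30.0, 2.0]])
        t = make_table(x.copy(), columns=list("AB"))
        w = pd.Series([0.5, 0.5], index=list("AB"))

        def closeness_of(table, i):
            std = ewm_topsis.standardize(table)
            zp, zm = ewm_topsis.ideal_solutions(std)
            dp, dm = ewm_topsis.distances(std, w, zp, zm)
            return ewm_topsis.closeness(dp, dm).iloc[i]

        before = closeness_of(t, 1)
        x2 = x.copy()
        x2[1, 0] = 25.0  # still inside (min, max) of the column
        after = closeness_of(make_table(x2, columns=list("AB")), 1)
        assert after > before

    def test_dominant_object_scores_one(self):
        x = np.array([[9.0, 9.0, 9.0], [2.0, 3.0, 1.0], [1.0, 2.0, 2.0]])
        t = make_table(x, columns=list("ABC"))
        _, r = ewm_topsis.evaluate(t)
        assert r.closeness.iloc[0] == pytest.approx(1.0)
        assert r.rank.iloc[0] == 1

    def test_entropy_and_closeness_bounds(self, table_2022):
        w, r = ewm_topsis.evaluate(table_2022)
        assert ((w.entropy >= 0) & (w.entropy <= 1)).all()
        assert ((r.closeness >= 0) & (r.closeness <= 1)).all()
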