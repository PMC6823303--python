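import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asrtlab import gg_epsilon, lsd_pairwise, one_sample_t, paired_t, rm_anova


# ---------------------------------------------------------------------------
# independent oracle: balanced fully-within ANOVA from first principles

def brute_force_rm_anova(y: np.ndarray, factor_names):
    """Sums of squares by repeated mean-centering over axes.

    ``y`` has shape (n_subjects, k1, ..., kd).  For an effect (a set of
    factor axes), center over each axis in the effect and average over every
    other axis (subject included); SS is the squared effect array times the
    count of observations collapsed into each entry.  Each effect is tested
    against its interaction with the subject axis.
    """
    d = y.ndim - 1
    axes = list(range(1, d + 1))

    def effect_array(include):
        e = y.astype(float)
        for ax in sorted(range(y.ndim), reverse=True):
            m = e.mean(axis=ax, keepdims=True)
            e = (e - m) if ax in include else m
        return np.squeeze(e) if np.ndim(e) else e

    def ss(include):
        e = effect_array(include)
        collapsed = np.prod([y.shape[ax] for ax in range(y.ndim)
                             if ax not in include])
        return collapsed * float(np.sum(np.asarray(e) ** 2))

    out = {}
    n = y.shape[0]
    for size in range(1, d + 1):
        for combo in itertools.combinations(axes, size):
            df1 = int(np.prod([y.shape[ax] - 1 for ax in combo]))
            df2 = df1 * (n - 1)
            ss_eff = ss(set(combo))
            ss_err = ss(set(combo) | {0})
            name = " * ".join(factor_names[ax - 1] for ax in combo)
            out[name] = {"SS": ss_eff, "SS_err": ss_err,
                         "F": (ss_eff / df1) / (ss_err / df2),
                         "df1": df1, "df2": df2}
    return out


def to_long(y, factor_names, levels):
    n = y.shape[0]
    idx = pd.MultiIndex.from_product(
        [range(1, n + 1)] + levels, names=["subject"] + factor_names)
    return idx.to_frame(index=False).assign(value=y.ravel())


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


class TestRmAnovaOracle:
    @pytest.mark.parametrize("shape,names", [
        ((3, 2, 2), ["a", "b"]),
        ((4, 3, 6), ["type", "epoch"]),
        ((4, 2, 3, 4), ["locking", "type", "epoch"]),
    ])
    def test_matches_brute_force_partition(self, rng, shape, names):
        y = rng.normal(size=shape)
        levels = [[f"l{i}" for i in range(k)] for k in shape[1:]]
        table = rm_anova(to_long(y, names, levels),
                         dict(zip(names, levels))).set_index("effect")
        oracle = brute_force_rm_anova(y, names)
        assert set(table.index) == set(oracle)
        for eff, o in oracle.items():
            r = table.loc[eff]
            assert r["F"] == pytest.approx(o["F"], rel=1e-10)
            assert (r["df1"], r["df2"]) == (o["df1"], o["df2"])
            # eta_p2 from the same SS partition
            assert r["eta_p2"] == pytest.approx(
                o["SS"] / (o["SS"] + o["SS_err"]), rel=1e-10)

    def test_two_level_factor_equals_squared_paired_t(self, rng):
        y = rng.normal(size=(10, 2))
        table = rm_anova(to_long(y, ["cond"], [["x", "y"]]),
                         {"cond": ["x", "y"]})
        t = paired_t(y[:, 0], y[:, 1])
        assert table["F"].iloc[0] == pytest.approx(t.t ** 2, rel=1e-12)
        assert table["epsilon"].iloc[0] == 1.0
        assert table["p"].iloc[0] == pytest.approx(t.p, rel=1e-12)

    def test_agrees_with_pingouin_two_way(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(size=(8, 3, 4)) + rng.normal(size=(8, 1, 1))
        names = ["type", "epoch"]
        levels = [["p", "rh", "rl"], list("1234")]
        long = to_long(y, names, levels)
        ours = rm_anova(long, dict(zip(names, levels))).set_index("effect")
        theirs = pg.rm_anova(data=long, dv="value", within=names,
                             subject="subject", detailed=True)
        for eff_pg, eff_us in (("type", "type"), ("epoch", "epoch"),
                               ("type * epoch", "type * epoch")):
            row = theirs[theirs["Source"].str.lower() == eff_pg]
            assert ours.loc[eff_us, "F"] == pytest.approx(
                float(row["F"].iloc[0]), rel=1e-6)

    def test_agrees_with_statsmodels_three_way(self, rng):
        from statsmodels.stats.anova import AnovaRM
        y = rng.normal(size=(6, 2, 2, 3))
        names = ["locking", "type", "epoch"]
        levels = [["s", "r"], ["pat", "rnd"], ["1", "2", "3"]]
        long = to_long(y, names, levels)
        ours = rm_anova(long, dict(zip(names, levels))).set_index("effect")
        theirs = AnovaRM(long, depvar="value", subject="subject",
                         within=names).fit().anova_table
        for eff in theirs.index:
            key = " * ".join(eff.split(":"))
            assert ours.loc[key, "F"] == pytest.approx(
                float(theirs.loc[eff, "F Value"]), rel=1e-8)

    def test_missing_cell_names_subject_and_cell(self, rng):
        y = rng.normal(size=(3, 2, 2))
        long = to_long(y, ["a", "b"], [["x", "y"], ["u", "v"]])
        long = long.drop(long.index[-1])
        with pytest.raises(ValueError, match="missing cell"):
            rm_anova(long, {"a": ["x", "y"], "b": ["u", "v"]})

    def test_constant_data_raises_not_nan(self):
        long = to_long(np.ones((4, 3)), ["a"], [["x", "y", "z"]])
        with pytest.raises(ValueError, match="undefined"):
            rm_anova(long, {"a": ["x", "y", "z"]})

    def test_gg_correction_never_lowers_p(self, rng):
        for _ in range(20):
            y = rng.normal(size=(6, 4)) * rng.gamma(1.0, size=4)
            table = rm_anova(to_long(y, ["a"], [list("wxyz")]),
                             {"a": list("wxyz")})
            assert (table["p_gg"] >= table["p"] - 1e-15).all()


class TestGgEpsilon:
    def test_two_levels_always_one(self, rng):
        for _ in range(5):
            x = rng.normal(size=(10, 2))
            assert gg_epsilon(np.cov(x, rowvar=False)) == 1.0

    def test_compound_symmetry_gives_one(self):
        k = 5
        cov = np.full((k, k), 0.3) + np.eye(k) * 0.7
        assert gg_epsilon(cov) == pytest.approx(1.0)

    def test_rank_one_attains_lower_bound(self):
        v = np.array([3.0, -1.0, 0.5, 1.5])
        v = v - v.mean()  # ensure the structure survives double-centering
        cov = np.outer(v, v)
        assert gg_epsilon(cov) == pytest.approx(1.0 / 3.0)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(size=(12, 4)) * np.array([1.0, 2.0, 0.5, 1.5])
        df = pd.DataFrame(x, columns=list("abcd"))
        assert gg_epsilon(np.cov(x, rowvar=False)) == pytest.approx(
            float(pg.epsilon(df, correction="gg")), rel=1e-10)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            gg_epsilon(np.ones((3, 4)))


class TestTTests:
    def test_hand_computed_example(self):
        # mean 2, sd 1, se 1/sqrt(3) -> t = 2*sqrt(3)
        r = one_sample_t([1.0, 2.0, 3.0], 0.0)
        assert r.t == pytest.approx(2.0 * np.sqrt(3.0), rel=1e-12)
        assert r.df == 2

    def test_constant_sample_at_mu0_is_null(self):
        r = one_sample_t([5.0, 5.0, 5.0], 5.0)
        assert (r.t, r.p) == (0.0, 1.0)

    def test_constant_sample_away_from_mu0_undefined(self):
        with pytest.raises(ValueError):
            one_sample_t([5.0, 5.0, 5.0], 4.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=12),
           st.integers(0, 2 ** 31 - 1))
    def test_paired_equals_one_sample_on_differences(self, a, seed):
        b = np.random.default_rng(seed).normal(size=len(a))
        a = np.asarray(a)
        if np.std(a - b, ddof=1) == 0:
            return
        pr = paired_t(a, b)
        os = one_sample_t(a - b, 0.0)
        assert pr.t == pytest.approx(os.t, rel=1e-12)
        assert pr.p == pytest.approx(os.p, rel=1e-12)

    def test_scipy_cross_check(self, rng):
        from scipy import stats as sps
        x = rng.normal(1.0, 2.0, size=15)
        r = one_sample_t(x, 0.5)
        ref = sps.ttest_1samp(x, 0.5)
        assert r.t == pytest.approx(ref.statistic, rel=1e-12)
        assert r.p == pytest.approx(ref.pvalue, rel=1e-12)


class TestLsdPairwise:
    def test_matches_direct_paired_t(self, rng):
        y = rng.normal(size=(9, 3))
        long = to_long(y, ["cat"], [["a", "b", "c"]])
        table = lsd_pairwise(long, "cat", ["a", "b", "c"])
        assert len(table) == 3
        for _, row in table.iterrows():
            i, j = ["a", "b", "c"].index(row["level_a"]), \
                ["a", "b", "c"].index(row["level_b"])
            ref = paired_t(y[:, i], y[:, j])
            assert row["t"] == pytest.approx(ref.t, rel=1e-12)
            assert row["p"] == pytest.approx(ref.p, rel=1e-12)

    def test_identical_columns_null_result(self):
        y = np.tile(np.arange(5.0)[:, None], (1, 2))
        long = to_long(y, ["cat"], [["a", "b"]])
        table = lsd_pairwise(long, "cat", ["a", "b"])
        assert table["mean_diff"].iloc[0] == 0.0
        assert table["p"].iloc[0] == 1.0

    def test_antisymmetry_of_differences(self, rng):
        y = rng.normal(size=(7, 3))
        long = to_long(y, ["cat"], [["a", "b", "c"]])
        t1 = lsd_pairwise(long, "cat", ["a", "b", "c"])
        t2 = lsd_pairwise(long, "cat", ["c", "b", "a"])
        d1 = t1.set_index(["level_a", "level_b"])["mean_diff"]
        d2 = t2.set_index(["level_a", "level_b"])["mean_diff"]
        for (a, b), v in d1.items():
            assert d2[(b, a)] == pytest.approx(-v, rel=1e-12)
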