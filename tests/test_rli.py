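import numpy as np
import pandas as pd
import pytest

from redlisting import (
    DataError,
    UsageError,
    category_weight,
    rli_bootstrap,
    rli_multi,
    rli_point,
    rli_sampled,
)
from redlisting.rli import read_category_table


@pytest.fixture
def example_table() -> pd.DataFrame:
    """The classic 5-species two-assessment worked example."""
    return pd.DataFrame(
        {
            "2000": ["LC", "EN", "EX", "LC", "CR"],
            "2010": ["LC", "EN", "EX", "CR", "EX"],
        },
        index=[f"sp{i}" for i in range(1, 6)],
    )


class TestCategoryWeight:
    @pytest.mark.parametrize(
        "code,weight",
        [("LC", 0), ("NT", 1), ("VU", 2), ("EN", 3), ("CR", 4), ("EW", 5), ("EX", 5)],
    )
    def test_ladder(self, code, weight):
        assert category_weight(code) == weight

    def test_unknown_code_named(self):
        with pytest.raises(UsageError, match="XX"):
            category_weight("XX")

    def test_dd_has_no_weight(self):
        with pytest.raises(UsageError, match="DD"):
            category_weight("DD")


class TestRliPoint:
    def test_all_least_concern_is_one(self):
        assert rli_point(["LC"] * 7) == 1.0

    def test_all_extinct_is_zero(self):
        assert rli_point(["EX"] * 4) == 0.0

    def test_worked_example_columns(self, example_table):
        # 2000: weights 0+3+5+0+4 = 12 over 5*5 -> 1 - 12/25 = 0.52
        # 2010: weights 0+3+5+4+5 = 17 over 5*5 -> 1 - 17/25 = 0.32
        assert rli_point(example_table["2000"]) == pytest.approx(0.52)
        assert rli_point(example_table["2010"]) == pytest.approx(0.32)

    def test_equals_one_minus_mean_weight_over_five(self):
        rng = np.random.default_rng(0)
        codes = rng.choice(["LC", "NT", "VU", "EN", "CR", "EX"], size=30).tolist()
        weights = [category_weight(c) for c in codes]
        assert rli_point(codes) == pytest.approx(1 - np.mean(weights) / 5)
        assert rli_point(codes[::-1]) == rli_point(codes)

    def test_one_step_worse_drops_by_1_over_5n(self):
        codes = ["LC", "VU", "EN", "NT", "LC"]
        worse = list(codes)
        worse[0] = "NT"
        assert rli_point(codes) - rli_point(worse) == pytest.approx(1 / (5 * len(codes)))

    def test_dd_excluded_from_n(self):
        assert rli_point(["LC", "DD", "EX"]) == pytest.approx(1 - 5 / 10)

    def test_all_dd_rejected(self):
        with pytest.raises(DataError, match="Data Deficient"):
            rli_point(["DD", "DD"])


class TestRliBootstrap:
    def test_constant_table_has_degenerate_limits(self):
        table = pd.DataFrame({"a": ["LC"] * 6, "b": ["LC"] * 6})
        res = rli_bootstrap(table, reps=200, seed=0)
        np.testing.assert_allclose(res.lower, 1.0)
        np.testing.assert_allclose(res.upper, 1.0)
        assert not res.significant.any()

    def test_single_species_limits_collapse(self):
        table = pd.DataFrame({"a": ["VU"], "b": ["EN"]})
        res = rli_bootstrap(table, reps=100, seed=1)
        np.testing.assert_allclose(res.lower, res.values)
        np.testing.assert_allclose(res.upper, res.values)

    def test_replicate_mean_close_to_point_estimate(self, example_table):
        res = rli_bootstrap(example_table, reps=10_000, seed=2)
        # the index is a mean statistic, so the bootstrap is unbiased:
        # the replicate mean converges on the point estimate
        for d in range(2):
            assert res.lower[d] <= res.values[d] <= res.upper[d]
            assert abs(res.replicates[:, d].mean() - res.values[d]) < 0.02
            assert res.lower[d] <= np.median(res.replicates[:, d]) <= res.upper[d]

    def test_limits_bracket_point_and_shrink_with_n(self):
        rng = np.random.default_rng(3)
        widths = []
        for n in (5, 50, 500):
            codes = rng.choice(["LC", "NT", "VU", "EN", "CR", "EX"], size=(n, 2))
            table = pd.DataFrame(codes, columns=["a", "b"])
            res = rli_bootstrap(table, reps=500, seed=4)
            assert np.all(res.lower <= res.values + 1e-12)
            assert np.all(res.upper >= res.values - 1e-12)
            widths.append(float(np.mean(res.upper - res.lower)))
        assert widths[0] > widths[1] > widths[2]

    def test_reps_floor(self, example_table):
        with pytest.raises(UsageError):
            rli_bootstrap(example_table, reps=1)

    def test_null_tables_rarely_flag_change(self):
        # calibration: identical columns -> observed change 0 -> sign
        # undefined -> the flag must never fire, regardless of resampling
        rng = np.random.default_rng(5)
        fired = 0
        for _ in range(50):
            codes = rng.choice(["LC", "NT", "VU", "EN", "CR"], size=20)
            table = pd.DataFrame({"a": codes, "b": codes})
            res = rli_bootstrap(table, reps=200, seed=int(rng.integers(2**31)))
            fired += int(res.significant.any())
        assert fired == 0

    def test_strong_decline_is_significant(self):
        table = pd.DataFrame({"a": ["LC"] * 20, "b": ["EN"] * 20})
        res = rli_bootstrap(table, reps=1000, seed=6)
        assert res.significant.tolist() == [True]


class TestRliMulti:
    def test_single_group_reduces_to_bootstrap(self, example_table):
        out = rli_multi(example_table, ["all"] * 5, reps=200, seed=7)
        assert list(out) == ["all"]
        np.testing.assert_allclose(out["all"].values, [0.52, 0.32])

    def test_two_groups_first_appearance_order(self, example_table):
        groups = ["Arthropods", "Arthropods", "Birds", "Birds", "Birds"]
        out = rli_multi(example_table, groups, reps=200, seed=8)
        assert list(out) == ["Arthropods", "Birds"]
        for g, rows in (("Arthropods", [0, 1]), ("Birds", [2, 3, 4])):
            for d, col in enumerate(example_table.columns):
                expected = rli_point(example_table.iloc[rows][col])
                assert out[g].values[d] == pytest.approx(expected)

    def test_unassessable_group_warns_not_fatal(self):
        table = pd.DataFrame({"a": ["LC", "DD"], "b": ["LC", "DD"]})
        with pytest.warns(UserWarning, match="bad"):
            out = rli_multi(table, ["good", "bad"], reps=100, seed=9)
        assert out["bad"] is None
        assert out["good"] is not None


class TestRliSampled:
    def test_uniform_category_table_needs_only_two(self):
        table = pd.DataFrame({"a": ["VU"] * 10, "b": ["VU"] * 10})
        res = rli_sampled(table, max_error=0.01, reps=100, seed=10)
        np.testing.assert_allclose(res.error_quantile, 0.0)
        assert res.minimal_n == 2

    def test_full_sample_has_zero_error(self):
        rng = np.random.default_rng(11)
        codes = rng.choice(["LC", "VU", "EX"], size=(8, 2))
        table = pd.DataFrame(codes, columns=["a", "b"])
        res = rli_sampled(table, max_error=0.001, reps=50, seed=12)
        assert res.error_quantile[-1] == 0.0

    def test_curve_decreasing_and_matches_independent_stream(self):
        rng = np.random.default_rng(13)
        codes = rng.choice(["LC", "NT", "VU", "EN", "CR", "EX"], size=(20, 2))
        table = pd.DataFrame(codes, columns=["a", "b"])
        res = rli_sampled(table, max_error=0.05, reps=1000, seed=14)
        # non-increasing within Monte-Carlo noise: compare smoothed ends
        assert np.mean(res.error_quantile[:5]) > np.mean(res.error_quantile[-5:])
        # independent Monte-Carlo oracle with a different RNG stream
        from redlisting.rli import _index_from_weights, _weights_matrix

        w = _weights_matrix(table, None)
        full = _index_from_weights(w)
        rng2 = np.random.RandomState(999)  # legacy generator: independent stream
        qs = []
        for n in res.sizes:
            if n == len(w):
                qs.append(0.0)
                continue
            worst = [
                np.max(np.abs(_index_from_weights(w[rng2.choice(len(w), n, replace=False)]) - full))
                for _ in range(1000)
            ]
            qs.append(np.percentile(worst, 95))
        minimal_oracle = int(res.sizes[np.nonzero(np.array(qs) <= 0.05)[0][0]])
        assert abs(res.minimal_n - minimal_oracle) <= 1


class TestCategoryTableIo:
    def test_round_trip_with_groups(self, tmp_path, example_table):
        path = tmp_path / "cats.csv"
        df = example_table.reset_index().rename(columns={"index": "species"})
        df.insert(0, "group", ["x", "x", "y", "y", "y"])
        df.to_csv(path, index=False)
        table, groups = read_category_table(path)
        assert list(table.columns) == ["2000", "2010"]
        assert groups.tolist() == ["x", "x", "y", "y", "y"]
        np.testing.assert_array_equal(table.to_numpy(), example_table.to_numpy())
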