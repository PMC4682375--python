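import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comirnet.interactions import TargetMap
from comirnet.preprocess import (
    DEResult,
    DESignature,
    ExpressionDataset,
    bh_adjust,
    check_cross_comparable,
    differential_expression,
    intersect_signatures,
    normalize_dataset,
    quantile_normalize,
    restrict_to_interaction_universe,
)
from comirnet.synthetic import generate_expression, generate_truth

from .conftest import small_config
from .oracles import bh_stepup_naive


def make_dataset(values, n_control=None, dataset_id="D1"):
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    n_control = n_control if n_control is not None else n_samples // 2
    return ExpressionDataset(
        dataset_id=dataset_id,
        genes=[f"g{i}" for i in range(n_genes)],
        samples=[f"s{j}" for j in range(n_samples)],
        values=values,
        group=["control"] * n_control + ["treated"] * (n_samples - n_control),
    )


class TestExpressionDataset:
    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            ExpressionDataset("D", ["g1"], ["s1", "s2", "s3", "s4"],
                              np.zeros((2, 4)), ["control"] * 2 + ["treated"] * 2)

    def test_rejects_duplicate_genes(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_dataset(np.zeros((2, 4))).__class__(
                "D", ["g1", "g1"], [f"s{j}" for j in range(4)], np.zeros((2, 4)),
                ["control"] * 2 + ["treated"] * 2,
            )

    def test_rejects_single_sample_group(self):
        with pytest.raises(ValueError, match=">=2 samples"):
            make_dataset(np.zeros((2, 3)), n_control=1)


class TestCrossComparable:
    def test_identical_columns_comparable(self):
        ds = make_dataset(np.tile([[1.0], [5.0], [9.0]], (1, 4)))
        assert check_cross_comparable(ds)["comparable"] is True

    def test_shifted_column_flagged(self):
        values = np.tile([[1.0], [5.0], [9.0]], (1, 4))
        values[:, 0] += 10
        assert check_cross_comparable(make_dataset(values))["comparable"] is False

    def test_median_of_three_values(self):
        ds = make_dataset(np.array([[1.0], [2.0], [9.0]]).repeat(4, axis=1))
        assert check_cross_comparable(ds)["quartiles"]["median"].iloc[0] == 2.0


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        values = np.array([[1.0, 1.0], [3.0, 3.0], [2.0, 2.0]])
        np.testing.assert_allclose(quantile_normalize(values), values)

    def test_two_by_two_rank_means(self):
        # rows g1=(1,4), g2=(3,2): rank means (1+2)/2=1.5 and (3+4)/2=3.5
        out = quantile_normalize(np.array([[1.0, 4.0], [3.0, 2.0]]))
        np.testing.assert_allclose(out, [[1.5, 3.5], [3.5, 1.5]])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(50, 4))
        once = quantile_normalize(values)
        np.testing.assert_allclose(quantile_normalize(once), once, atol=1e-12)

    def test_sorted_columns_identical(self):
        rng = np.random.default_rng(1)
        out = quantile_normalize(rng.normal(size=(100, 5)))
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_array_equal(np.sort(out[:, j]), ref)

    def test_rejects_missing_values(self):
        with pytest.raises(ValueError, match="missing"):
            quantile_normalize(np.array([[1.0, np.nan], [2.0, 3.0]]))

    def test_normalize_dataset_auto_skips_comparable(self):
        rng = np.random.default_rng(2)
        ds = make_dataset(rng.normal(7, 0.01, size=(200, 4)))
        assert normalize_dataset(ds, mode="auto") is ds
        shifted = ds.values.copy()
        shifted[:, 0] += 3
        ds2 = make_dataset(shifted)
        out = normalize_dataset(ds2, mode="auto")
        assert check_cross_comparable(out)["comparable"]


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.01, 0.04, 0.9], [0.03, 0.06, 0.9]),
            ([0.42], [0.42]),
        ],
    )
    def test_worked_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_matches_naive_oracle_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40)).tolist()
            np.testing.assert_allclose(bh_adjust(p), bh_stepup_naive(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.random(200)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_capped(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)


class TestDifferentialExpression:
    def test_null_type_one_error_rate(self):
        cfg = small_config(n_genes=2000, n_datasets=1, effect_size=0.0,
                           platform_dropout=0.0, n_coop_groups=0, seed=5)
        truth = generate_truth(cfg)
        (ds,) = generate_expression(cfg, truth)
        res = differential_expression(ds)
        frac = float((res.table["p"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07
        # BH keeps realized discoveries near zero under the pure null
        assert (res.table["status"] != "ns").sum() <= 5

    def test_constant_gene_is_ns(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(20, 8))
        values[0] = 3.0
        res = differential_expression(make_dataset(values))
        assert res.table.iloc[0]["status"] == "ns"
        assert res.table.iloc[0]["p"] == 1.0

    def test_zero_variance_nonzero_effect_gets_tiny_p(self):
        values = np.zeros((3, 8))
        values[0, 4:] = 2.0  # exact shift, no noise
        res = differential_expression(make_dataset(values))
        assert 0 < res.table.iloc[0]["p"] < 1e-300
        assert res.table.iloc[0]["status"] == "up"

    def test_planted_strong_shift_called_up(self):
        # +4 log2 shift, sd 0.5, 6v6: t ~ 13.9, overwhelming evidence
        rng = np.random.default_rng(7)
        values = rng.normal(7, 0.5, size=(100, 12))
        values[0, 6:] += 4.0
        res = differential_expression(make_dataset(values))
        assert res.table.iloc[0]["status"] == "up"
        assert res.table.iloc[0]["p"] < 1e-6

    def test_welch_fallback_agrees_on_strong_signal(self):
        rng = np.random.default_rng(8)
        values = rng.normal(7, 0.5, size=(50, 12))
        values[0, 6:] += 4.0
        res = differential_expression(make_dataset(values), moderate=False)
        assert res.table.iloc[0]["status"] == "up"

    def test_realized_fdr_controlled_with_planted_signal(self):
        cfg = small_config(n_genes=2000, n_datasets=1, platform_dropout=0.0, seed=9)
        truth = generate_truth(cfg)
        (ds,) = generate_expression(cfg, truth)
        res = differential_expression(ds)
        called = res.up | res.down
        false = called - truth.de_up - truth.de_down
        n = max(len(called), 1)
        assert len(false) / n <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)


def de_result_from_sets(up, down, universe, dataset_id="D"):
    status = ["up" if g in up else "down" if g in down else "ns" for g in universe]
    table = pd.DataFrame(
        {"effect": [1.0 if s == "up" else -1.0 if s == "down" else 0.0 for s in status],
         "p": 0.001, "p_adj": 0.001, "status": status},
        index=pd.Index(list(universe), name="gene_id"),
    )
    return DEResult(dataset_id=dataset_id, table=table)


class TestIntersectSignatures:
    def test_single_dataset_identity(self):
        r = de_result_from_sets({"g1"}, {"g2"}, ["g1", "g2", "g3"])
        sig = intersect_signatures([r])
        assert sig.up == {"g1"} and sig.down == {"g2"}

    def test_set_intersection(self):
        a = de_result_from_sets({"g1", "g2"}, set(), ["g1", "g2", "g3"], "A")
        b = de_result_from_sets({"g2", "g3"}, set(), ["g1", "g2", "g3"], "B")
        assert intersect_signatures([a, b]).up == {"g2"}

    def test_ns_anywhere_excludes(self):
        universe = ["g1", "g2"]
        results = [de_result_from_sets({"g1"}, set(), universe, f"D{i}") for i in range(4)]
        results.append(de_result_from_sets(set(), set(), universe, "D4"))
        assert intersect_signatures(results).up == set()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            intersect_signatures([])


class TestRestrictToUniverse:
    tm = TargetMap(targets={"m1": {"g1", "g9"}})

    def test_inside_universe_unchanged(self):
        sig = DESignature(up=frozenset({"g1"}), down=frozenset())
        assert restrict_to_interaction_universe(sig, self.tm).up == {"g1"}

    def test_untargeted_gene_dropped(self):
        sig = DESignature(up=frozenset({"g1", "g2"}), down=frozenset())
        assert restrict_to_interaction_universe(sig, self.tm).up == {"g1"}

    def test_empty_signature_stays_empty(self):
        sig = DESignature(up=frozenset(), down=frozenset())
        out = restrict_to_interaction_universe(sig, self.tm)
        assert out.up == frozenset() and out.down == frozenset()
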