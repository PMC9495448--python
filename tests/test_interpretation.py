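"""Percentile ranks, local feature/model ranks and rank product scores."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ensint import (BasePredictionMatrix, LabelVector, ModalityTable,
                    compute_lfr, compute_lmr, interpret_ei,
                    rank_product_scores, to_percentile_ranks)
from ensint.ensemble_layer import EnsembleModel, stacking_fit
from ensint.interpretation import LocalFeatureRanks, LocalModelRanks
from ensint.local_layer import BaseClassifierSpec, LocalModel

from conftest import make_complementary


class TestPercentileRanks:
    def test_basic_ranking(self):
        out = to_percentile_ranks({"a": 3.0, "b": 1.0, "c": 2.0})
        assert out == {"a": pytest.approx(1 / 3), "b": pytest.approx(1.0),
                       "c": pytest.approx(2 / 3)}

    def test_single_item(self):
        assert to_percentile_ranks({"a": 5.0}) == {"a": 1.0}

    def test_tie_gets_mean_rank(self):
        out = to_percentile_ranks({"a": 2.0, "b": 2.0})
        assert out == {"a": 0.75, "b": 0.75}

    def test_lower_is_better_flag(self):
        out = to_percentile_ranks({"a": 3.0, "b": 1.0}, higher_is_better=False)
        assert out["b"] == 0.5 and out["a"] == 1.0

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            to_percentile_ranks({"a": np.nan})

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30))
    def test_percentile_rank_law(self, values):
        """Outputs live in {i/n} plus tie-averages, min 1/n when no top tie,
        max 1, always within (0, 1]."""
        scores = {f"k{i}": v for i, v in enumerate(values)}
        out = to_percentile_ranks(scores)
        n = len(values)
        vals = sorted(out.values())
        assert all(0 < v <= 1 for v in vals)
        assert max(vals) <= 1.0
        assert min(vals) >= 1 / n
        # every value is a mean of a consecutive integer run, divided by n
        for v in vals:
            doubled = v * n * 2  # 2*mean of an integer run is an integer
            assert doubled == pytest.approx(round(doubled), abs=1e-9)
        if len(set(values)) == n:  # no ties: exactly {1/n, ..., 1}
            assert vals == pytest.approx([(i + 1) / n for i in range(n)])


class TestComputeLfr:
    def make_model(self, table, labels, algorithm="logistic_regression"):
        spec = BaseClassifierSpec(algorithm)
        model = LocalModel(spec, table.name, 0, 0, list(table.feature_names),
                           list(table.entity_ids))
        est = spec.build(0)
        est.fit(table.values, labels.labels)
        model.estimator = est
        return model

    @pytest.fixture
    def planted_table(self):
        rng = np.random.default_rng(0)
        n = 120
        y = np.array([1] * 40 + [0] * 80)
        X = rng.normal(size=(n, 5))
        X[:, 2] = y + 0.1 * rng.normal(size=n)  # near label-copy feature
        ids = [f"e{i}" for i in range(n)]
        return (ModalityTable("m", ids, [f"f{j}" for j in range(5)], X),
                LabelVector(ids, y))

    def test_label_copy_feature_ranked_first(self, planted_table):
        table, labels = planted_table
        model = self.make_model(table, labels)
        lfr = compute_lfr(model, table, labels, seed=0)
        assert lfr.ranks["f2"] == pytest.approx(1 / 5)

    def test_constant_feature_near_worst(self, planted_table):
        table, labels = planted_table
        X = table.values.copy()
        X[:, 4] = 3.14
        table2 = ModalityTable("m", table.entity_ids, table.feature_names, X)
        model = self.make_model(table2, labels)
        lfr = compute_lfr(model, table2, labels, seed=0)
        assert lfr.ranks["f4"] >= 3 / 5

    def test_feature_order_permutation_invariant(self, planted_table):
        table, labels = planted_table
        model = self.make_model(table, labels)
        lfr = compute_lfr(model, table, labels, seed=0)
        perm = [3, 0, 4, 2, 1]
        t2 = ModalityTable("m", table.entity_ids,
                           [table.feature_names[j] for j in perm],
                           table.values[:, perm])
        model2 = self.make_model(t2, labels)
        lfr2 = compute_lfr(model2, t2, labels, seed=0)
        for f in table.feature_names:
            assert lfr.ranks[f] == pytest.approx(lfr2.ranks[f])

    def test_single_feature_modality_trivial_rank(self, planted_table):
        table, labels = planted_table
        t1 = ModalityTable("m", table.entity_ids, ["f2"],
                           table.values[:, [2]])
        model = self.make_model(t1, labels)
        lfr = compute_lfr(model, t1, labels, seed=0)
        assert lfr.ranks == {"f2": 1.0}


class TestComputeLmr:
    def test_mean_aggregation_uniform_ranks(self):
        cols = [("m", f"a{j}") for j in range(5)]
        ens = EnsembleModel("mean", cols)
        bpm = BasePredictionMatrix(["e0"], cols, np.full((1, 5), 0.5))
        lmr = compute_lmr(ens, bpm, np.array([1]))
        assert list(lmr.ranks.values()) == pytest.approx([6 / 10] * 5)

    def test_ces_inclusion_count_order(self):
        cols = [("m", "A"), ("m", "B"), ("m", "C")]
        ens = EnsembleModel("ces", cols,
                            selection=Counter({("m", "A"): 3, ("m", "B"): 1}))
        bpm = BasePredictionMatrix(["e0"], cols, np.full((1, 3), 0.5))
        lmr = compute_lmr(ens, bpm, np.array([1]))
        assert lmr.ranks[("m", "A")] < lmr.ranks[("m", "B")] \
            < lmr.ranks[("m", "C")]

    def test_stacking_ignored_column_worst_rank(self):
        rng = np.random.default_rng(2)
        n = 300
        y = rng.integers(0, 2, n)
        informative = np.clip(0.5 * y + 0.25 + 0.1 * rng.normal(size=n), 0, 1)
        cols = {("m", "A"): informative,
                ("m", "B"): np.clip(informative + 0.05 * rng.normal(size=n), 0, 1),
                ("m", "C"): rng.random(n)}  # pure noise, ignorable
        bpm = BasePredictionMatrix([f"e{i}" for i in range(n)], list(cols),
                                   np.column_stack(list(cols.values())))
        ens = stacking_fit(bpm, y, "logistic_regression", seed=0)
        lmr = compute_lmr(ens, bpm, y, n_permutations=30, seed=0)
        assert lmr.ranks[("m", "C")] == max(lmr.ranks.values())

    def test_bad_permutation_count_rejected(self):
        ens = EnsembleModel("mean", [("m", "A")])
        bpm = BasePredictionMatrix(["e0"], [("m", "A")], np.array([[0.5]]))
        with pytest.raises(ValueError, match="n_permutations"):
            compute_lmr(ens, bpm, np.array([1]), n_permutations=0)


class TestRankProductScores:
    def test_direct_formula(self):
        lmr = LocalModelRanks("mean", {("x", "A"): 0.5, ("y", "B"): 1.0})
        lfrs = [LocalFeatureRanks(("x", "A"), "x", {"f": 0.2}),
                LocalFeatureRanks(("y", "B"), "y", {"g": 0.4})]
        rps = rank_product_scores(lmr, lfrs)
        assert dict(zip(rps.feature, rps.rps)) == {
            "f": pytest.approx(0.1), "g": pytest.approx(0.4)}

    def test_feature_shared_across_models_averages(self):
        lmr = LocalModelRanks("mean", {("x", "A"): 0.5, ("x", "B"): 1.0})
        lfrs = [LocalFeatureRanks(("x", "A"), "x", {"f": 0.2}),
                LocalFeatureRanks(("x", "B"), "x", {"f": 0.4})]
        rps = rank_product_scores(lmr, lfrs)
        # (0.5*0.2 + 1.0*0.4) / 2 = 0.25
        assert rps.rps.iloc[0] == pytest.approx(0.25)

    def test_single_model_product(self):
        lmr = LocalModelRanks("mean", {("x", "A"): 0.5})
        lfrs = [LocalFeatureRanks(("x", "A"), "x", {"f": 0.2})]
        assert rank_product_scores(lmr, lfrs).rps.iloc[0] == pytest.approx(0.1)

    def test_duplicate_feature_across_modalities_rejected(self):
        lmr = LocalModelRanks("mean", {("x", "A"): 0.5, ("y", "B"): 1.0})
        lfrs = [LocalFeatureRanks(("x", "A"), "x", {"f": 0.2}),
                LocalFeatureRanks(("y", "B"), "y", {"f": 0.4})]
        with pytest.raises(ValueError, match="modality-qualified"):
            rank_product_scores(lmr, lfrs)

    def test_monotone_in_lfr(self):
        lmr = LocalModelRanks("mean", {("x", "A"): 0.5, ("x", "B"): 0.8})
        base = [LocalFeatureRanks(("x", "A"), "x", {"f": 0.6, "g": 0.2}),
                LocalFeatureRanks(("x", "B"), "x", {"f": 0.6, "g": 0.2})]
        improved = [LocalFeatureRanks(("x", "A"), "x", {"f": 0.3, "g": 0.2}),
                    LocalFeatureRanks(("x", "B"), "x", {"f": 0.6, "g": 0.2})]
        r0 = rank_product_scores(lmr, base).set_index("feature").rps
        r1 = rank_product_scores(lmr, improved).set_index("feature").rps
        assert r1["f"] <= r0["f"]
        assert r1["g"] == r0["g"]

    def test_sorted_ascending(self):
        lmr = LocalModelRanks("mean", {("x", "A"): 1.0})
        lfrs = [LocalFeatureRanks(("x", "A"), "x",
                                  {"f": 0.9, "g": 0.1, "h": 0.5})]
        rps = rank_product_scores(lmr, lfrs)
        assert rps.rps.is_monotonic_increasing


class TestInterpretEi:
    def test_planted_feature_tops_rps(self, fast_config):
        dataset, ground_truth, _ = make_complementary(
            n_entities=200, seed=3, with_noise=False, prevalence=0.3)
        result = interpret_ei(dataset, "mean", fast_config.replace(seed=3))
        top2 = result.rps.head(2).feature.tolist()
        planted = [f for feats in ground_truth.values() for f in feats]
        assert set(planted) & set(top2)

    def test_unknown_variant_rejected(self, fast_config, small_dataset):
        with pytest.raises(ValueError, match="variant"):
            interpret_ei(small_dataset[0], "bagging", fast_config)
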