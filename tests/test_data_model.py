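"""Containers, parsers, alignment, fold plans and round-trip IO."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ensint import (BasePredictionMatrix, LabelVector, ModalityTable,
                    MultimodalDataset, RunConfig, align_entities, derive_seed,
                    make_fold_plan, read_modality_table, read_predictions,
                    read_rps_table, write_modality_table, write_predictions,
                    write_rps_table)
from ensint.data_model import read_fold_plan, write_fold_plan


# ---------------------------------------------------------------------------
# Modality table parsing
# ---------------------------------------------------------------------------

class TestReadModalityTable:
    def test_na_cell_flagged_missing(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("entity_id\tf1\tf2\ne1\t1.5\t2\ne2\tNA\t4\ne3\t5\t6\n")
        t = read_modality_table(p)
        assert t.missing_mask.sum() == 1
        assert t.missing_mask[1, 0]
        assert t.values[0, 0] == 1.5

    def test_header_only_file_is_error(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("entity_id\tf1\tf2\n")
        with pytest.raises(ValueError, match="no entities"):
            read_modality_table(p)

    def test_reading_twice_is_bit_stable(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("entity_id\tf1\tf2\ne2\t0.1\t0.2\ne1\tnan\t0.4\n")
        a, b = read_modality_table(p), read_modality_table(p)
        assert a.entity_ids == b.entity_ids
        np.testing.assert_array_equal(a.missing_mask, b.missing_mask)
        np.testing.assert_array_equal(a.values[~a.missing_mask],
                                      b.values[~b.missing_mask])

    def test_duplicate_entity_ids_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("entity_id\tf1\ne1\t1\ne1\t2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_modality_table(p)

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("entity_id\tf1\tf2\ne1\t1\tbogus\n")
        with pytest.raises(ValueError, match="e1.*f2"):
            read_modality_table(p)

    def test_roundtrip_preserves_values_and_mask(self, tmp_path, toy_table):
        p = tmp_path / "roundtrip.tsv"
        write_modality_table(toy_table, p)
        back = read_modality_table(p, name="toy")
        np.testing.assert_array_equal(back.missing_mask, toy_table.missing_mask)
        np.testing.assert_array_equal(back.values[~back.missing_mask],
                                      toy_table.values[~toy_table.missing_mask])


class TestModalityTableInvariants:
    def test_duplicate_feature_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate feature"):
            ModalityTable("m", ["e1"], ["f", "f"], np.ones((1, 2)))

    def test_non_finite_observed_value_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            ModalityTable("m", ["e1"], ["f1"], np.array([[np.inf]]),
                          np.array([[False]]))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ModalityTable("m", [], ["f1"], np.empty((0, 1)))


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

class TestAlignEntities:
    def test_absent_entity_gets_zero_row_as_data(self):
        a = ModalityTable("a", ["e1", "e2"], ["x"], [[1.0], [2.0]])
        b = ModalityTable("b", ["e1"], ["y"], [[3.0]])
        labels = LabelVector(["e1", "e2"], [1, 0])
        out = align_entities(MultimodalDataset([a, b], labels))
        mb = out.modality("b")
        assert mb.entity_ids == ["e1", "e2"]
        assert mb.values[1, 0] == 0.0
        assert not mb.missing_mask[1, 0]  # zeros are data, not missingness

    def test_shared_entities_identity_up_to_ordering(self):
        a = ModalityTable("a", ["e2", "e1"], ["x"], [[2.0], [1.0]])
        labels = LabelVector(["e1", "e2"], [1, 0])
        out = align_entities(MultimodalDataset([a], labels))
        assert out.modality("a").entity_ids == ["e1", "e2"]
        np.testing.assert_array_equal(out.modality("a").values, [[1.0], [2.0]])

    def test_disjoint_modalities_union_sized_zero_filled(self, caplog):
        a = ModalityTable("a", ["e1"], ["x"], [[1.0]])
        b = ModalityTable("b", ["e2"], ["y"], [[2.0]])
        labels = LabelVector(["e1", "e2", "e3"], [1, 0, 0])
        out = align_entities(MultimodalDataset([a, b], labels))
        for m in out.modalities:
            assert m.entity_ids == ["e1", "e2", "e3"]
        # e3 is in no modality: retained zero-filled with a warning
        assert "no modality" in caplog.text
        assert out.modality("a").values[2, 0] == 0.0

    def test_unlabeled_entities_dropped(self):
        a = ModalityTable("a", ["e1", "zz"], ["x"], [[1.0], [9.0]])
        labels = LabelVector(["e1"], [1])
        out = align_entities(MultimodalDataset([a], labels))
        assert out.modality("a").entity_ids == ["e1"]


# ---------------------------------------------------------------------------
# Fold plan IO and invariants
# ---------------------------------------------------------------------------

class TestFoldPlan:
    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_outer_folds_partition_entities(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        labels = LabelVector([f"e{i}" for i in range(n)],
                             rng.permutation([1] * 20 + [0] * 40))
        plan = make_fold_plan(labels, 5, 3, seed)
        plan.validate(labels)
        tests = [set(plan.outer_test(o)) for o in range(5)]
        assert set().union(*tests) == set(labels.entity_ids)
        for i in range(5):
            for j in range(i + 1, 5):
                assert not tests[i] & tests[j]

    def test_roundtrip_through_tsv(self, tmp_path):
        labels = LabelVector([f"e{i}" for i in range(40)], [1] * 15 + [0] * 25)
        plan = make_fold_plan(labels, 5, 5, seed=3)
        p = tmp_path / "plan.tsv"
        write_fold_plan(plan, p)
        back = read_fold_plan(p, seed=3)
        assert back.outer_assignment == plan.outer_assignment
        assert back.inner_assignment == plan.inner_assignment


# ---------------------------------------------------------------------------
# Prediction matrix / RPS table IO
# ---------------------------------------------------------------------------

class TestPredictionIO:
    def test_scores_roundtrip_losslessly(self, tmp_path):
        rng = np.random.default_rng(0)
        bpm = BasePredictionMatrix(
            ["e1", "e2", "e3"], [("a", "knn"), ("b", "svm_linear")],
            rng.random((3, 2)))
        p = tmp_path / "bpm.tsv"
        write_predictions(bpm, p)
        back = read_predictions(p)
        np.testing.assert_array_equal(back.scores, bpm.scores)
        assert back.column_ids == bpm.column_ids

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            BasePredictionMatrix(["e1"], [("a", "knn")], np.array([[1.5]]))

    def test_rps_written_sorted_ascending(self, tmp_path):
        df = pd.DataFrame({"modality": ["m", "m", "m"],
                           "feature": ["f1", "f2", "f3"],
                           "rps": [0.9, 0.1, 0.5]})
        p = tmp_path / "rps.tsv"
        write_rps_table(df, p)
        back = read_rps_table(p)
        assert back["rps"].is_monotonic_increasing
        assert back["feature"].tolist() == ["f2", "f3", "f1"]

    def test_empty_rps_table_writes_header_only(self, tmp_path):
        p = tmp_path / "rps.tsv"
        write_rps_table(pd.DataFrame(columns=["modality", "feature", "rps"]), p)
        assert p.read_text().strip() == "modality\tfeature\trps"


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

class TestRunConfig:
    def test_unknown_key_error_names_key(self):
        with pytest.raises(ValueError, match="bogus_knob"):
            RunConfig.from_mapping({"seed": 1, "bogus_knob": 2})

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("seed: 42\nk_outer: 3\nces:\n  metric: auprc\n"
                     "local_roster: [naive_bayes]\n")
        cfg = RunConfig.from_file(p)
        assert cfg.seed == 42 and cfg.k_outer == 3
        assert cfg.ces_metric == "auprc"
        assert cfg.local_roster == ["naive_bayes"]
        assert len(cfg.meta_roster) == 9  # default meta roster untouched

    def test_empty_roster_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            RunConfig(local_roster=[])

    def test_derived_seeds_stable_and_bounded(self):
        a = derive_seed(1, "local", 0, "mod_a")
        assert a == derive_seed(1, "local", 0, "mod_a")
        assert a != derive_seed(1, "local", 1, "mod_a")
        assert 0 <= a < 2**31
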