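"""Evaluation protocols: baselines, CV bookkeeping, inter-session guard rails."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import foodspec as fs
from foodspec.validation import _splits


class TestZeroR:
    def test_one_vs_all_design_baseline(self):
        labels = ["t"] * 44 + ["rest"] * 88
        assert fs.zeror(labels) == pytest.approx(66.67, abs=0.01)
        assert fs.zeror(labels) >= 66.0

    def test_balanced_three_class_baseline(self):
        labels = ["G"] * 44 + ["B"] * 44 + ["P"] * 44
        assert fs.zeror(labels) == pytest.approx(33.33, abs=0.01)
        assert fs.zeror(labels) >= 33.0

    def test_single_class(self):
        assert fs.zeror(["x"] * 7) == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fs.zeror([])

    @given(st.lists(st.sampled_from("abcd"), min_size=1, max_size=60))
    def test_matches_count_and_max_oracle(self, labels):
        expected = 100.0 * max(Counter(labels).values()) / len(labels)
        assert fs.zeror(labels) == pytest.approx(expected)


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        cm = fs.confusion(["A", "B", "A"], ["A", "B", "A"], ["A", "B"])
        np.testing.assert_array_equal(cm.counts, [[2, 0], [0, 1]])
        np.testing.assert_allclose(np.diag(cm.row_percents), 100.0)

    def test_hand_counted_rows(self):
        cm = fs.confusion(["A", "A", "B", "B"], ["A", "B", "B", "B"], ["A", "B"])
        np.testing.assert_allclose(cm.row_percents, [[50, 50], [0, 100]])

    def test_rows_sum_to_hundred(self):
        rng = np.random.default_rng(0)
        true = list(rng.choice(["A", "B", "C"], 50))
        pred = list(rng.choice(["A", "B", "C"], 50))
        cm = fs.confusion(true, pred, ["A", "B", "C"])
        np.testing.assert_allclose(cm.row_percents.sum(axis=1), 100.0, atol=1e-9)

    def test_label_outside_classes_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            fs.confusion(["A"], ["Z"], ["A", "B"])


class TestSelectComponents:
    @pytest.mark.parametrize(
        "accs, expected",
        [([80, 94, 94, 90], 2), ([70, 80, 90, 95], 4), ([88], 1)],
    )
    def test_peak_with_tie_toward_fewer(self, accs, expected):
        curve = fs.AccuracyCurve(
            components=list(range(1, len(accs) + 1)),
            mean_accuracy=np.array(accs, float),
            sd_accuracy=np.array([]),
            n_evaluations=1,
        )
        assert fs.select_components(curve) == expected


class TestRepeatedCV:
    def test_toy_bookkeeping(self, small_grid):
        """repeats=1, k=2 on 4 samples: exactly 2 fold accuracies averaged."""
        rng = np.random.default_rng(0)
        X = rng.random((4, len(small_grid)))
        metas = [
            fs.SampleMeta(f"a{i}", ["A", "B"][i % 2], False, "s1", 1, 1)
            for i in range(4)
        ]
        s = fs.SpectraSet(small_grid, X, metas)
        cfg = fs.EvalConfig(k_folds=2, repeats=1, components_range=(1,), seed=0)
        curve = fs.repeated_cv(s, cfg, "type")
        assert curve.n_evaluations == 2
        assert len(curve.records) == 2
        assert curve.mean_accuracy[0] == pytest.approx(
            curve.records["accuracy"].mean()
        )

    def test_separable_data_high_accuracy(self, separable_preprocessed):
        cfg = fs.EvalConfig(k_folds=5, repeats=2, components_range=(2,), seed=1)
        curve = fs.repeated_cv(separable_preprocessed, cfg, "type")
        assert curve.mean_accuracy[0] >= 95.0

    def test_permuted_labels_fall_to_baseline(self, separable_preprocessed):
        """Destroying the label-spectrum link leaves accuracy at the ZeroR level."""
        s = separable_preprocessed
        rng = np.random.default_rng(17)
        # shuffling the rows while keeping metadata order severs the link
        s_perm = fs.SpectraSet(s.grid, s.matrix[rng.permutation(s.n_rows)], list(s.metas))
        cfg = fs.EvalConfig(k_folds=5, repeats=3, components_range=(2,), seed=2)
        curve = fs.repeated_cv(s_perm, cfg, "type")
        base = fs.zeror([m.type_label for m in s.metas])
        assert abs(curve.mean_accuracy[0] - base) <= max(3 * curve.sd_accuracy[0], 5.0)

    def test_fixed_seed_bit_reproducible(self, separable_preprocessed):
        cfg = fs.EvalConfig(k_folds=5, repeats=2, components_range=(1, 2), seed=5)
        c1 = fs.repeated_cv(separable_preprocessed, cfg, "type")
        c2 = fs.repeated_cv(separable_preprocessed, cfg, "type")
        np.testing.assert_array_equal(c1.mean_accuracy, c2.mean_accuracy)
        assert c1.records.equals(c2.records)

    def test_seed_changes_partition_not_conclusion(self, separable_preprocessed):
        cfg_a = fs.EvalConfig(k_folds=5, repeats=2, components_range=(2,), seed=5)
        cfg_b = fs.EvalConfig(k_folds=5, repeats=2, components_range=(2,), seed=99)
        ca = fs.repeated_cv(separable_preprocessed, cfg_a, "type")
        cb = fs.repeated_cv(separable_preprocessed, cfg_b, "type")
        spread = max(3 * max(ca.sd_accuracy[0], cb.sd_accuracy[0]), 1.0)
        assert abs(ca.mean_accuracy[0] - cb.mean_accuracy[0]) <= spread

    def test_folds_disjoint_and_exhaustive(self, separable_preprocessed):
        s = separable_preprocessed
        labels = [m.type_label for m in s.metas]
        cfg = fs.EvalConfig(k_folds=5, repeats=1, seed=3)
        seen = []
        for train_idx, test_idx in _splits(labels, s.metas, cfg, cfg.seed):
            assert set(train_idx).isdisjoint(test_idx)
            assert len(set(train_idx) | set(test_idx)) == s.n_rows
            seen.extend(test_idx)
        assert sorted(seen) == list(range(s.n_rows))

    def test_specimen_folds_never_split_a_specimen(self, separable_preprocessed):
        s = separable_preprocessed
        labels = [m.type_label for m in s.metas]
        cfg = fs.EvalConfig(k_folds=4, repeats=1, fold_unit="specimen", seed=3)
        for train_idx, test_idx in _splits(labels, s.metas, cfg, cfg.seed):
            train_specs = {s.metas[i].specimen_id for i in train_idx}
            test_specs = {s.metas[i].specimen_id for i in test_idx}
            assert train_specs.isdisjoint(test_specs)

    def test_class_too_small_to_stratify(self, small_grid):
        rng = np.random.default_rng(0)
        metas = [
            fs.SampleMeta(f"a{i}", "A" if i < 3 else "B", False, "s1", 1, 1)
            for i in range(20)
        ]
        s = fs.SpectraSet(small_grid, rng.random((20, len(small_grid))), metas)
        with pytest.raises(ValueError, match="stratify"):
            fs.repeated_cv(s, fs.EvalConfig(k_folds=5, repeats=1), "type")

    def test_cv_beats_zeror_on_separable_data(self, separable_preprocessed):
        s = separable_preprocessed
        cfg = fs.EvalConfig(k_folds=5, repeats=2, components_range=(2,), seed=1)
        curve = fs.repeated_cv(s, cfg, "type")
        assert curve.mean_accuracy[0] >= fs.zeror([m.type_label for m in s.metas])


class TestIntersession:
    def test_shared_session_rejected(self, separable_preprocessed):
        cfg = fs.EvalConfig(components_range=(1, 2))
        with pytest.raises(ValueError, match="share session"):
            fs.intersession_eval(separable_preprocessed, separable_preprocessed, cfg)

    def test_identical_conditions_control(self):
        """Zero session shift: inter-session accuracy tracks within-session CV."""
        cfg = fs.SimConfig(
            grid=fs.WavelengthGrid.linspace(380, 700, 128),
            n_per_type=10,
            noise_sd=0.01,
            specimen_jitter_sd=0.02,
            signatures=(
                fs.ClassSignature("alpha", ((520.0, 25.0, 0.30),)),
                fs.ClassSignature("beta", ((620.0, 25.0, 0.30),)),
            ),
            sessions=(
                fs.SessionEffect("session1", seed_offset=0),
                fs.SessionEffect("session2", seed_offset=5),
            ),
            seed=23,
        )
        s1, s2 = [fs.preprocess_pipeline(fs.average_scans(x)) for x in fs.generate_dataset(cfg)]
        ecfg = fs.EvalConfig(k_folds=5, repeats=2, components_range=(2,), seed=0)
        cv = fs.repeated_cv(s1, ecfg, "type")
        inter = fs.intersession_eval(s1, s2, ecfg, "type")
        assert abs(inter.mean_accuracy[0] - cv.mean_accuracy[0]) <= 2.0

    def test_constant_offset_removed_by_preprocessing(self):
        """A flat ambient offset is cancelled by zero correction, so the
        inter-session curve is identical to the no-offset control."""
        base_sessions = (
            fs.SessionEffect("session1", seed_offset=0),
            fs.SessionEffect("session2", seed_offset=5),
        )
        offset_sessions = (
            fs.SessionEffect("session1", seed_offset=0),
            fs.SessionEffect("session2", additive_offset=(0.5,), seed_offset=5),
        )
        kw = dict(
            grid=fs.WavelengthGrid.linspace(380, 700, 128),
            n_per_type=8,
            noise_sd=0.01,
            signatures=(
                fs.ClassSignature("alpha", ((520.0, 25.0, 0.30),)),
                fs.ClassSignature("beta", ((620.0, 25.0, 0.30),)),
            ),
            seed=29,
        )
        ecfg = fs.EvalConfig(components_range=(1, 2, 3))
        curves = []
        for sessions in (base_sessions, offset_sessions):
            s1, s2 = [
                fs.preprocess_pipeline(fs.average_scans(x))
                for x in fs.generate_dataset(fs.SimConfig(sessions=sessions, **kw))
            ]
            curves.append(fs.intersession_eval(s1, s2, ecfg, "type"))
        np.testing.assert_allclose(
            curves[0].mean_accuracy, curves[1].mean_accuracy, atol=1e-9
        )

    def test_grid_mismatch_rejected(self, separable_preprocessed, small_grid):
        other = fs.SpectraSet(
            fs.WavelengthGrid.linspace(380, 700, 64),
            np.ones((2, 64)),
            [fs.SampleMeta("x", "alpha", False, "s9", 1, 1) for _ in range(2)],
        )
        with pytest.raises(ValueError, match="grid"):
            fs.intersession_eval(separable_preprocessed, other, fs.EvalConfig())
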