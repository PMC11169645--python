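"""Metrics, training contract, group-difference maps, window sweep."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from astnet.evaluation import (
    EvalMetrics,
    TrainSettings,
    evaluate,
    group_difference_maps,
    predict,
    train,
    window_sweep,
)
from astnet.model import ASTNet, ModelConfig
from astnet.synthetic import CohortSpec, generate_cohort
from astnet.windowing import RoiTimeSeries

from _oracles import welch_ttest_oracle


class TestEvalMetrics:
    def test_worked_example(self):
        m = EvalMetrics(tp=3, tn=2, fp=1, fn=2)
        assert round(m.acc, 1) == 62.5
        assert round(m.sen, 1) == 60.0
        assert round(m.spe, 1) == 66.7

    def test_perfect_predictions(self):
        m = EvalMetrics.from_predictions([0, 0, 1, 1], [0, 0, 1, 1])
        assert m.acc == m.sen == m.spe == 100.0

    def test_zero_denominator_warns_and_reports_nan(self):
        with pytest.warns(UserWarning, match="SEN undefined"):
            m = EvalMetrics(tp=0, tn=4, fp=1, fn=0)
        assert np.isnan(m.sen) and not np.isnan(m.acc)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_identities_hold_for_all_confusion_tables(self, counts):
        tp, tn, fp, fn = counts
        if tp + tn + fp + fn == 0 or tp + fn == 0 or tn + fp == 0:
            return
        m = EvalMetrics(tp=tp, tn=tn, fp=fp, fn=fn)
        assert m.acc == pytest.approx(100 * (tp + tn) / (tp + tn + fp + fn))
        assert m.sen == pytest.approx(100 * tp / (tp + fn))
        assert m.spe == pytest.approx(100 * tn / (tn + fp))

    def test_matches_brute_force_tally(self, rng):
        y_true = rng.integers(0, 2, size=20)
        y_pred = rng.integers(0, 2, size=20)
        m = EvalMetrics.from_predictions(y_true, y_pred)
        tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for t, p in zip(y_true, y_pred):
            key = ("t" if t == p else "f") + ("p" if p == 1 else "n")
            tally[key] += 1
        assert (m.tp, m.tn, m.fp, m.fn) == (
            tally["tp"], tally["tn"], tally["fp"], tally["fn"]
        )


class TestTrainContract:
    def test_rejects_degenerate_cohorts(self, tiny_config, tiny_cohort):
        model = ASTNet(tiny_config, n_timepoints=40)
        with pytest.raises(ValueError, match="empty"):
            train(model, [], TrainSettings(max_epochs=1))
        single_class = [s for s in tiny_cohort if s.label == 0]
        with pytest.raises(ValueError, match="both classes"):
            train(model, single_class, TrainSettings(max_epochs=1))

    def test_history_csv_roundtrip(self, tiny_config, tiny_cohort, tmp_path):
        model = ASTNet(tiny_config, n_timepoints=40)
        history = train(model, tiny_cohort, TrainSettings(max_epochs=2, seed=1),
                        history_path=tmp_path / "history.csv")
        reloaded = pd.read_csv(tmp_path / "history.csv")
        pd.testing.assert_frame_equal(history, reloaded)

    def test_evaluate_counts_every_subject(self, tiny_config, tiny_cohort):
        model = ASTNet(tiny_config, n_timepoints=40)
        m = evaluate(model, tiny_cohort)
        assert m.tp + m.tn + m.fp + m.fn == len(tiny_cohort)
        preds = predict(model, tiny_cohort).argmax(axis=1)
        labels = np.array([s.label for s in tiny_cohort])
        ref = EvalMetrics.from_predictions(labels, preds)
        assert (m.tp, m.tn, m.fp, m.fn) == (ref.tp, ref.tn, ref.fp, ref.fn)


@pytest.fixture(scope="module")
def effect_cohort():
    return generate_cohort(CohortSpec(n_subjects_per_group=40, seed=13))


class TestGroupDifferenceMaps:
    def test_identical_groups_give_all_ones(self):
        rng = np.random.default_rng(0)
        base = [rng.normal(size=(6, 40)) for _ in range(4)]
        cohort = [RoiTimeSeries(f"a{i}", d, 0) for i, d in enumerate(base)]
        cohort += [RoiTimeSeries(f"b{i}", d, 1) for i, d in enumerate(base)]
        maps, static = group_difference_maps(cohort, source="pearson",
                                             window_length=20)
        for m in maps + [static]:
            np.testing.assert_allclose(m.p_values, 1.0, atol=1e-12)
            assert m.binarized.min() == 1

    def test_pvalue_matches_welch_oracle(self, effect_cohort):
        maps, _ = group_difference_maps(effect_cohort, source="pearson",
                                        window_length=20)
        from astnet.evaluation import _windowed_pearson_cohort

        fc = _windowed_pearson_cohort(effect_cohort, 20)
        labels = np.array([s.label for s in effect_cohort])
        seg, i, j = 7, 0, 5
        expected = welch_ttest_oracle(fc[labels == 0, seg, i, j],
                                      fc[labels == 1, seg, i, j])
        assert maps[seg].p_values[i, j] == pytest.approx(expected, abs=1e-10)

    def test_planted_edges_detected_in_affected_segments(self, effect_cohort):
        from astnet.synthetic import ground_truth_diff_mask

        spec = CohortSpec(n_subjects_per_group=40, seed=13)
        mask = ground_truth_diff_mask(spec)[1]
        maps, _ = group_difference_maps(effect_cohort, source="pearson",
                                        window_length=20)
        affected = maps[6:]  # state 1 covers the last six windows
        iu = np.triu_indices(20, 1)
        planted = mask[iu] == 1
        hit = np.mean([(m.binarized[iu][planted] == 0).mean() for m in affected])
        false = np.mean([(m.binarized[iu][~planted] == 0).mean() for m in affected])
        assert hit >= 0.8
        assert false <= 0.10

    def test_permuted_labels_flag_about_five_percent(self, effect_cohort):
        rng = np.random.default_rng(99)
        labels = rng.permutation([s.label for s in effect_cohort])
        shuffled = [RoiTimeSeries(s.subject_id, s.data, int(l))
                    for s, l in zip(effect_cohort, labels)]
        maps, _ = group_difference_maps(shuffled, source="pearson",
                                        window_length=20)
        iu = np.triu_indices(20, 1)
        rate = np.mean([(m.binarized[iu] == 0).mean() for m in maps])
        assert 0.02 < rate < 0.08

    def test_group_size_and_source_validation(self, tiny_cohort):
        with pytest.raises(ValueError, match="at least 2"):
            group_difference_maps(tiny_cohort[:1] + tiny_cohort[-2:],
                                  source="pearson", window_length=10)
        with pytest.raises(ValueError, match="source"):
            group_difference_maps(tiny_cohort, source="magic")
        with pytest.raises(ValueError, match="window_length"):
            group_difference_maps(tiny_cohort, source="pearson")

    def test_model_source_uses_learned_connectivity(self, tiny_config,
                                                    tiny_cohort):
        model = ASTNet(tiny_config, n_timepoints=40)
        maps, static = group_difference_maps(tiny_cohort, model=model,
                                             source="model")
        assert len(maps) == 4 and maps[0].p_values.shape == (6, 6)
        assert static.segment_index == -1


class TestWindowSweep:
    def test_segment_counts_follow_floor_arithmetic(self):
        spec = CohortSpec(n_subjects_per_group=6, n_rois=6, n_timepoints=231,
                          window_length=20, effect_edges=[(0, 3)], seed=2)
        cohort = generate_cohort(spec)
        config = ModelConfig(n_rois=6, gcn_dims=(4,), mlp_dims=(8, 4),
                             gru_units=2, gru_layers=1, head_dims=(4, 2), seed=0)
        frame = window_sweep(
            cohort, [10, 15, 20, 25, 30, 300], config,
            TrainSettings(max_epochs=1, seed=0), test_fraction=0.34,
        )
        assert list(frame.window_length) == [10, 15, 20, 25, 30]  # 300 skipped
        assert list(frame.n_segments) == [23, 15, 11, 9, 7]
        assert set(frame.columns) >= {"acc", "sen", "spe"}
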