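"""Windowing, per-window normalization, run-wise folds, EDF and labels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aesmbe.data import (
    OTHER_SUBJECT,
    PRETRAINING_TEMPLATE,
    REGISTRATION_TEMPLATE,
    Run,
    SplitTemplate,
    Window,
    check_no_leakage,
    degenerate_channels,
    make_folds,
    normalize_window,
    read_edf_run,
    relabel_for_pretraining,
    segment_run,
    task_for_run_index,
)


class TestNormalization:
    def test_hand_case_population_sigma(self):
        out = normalize_window(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out[0], [-1.224744871, 0.0, 1.224744871], atol=1e-8)

    def test_constant_channel_zeros_and_flag(self):
        raw = np.array([[5.0, 5.0, 5.0, 5.0], [0.0, 1.0, 0.0, 1.0]])
        out = normalize_window(raw)
        np.testing.assert_array_equal(out[0], np.zeros(4))
        assert not np.isnan(out).any()
        np.testing.assert_array_equal(degenerate_channels(raw), [True, False])

    @given(
        st.integers(0, 2**31 - 1),
        st.integers(1, 6),
        st.integers(2, 64),
    )
    @settings(max_examples=50, deadline=None)
    def test_moments_and_idempotence(self, seed, channels, h):
        raw = np.random.default_rng(seed).standard_normal((channels, h)) * 7 + 3
        out = normalize_window(raw)
        ok = ~degenerate_channels(raw)
        assert np.abs(out[ok].mean(axis=1)).max(initial=0.0) < 1e-6
        assert np.abs(out[ok].std(axis=1) - 1).max(initial=0.0) < 1e-6
        np.testing.assert_allclose(normalize_window(out), out, atol=1e-6)


class TestSegmentation:
    def _run(self, n_samples, subject=1, run_index=3):
        rng = np.random.default_rng(0)
        return Run(
            subject_id=subject,
            run_index=run_index,
            task=task_for_run_index(run_index),
            data=rng.standard_normal((3, n_samples)),
            fs=160.0,
        )

    def test_window_count_and_remainder(self):
        windows = segment_run(self._run(1000), H=160)
        assert len(windows) == 6
        assert all(w.H == 160 for w in windows)

    def test_single_window_and_short_run(self):
        assert len(segment_run(self._run(160), H=160)) == 1
        with pytest.warns(UserWarning):
            assert segment_run(self._run(100), H=160) == []

    def test_label_inheritance(self):
        for w in segment_run(self._run(500, subject=7, run_index=4), H=160):
            assert (w.subject_id, w.task, w.run_index) == (7, "motor_imagery", 4)


class TestFolds:
    def _runs(self, n=14):
        rng = np.random.default_rng(1)
        return [
            Run(
                subject_id=0,
                run_index=i,
                task=task_for_run_index(i),
                data=rng.standard_normal((2, 480)),
                fs=160.0,
            )
            for i in range(1, n + 1)
        ]

    def test_pretraining_fold_sizes(self):
        folds = make_folds(self._runs(), PRETRAINING_TEMPLATE)
        train_w, test_w = folds[0]
        assert len({w.run_index for w in train_w}) == 9
        assert len({w.run_index for w in test_w}) == 5
        assert {w.run_index for w in train_w} & {w.run_index for w in test_w} == set()

    def test_registration_fold_sizes(self):
        for train_w, test_w in make_folds(self._runs(), REGISTRATION_TEMPLATE):
            assert len({w.run_index for w in test_w}) == 4
            assert len({w.run_index for w in train_w}) == 10

    def test_window_count_conservation(self):
        runs = self._runs()
        expected = sum(r.n_samples // 160 for r in runs)
        for train_w, test_w in make_folds(runs, PRETRAINING_TEMPLATE):
            assert len(train_w) + len(test_w) == expected

    def test_no_leakage_everywhere_and_negative_control(self):
        folds = make_folds(self._runs(), PRETRAINING_TEMPLATE)
        for train_w, test_w in folds:
            assert check_no_leakage(train_w, test_w) == set()
        # deliberately corrupt: copy one test-run window into the train side
        train_w, test_w = folds[0]
        assert check_no_leakage(train_w + [test_w[0]], test_w) == {
            (test_w[0].subject_id, test_w[0].run_index)
        }

    def test_overlapping_template_rejected(self):
        with pytest.raises(ValueError):
            SplitTemplate(stage="x", folds=(((1, 2, 3), (3, 4)),))

    def test_missing_run_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            make_folds(self._runs(10), PRETRAINING_TEMPLATE)


class TestEDF:
    def test_round_trip(self, edf_file):
        path, data = edf_file
        run = read_edf_run(path, subject_id=1, run_index=1)
        assert run.data.shape == (4, 320)
        assert run.fs == 160.0
        assert run.task == "rest"
        # EDF stores int16-quantized physical values; the reader may rescale
        # to SI units, so compare after a least-squares scale match
        scale = float(
            (run.data * data).sum() / (run.data**2).sum()
        )
        np.testing.assert_allclose(run.data * scale, data, atol=0.01)

    def test_task_convention(self):
        assert [task_for_run_index(i) for i in (1, 2, 3, 4, 13, 14)] == [
            "rest",
            "rest",
            "motor_execution",
            "motor_imagery",
            "motor_execution",
            "motor_imagery",
        ]

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.edf"):
            read_edf_run(tmp_path / "nope.edf", 1, 1)


class TestPretrainingLabels:
    def _windows(self, subject, n, task="rest"):
        return [
            Window(
                data=np.zeros((2, 4)),
                subject_id=subject,
                task=task,
                run_index=1,
                window_index=i,
            )
            for i in range(n)
        ]

    def test_balancing_rule(self):
        windows = self._windows(0, 10) + self._windows(1, 25, "motor_imagery")
        kept, labels = relabel_for_pretraining(windows, target_subject=0, seed=1)
        assert len(kept) == 20
        assert (labels == OTHER_SUBJECT).sum() == 10
        assert (labels == "rest").sum() == 10
        assert len(set(labels)) <= 4

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            relabel_for_pretraining(self._windows(0, 5), target_subject=0)

    def test_absent_target_rejected(self):
        with pytest.raises(ValueError):
            relabel_for_pretraining(self._windows(0, 5), target_subject=3)

    def test_subsampling_is_seeded(self):
        windows = self._windows(0, 5) + self._windows(1, 50, "motor_execution")
        a = relabel_for_pretraining(windows, 0, seed=7)
        b = relabel_for_pretraining(windows, 0, seed=7)
        assert [w.window_index for w in a[0]] == [w.window_index for w in b[0]]
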