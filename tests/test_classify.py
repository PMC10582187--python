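"""Per-frame classifiers: specs, training, inference, segmentation."""

import numpy as np
import pytest

import tracefret as tf
from tracefret.classify import FrameClassification, smooth_labels

from conftest import smoke_config


class TestBuildModel:
    @pytest.mark.parametrize(
        "modality,task,width",
        [
            ("3c_alex", "states3", 5),
            ("2c_alex", "trace", 3),
            ("2c_alex", "states2", 2),
            ("1c", "states2", 1),
            ("3c_alex", "trace", 6),
        ],
    )
    def test_input_widths(self, modality, task, width):
        assert tf.build_model(modality, task).n_input_channels == width

    def test_n_states_classes(self):
        spec = tf.build_model("1c", "n_states")
        assert spec.class_names == (2, 3, 4)

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError, match="task"):
            tf.build_model("2c_alex", "states5")


class TestTraining:
    def test_overfit_ten_traces_loss_decreases(self):
        ds = tf.generate_dataset(
            smoke_config(n_traces=10, seed=1, dynamic_only=True, n_states=2)
        )
        model = tf.train_model(
            tf.build_model("2c_alex", "states2"), ds,
            tf.TrainConfig(seed=0, max_epochs=15, early_stopping=False),
        )
        loss = model.history["loss_curve"]
        assert loss[-1] < loss[0]
        assert model.history["train_accuracy"] > 0.9

    def test_separable_noise_free_data_fit_to_99pct(self):
        """200 clean two-state traces reach >99% training accuracy fast."""
        ds = tf.generate_dataset(
            smoke_config(n_traces=200, seed=2, dynamic_only=True, n_states=2,
                         snr_range=(200.0, 200.0))
        )
        model = tf.train_model(
            tf.build_model("2c_alex", "states2"), ds,
            tf.TrainConfig(seed=0, max_epochs=20, max_train_frames=60_000),
        )
        assert model.history["train_accuracy"] > 0.99

    def test_missing_state_class_raises(self):
        ds = tf.generate_dataset(
            smoke_config(n_traces=30, seed=3, dynamic_only=True, n_states=2)
        )
        with pytest.raises(ValueError, match="states3|absent"):
            tf.train_model(tf.build_model("2c_alex", "states3"), ds)


class TestInference:
    def test_probability_rows_are_distributions(self, states2_model):
        ds = tf.generate_dataset(
            smoke_config(n_traces=3, seed=4, dynamic_only=True, n_states=2)
        )
        for tr in ds:
            prob = states2_model.predict_proba_frames(tr.channels[:, [0, 1]])
            assert prob.shape == (tr.n_frames, 2)
            assert np.allclose(prob.sum(axis=1), 1.0, atol=1e-6)
            assert np.all(prob >= 0)

    def test_noise_free_segment_decoded_exactly(self, states2_model):
        ds = tf.generate_dataset(
            smoke_config(n_traces=5, seed=5, dynamic_only=True, n_states=2,
                         snr_range=(500.0, 500.0))
        )
        for tr in ds:
            sc = tf.classify_states(states2_model, tr.channels[:, [0, 1]])
            pure = tr.pure_frames & (tr.states > 0)
            assert (sc.states[pure] == tr.states[pure]).mean() == 1.0

    def test_state_confidence_decreases_with_noise(self, states2_model):
        confs = []
        for snr in (20.0, 2.0, 0.5):
            ds = tf.generate_dataset(
                smoke_config(n_traces=10, seed=6, dynamic_only=True, n_states=2,
                             snr_range=(snr, snr))
            )
            p = [tf.classify_states(states2_model, t.channels[:, [0, 1]]).confidence
                 for t in ds]
            confs.append(np.mean(p))
        assert confs[0] > confs[1] > confs[2]

    def test_accuracy_monotone_on_snr_ladder(self, states2_model):
        """Validation accuracy is non-increasing as SNR drops (tol 1 point)."""
        accs = []
        for snr in (20.0, 8.0, 2.0):
            ds = tf.generate_dataset(
                smoke_config(n_traces=30, seed=7, dynamic_only=True, n_states=2,
                             snr_range=(snr, snr))
            )
            accs.append(tf.evaluate_confusion(states2_model, ds).accuracy)
        assert accs[0] >= accs[1] - 0.01
        assert accs[1] >= accs[2] - 0.01

    def test_confidence_threshold_above_one_rejects_everything(self, trace_model):
        ds = tf.generate_dataset(smoke_config(n_traces=5, seed=8))
        for tr in ds:
            fc = tf.classify_frames(trace_model, tr, threshold=1.01)
            assert not fc.accepted
            assert 0.0 <= fc.confidence <= 1.0

    def test_fully_bleached_frames_called_bleached(self, trace_model):
        km = tf.KineticModel(1, np.zeros((1, 1)), {"DA": np.array([0.6])})
        pm = tf.PhotophysicsModel({"D": 0.0, "A": 0.0}, {"D": 1000.0, "A": 900.0})
        det = tf.DetectionModel.ideal("2c_alex")
        rng = np.random.default_rng(9)
        occ = np.ones((300, 1))
        tr = tf.render_trace(occ, km, pm, det, "2c_alex", rng, 0.05, snr=15.0,
                             bleach_time_s={"D": 4.0, "A": 2.0})
        fc = tf.classify_frames(trace_model, tr, threshold=0.0)
        alphabet = tf.CategoryAlphabet("2c_alex")
        tail = fc.labels[150:]
        assert (tail == alphabet.index("bleached")).mean() > 0.5


class TestSegmentation:
    def _fc(self, codes):
        alphabet = tf.CategoryAlphabet("2c_alex")
        n = len(codes)
        prob = np.zeros((n, len(alphabet)))
        prob[np.arange(n), codes] = 1.0
        return FrameClassification(prob=prob, labels=np.asarray(codes),
                                   class_names=alphabet.labels, confidence=1.0,
                                   accepted=True, threshold=0.9)

    def test_bleach_frames_from_constructed_labels(self):
        alphabet = tf.CategoryAlphabet("2c_alex")
        codes = ([alphabet.index("DA-dynamic")] * 100
                 + [alphabet.index("D-only")] * 50
                 + [alphabet.index("bleached")] * 50)
        segs = tf.segment_trace(self._fc(codes))
        assert segs.analysis == (0, 100)
        assert segs.dynamic
        assert segs.bleach_frame == {"D": 150, "A": 100}
        assert segs.background == (150, 200)

    def test_all_noisy_trace_has_no_segments(self):
        alphabet = tf.CategoryAlphabet("2c_alex")
        segs = tf.segment_trace(self._fc([alphabet.index("noisy")] * 120))
        assert segs.junk and segs.analysis is None

    def test_single_frame_flicker_removed_by_smoothing(self):
        alphabet = tf.CategoryAlphabet("2c_alex")
        codes = np.array([alphabet.index("DA-dynamic")] * 80)
        codes[40] = alphabet.index("A-only")
        smoothed = smooth_labels(codes, min_run=3)
        # oracle: a majority filter of width 3 removes the island
        assert np.all(smoothed == alphabet.index("DA-dynamic"))
        segs = tf.segment_trace(self._fc(codes))
        assert segs.analysis == (0, 80)


class TestConfusion:
    def test_confusion_rows_normalized(self, states2_model):
        ds = tf.generate_dataset(
            smoke_config(n_traces=30, seed=10, dynamic_only=True, n_states=2)
        )
        rep = tf.evaluate_confusion(states2_model, ds)
        assert np.allclose(rep.confusion.sum(axis=1), 1.0)
        assert 0.9 < rep.accuracy <= 1.0

    def test_match_accuracy_handles_permuted_labels(self):
        truth = np.array([1, 1, 2, 2, 1])
        flipped = np.array([2, 2, 1, 1, 2])
        assert tf.match_accuracy(flipped, truth, 2) == 1.0


class TestNStates:
    @pytest.fixture(scope="class")
    def n_states_model(self):
        ds = tf.generate_dataset(
            smoke_config(n_traces=700, seed=13, dynamic_only=True,
                         dwell_range_frames=(10.0, 40.0), n_frames=800)
        )
        return tf.train_model(tf.build_model("2c_alex", "n_states"), ds,
                              tf.TrainConfig(seed=0, max_epochs=80))

    def test_probabilities_sum_to_one_and_route(self, n_states_model):
        ds = tf.generate_dataset(
            smoke_config(n_traces=4, seed=14, dynamic_only=True, n_states=3,
                         dwell_range_frames=(10.0, 40.0))
        )
        for tr in ds:
            p = tf.predict_n_states(n_states_model, tr.channels[:, [0, 1]])
            assert p.shape == (3,)
            assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_better_than_chance_on_held_out(self, n_states_model):
        ds = tf.generate_dataset(
            smoke_config(n_traces=60, seed=15, dynamic_only=True,
                         dwell_range_frames=(10.0, 40.0), n_frames=800)
        )
        correct = total = 0
        for tr in ds:
            k = tr.kinetic_model.n_states
            p = tf.predict_n_states(n_states_model, tr.channels[:, [0, 1]])
            correct += int((2, 3, 4)[int(np.argmax(p))] == k)
            total += 1
        assert correct / total > 0.6


def test_benchmark_zero_contrast_near_chance(states2_model):
    df = tf.benchmark_vs_hmm(
        states2_model, snr_values=(10.0,), contrast_values=(0.0,),
        dwell_frames_values=(20.0,), n_traces=6, n_frames=200, seed=0,
    )
    row = df.iloc[0]
    assert row.classifier_accuracy < 0.75
    assert row.hmm_accuracy < 0.85  # best-permutation floor is 0.5
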