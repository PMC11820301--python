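import numpy as np
import pytest

from vagpipe import CNNConfig, Recording, RecordingMeta, build_cnn, cwt_scalogram, scalogram_to_input, train_cnn
from vagpipe._cnn import conv_output_size, softmax
from vagpipe.signal_model import InvalidInputError
from vagpipe.tfr_classify import SplitError, stratified_subject_split


def tone_recording(freq, fs=1000.0, duration=2.0, subject="t"):
    t = np.arange(int(fs * duration)) / fs
    return Recording(
        samples=np.sin(2 * np.pi * freq * t), fs=fs, meta=RecordingMeta(subject_id=subject)
    )


class TestCwtScalogram:
    def test_tone_localised_on_frequency_axis(self):
        s = cwt_scalogram(tone_recording(50.0), n_scales=64, f_min=5.0, f_max=200.0)
        row = s.magnitude.mean(axis=1).argmax()
        grid_step = s.freqs_hz[row + 1] / s.freqs_hz[row]
        assert 50.0 / grid_step <= s.freqs_hz[row] <= 50.0 * grid_step

    def test_zero_signal_zero_magnitude(self):
        rec = Recording(samples=np.zeros(1000), fs=1000.0)
        s = cwt_scalogram(rec, n_scales=16)
        assert np.allclose(s.magnitude, 0.0)

    def test_magnitude_homogeneity(self):
        rec = tone_recording(30.0)
        s1 = cwt_scalogram(rec, n_scales=16)
        s2 = cwt_scalogram(rec.with_samples(2 * rec.samples), n_scales=16)
        np.testing.assert_allclose(s2.magnitude, 2 * s1.magnitude, rtol=1e-9)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(InvalidInputError):
            cwt_scalogram(tone_recording(10.0), n_scales=16, f_min=1.0, f_max=600.0)


class TestScalogramToInput:
    def test_output_shape_and_range(self):
        s = cwt_scalogram(tone_recording(20.0), n_scales=32)
        img = scalogram_to_input(s, (64, 64))
        assert img.shape == (64, 64)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_constant_magnitude_maps_to_zeros(self):
        from vagpipe.tfr_classify import Scalogram

        s = Scalogram(
            magnitude=np.full((16, 100), 3.0),
            freqs_hz=np.geomspace(1, 100, 16),
            times_s=np.arange(100) / 1000.0,
            source_meta=RecordingMeta(subject_id="c"),
        )
        assert np.all(scalogram_to_input(s, (32, 32)) == 0.0)

    def test_argmax_row_preserved_before_resize(self):
        s = cwt_scalogram(tone_recording(50.0), n_scales=64, f_min=5.0, f_max=200.0)
        raw_row = s.magnitude.mean(axis=1).argmax()
        img = scalogram_to_input(s, s.magnitude.shape)  # no resize
        assert img.mean(axis=1).argmax() == raw_row


class TestBuildCnn:
    def test_conv_output_spatial_size(self):
        assert conv_output_size(128, 5, 2) == 64

    def test_parameter_count_closed_form(self):
        cfg = CNNConfig(input_size=(128, 128))
        model = build_cnn(cfg)
        flat = 32 * 32 * 10
        expected = (5 * 5 * 1 * 10 + 10) + (flat * 2 + 2)
        assert model.parameter_count == expected

    def test_softmax_normalisation(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((7, 2)) * 10
        np.testing.assert_allclose(softmax(z).sum(axis=1), 1.0, atol=1e-6)

    def test_input_smaller_than_filter_rejected(self):
        with pytest.raises(ValueError):
            build_cnn(CNNConfig(input_size=(3, 3)))


class TestSplit:
    def test_subject_disjoint_and_deterministic(self):
        labels = np.array([0] * 20 + [1] * 20)
        subjects = [f"s{i}" for i in range(40)]
        tr1, va1, te1 = stratified_subject_split(labels, subjects, (0.7, 0.2, 0.1), seed=4)
        tr2, va2, te2 = stratified_subject_split(labels, subjects, (0.7, 0.2, 0.1), seed=4)
        np.testing.assert_array_equal(tr1, tr2)
        np.testing.assert_array_equal(te1, te2)
        all_sets = [set(np.asarray(subjects)[idx]) for idx in (tr1, va1, te1)]
        assert not (all_sets[0] & all_sets[1] | all_sets[0] & all_sets[2] | all_sets[1] & all_sets[2])

    def test_each_split_contains_both_classes(self):
        labels = np.array([0] * 15 + [1] * 15)
        subjects = [f"s{i}" for i in range(30)]
        for idx in stratified_subject_split(labels, subjects, (0.7, 0.2, 0.1), seed=0):
            assert set(labels[idx]) == {0, 1}

    def test_too_few_subjects_raises(self):
        with pytest.raises(SplitError):
            stratified_subject_split(np.array([0, 0, 1, 1]), ["a", "b", "c", "d"], (0.7, 0.2, 0.1), 0)


def _banded_dataset(rng, n_per_class=20, size=64):
    """Two classes with energy in disjoint row bands: perfectly separable."""
    X = 0.05 * rng.random((2 * n_per_class, size, size))
    y = np.repeat([0, 1], n_per_class)
    X[:n_per_class, 10:20, :] += 0.9
    X[n_per_class:, 40:50, :] += 0.9
    subjects = [f"s{i}" for i in range(2 * n_per_class)]
    return X, y, subjects


class TestTrainCnn:
    def test_separable_classes_high_accuracy(self):
        rng = np.random.default_rng(1)
        X, y, subjects = _banded_dataset(rng)
        cfg = CNNConfig(repetitions=2, seed=2, input_size=(64, 64), batch_size=8)
        res = train_cnn(X, y, subjects, cfg)
        assert res.accuracy["testing"] >= 0.95
        assert res.confusion.sum() == len(res.split_subjects["test"])

    def test_permuted_labels_chance_level(self):
        rng = np.random.default_rng(2)
        X, y, subjects = _banded_dataset(rng)
        yp = rng.permutation(y)
        cfg = CNNConfig(repetitions=2, seed=2, input_size=(64, 64), batch_size=8)
        res = train_cnn(X, yp, subjects, cfg)
        assert 0.35 <= res.accuracy["testing"] <= 0.65 + 1e-9

    def test_split_reproducible_across_calls(self):
        rng = np.random.default_rng(3)
        X, y, subjects = _banded_dataset(rng, n_per_class=12)
        cfg = CNNConfig(repetitions=1, seed=9, input_size=(64, 64))
        r1 = train_cnn(X, y, subjects, cfg)
        r2 = train_cnn(X, y, subjects, cfg)
        assert r1.split_subjects == r2.split_subjects

    def test_too_few_examples_rejected(self):
        rng = np.random.default_rng(4)
        X = rng.random((10, 64, 64))
        y = np.repeat([0, 1], 5)
        with pytest.raises(InvalidInputError):
            train_cnn(X, y, [f"s{i}" for i in range(10)], CNNConfig(input_size=(64, 64)))
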