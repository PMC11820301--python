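"""CWT scalograms and the CNN classifier.

The reconstructed (or raw) waveform is mapped to a time-frequency image
with the analytic Morlet continuous wavelet transform on a logarithmic
frequency grid; the magnitude image, log-compressed and min-max normalised,
is the input to a small convolutional network:

    input (H x W x 1)
      -> conv, 10 filters 5x5, stride 2, 'same' padding -> ReLU
      -> max-pool 2x2, stride 2
      -> fully connected (2) -> softmax

trained with SGD (learning rate 0.001, momentum 0.26) and L2 coefficient
0.74, for at most 200 epochs with early stopping on validation accuracy,
repeated 5 times with distinct child seeds.  The 70/20/10
train/validation/test split is stratified by class and disjoint by subject
so no subject leaks across splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt
from scipy.ndimage import map_coordinates, uniform_filter

from ._cnn import SmallCNN
from .signal_model import InvalidInputError, Recording, RecordingMeta


@dataclass
class Scalogram:
    """Time-scale magnitude matrix (scales x time) with its axes."""

    magnitude: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    source_meta: RecordingMeta

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.magnitude.shape != (self.freqs_hz.size, self.times_s.size):
            raise InvalidInputError("magnitude shape must match (freqs, times)")
        if np.any(self.magnitude < 0):
            raise InvalidInputError("magnitudes must be non-negative")


MORLET = "cmor1.5-1.0"


def cwt_scalogram(
    recording: Recording,
    n_scales: int = 64,
    f_min: float = 1.0,
    f_max: float | None = None,
) -> Scalogram:
    """Analytic Morlet CWT magnitude on a log frequency grid.

    ``f_max`` defaults to a quarter of the sampling rate (half of Nyquist);
    it must not exceed the Nyquist frequency.  Frequencies are returned in
    ascending order.
    """
    nyquist = recording.fs / 2.0
    if f_max is None:
        f_max = nyquist / 2.0
    if not 0 < f_min < f_max:
        raise InvalidInputError("need 0 < f_min < f_max")
    if f_max > nyquist:
        raise InvalidInputError(f"f_max {f_max} Hz exceeds Nyquist {nyquist} Hz")
    if n_scales < 8:
        raise InvalidInputError("n_scales must be >= 8")
    freqs = np.geomspace(f_min, f_max, n_scales)
    fc = pywt.central_frequency(MORLET)
    scales = fc * recording.fs / freqs
    coef, _ = pywt.cwt(
        recording.samples, scales, MORLET, sampling_period=1.0 / recording.fs, method="fft"
    )
    # rows follow `scales`, so row j corresponds to freqs[j] (ascending)
    return Scalogram(
        magnitude=np.abs(coef),
        freqs_hz=freqs,
        times_s=recording.times,
        source_meta=recording.meta,
    )


def scalogram_to_input(s: Scalogram, input_size: tuple[int, int] = (128, 128)) -> np.ndarray:
    """Log-compress, min-max normalise to [0, 1], resize to ``input_size``.

    Downsampling is anti-aliased: each axis is box-filtered at the
    decimation factor before the bilinear interpolation, so short transients
    contribute to the output no matter where they fall between sample
    columns (plain bilinear subsampling would silently drop most of a
    sparse image's energy).
    """
    img = np.log1p(s.magnitude)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        img = np.zeros_like(img)
    h, w = input_size
    factors = (img.shape[0] / h, img.shape[1] / w)
    size = tuple(max(1, int(round(f))) for f in factors)
    if max(size) > 1:
        img = uniform_filter(img, size=size, mode="nearest")
    rows = np.linspace(0, img.shape[0] - 1, h)
    cols = np.linspace(0, img.shape[1] - 1, w)
    grid = np.meshgrid(rows, cols, indexing="ij")
    return map_coordinates(img, grid, order=1, mode="nearest")


@dataclass
class CNNConfig:
    """Architecture and training hyperparameters."""

    num_filters: int = 10
    filter_size: int = 5
    stride: int = 2
    l2_regularization: float = 0.74
    learning_rate: float = 0.001
    momentum: float = 0.26
    max_epochs: int = 200
    repetitions: int = 5
    split: tuple[float, float, float] = (0.70, 0.20, 0.10)
    input_size: tuple[int, int] = (128, 128)
    batch_size: int = 8
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise InvalidInputError("split fractions must sum to 1")
        for name in ("num_filters", "filter_size", "stride", "l2_regularization",
                     "learning_rate", "momentum", "max_epochs", "repetitions"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")


@dataclass
class TrainResult:
    """Averaged accuracies over repetitions, with per-repetition detail."""

    accuracy: dict  # {"learning": .., "validation": .., "testing": ..}
    per_repetition: list[dict]
    confusion: np.ndarray
    history: list[dict]
    split_subjects: dict

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)


def build_cnn(cfg: CNNConfig, seed: int | None = None) -> SmallCNN:
    """Instantiate the network with seeded He-normal weights."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    return SmallCNN(
        input_size=cfg.input_size,
        num_filters=cfg.num_filters,
        filter_size=cfg.filter_size,
        stride=cfg.stride,
        rng=rng,
    )


class SplitError(ValueError):
    """A class is absent from one of the train/val/test splits."""


def stratified_subject_split(
    labels: np.ndarray,
    subjects: Sequence[str],
    split: tuple[float, float, float],
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Subject-disjoint stratified indices for (train, val, test)."""
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    rng = np.random.default_rng(seed)
    assign: dict[str, int] = {}
    for cls in np.unique(labels):
        cls_subjects = np.unique(subjects[labels == cls])
        rng.shuffle(cls_subjects)
        n = cls_subjects.size
        n_test = max(1, int(round(split[2] * n)))
        n_val = max(1, int(round(split[1] * n)))
        if n_test + n_val >= n:
            raise SplitError(f"class {cls}: too few subjects ({n}) for a 3-way split")
        for s in cls_subjects[: n - n_val - n_test]:
            assign[s] = 0
        for s in cls_subjects[n - n_val - n_test : n - n_test]:
            assign[s] = 1
        for s in cls_subjects[n - n_test :]:
            assign[s] = 2
    membership = np.array([assign[s] for s in subjects])
    out = tuple(np.flatnonzero(membership == k) for k in range(3))
    for k, idx in enumerate(out):
        if np.unique(labels[idx]).size < np.unique(labels).size:
            raise SplitError(f"split part {k} is missing a class")
    return out  # type: ignore[return-value]


def _accuracy(model: SmallCNN, patches: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean(model.predict(patches) == labels))


def train_cnn(
    inputs: np.ndarray,
    labels: np.ndarray,
    subjects: Sequence[str],
    cfg: CNNConfig | None = None,
) -> TrainResult:
    """Train the classifier with the configured protocol.

    ``inputs`` is a stack (N, H, W) of normalised scalogram images.  The
    split is computed once from ``cfg.seed``; each repetition re-initialises
    the network and the shuffling from an independent child seed and keeps
    the weights of its best validation epoch.  Needs at least 10 examples
    per class.
    """
    cfg = cfg or CNNConfig()
    inputs = np.asarray(inputs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < 10:
        raise InvalidInputError(f"need >= 10 examples per class, got {counts.tolist()}")
    tr, va, te = stratified_subject_split(labels, subjects, cfg.split, cfg.seed)

    template = build_cnn(cfg)
    p_tr = template.prepare(inputs[tr])
    p_va = template.prepare(inputs[va])
    p_te = template.prepare(inputs[te])
    y_tr, y_va, y_te = labels[tr], labels[va], labels[te]

    child_seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.repetitions) % (2**31)
    per_rep = []
    histories = []
    confusion = np.zeros((2, 2), dtype=int)
    for rep in range(cfg.repetitions):
        rep_rng = np.random.default_rng(int(child_seeds[rep]))
        model = build_cnn(cfg, seed=int(child_seeds[rep]))
        best = {"val": -1.0, "params": model.params(), "epoch": 0}
        history = {"loss": [], "train_acc": [], "val_acc": []}
        stale = 0
        order = np.arange(len(y_tr))
        for epoch in range(cfg.max_epochs):
            rep_rng.shuffle(order)
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                loss, grads = model.loss_and_grads(p_tr[batch], y_tr[batch], cfg.l2_regularization)
                model.sgd_step(grads, cfg.learning_rate, cfg.momentum)
                losses.append(loss)
            acc_tr = _accuracy(model, p_tr, y_tr)
            acc_va = _accuracy(model, p_va, y_va)
            history["loss"].append(float(np.mean(losses)))
            history["train_acc"].append(acc_tr)
            history["val_acc"].append(acc_va)
            if acc_va > best["val"]:
                best = {"val": acc_va, "params": {k: v.copy() for k, v in model.params().items()},
                        "epoch": epoch}
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        model.set_params(best["params"])
        pred_te = model.predict(p_te)
        rep_result = {
            "learning": _accuracy(model, p_tr, y_tr),
            "validation": _accuracy(model, p_va, y_va),
            "testing": float(np.mean(pred_te == y_te)),
            "best_epoch": best["epoch"],
        }
        per_rep.append(rep_result)
        histories.append(history)
        confusion = np.zeros((2, 2), dtype=int)
        for t, p in zip(y_te, pred_te):
            confusion[t, p] += 1

    accuracy = {
        key: float(np.mean([r[key] for r in per_rep]))
        for key in ("learning", "validation", "testing")
    }
    subjects = np.asarray(subjects)
    return TrainResult(
        accuracy=accuracy,
        per_repetition=per_rep,
        confusion=confusion,
        history=histories,
        split_subjects={
            "train": sorted(set(subjects[tr])),
            "validation": sorted(set(subjects[va])),
            "test": sorted(set(subjects[te])),
        },
    )
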