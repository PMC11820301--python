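"""Compact NumPy CNN: conv -> ReLU -> max-pool -> dense -> softmax.

The network is small enough (tens of thousands of parameters, hundreds of
training images) that an explicit NumPy implementation is both fast and
fully deterministic.  Convolution is realised as a matrix product against
precomputed im2col patches: the inputs never change during training, so the
patch tensor is built once per dataset and every forward pass is two GEMMs.

Optimisation is plain SGD with momentum and L2 weight decay on the weights
(not the biases), minimising the softmax cross-entropy.
"""

from __future__ import annotations

import numpy as np


def conv_output_size(size: int, kernel: int, stride: int) -> int:
    """Spatial output size for 'same' padding: ceil(size / stride)."""
    return -(-size // stride)


def _same_padding(size: int, kernel: int, stride: int) -> tuple[int, int]:
    out = conv_output_size(size, kernel, stride)
    total = max(0, (out - 1) * stride + kernel - size)
    return total // 2, total - total // 2


def im2col(images: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """Extract conv patches: (N, H, W) -> (N, out_h*out_w, kernel*kernel)."""
    n, h, w = images.shape
    pt, pb = _same_padding(h, kernel, stride)
    pl, pr = _same_padding(w, kernel, stride)
    padded = np.pad(images, ((0, 0), (pt, pb), (pl, pr)))
    out_h = conv_output_size(h, kernel, stride)
    out_w = conv_output_size(w, kernel, stride)
    s0, s1, s2 = padded.strides
    windows = np.lib.stride_tricks.as_strided(
        padded,
        shape=(n, out_h, out_w, kernel, kernel),
        strides=(s0, s1 * stride, s2 * stride, s1, s2),
    )
    return windows.reshape(n, out_h * out_w, kernel * kernel).astype(np.float32)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallCNN:
    """One conv block and a dense softmax head for binary classification."""

    def __init__(
        self,
        input_size: tuple[int, int],
        num_filters: int = 10,
        filter_size: int = 5,
        stride: int = 2,
        n_classes: int = 2,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        h, w = input_size
        if h < filter_size or w < filter_size:
            raise ValueError(f"input {input_size} smaller than one {filter_size}x{filter_size} filter")
        self.input_size = (h, w)
        self.num_filters = num_filters
        self.filter_size = filter_size
        self.stride = stride
        self.out_h = conv_output_size(h, filter_size, stride)
        self.out_w = conv_output_size(w, filter_size, stride)
        self.pool_h = self.out_h // 2
        self.pool_w = self.out_w // 2
        self.flat = self.pool_h * self.pool_w * num_filters
        k2 = filter_size * filter_size
        self.Wc = (rng.standard_normal((k2, num_filters)) * np.sqrt(2.0 / k2)).astype(np.float32)
        self.bc = np.zeros(num_filters, dtype=np.float32)
        self.Wf = (rng.standard_normal((self.flat, n_classes)) * np.sqrt(2.0 / self.flat)).astype(
            np.float32
        )
        self.bf = np.zeros(n_classes, dtype=np.float32)
        self._velocity = {k: np.zeros_like(v) for k, v in self.params().items()}

    def params(self) -> dict[str, np.ndarray]:
        return {"Wc": self.Wc, "bc": self.bc, "Wf": self.Wf, "bf": self.bf}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.Wc = params["Wc"].copy()
        self.bc = params["bc"].copy()
        self.Wf = params["Wf"].copy()
        self.bf = params["bf"].copy()

    @property
    def parameter_count(self) -> int:
        return sum(p.size for p in self.params().values())

    def prepare(self, images: np.ndarray) -> np.ndarray:
        """Precompute the im2col patch tensor for a stack of images."""
        if images.shape[1:] != self.input_size:
            raise ValueError(f"expected images of size {self.input_size}, got {images.shape[1:]}")
        return im2col(images, self.filter_size, self.stride)

    def _forward(self, patches: np.ndarray):
        conv = patches @ self.Wc + self.bc  # (N, pos, C)
        relu = np.maximum(conv, 0.0)
        n = patches.shape[0]
        grid = relu.reshape(n, self.out_h, self.out_w, self.num_filters)
        g = grid[:, : self.pool_h * 2, : self.pool_w * 2, :]
        blocks = g.reshape(n, self.pool_h, 2, self.pool_w, 2, self.num_filters)
        pooled = blocks.max(axis=(2, 4))
        flat = pooled.reshape(n, self.flat)
        logits = flat @ self.Wf + self.bf
        return conv, blocks, pooled, flat, logits

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        return softmax(self._forward(patches)[-1])

    def predict(self, patches: np.ndarray) -> np.ndarray:
        return self.predict_proba(patches).argmax(axis=1)

    def loss_and_grads(
        self, patches: np.ndarray, labels: np.ndarray, l2: float
    ) -> tuple[float, dict[str, np.ndarray]]:
        n = patches.shape[0]
        conv, blocks, pooled, flat, logits = self._forward(patches)
        probs = softmax(logits)
        eps = 1e-12
        data_loss = -np.mean(np.log(probs[np.arange(n), labels] + eps))
        reg_loss = 0.5 * l2 * (np.sum(self.Wc**2) + np.sum(self.Wf**2))

        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits /= n
        gWf = flat.T @ dlogits + l2 * self.Wf
        gbf = dlogits.sum(axis=0)
        dflat = dlogits @ self.Wf.T
        dpooled = dflat.reshape(n, self.pool_h, self.pool_w, self.num_filters)
        # route pooling gradient to the block maxima (ties share equally)
        maxb = pooled[:, :, None, :, None, :]
        mask = (blocks == maxb).astype(np.float32)
        mask /= np.maximum(mask.sum(axis=(2, 4), keepdims=True), 1.0)
        dblocks = mask * dpooled[:, :, None, :, None, :]
        dgrid = np.zeros((n, self.out_h, self.out_w, self.num_filters), dtype=np.float32)
        dgrid[:, : self.pool_h * 2, : self.pool_w * 2, :] = dblocks.reshape(
            n, self.pool_h * 2, self.pool_w * 2, self.num_filters
        )
        drelu = dgrid.reshape(n, self.out_h * self.out_w, self.num_filters)
        dconv = drelu * (conv > 0)
        gWc = np.einsum("npk,npc->kc", patches, dconv.astype(np.float32)) + l2 * self.Wc
        gbc = dconv.sum(axis=(0, 1))
        return float(data_loss + reg_loss), {"Wc": gWc, "bc": gbc, "Wf": gWf, "bf": gbf}

    def sgd_step(self, grads: dict[str, np.ndarray], lr: float, momentum: float) -> None:
        for key, param in self.params().items():
            v = self._velocity[key]
            v *= momentum
            v -= lr * grads[key]
            param += v
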