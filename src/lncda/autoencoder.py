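"""Single-hidden-layer autoencoder for feature compression.

Architecture: input(p) -> dense(latent, sigmoid) -> output(p, sigmoid),
trained to minimise the mean squared reconstruction error.  Inputs are
association scores and similarities, all in [0, 1], so a sigmoid output
is range-compatible without extra scaling.  Training uses mini-batch
Adam and is fully deterministic given a seed.  Implemented directly in
NumPy: a single dense layer pair needs no framework.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class AutoencoderSpec:
    """Hyperparameters for one autoencoder."""

    input_dim: int
    latent_dim: int = 256
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim >= self.input_dim:
            raise ValueError(
                f"latent_dim ({self.latent_dim}) must be smaller than "
                f"input_dim ({self.input_dim})"
            )
        if self.latent_dim < 1 or self.input_dim < 1:
            raise ValueError("dimensions must be positive")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class Autoencoder:
    """A trained (or trainable) encoder/decoder pair.

    ``loss_history`` records the full-data MSE after every epoch, with
    the pre-training loss prepended at index 0.
    """

    spec: AutoencoderSpec
    w_enc: np.ndarray = field(init=False, repr=False)
    b_enc: np.ndarray = field(init=False, repr=False)
    w_dec: np.ndarray = field(init=False, repr=False)
    b_dec: np.ndarray = field(init=False, repr=False)
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.spec.seed)
        p, h = self.spec.input_dim, self.spec.latent_dim
        lim_e = np.sqrt(6.0 / (p + h))
        lim_d = np.sqrt(6.0 / (h + p))
        self.w_enc = rng.uniform(-lim_e, lim_e, size=(p, h))
        self.b_enc = np.zeros(h)
        self.w_dec = rng.uniform(-lim_d, lim_d, size=(h, p))
        self.b_dec = np.zeros(p)

    # forward passes -------------------------------------------------
    def encode(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.spec.input_dim:
            raise ValueError(
                f"feature width {x.shape[-1]} does not match encoder "
                f"input_dim {self.spec.input_dim}"
            )
        return _sigmoid(x @ self.w_enc + self.b_enc)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return _sigmoid(self.encode(x) @ self.w_dec + self.b_dec)

    def mse(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        return float(np.mean((x - self.reconstruct(x)) ** 2))

    # training -------------------------------------------------------
    def fit(self, x: np.ndarray) -> "Autoencoder":
        """Train by mini-batch Adam on the reconstruction MSE."""
        x = np.asarray(x, dtype=float)
        if not np.isfinite(x).all():
            raise ValueError("training features must be finite")
        if x.ndim != 2 or x.shape[1] != self.spec.input_dim:
            raise ValueError(f"expected (n, {self.spec.input_dim}) training matrix")
        n = x.shape[0]
        rng = np.random.default_rng(self.spec.seed + 1)
        params = [self.w_enc, self.b_enc, self.w_dec, self.b_dec]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr = self.spec.learning_rate
        t = 0
        self.loss_history = [self.mse(x)]
        for _ in range(self.spec.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.spec.batch_size):
                xb = x[order[start : start + self.spec.batch_size]]
                nb = xb.shape[0]
                # forward
                h = _sigmoid(xb @ self.w_enc + self.b_enc)
                y = _sigmoid(h @ self.w_dec + self.b_dec)
                # backward (MSE averaged over all matrix entries)
                dy = 2.0 * (y - xb) / (nb * self.spec.input_dim)
                dz2 = dy * y * (1.0 - y)
                g_wdec = h.T @ dz2
                g_bdec = dz2.sum(axis=0)
                dh = dz2 @ self.w_dec.T
                dz1 = dh * h * (1.0 - h)
                g_wenc = xb.T @ dz1
                g_benc = dz1.sum(axis=0)
                t += 1
                for p, g, mi, vi in zip(
                    params, (g_wenc, g_benc, g_wdec, g_bdec), m, v
                ):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    mhat = mi / (1 - beta1**t)
                    vhat = vi / (1 - beta2**t)
                    p -= lr * mhat / (np.sqrt(vhat) + eps)
            self.loss_history.append(self.mse(x))
        return self

    # persistence ----------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(
            path,
            w_enc=self.w_enc,
            b_enc=self.b_enc,
            w_dec=self.w_dec,
            b_dec=self.b_dec,
            loss_history=np.asarray(self.loss_history),
            spec=np.asarray(
                [
                    self.spec.input_dim,
                    self.spec.latent_dim,
                    self.spec.epochs,
                    self.spec.batch_size,
                    self.spec.seed,
                ],
                dtype=float,
            ),
            learning_rate=self.spec.learning_rate,
            version=1,
        )
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "Autoencoder":
        data = np.load(path)
        p, h, epochs, batch, seed = (int(v) for v in data["spec"])
        spec = AutoencoderSpec(
            input_dim=p,
            latent_dim=h,
            epochs=epochs,
            batch_size=batch,
            learning_rate=float(data["learning_rate"]),
            seed=seed,
        )
        ae = cls(spec)
        ae.w_enc = data["w_enc"]
        ae.b_enc = data["b_enc"]
        ae.w_dec = data["w_dec"]
        ae.b_dec = data["b_dec"]
        ae.loss_history = list(data["loss_history"])
        return ae
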