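"""Compact convolutional EEG classifier in the EEGNet-8,2 configuration.

The network follows the published compact-CNN design for EEG decoding:
a bank of temporal filters (kernel length half the sampling rate), depthwise
spatial filtering across electrodes with a max-norm constraint, a separable
convolution stage, exponential-linear activations, two average-pooling
stages, dropout, and a dense soft-max readout.  Implemented directly in
NumPy with manual backpropagation so that reference-based attribution
multipliers can be propagated through the exact same graph.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .layers import (ELU, AvgPool, BatchNorm, Dense, DepthwiseSpatial,
                     DepthwiseTemporalConv, Dropout, Flatten, Identity,
                     PointwiseConv, TemporalConv)


def _act(kind: str):
    return Identity() if kind == "identity" else ELU()


class EEGNetModel:
    """EEGNet-8,2-style classifier over (E, T) input matrices.

    Parameters
    ----------
    n_electrodes, n_times : int
        Input shape.
    n_classes : int
        Number of phoneme labels.
    fs : float
        Sampling rate; sets the temporal kernel to ``fs / 2`` samples.
    f1, depth : int
        Temporal filter count and spatial filters per temporal filter.
    dropout : float
        Dropout probability in both blocks.
    activation : {"elu", "identity"}
        "identity" yields a purely linear network (used by attribution
        oracles in tests).
    """

    def __init__(self, n_electrodes: int, n_times: int, n_classes: int,
                 fs: float, f1: int = 8, depth: int = 2, dropout: float = 0.5,
                 activation: str = "elu", seed: int = 0,
                 dtype=np.float64):
        rng = np.random.default_rng(seed)
        self.dtype = np.dtype(dtype)
        self.n_electrodes, self.n_times, self.n_classes = n_electrodes, n_times, n_classes
        kt = max(3, int(round(fs / 2)) | 1)   # odd temporal kernel, fs/2 samples
        c = f1 * depth
        t_pool1 = n_times // 4
        t_pool2 = t_pool1 // 8
        if t_pool2 < 1:
            raise ValueError(f"n_times={n_times} too short for the pooling stages")
        self.layers = [
            TemporalConv(f1, kt, rng),
            BatchNorm(f1),
            DepthwiseSpatial(f1, depth, n_electrodes, rng, max_norm=1.0),
            BatchNorm(c),
            _act(activation),
            AvgPool(4),
            Dropout(dropout),
            DepthwiseTemporalConv(c, min(16, max(3, t_pool1)), rng),
            PointwiseConv(c, c, rng),
            BatchNorm(c),
            _act(activation),
            AvgPool(8),
            Dropout(dropout),
            Flatten(),
            Dense(c * t_pool2, n_classes, rng, max_norm=0.25),
        ]
        if self.dtype != np.float64:
            for layer in self.layers:
                for k in layer.params:
                    layer.params[k] = layer.params[k].astype(self.dtype)
                if hasattr(layer, "running_mean"):
                    layer.running_mean = layer.running_mean.astype(self.dtype)
                    layer.running_var = layer.running_var.astype(self.dtype)

    # ------------------------------------------------------------------ core
    def forward_train(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        h = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            h = layer.forward(h, training=True, rng=rng)
        return h

    def logits(self, x: np.ndarray) -> np.ndarray:
        h = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            h = layer.infer(h)
        return h

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = self.logits(x)
        z = z - z.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)

    def loss_and_backward(self, x, y, rng) -> float:
        """Cross-entropy loss; fills parameter gradients."""
        z = self.forward_train(x, rng)
        zs = z - z.max(axis=1, keepdims=True)
        p = np.exp(zs)
        p /= p.sum(axis=1, keepdims=True)
        n = len(y)
        loss = -np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean()
        dz = p.copy()
        dz[np.arange(n), y] -= 1.0
        dz /= n
        g = dz
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return loss

    def eval_loss(self, x, y) -> float:
        p = self.predict_proba(x)
        return -np.log(np.maximum(p[np.arange(len(y)), y], 1e-12)).mean()

    # ----------------------------------------------------------- parameters
    def parameters(self):
        for layer in self.layers:
            for name, val in layer.params.items():
                yield layer, name, val

    def get_state(self) -> list:
        state = []
        for layer in self.layers:
            entry = {k: v.copy() for k, v in layer.params.items()}
            if isinstance(layer, BatchNorm):
                entry["_rm"] = layer.running_mean.copy()
                entry["_rv"] = layer.running_var.copy()
            state.append(entry)
        return state

    def set_state(self, state: list) -> None:
        for layer, entry in zip(self.layers, state):
            for k, v in entry.items():
                if k == "_rm":
                    layer.running_mean = v.copy()
                elif k == "_rv":
                    layer.running_var = v.copy()
                else:
                    layer.params[k][...] = v

    # ---------------------------------------------------------- attribution
    def attribute(self, x: np.ndarray, target: int,
                  reference: np.ndarray | None = None,
                  rule: str = "rescale") -> np.ndarray:
        """Contribution scores of one input toward the target's logit.

        Backpropagates attribution multipliers from the target's pre-soft-max
        output to the input, relative to a reference input (default: the
        all-zero matrix).  With ``rule="rescale"`` the scores satisfy the
        completeness identity: their sum equals the difference between the
        target logit at the input and at the reference.  ``rule="gradient"``
        yields plain gradient-times-(input-minus-reference).
        """
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_electrodes, self.n_times):
            raise ValueError("input shape mismatch")
        ref = np.zeros_like(x) if reference is None else np.asarray(reference, float)
        acts_x, acts_r = [], []
        hx, hr = x[None], ref[None]
        for layer in self.layers:
            acts_x.append(hx)
            acts_r.append(hr)
            hx = layer.infer(hx)
            hr = layer.infer(hr)
        m = np.zeros((1, self.n_classes))
        m[0, target] = 1.0
        for layer, ax, ar in zip(reversed(self.layers), reversed(acts_x),
                                 reversed(acts_r)):
            m = layer.multipliers(m, ax, ar, rule=rule)
        return (m * (x[None] - ref[None]))[0]


@dataclass
class TrainConfig:
    """Optimization schedule for the classifier (printed protocol defaults)."""

    lr: float = 1e-3
    lr_decay: float = 0.7
    lr_decay_every: int = 100
    max_epochs: int = 300
    batch_size: int = 16
    patience: int | None = None   # early stop on stagnant validation loss
    adam_b1: float = 0.9
    adam_b2: float = 0.999
    adam_eps: float = 1e-8


def train_model(model: EEGNetModel, x_train, y_train, x_val, y_val,
                cfg: TrainConfig, seed: int = 0) -> dict:
    """Train with Adam + step-decay LR; return the lowest-validation-loss state.

    The model is left holding the checkpoint weights.  Returns a small history
    dict (per-epoch train/validation loss, best epoch).
    """
    rng = np.random.default_rng(seed)
    mom1 = {}
    mom2 = {}
    step = 0
    best = (np.inf, model.get_state(), -1)
    hist_tr, hist_va = [], []
    n = len(y_train)
    for epoch in range(cfg.max_epochs):
        lr = cfg.lr * cfg.lr_decay ** (epoch // cfg.lr_decay_every)
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss = model.loss_and_backward(x_train[idx], y_train[idx], rng)
            ep_loss += loss * len(idx)
            step += 1
            for i, (layer, name, val) in enumerate(model.parameters()):
                g = layer.grads[name]
                key = (i, name)
                m1 = mom1.setdefault(key, np.zeros_like(val))
                m2 = mom2.setdefault(key, np.zeros_like(val))
                m1 *= cfg.adam_b1
                m1 += (1 - cfg.adam_b1) * g
                m2 *= cfg.adam_b2
                m2 += (1 - cfg.adam_b2) * g * g
                mhat = m1 / (1 - cfg.adam_b1 ** step)
                vhat = m2 / (1 - cfg.adam_b2 ** step)
                val -= lr * mhat / (np.sqrt(vhat) + cfg.adam_eps)
            for layer in model.layers:
                layer.apply_constraints()
        hist_tr.append(ep_loss / n)
        va = model.eval_loss(x_val, y_val)
        hist_va.append(va)
        if va < best[0] - 1e-9:
            best = (va, model.get_state(), epoch)
        if cfg.patience is not None and epoch - best[2] >= cfg.patience:
            break
    model.set_state(best[1])
    return {"train_loss": hist_tr, "val_loss": hist_va, "best_epoch": best[2],
            "best_val_loss": best[0]}
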