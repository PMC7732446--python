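"""Symmetric deep autoencoder over one-hot SNP rows.

The network compresses a one-hot genotype row (4 channels per locus) through
a stack of ReLU-activated dense encoder layers to a narrow bottleneck, then
mirrors the stack back to the input width. The output head is a per-locus
4-way softmax; training minimises the per-locus categorical cross-entropy

    L = mean over (sample, non-missing locus) of  -sum_c y_c log p_c ,

with Adam. A sigmoid head with binary cross-entropy is available as a
configuration alternative. Everything is plain NumPy: seeded He-uniform
initialisation, explicit backpropagation, and single-threaded determinism,
so identical seeds give bit-identical training runs.

Default architecture (for panels of a few thousand loci): encoder widths
2000 and 700, bottleneck 40, learning rate 0.001.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .encoding import EncodedMatrix

__all__ = ["ArchitectureSpec", "Autoencoder", "depth_search"]


@dataclass
class ArchitectureSpec:
    """Hyperparameters of the symmetric autoencoder.

    ``input_dim`` is 4L for an L-locus one-hot panel. The decoder mirrors
    ``encoder_widths``. ``loss`` is ``"categorical"`` (per-locus softmax +
    categorical cross-entropy, the default) or ``"binary"`` (elementwise
    sigmoid + binary cross-entropy).
    """

    input_dim: int
    encoder_widths: Sequence[int] = (2000, 700)
    bottleneck_dim: int = 40
    activation: str = "relu"
    learning_rate: float = 0.001
    loss: str = "categorical"

    def __post_init__(self):
        self.encoder_widths = list(self.encoder_widths)
        if self.input_dim <= 0 or any(w <= 0 for w in self.encoder_widths):
            raise ValueError("dimensions must be positive")
        if not self.encoder_widths:
            raise ValueError("need at least one encoder hidden layer")
        if not self.bottleneck_dim < min(self.encoder_widths) < self.input_dim:
            raise ValueError(
                f"require bottleneck ({self.bottleneck_dim}) < min encoder width "
                f"({min(self.encoder_widths)}) < input_dim ({self.input_dim})"
            )
        if self.activation != "relu":
            raise ValueError("only relu activation is supported")
        if self.loss not in ("categorical", "binary"):
            raise ValueError("loss must be 'categorical' or 'binary'")
        if self.loss == "categorical" and self.input_dim % 4:
            raise ValueError("categorical loss needs input_dim divisible by 4")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")

    @property
    def layer_widths(self) -> list:
        """Full width chain input -> encoder -> bottleneck -> decoder -> input."""
        enc = list(self.encoder_widths)
        return [self.input_dim] + enc + [self.bottleneck_dim] + enc[::-1] + [self.input_dim]


def _he_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _softmax_blocks(z: np.ndarray) -> np.ndarray:
    """Stable softmax over each consecutive 4-column block."""
    n, d = z.shape
    zb = z.reshape(n, d // 4, 4)
    zb = zb - zb.max(axis=2, keepdims=True)
    e = np.exp(zb)
    return (e / e.sum(axis=2, keepdims=True)).reshape(n, d)


class Autoencoder:
    """Seeded, trainable dense autoencoder (see module docstring).

    Build with :meth:`build`, then :meth:`train`, then :meth:`encode` /
    :meth:`reconstruct`. Encoding an untrained model raises.
    """

    def __init__(self, spec: ArchitectureSpec, weights, biases, seed: int):
        self.spec = spec
        self.weights = weights
        self.biases = biases
        self.training_seed = seed
        self.loss_history: list = []
        self.trained = False
        self._adam_state = None

    # ------------------------------------------------------------------ build

    @classmethod
    def build(cls, spec: ArchitectureSpec, seed: int, dtype=np.float64) -> "Autoencoder":
        """He-uniform seeded initialisation of the full layer chain."""
        rng = np.random.default_rng(seed)
        widths = spec.layer_widths
        weights = [
            _he_uniform(rng, widths[i], widths[i + 1]).astype(dtype)
            for i in range(len(widths) - 1)
        ]
        # small positive bias on hidden layers keeps ReLU units initially
        # active (avoids dead units and collapsed bottleneck rows);
        # the output layer bias stays at zero
        n_layers = len(widths) - 1
        biases = [
            np.full(widths[i + 1], 0.01 if i < n_layers - 1 else 0.0, dtype=dtype)
            for i in range(n_layers)
        ]
        return cls(spec, weights, biases, seed)

    @property
    def bottleneck_index(self) -> int:
        # activations list index of the bottleneck layer output
        return len(self.spec.encoder_widths) + 1

    # ---------------------------------------------------------------- forward

    def _forward(self, X: np.ndarray) -> list:
        """Return activations [input, h1, ..., bottleneck, ..., output]."""
        a = [X]
        n_layers = len(self.weights)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a[-1] @ W + b
            if i < n_layers - 1:
                z = np.maximum(z, 0.0)  # ReLU on all hidden layers incl. bottleneck
            else:
                z = _softmax_blocks(z) if self.spec.loss == "categorical" else 1.0 / (1.0 + np.exp(-z))
            a.append(z)
        return a

    def _loss_and_output_grad(self, Y: np.ndarray, P: np.ndarray):
        """Loss and gradient w.r.t. output-layer pre-activation (logits)."""
        eps = 1e-12
        n, d = Y.shape
        if self.spec.loss == "categorical":
            yb = Y.reshape(n, d // 4, 4)
            pb = P.reshape(n, d // 4, 4)
            mask = yb.sum(axis=2) > 0  # missing blocks carry no target mass
            denom = max(int(mask.sum()), 1)
            loss = -(yb * np.log(pb + eps)).sum() / denom
            dZ = (pb - yb) * mask[:, :, None] / denom
            return loss, dZ.reshape(n, d)
        denom = Y.size
        loss = -(Y * np.log(P + eps) + (1 - Y) * np.log(1 - P + eps)).sum() / denom
        return loss, (P - Y) / denom

    def _loss_and_grads(self, X: np.ndarray):
        """Full-batch loss and parameter gradients (used by Adam and by the
        finite-difference gradient check)."""
        acts = self._forward(X)
        loss, dZ = self._loss_and_output_grad(X, acts[-1])
        gW = [None] * len(self.weights)
        gb = [None] * len(self.weights)
        for i in range(len(self.weights) - 1, -1, -1):
            gW[i] = acts[i].T @ dZ
            gb[i] = dZ.sum(axis=0)
            if i > 0:
                dZ = (dZ @ self.weights[i].T) * (acts[i] > 0)
        return loss, gW, gb

    # ------------------------------------------------------------------ train

    def _init_adam(self):
        self._adam_state = {
            "mW": [np.zeros_like(W) for W in self.weights],
            "vW": [np.zeros_like(W) for W in self.weights],
            "mb": [np.zeros_like(b) for b in self.biases],
            "vb": [np.zeros_like(b) for b in self.biases],
            "t": 0,
        }

    def _adam_step(self, gW, gb, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        s = self._adam_state
        s["t"] += 1
        t = s["t"]
        for i in range(len(self.weights)):
            for key, params, grads in (("W", self.weights, gW), ("b", self.biases, gb)):
                m, v = s["m" + key][i], s["v" + key][i]
                g = grads[i]
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * g * g
                mhat = m / (1 - beta1 ** t)
                vhat = v / (1 - beta2 ** t)
                params[i] -= lr * mhat / (np.sqrt(vhat) + eps)

    def train(
        self,
        data: EncodedMatrix,
        epochs: int = 200,
        batch_size: int = 32,
        seed: Optional[int] = None,
        patience: Optional[int] = None,
    ) -> "Autoencoder":
        """Minibatch Adam training on a one-hot matrix.

        Sample order is reshuffled every epoch from ``seed`` (default: the
        build seed). The recorded epoch loss is the batch-size-weighted mean
        of minibatch losses. ``patience`` enables early stopping on the
        training loss (off by default).
        """
        X = self._check_input(data)
        if seed is None:
            seed = self.training_seed
        rng = np.random.default_rng(seed)
        if self._adam_state is None:
            self._init_adam()
        n = X.shape[0]
        best, since_best = np.inf, 0
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss, weight = 0.0, 0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                loss, gW, gb = self._loss_and_grads(X[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss {loss!r} at epoch {len(self.loss_history) + 1}"
                    )
                self._adam_step(gW, gb, self.spec.learning_rate)
                epoch_loss += loss * len(idx)
                weight += len(idx)
            self.loss_history.append(epoch_loss / weight)
            if patience is not None:
                if self.loss_history[-1] < best - 1e-12:
                    best, since_best = self.loss_history[-1], 0
                else:
                    since_best += 1
                    if since_best >= patience:
                        break
        self.trained = True
        return self

    # ------------------------------------------------------------- inference

    def _check_input(self, data: EncodedMatrix) -> np.ndarray:
        if data.scheme != "one_hot":
            raise ValueError("autoencoder requires one_hot-encoded data")
        X = np.asarray(data.values, dtype=self.weights[0].dtype)
        if X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"data width {X.shape[1]} != spec input_dim {self.spec.input_dim}"
            )
        return X

    def encode(self, data: EncodedMatrix) -> np.ndarray:
        """Bottleneck activations, shape (n, bottleneck_dim).

        Warns when the embedding has collapsed (every bottleneck unit dead,
        all rows identical) — a known ReLU failure mode on very narrow
        bottlenecks; widen the layers or retrain with another seed.
        """
        if not self.trained:
            raise RuntimeError("model has not been trained; call train() first")
        X = self._check_input(data)
        emb = self._forward(X)[self.bottleneck_index]
        if emb.shape[0] > 1 and (emb == 0).all():
            import warnings

            warnings.warn(
                "bottleneck embedding collapsed to a single point (all ReLU "
                "units dead); clustering on it is meaningless — widen the "
                "encoder/bottleneck or use a different training seed",
                RuntimeWarning, stacklevel=2,
            )
        return emb

    def reconstruct(self, data: EncodedMatrix) -> EncodedMatrix:
        """Per-locus probability blocks (each 4-block sums to 1)."""
        X = self._check_input(data)
        P = self._forward(X)[-1]
        return EncodedMatrix(P, "one_hot", list(data.locus_ids), list(data.sample_ids))

    def reconstruction_loss(self, data: EncodedMatrix) -> float:
        """The training loss formula evaluated on ``data`` (no update)."""
        X = self._check_input(data)
        loss, _ = self._loss_and_output_grad(X, self._forward(X)[-1])
        return float(loss)

    # ------------------------------------------------------------ checkpoint

    def save(self, path) -> None:
        arrays = {f"W{i}": W for i, W in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        meta = dict(
            spec=asdict(self.spec), seed=self.training_seed,
            loss_history=self.loss_history, trained=self.trained,
        )
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "Autoencoder":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            spec = ArchitectureSpec(**meta["spec"])
            n = len(spec.layer_widths) - 1
            model = cls(spec, [z[f"W{i}"] for i in range(n)],
                        [z[f"b{i}"] for i in range(n)], meta["seed"])
        model.loss_history = list(meta["loss_history"])
        model.trained = bool(meta["trained"])
        return model


def _width_schedule(depth: int, first: int, last: int) -> list:
    """Geometric interpolation of ``depth`` encoder widths from first to last."""
    if depth == 1:
        return [last]
    ratios = np.linspace(0, 1, depth)
    return [int(round(first * (last / first) ** r)) for r in ratios]


def depth_search(
    data: EncodedMatrix,
    depths: Sequence[int] = (1, 2, 3, 4),
    seed: int = 0,
    base_spec: Optional[ArchitectureSpec] = None,
    epochs: int = 100,
    batch_size: int = 32,
    holdout_fraction: float = 0.0,
) -> list:
    """Train one autoencoder per candidate encoder depth; rank by final loss.

    Each depth maps to a geometric width schedule between the first and last
    default encoder widths. Returns a list of dicts
    ``{"depth", "widths", "final_loss"}`` sorted by ascending loss
    (ties by depth). With ``holdout_fraction > 0`` the loss is evaluated on a
    seeded holdout split instead of the training data.
    """
    if not depths:
        raise ValueError("empty candidate list")
    if base_spec is None:
        base_spec = ArchitectureSpec(input_dim=data.values.shape[1])
    first, last = base_spec.encoder_widths[0], base_spec.encoder_widths[-1]
    n = data.values.shape[0]
    rng = np.random.default_rng(seed)
    if holdout_fraction > 0:
        n_hold = max(1, int(round(holdout_fraction * n)))
        perm = rng.permutation(n)
        hold_idx, train_idx = perm[:n_hold], perm[n_hold:]
    else:
        hold_idx, train_idx = None, np.arange(n)

    def _subset(idx):
        return EncodedMatrix(
            data.values[idx], "one_hot", list(data.locus_ids),
            [data.sample_ids[i] for i in idx],
        )

    train_data = _subset(train_idx)
    report = []
    for depth in depths:
        widths = _width_schedule(int(depth), first, last)
        spec = ArchitectureSpec(
            input_dim=base_spec.input_dim,
            encoder_widths=widths,
            bottleneck_dim=base_spec.bottleneck_dim,
            learning_rate=base_spec.learning_rate,
            loss=base_spec.loss,
        )
        model = Autoencoder.build(spec, seed=seed).train(
            train_data, epochs=epochs, batch_size=batch_size, seed=seed
        )
        final = (
            model.reconstruction_loss(_subset(hold_idx))
            if hold_idx is not None else model.loss_history[-1]
        )
        report.append({"depth": int(depth), "widths": widths, "final_loss": float(final)})
    report.sort(key=lambda r: (r["final_loss"], r["depth"]))
    return report
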