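"""Closed-set person identification: the CMA model (convolutions +
multi-head self-attention) over subject-specifically selected electrodes.

Input construction: for a sample of subject *s*, the top-``budget``
electrodes of *s*'s frozen pre-training ranking are gathered from the full
recording and stacked in ascending electrode-index order, so every subject
yields an input of identical shape (budget x H) even though the physical
electrodes differ.  A single unified K-class network is then trained over
all enrolled subjects.

The network: a stack of strided 1-D convolutions (Conv -> BN -> ReLU)
reduces (K_chan, H) to (C', H'); the feature map is transposed to a
time-major token sequence and passed through L post-norm Transformer
encoder layers (multi-head self-attention with softmax(Q K^T / sqrt(d)) V,
then a position-wise feed-forward block, each wrapped as
LN(x + sublayer(x))); global average pooling over time and a final FC
produce the K-class softmax posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .backbone import ChannelRanking

__all__ = [
    "IdentityPrediction",
    "assemble_input",
    "ConvStack",
    "EncoderLayer",
    "CMANet",
    "PersonIdentifier",
    "conv_stack_forward",
    "encoder_forward",
    "classify",
    "train_registration",
]


@dataclass(frozen=True)
class IdentityPrediction:
    """Posterior, hard one-hot decision, and the decoded identity."""

    probabilities: np.ndarray  # K-vector, sums to 1
    one_hot: np.ndarray  # exactly one 1, at argmax (ties -> lowest index)
    predicted_id: object


def assemble_input(
    data: np.ndarray, ranking: ChannelRanking, budget: int
) -> np.ndarray:
    """Gather the top-``budget`` ranked channels, ascending electrode order.

    ``data`` is one full-montage window/run (C x H) or a batch (N x C x H);
    the output has exactly ``budget`` rows regardless of which physical
    electrodes the subject's ranking selected.
    """
    if ranking is None:
        raise ValueError("no ranking available for this subject (not enrolled)")
    rows = ranking.top(budget)  # ascending order
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 2:
        return data[rows]
    if data.ndim == 3:
        return data[:, rows]
    raise ValueError(f"expected (C, H) or (N, C, H), got {data.shape}")


# ------------------------------------------------------------------ network
class ConvStack(nn.Module):
    """Strided Conv1d -> BN -> ReLU feature extractor, (K_chan,H) -> (C',H')."""

    def __init__(
        self,
        in_channels: int,
        rng: np.random.Generator,
        channels: tuple = (64, 64, 64),
        kernels: tuple = (7, 5, 3),
        strides: tuple = (2, 2, 2),
    ):
        super().__init__()
        if not len(channels) == len(kernels) == len(strides):
            raise ValueError("channels, kernels and strides must align")
        self.n_layers = len(channels)
        self.stride_product = int(np.prod(strides))
        prev = in_channels
        for i, (c, k, s) in enumerate(zip(channels, kernels, strides)):
            setattr(self, f"conv{i}", nn.Conv1d(prev, c, k, rng, stride=s, padding=k // 2))
            setattr(self, f"bn{i}", nn.BatchNorm1d(c))
            prev = c
        self.out_channels = prev

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        h = x
        for i in range(self.n_layers):
            h = getattr(self, f"conv{i}")(h)
            h = getattr(self, f"bn{i}")(h)
            h = h.relu()
        return h


class EncoderLayer(nn.Module):
    """Post-norm Transformer encoder layer over (N, T, C') token sequences."""

    def __init__(
        self,
        d_model: int,
        n_heads: int,
        ffn_dim: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        if d_model % n_heads:
            raise ValueError(
                f"d_model={d_model} not divisible by n_heads={n_heads} "
                "(h * d must equal C')"
            )
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.W_Q = nn.Parameter(nn.uniform_init(rng, (d_model, d_model), d_model))
        self.W_K = nn.Parameter(nn.uniform_init(rng, (d_model, d_model), d_model))
        self.W_V = nn.Parameter(nn.uniform_init(rng, (d_model, d_model), d_model))
        self.W_O = nn.Parameter(nn.uniform_init(rng, (d_model, d_model), d_model))
        self.ln1 = nn.LayerNorm(d_model)
        self.ln2 = nn.LayerNorm(d_model)
        self.ffn1 = nn.Linear(d_model, ffn_dim, rng)
        self.ffn2 = nn.Linear(ffn_dim, d_model, rng)
        self.last_attention: np.ndarray | None = None

    def _split_heads(self, x: nn.Tensor) -> nn.Tensor:
        n, t, _ = x.shape
        return x.reshape(n, t, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def _mhsa(self, z: nn.Tensor) -> nn.Tensor:
        n, t, dm = z.shape
        q = self._split_heads(z @ self.W_Q)  # (N, h, T, d)
        k = self._split_heads(z @ self.W_K)
        v = self._split_heads(z @ self.W_V)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        att = scores.softmax(axis=-1)  # rows sum to 1
        self.last_attention = att.data
        ctx = att @ v  # (N, h, T, d)
        merged = ctx.transpose(0, 2, 1, 3).reshape(n, t, dm)
        return merged @ self.W_O

    def __call__(self, z: nn.Tensor) -> nn.Tensor:
        z1 = self.ln1(z + self._mhsa(z))
        ff = self.ffn2(self.ffn1(z1).relu())
        return self.ln2(z1 + ff)


class CMANet(nn.Module):
    """Conv stack + Transformer encoder + softmax identity head."""

    def __init__(
        self,
        in_channels: int,
        n_identities: int,
        conv_channels: tuple = (64, 64, 64),
        conv_kernels: tuple = (7, 5, 3),
        conv_strides: tuple = (2, 2, 2),
        n_layers: int = 2,
        n_heads: int = 4,
        ffn_dim: int = 128,
        seed: int = 0,
    ):
        super().__init__()
        if n_identities < 2:
            raise ValueError("closed-set identification needs >= 2 identities")
        rng = np.random.default_rng(seed)
        self.conv = ConvStack(in_channels, rng, conv_channels, conv_kernels, conv_strides)
        self.n_layers = n_layers
        for i in range(n_layers):
            setattr(
                self,
                f"enc{i}",
                EncoderLayer(self.conv.out_channels, n_heads, ffn_dim, rng),
            )
        self.head = nn.Linear(self.conv.out_channels, n_identities, rng)
        self.in_channels = in_channels
        self.n_identities = n_identities

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        if x.shape[2] % self.conv.stride_product:
            raise ValueError(
                f"window length {x.shape[2]} not divisible by the conv stack's "
                f"stride product {self.conv.stride_product}"
            )
        f = self.conv(x)  # (N, C', H')
        z = f.swapaxes(1, 2)  # time-major tokens (N, H', C')
        for i in range(self.n_layers):
            z = getattr(self, f"enc{i}")(z)
        pooled = z.mean(axis=1)  # temporal average, (N, C')
        return self.head(pooled)  # logits (N, K)


# -------------------------------------------------------------- functional
def conv_stack_forward(X: np.ndarray, stack: ConvStack) -> np.ndarray:
    """Run the convolutional feature extractor on a raw array."""
    X = np.asarray(X, dtype=np.float64)
    squeeze = X.ndim == 2
    if squeeze:
        X = X[None]
    if X.shape[2] % stack.stride_product:
        raise ValueError(
            f"length {X.shape[2]} not divisible by stride product "
            f"{stack.stride_product}"
        )
    out = stack(nn.Tensor(X)).data
    return out[0] if squeeze else out


def encoder_forward(Z0: np.ndarray, layers: list[EncoderLayer]) -> np.ndarray:
    """Apply encoder layers to a time-major token array (T, C') or (N, T, C')."""
    Z0 = np.asarray(Z0, dtype=np.float64)
    squeeze = Z0.ndim == 2
    z = nn.Tensor(Z0[None] if squeeze else Z0)
    for layer in layers:
        z = layer(z)
    return z.data[0] if squeeze else z.data


def classify(
    ZL: np.ndarray, head: nn.Linear, classes: np.ndarray | None = None
) -> IdentityPrediction:
    """Temporal average -> FC -> softmax -> one-hot (ties: lowest index)."""
    ZL = np.asarray(ZL, dtype=np.float64)
    if ZL.ndim != 2:
        raise ValueError("classify expects a single token sequence (T, C')")
    pooled = ZL.mean(axis=0)
    y = pooled @ head.weight.data + (head.bias.data if head.bias is not None else 0.0)
    e = np.exp(y - y.max())
    p = e / e.sum()
    k = int(np.argmax(p))  # argmax returns the first (lowest) index on ties
    onehot = np.zeros_like(p)
    onehot[k] = 1.0
    return IdentityPrediction(
        probabilities=p,
        one_hot=onehot,
        predicted_id=classes[k] if classes is not None else k,
    )


# ---------------------------------------------------------------- estimator
class PersonIdentifier(BaseEstimator, ClassifierMixin):
    """Closed-set identity classifier over assembled electrode windows.

    A scikit-learn style estimator: ``fit(X, y)`` with ``X`` shaped
    ``(n_windows, budget, H)`` (already assembled per subject via
    :func:`assemble_input`) and ``y`` the identity labels.  The output
    layer has exactly one unit per enrolled identity; ``predict`` can never
    emit an identity outside ``classes_``.
    """

    def __init__(
        self,
        conv_channels: tuple = (64, 64, 64),
        conv_kernels: tuple = (7, 5, 3),
        conv_strides: tuple = (2, 2, 2),
        n_layers: int = 2,
        n_heads: int = 4,
        ffn_dim: int = 128,
        lr: float = 1e-4,
        momentum: float = 0.9,
        batch_size: int = 256,
        max_epochs: int = 1000,
        patience: int = 20,
        min_delta: float = 1e-4,
        clip_norm: float = 5.0,
        seed: int = 0,
    ):
        self.conv_channels = conv_channels
        self.conv_kernels = conv_kernels
        self.conv_strides = conv_strides
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.ffn_dim = ffn_dim
        self.lr = lr
        self.momentum = momentum
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_delta = min_delta
        self.clip_norm = clip_norm
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("X must be (n_windows, budget, H)")
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need >= 2 enrolled identities")
        lookup = {c: i for i, c in enumerate(self.classes_)}
        yi = np.array([lookup[v] for v in y], dtype=np.intp)
        n = len(X)
        self.net_ = CMANet(
            in_channels=X.shape[1],
            n_identities=len(self.classes_),
            conv_channels=tuple(self.conv_channels),
            conv_kernels=tuple(self.conv_kernels),
            conv_strides=tuple(self.conv_strides),
            n_layers=self.n_layers,
            n_heads=self.n_heads,
            ffn_dim=self.ffn_dim,
            seed=self.seed,
        )
        opt = nn.SGD(
            self.net_.parameters(),
            lr=self.lr,
            momentum=self.momentum,
            clip_norm=self.clip_norm,
        )
        rng = np.random.default_rng(self.seed + 1)
        history = []
        best = np.inf
        stale = 0
        self.net_.train()
        for _epoch in range(self.max_epochs):
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = perm[start : start + self.batch_size]
                loss = self.net_(nn.Tensor(X[idx])).cross_entropy(yi[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data) * len(idx))
            epoch_loss = float(np.sum(losses) / n)
            history.append(epoch_loss)
            if epoch_loss < best - self.min_delta:
                best = epoch_loss
                stale = 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
        self.net_.eval()
        self.loss_history_ = history
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=np.float64)
        out = []
        for start in range(0, len(X), self.batch_size):
            logits = self.net_(nn.Tensor(X[start : start + self.batch_size]))
            out.append(logits.softmax(axis=1).data)
        return np.vstack(out)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def predict_identity(self, window: np.ndarray) -> IdentityPrediction:
        """Full prediction record (posterior + one-hot) for one window."""
        p = self.predict_proba(np.asarray(window)[None])[0]
        k = int(np.argmax(p))
        onehot = np.zeros_like(p)
        onehot[k] = 1.0
        return IdentityPrediction(
            probabilities=p, one_hot=onehot, predicted_id=self.classes_[k]
        )

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise RuntimeError("PersonIdentifier is not fitted")


def train_registration(
    assembled_windows: np.ndarray, identities, hyper: dict | None = None
) -> PersonIdentifier:
    """Convenience wrapper: fit a :class:`PersonIdentifier`."""
    est = PersonIdentifier(**(hyper or {}))
    return est.fit(np.asarray(assembled_windows, dtype=np.float64), identities)
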