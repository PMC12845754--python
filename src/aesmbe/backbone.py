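"""The AES-MBE backbone: channel attention, multi-scale bidirectional
encoding, a 4-class intent head, and post-training electrode ranking.

Architecture (for a batch of normalized windows, shape ``(N, C, H)``):

* input batch normalization (per channel, eps 1e-4);
* AES channel attention: a pooled per-channel descriptor ``z`` (rectified
  temporal mean, batch-standardized — see :class:`AESLayer` for why)
  passes through a square fully connected layer and a sigmoid, producing
  per-channel gates ``alpha`` in [0, 1] that multiply the input without
  changing its shape;
* N multi-scale bidirectional encoder (MBE) blocks.  Each block first
  applies its own channel gate (GAP -> FC -> sigmoid), then runs two
  temporal branches: the *forward* branch applies a local convolution
  (kernel 3), a sigmoid, a global convolution (kernel 7) and a
  channel-mixing projection applied across the transposed (time-major)
  layout, and adds the same projection of the branch input as a residual;
  the *backward* branch applies its own copy of that pipeline to the
  time-reversed signal and reverses the result.  The two branch outputs
  are combined (sum by default) preserving ``(C, H)``;
* global average pooling over time, then FC ``C -> 16 -> 4``.

After training, electrode importance is read off the AES weight matrix:
``s_c = sum_j |w_{j,c}|`` (column-magnitude aggregation), which depends on
the learned weights only, never on data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .data import PRETRAIN_CLASSES

__all__ = [
    "ChannelRanking",
    "AESLayer",
    "MBEBlock",
    "BackboneNet",
    "IntentBackbone",
    "aes_forward",
    "init_fc_weights",
    "mbe_block_forward",
    "backbone_forward",
    "train_pretraining",
    "channel_importance",
    "rank_and_select",
]


# ----------------------------------------------------------------- ranking
@dataclass(frozen=True)
class ChannelRanking:
    """Frozen per-subject electrode importance (bridge between stages)."""

    subject_id: int
    scores: tuple  # importance score per channel, index-aligned
    order: tuple  # channel indices by descending score (ties: ascending index)

    def top(self, n: int) -> list[int]:
        """Top-``n`` channels re-sorted ascending for input assembly."""
        if not 1 <= n <= len(self.order):
            raise ValueError(f"budget {n} out of range [1, {len(self.order)}]")
        return sorted(self.order[:n])


def channel_importance(w_fc: np.ndarray) -> np.ndarray:
    """Importance score per channel: ``s_c = sum_j |w_{j,c}|``.

    ``w_fc`` is the learned square attention weight matrix with element
    ``[j, c]`` connecting input channel ``c`` to output unit ``j``; the
    score aggregates the magnitudes of all weights attached to channel
    ``c``.  Being weights-only, the score is independent of any data batch.
    """
    w_fc = np.asarray(w_fc, dtype=np.float64)
    if w_fc.ndim != 2 or w_fc.shape[0] != w_fc.shape[1]:
        raise ValueError(f"expected a square weight matrix, got {w_fc.shape}")
    return np.abs(w_fc).sum(axis=0)


def rank_and_select(
    scores: np.ndarray, n: int, subject_id: int = -1
) -> tuple[ChannelRanking, list[int]]:
    """Rank channels by descending score and select the top ``n``.

    Ties are broken by ascending channel index; the selected subset is
    returned re-sorted ascending, the canonical order used when stacking
    electrodes into identification inputs.
    """
    scores = np.asarray(scores, dtype=np.float64)
    c = scores.shape[0]
    if not 1 <= n <= c:
        raise ValueError(f"n={n} out of range [1, {c}]")
    order = tuple(np.lexsort((np.arange(c), -scores)).tolist())
    ranking = ChannelRanking(
        subject_id=subject_id, scores=tuple(scores.tolist()), order=order
    )
    return ranking, ranking.top(n)


def init_fc_weights(C: int, seed: int) -> np.ndarray:
    """Square attention weights, i.i.d. uniform on [-1/sqrt(C), 1/sqrt(C)]."""
    if C < 1:
        raise ValueError("C must be >= 1")
    return nn.uniform_init(np.random.default_rng(seed), (C, C), C)


# ------------------------------------------------------------------ layers
class AESLayer(nn.Module):
    """Channel-attention gate; keeps input dimensionality unchanged.

    ``descriptor`` selects the per-channel pooled statistic ``z``:

    * ``"abs_mean"`` (default) — temporal mean of the absolute amplitude.
      Because every window is normalized to zero mean and unit variance per
      channel, the plain temporal mean is identically zero for real inputs
      and carries no information; the rectified mean still differs between
      oscillation-dominated and noise-dominated channels and gives the
      attention weights a usable learning signal.
    * ``"mean"`` — the plain temporal mean.

    With ``standardize=True`` (default) the descriptor is z-scored per
    channel across the batch (running estimates in eval mode) before the
    attention FC.  The rectified mean concentrates around a nearly
    channel-independent constant; standardization removes that constant and
    rescales the informative fluctuations to unit order, which is what lets
    the attention weights — and hence the post-training electrode ranking —
    latch onto discriminative channels instead of initialization noise.
    """

    def __init__(
        self,
        C: int,
        rng: np.random.Generator,
        descriptor: str = "abs_mean",
        standardize: bool = True,
        momentum: float = 0.1,
    ):
        super().__init__()
        if descriptor not in ("abs_mean", "mean"):
            raise ValueError(f"unknown descriptor {descriptor!r}")
        self.W_fc = nn.Parameter(nn.uniform_init(rng, (C, C), C))
        self.descriptor = descriptor
        self.standardize = standardize
        self.momentum = momentum
        self.z_mean = np.zeros(C)
        self.z_var = np.ones(C)
        self.last_alpha: np.ndarray | None = None

    def _buffers(self):
        return {"z_mean": self.z_mean, "z_var": self.z_var}

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        pooled = x.abs() if self.descriptor == "abs_mean" else x
        z = pooled.mean(axis=2)  # (N, C)
        if self.standardize:
            if self.training:
                mu = z.data.mean(axis=0)
                var = z.data.var(axis=0)
                self.z_mean = (1 - self.momentum) * self.z_mean + self.momentum * mu
                self.z_var = (1 - self.momentum) * self.z_var + self.momentum * var
                zc = z - z.mean(axis=0, keepdims=True)
                z = zc * ((zc * zc).mean(axis=0, keepdims=True) + 1e-5) ** -0.5
            else:
                z = (z - self.z_mean) * (1.0 / np.sqrt(self.z_var + 1e-5))
        alpha = (z @ self.W_fc.swapaxes(0, 1)).sigmoid()  # alpha_j = sig(sum_c w_jc z_c)
        self.last_alpha = alpha.data
        n, c = alpha.shape
        return x * alpha.reshape(n, c, 1)


class _DirectionalBranch(nn.Module):
    """One temporal direction of an MBE block (local+global conv + proj)."""

    def __init__(self, C: int, k_local: int, k_global: int, rng: np.random.Generator):
        super().__init__()
        self.conv_local = nn.Conv1d(C, C, k_local, rng, padding=k_local // 2)
        self.conv_global = nn.Conv1d(C, C, k_global, rng, padding=k_global // 2)
        self.proj = nn.Linear(C, C, rng)  # applied in time-major layout
        # near-identity projection start: the residual then transmits the
        # per-channel structure of the input instead of a random mixture,
        # which a plain uniform init would gaussianize away
        self.proj.weight.data = np.eye(C) + nn.uniform_init(rng, (C, C), C) * 0.1
        self.proj.bias.data[:] = 0.0

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        h = self.conv_local(x).sigmoid()
        h = self.conv_global(h)
        h = self.proj(h.swapaxes(1, 2)).swapaxes(1, 2)
        res = self.proj(x.swapaxes(1, 2)).swapaxes(1, 2)  # projected-input residual
        return h + res


class MBEBlock(nn.Module):
    """Multi-scale bidirectional encoder block, shape-preserving (C, H)."""

    def __init__(
        self,
        C: int,
        rng: np.random.Generator,
        k_local: int = 3,
        k_global: int = 7,
        combine: str = "sum",
    ):
        super().__init__()
        if combine not in ("sum", "mean", "concat"):
            raise ValueError(f"unknown combine mode {combine!r}")
        self.gate_fc = nn.Linear(C, C, rng)
        self.fwd = _DirectionalBranch(C, k_local, k_global, rng)
        self.bwd = _DirectionalBranch(C, k_local, k_global, rng)
        self.combine = combine
        self.k_global = k_global
        if combine == "concat":
            self.fuse = nn.Conv1d(2 * C, C, 1, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        if x.shape[2] < self.k_global:
            raise ValueError(
                f"window length {x.shape[2]} shorter than global kernel {self.k_global}"
            )
        n, c, _ = x.shape
        # rectified pooling: a plain temporal mean of the (near) zero-mean
        # input would be uninformative, see AESLayer
        gate = self.gate_fc(x.abs().mean(axis=2)).sigmoid().reshape(n, c, 1)
        xg = x * gate
        f_out = self.fwd(xg)
        b_out = self.bwd(xg.flip(2)).flip(2)
        if self.combine == "sum":
            return f_out + b_out
        if self.combine == "mean":
            return (f_out + b_out) * 0.5
        return self.fuse(nn.Tensor.concat([f_out, b_out], axis=1))


class BackboneNet(nn.Module):
    """BN -> AES -> MBE x N -> GAP -> FC C x 16 -> FC 16 x 4."""

    def __init__(
        self,
        C: int,
        n_blocks: int = 2,
        hidden_dim: int = 16,
        n_classes: int = 4,
        combine: str = "sum",
        k_local: int = 3,
        k_global: int = 7,
        bn_eps: float = 1e-4,
        descriptor: str = "abs_mean",
        standardize: bool = True,
        seed: int = 0,
    ):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.C = C
        self.bn = nn.BatchNorm1d(C, eps=bn_eps)
        self.aes = AESLayer(C, rng, descriptor=descriptor, standardize=standardize)
        self.n_blocks = n_blocks
        for i in range(n_blocks):
            setattr(self, f"block{i}", MBEBlock(C, rng, k_local, k_global, combine))
        self.fc1 = nn.Linear(C, hidden_dim, rng)
        self.fc2 = nn.Linear(hidden_dim, n_classes, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        if x.shape[1] != self.C:
            raise ValueError(f"expected {self.C} channels, got {x.shape[1]}")
        h = self.bn(x)
        h = self.aes(h)
        for i in range(self.n_blocks):
            h = getattr(self, f"block{i}")(h)
        pooled = h.abs().mean(axis=2)  # rectified GAP, (N, C)
        return self.fc2(self.fc1(pooled))  # logits (N, 4)


# -------------------------------------------------------------- functional
def _as_batch(X: np.ndarray) -> tuple[np.ndarray, bool]:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 2:
        return X[None], True
    if X.ndim == 3:
        return X, False
    raise ValueError(f"expected (C, H) or (N, C, H), got shape {X.shape}")


def aes_forward(
    X: np.ndarray, w_fc: np.ndarray, descriptor: str = "mean"
) -> tuple[np.ndarray, np.ndarray]:
    """Channel-attention forward pass on raw arrays.

    ``descriptor`` chooses the pooled channel statistic ("mean" here by
    default: the raw-op contract on arbitrary arrays; the trained network
    defaults to "abs_mean", see :class:`AESLayer`).  Returns the
    re-weighted signal (same shape as ``X``) and the attention vector
    ``alpha`` (one gate per channel, in [0, 1]).
    """
    xb, squeeze = _as_batch(X)
    w_fc = np.asarray(w_fc, dtype=np.float64)
    if w_fc.shape != (xb.shape[1], xb.shape[1]):
        raise ValueError(
            f"W_fc shape {w_fc.shape} incompatible with {xb.shape[1]} channels"
        )
    pooled = np.abs(xb) if descriptor == "abs_mean" else xb
    z = pooled.mean(axis=2)  # (N, C)
    alpha = 1.0 / (1.0 + np.exp(-(z @ w_fc.T)))
    out = xb * alpha[:, :, None]
    if squeeze:
        return out[0], alpha[0]
    return out, alpha


def mbe_block_forward(X: np.ndarray, block: MBEBlock) -> np.ndarray:
    """Run one MBE block on a raw array (shape-preserving)."""
    xb, squeeze = _as_batch(X)
    out = block(nn.Tensor(xb)).data
    return out[0] if squeeze else out


def backbone_forward(
    X: np.ndarray, net: BackboneNet
) -> tuple[np.ndarray, np.ndarray]:
    """Eval-mode logits and softmax probabilities for a batch of windows."""
    xb, squeeze = _as_batch(X)
    was_training = net.training
    net.eval()
    logits = net(nn.Tensor(xb))
    probs = logits.softmax(axis=1).data
    net.train(was_training)
    if squeeze:
        return logits.data[0], probs[0]
    return logits.data, probs


# ---------------------------------------------------------------- estimator
class IntentBackbone(BaseEstimator, ClassifierMixin):
    """Subject-specific 4-class intent model with built-in electrode scoring.

    A scikit-learn style classifier over windows shaped ``(n, C, H)``.
    Labels are the three task conditions of the target subject plus the
    ``other_subject`` negative class.  After fitting, the AES attention
    weights yield a frozen per-subject channel ranking
    (:meth:`channel_ranking`).

    Parameters
    ----------
    n_blocks : number of MBE blocks.
    combine : how the two temporal directions are merged ("sum", "mean",
        "concat").
    lr, momentum, batch_size : SGD-with-momentum settings.
    max_epochs, patience, min_delta : stopping rule — training ends at
        ``max_epochs`` or when the epoch loss has not improved by more than
        ``min_delta`` for ``patience`` consecutive epochs.
    seed : seeds parameter init and batch shuffling.
    """

    def __init__(
        self,
        n_blocks: int = 2,
        combine: str = "sum",
        hidden_dim: int = 16,
        k_local: int = 3,
        k_global: int = 7,
        bn_eps: float = 1e-4,
        descriptor: str = "abs_mean",
        standardize: bool = True,
        lr: float = 1e-4,
        momentum: float = 0.9,
        batch_size: int = 256,
        max_epochs: int = 1000,
        patience: int = 20,
        min_delta: float = 1e-4,
        clip_norm: float = 5.0,
        aes_weight_decay: float = 0.0,
        seed: int = 0,
    ):
        self.n_blocks = n_blocks
        self.combine = combine
        self.hidden_dim = hidden_dim
        self.k_local = k_local
        self.k_global = k_global
        self.bn_eps = bn_eps
        self.descriptor = descriptor
        self.standardize = standardize
        self.lr = lr
        self.momentum = momentum
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_delta = min_delta
        self.clip_norm = clip_norm
        self.aes_weight_decay = aes_weight_decay
        self.seed = seed

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("X must be (n_windows, C, H)")
        if len(X) == 0:
            raise ValueError("empty training set")
        y = np.asarray(y)
        # stable class order: canonical pre-training order first, then others
        uniq = list(dict.fromkeys(list(y)))
        ordered = [c for c in PRETRAIN_CLASSES if c in uniq]
        ordered += sorted(str(c) for c in uniq if c not in ordered)
        self.classes_ = np.array(ordered, dtype=object)
        class_to_idx = {c: i for i, c in enumerate(ordered)}
        yi = np.array([class_to_idx[v] for v in y], dtype=np.intp)

        n, C, H = X.shape
        self.net_ = BackboneNet(
            C,
            n_blocks=self.n_blocks,
            hidden_dim=self.hidden_dim,
            n_classes=len(ordered),
            combine=self.combine,
            k_local=self.k_local,
            k_global=self.k_global,
            bn_eps=self.bn_eps,
            descriptor=self.descriptor,
            standardize=self.standardize,
            seed=self.seed,
        )
        opt = nn.SGD(
            self.net_.parameters(),
            lr=self.lr,
            momentum=self.momentum,
            clip_norm=self.clip_norm,
        )
        rng = np.random.default_rng(self.seed + 1)
        history: list[float] = []
        best = np.inf
        stale = 0
        self.net_.train()
        for _epoch in range(self.max_epochs):
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = perm[start : start + self.batch_size]
                logits = self.net_(nn.Tensor(X[idx]))
                loss = logits.cross_entropy(yi[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                if self.aes_weight_decay:
                    # L2 shrinkage on the attention matrix only: decays the
                    # initialization so surviving magnitude reflects task
                    # gradient, sharpening the electrode ranking
                    self.net_.aes.W_fc.data *= 1.0 - self.lr * self.aes_weight_decay
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
        self.n_channels_ = C
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        _, probs = backbone_forward(np.asarray(X, dtype=np.float64), self.net_)
        return probs

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    # -- electrode selection ----------------------------------------------
    def channel_scores(self) -> np.ndarray:
        self._check_fitted()
        return channel_importance(self.net_.aes.W_fc.data)

    def channel_ranking(self, subject_id: int = -1) -> ChannelRanking:
        ranking, _ = rank_and_select(
            self.channel_scores(), self.n_channels_, subject_id=subject_id
        )
        return ranking

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise RuntimeError("IntentBackbone is not fitted")


def train_pretraining(
    windows: np.ndarray, labels, hyper: dict | None = None
) -> IntentBackbone:
    """Convenience wrapper: fit an :class:`IntentBackbone` on 4-class data."""
    est = IntentBackbone(**(hyper or {}))
    return est.fit(np.asarray(windows, dtype=np.float64), labels)
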