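"""The classifier: an ensemble of depthwise 1D-CNNs over pseudoimages.

Each ensemble member processes a pseudoimage of shape (n_rt, n_mz) as
n_mz parallel retention-time traces:

    input batch-norm (per m/z channel)
    -> depthwise 1D convolution along RT, one kernel per channel,
       no cross-channel mixing (valid padding)
    -> max pooling along RT (non-overlapping windows)
    -> spatial dropout (whole m/z channels, training only)
    -> flatten -> dense layer with L1 penalty -> softmax

The depthwise convolution smooths each trace and tolerates small RT
shifts; max pooling extracts the strongest local signal (peak apex) per
channel; spatial dropout discourages memorising individual noise
channels.  Members differ only in their random initialisation,
validation split and dropout stream; the ensemble prediction is the
arithmetic mean of the member softmax outputs.

The network is implemented directly in NumPy (forward, backward, Adam,
early stopping with best-weight restore) and is exactly reproducible:
training is a pure function of the configuration seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .binning import Pseudoimage

__all__ = [
    "MemberConfig",
    "EnsembleModel",
    "build_member",
    "train_ensemble",
    "predict_proba",
    "count_parameters",
    "save_ensemble",
    "load_ensemble",
]

_DTYPE = np.float32  # single precision: the network is memory-bandwidth bound
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass(frozen=True)
class MemberConfig:
    """Hyperparameters of one ensemble member.

    ``kernel_len`` — taps of the depthwise RT kernel (seconds of context
    = kernel_len x RT bin width).  ``pool_len`` — max-pool window along
    RT, stride equal to the window (non-overlapping).
    ``spatial_dropout_rate`` — probability of dropping an entire m/z
    channel during training.  ``l1_coeff`` — L1 penalty on the dense
    layer's weights.  ``val_fraction`` — stratified share of the
    training data held out per member for early stopping.
    """

    kernel_len: int = 9
    pool_len: int = 64
    spatial_dropout_rate: float = 0.1
    l1_coeff: float = 1e-4
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 50
    early_stop_patience: int = 5
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_len < 1 or self.pool_len < 1:
            raise ValueError("kernel_len and pool_len must be >= 1")
        if not 0.0 <= self.spatial_dropout_rate < 1.0:
            raise ValueError("spatial_dropout_rate must be in [0, 1)")
        if self.l1_coeff < 0:
            raise ValueError("l1_coeff must be >= 0")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


class Member:
    """One depthwise-1D-CNN member (weights + forward/backward passes)."""

    def __init__(self, config: MemberConfig, input_shape: tuple[int, int], n_classes: int,
                 rng: np.random.Generator):
        n_rt, n_mz = input_shape
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        if config.kernel_len > n_rt:
            raise ValueError(f"kernel_len {config.kernel_len} exceeds n_rt {n_rt}")
        conv_len = n_rt - config.kernel_len + 1
        if config.pool_len > conv_len:
            raise ValueError(f"pool_len {config.pool_len} exceeds conv output length {conv_len}")
        self.config = config
        self.input_shape = (n_rt, n_mz)
        self.n_classes = n_classes
        self.n_pool = conv_len // config.pool_len
        n_features = self.n_pool * n_mz

        self.params = {
            "bn_gamma": np.ones(n_mz, dtype=_DTYPE),
            "bn_beta": np.zeros(n_mz, dtype=_DTYPE),
            "conv_w": rng.normal(
                0.0, 1.0 / np.sqrt(config.kernel_len), (config.kernel_len, n_mz)
            ).astype(_DTYPE),
            "conv_b": np.zeros(n_mz, dtype=_DTYPE),
            "dense_w": rng.normal(
                0.0, np.sqrt(2.0 / n_features), (n_features, n_classes)
            ).astype(_DTYPE),
            "dense_b": np.zeros(n_classes, dtype=_DTYPE),
        }
        self.running_mean = np.zeros(n_mz, dtype=_DTYPE)
        self.running_var = np.ones(n_mz, dtype=_DTYPE)

    # -- forward ----------------------------------------------------------

    def _batchnorm(self, x: np.ndarray, training: bool, cache: dict | None) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = _BN_MOMENTUM * self.running_mean + (1 - _BN_MOMENTUM) * mu
            self.running_var = _BN_MOMENTUM * self.running_var + (1 - _BN_MOMENTUM) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mu) * inv_sd
        out = self.params["bn_gamma"] * xhat + self.params["bn_beta"]
        if cache is not None:
            cache["bn"] = (xhat, inv_sd)
        return out

    def _conv(self, x: np.ndarray, cache: dict | None) -> np.ndarray:
        # depthwise valid convolution as k shifted slice products: fast and
        # allocation-light compared to a windowed view
        k = self.config.kernel_len
        length = x.shape[1] - k + 1
        w = self.params["conv_w"]
        out = np.zeros((x.shape[0], length, x.shape[2]), dtype=_DTYPE)
        for j in range(k):
            out += x[:, j : j + length, :] * w[j]
        out += self.params["conv_b"]
        if cache is not None:
            cache["conv_in"] = x
        return out

    def _pool(self, x: np.ndarray, cache: dict | None) -> np.ndarray:
        p = self.config.pool_len
        b, length, c = x.shape
        trimmed = x[:, : self.n_pool * p, :].reshape(b, self.n_pool, p, c)
        argmax = trimmed.argmax(axis=2)
        out = np.take_along_axis(trimmed, argmax[:, :, None, :], axis=2)[:, :, 0, :]
        if cache is not None:
            cache["pool"] = (argmax, x.shape)
        return out

    def features(self, x: np.ndarray) -> np.ndarray:
        """Pre-flatten feature map (post-pool) at inference, shape (B, n_pool, n_mz)."""
        h = self._batchnorm(x, training=False, cache=None)
        h = self._conv(h, cache=None)
        return self._pool(h, cache=None)

    def forward(self, x: np.ndarray, training: bool = False,
                dropout_rng: np.random.Generator | None = None,
                cache: dict | None = None) -> np.ndarray:
        """Class probabilities for a batch of images (B, n_rt, n_mz)."""
        h = self._batchnorm(x, training, cache)
        h = self._conv(h, cache)
        h = self._pool(h, cache)
        rate = self.config.spatial_dropout_rate
        if training and rate > 0:
            mask = (dropout_rng.random((h.shape[0], 1, h.shape[2])) >= rate).astype(_DTYPE)
            mask /= _DTYPE(1.0 - rate)
            h = h * mask
            if cache is not None:
                cache["dropout"] = mask
        flat = h.reshape(h.shape[0], -1)
        logits = flat @ self.params["dense_w"] + self.params["dense_b"]
        logits -= logits.max(axis=1, keepdims=True)
        exp = np.exp(logits)
        probs = exp / exp.sum(axis=1, keepdims=True)
        if cache is not None:
            cache["flat"] = flat
            cache["probs"] = probs
        return probs

    # -- backward ---------------------------------------------------------

    def backward(self, cache: dict, y_onehot: np.ndarray) -> dict:
        """Gradients of mean cross-entropy + L1 penalty w.r.t. all parameters."""
        b = y_onehot.shape[0]
        p = self.params
        grads = {}
        dlogits = (cache["probs"] - y_onehot) / b
        grads["dense_w"] = cache["flat"].T @ dlogits + self.config.l1_coeff * np.sign(p["dense_w"])
        grads["dense_b"] = dlogits.sum(axis=0)
        dflat = dlogits @ p["dense_w"].T
        dh = dflat.reshape(b, self.n_pool, self.input_shape[1])
        if "dropout" in cache:
            dh = dh * cache["dropout"]
        # unpool: route gradient to the argmax positions
        argmax, conv_shape = cache["pool"]
        pool = self.config.pool_len
        dtrim = np.zeros((b, self.n_pool, pool, self.input_shape[1]), dtype=_DTYPE)
        np.put_along_axis(dtrim, argmax[:, :, None, :], dh[:, :, None, :], axis=2)
        dconv = np.zeros(conv_shape, dtype=_DTYPE)
        dconv[:, : self.n_pool * pool, :] = dtrim.reshape(b, self.n_pool * pool, -1)
        # depthwise conv
        conv_in = cache["conv_in"]  # post-batch-norm activations (B, T, C)
        length = dconv.shape[1]
        k = self.config.kernel_len
        dw = np.empty_like(p["conv_w"])
        dxhat_bn = np.zeros((b, self.input_shape[0], self.input_shape[1]), dtype=_DTYPE)
        w = p["conv_w"]
        for j in range(k):
            dw[j] = (conv_in[:, j : j + length, :] * dconv).sum(axis=(0, 1))
            dxhat_bn[:, j : j + length, :] += dconv * w[j]
        grads["conv_w"] = dw
        grads["conv_b"] = dconv.sum(axis=(0, 1))
        # batch norm
        xhat, inv_sd = cache["bn"]
        grads["bn_gamma"] = (dxhat_bn * xhat).sum(axis=(0, 1))
        grads["bn_beta"] = dxhat_bn.sum(axis=(0, 1))
        dxhat = dxhat_bn * p["bn_gamma"]
        n = b * self.input_shape[0]
        # dx not needed (input layer), but the gamma/beta/conv grads above
        # already account for the batch statistics through xhat
        _ = n, dxhat, inv_sd
        return grads

    def clone_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}


@dataclass
class EnsembleModel:
    """K trained members sharing an input shape and class order.

    Prediction is the arithmetic mean of the members' softmax outputs.
    """

    members: list[Member]
    n_classes: int
    input_shape: tuple[int, int]
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        for m in self.members:
            if m.input_shape != tuple(self.input_shape) or m.n_classes != self.n_classes:
                raise ValueError("all members must share input_shape and n_classes")


def build_member(config: MemberConfig, input_shape: tuple[int, int], n_classes: int,
                 rng: np.random.Generator | None = None) -> Member:
    """Construct an untrained member with seed-derived initial weights."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return Member(config, tuple(input_shape), n_classes, rng)


def _as_array(images: Sequence) -> np.ndarray:
    if not isinstance(images, np.ndarray):
        images = np.stack([
            im.values if isinstance(im, Pseudoimage) else np.asarray(im) for im in images
        ])
    return images.astype(_DTYPE, copy=False)


def _stratified_holdout(labels: np.ndarray, val_fraction: float,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split into train / validation index arrays."""
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(val_fraction * idx.size)))
        if n_val >= idx.size:
            n_val = idx.size - 1
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def _shift_rows(x: np.ndarray, shift: int) -> np.ndarray:
    """Translate an image along the RT axis by `shift` bins, zero filling."""
    out = np.zeros_like(x)
    if shift == 0:
        return x.copy()
    if shift > 0:
        out[shift:] = x[:-shift]
    else:
        out[:shift] = x[-shift:]
    return out


def _train_member(member: Member, x: np.ndarray, y: np.ndarray,
                  x_val: np.ndarray, y_val: np.ndarray,
                  rng: np.random.Generator) -> list[dict]:
    """Adam + early stopping on validation loss; returns the epoch log."""
    cfg = member.config
    n_classes = member.n_classes
    adam_m = {k: np.zeros_like(v) for k, v in member.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in member.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_loss = np.inf
    best_params = member.clone_params()
    best_running = (member.running_mean.copy(), member.running_var.copy())
    patience_left = cfg.early_stop_patience
    log = []
    eye = np.eye(n_classes, dtype=_DTYPE)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(x.shape[0])
        epoch_loss = 0.0
        for start in range(0, order.size, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            if batch.size < 2:
                continue  # batch norm needs more than one row
            cache: dict = {}
            probs = member.forward(x[batch], training=True, dropout_rng=rng, cache=cache)
            yb = eye[y[batch]]
            epoch_loss += -np.sum(np.log(np.clip(probs[np.arange(batch.size), y[batch]], 1e-12, None)))
            grads = member.backward(cache, yb)
            step += 1
            for key, grad in grads.items():
                adam_m[key] = beta1 * adam_m[key] + (1 - beta1) * grad
                adam_v[key] = beta2 * adam_v[key] + (1 - beta2) * grad**2
                m_hat = adam_m[key] / (1 - beta1**step)
                v_hat = adam_v[key] / (1 - beta2**step)
                member.params[key] -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        val_probs = member.forward(x_val, training=False)
        val_loss = float(
            -np.mean(np.log(np.clip(val_probs[np.arange(y_val.size), y_val], 1e-12, None)))
        )
        log.append({"epoch": epoch, "train_loss": epoch_loss / x.shape[0], "val_loss": val_loss})
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_params = member.clone_params()
            best_running = (member.running_mean.copy(), member.running_var.copy())
            patience_left = cfg.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    member.params = best_params
    member.running_mean, member.running_var = best_running
    return log


def train_ensemble(
    images: Sequence,
    labels: Sequence[str],
    n_members: int = 5,
    config: MemberConfig = MemberConfig(),
    oversample_classes: bool = True,
    shift_bins_max: int = 0,
    shift_copies: int = 0,
) -> EnsembleModel:
    """Train K members, each with its own initialisation and validation split.

    Every member gets a seed-derived random initialisation, its own
    stratified ``val_fraction`` hold-out used for early stopping on
    validation loss, and (when enabled) class balancing by random
    oversampling of its training portion.  ``shift_bins_max`` /
    ``shift_copies`` optionally add integer-bin RT translations of the
    training images for pipelines whose inputs are already binned;
    RT-shift augmentation of raw point clouds is preferred and lives in
    :mod:`lcmsnet.augmentation`.
    """
    x = _as_array(images)
    labels = np.asarray([str(l) for l in labels])
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    class_order = tuple(sorted(set(labels)))
    if len(class_order) < 2:
        raise ValueError("training data must contain at least 2 classes")
    y = np.searchsorted(class_order, labels)
    input_shape = tuple(x.shape[1:])

    members = []
    for k in range(n_members):
        seed = np.random.SeedSequence(config.seed, spawn_key=(k,))
        rng = np.random.default_rng(seed)
        member = build_member(config, input_shape, len(class_order), rng)
        train_idx, val_idx = _stratified_holdout(labels, config.val_fraction, rng)
        xt, yt = x[train_idx], y[train_idx]
        if oversample_classes:
            idx_list, _ = _oversample_indices(yt, rng)
            xt, yt = xt[idx_list], yt[idx_list]
        if shift_bins_max > 0 and shift_copies > 0:
            extra_x, extra_y = [], []
            for _ in range(shift_copies):
                shifts = rng.integers(-shift_bins_max, shift_bins_max + 1, xt.shape[0])
                extra_x.append(np.stack([_shift_rows(im, int(s)) for im, s in zip(xt, shifts)]))
                extra_y.append(yt)
            xt = np.concatenate([xt] + extra_x)
            yt = np.concatenate([yt] + extra_y)
        member.training_log = _train_member(member, xt, yt, x[val_idx], y[val_idx], rng)
        members.append(member)
    return EnsembleModel(
        members=members, n_classes=len(class_order),
        input_shape=input_shape, class_order=class_order,
    )


def _oversample_indices(y: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    idx = [np.arange(y.size)]
    for cls, count in zip(classes, counts):
        if count < target:
            members = np.flatnonzero(y == cls)
            idx.append(rng.choice(members, size=target - count, replace=True))
    all_idx = np.concatenate(idx)
    return all_idx, y[all_idx]


def predict_proba(model: EnsembleModel, images) -> np.ndarray:
    """Mean of the member softmax outputs over ``model.class_order``.

    Accepts a single pseudoimage (returns shape (n_classes,)) or a
    batch (returns (B, n_classes)); rows sum to 1 within 1e-6.
    """
    x = _as_array([images] if _is_single(images, model) else images)
    if tuple(x.shape[1:]) != tuple(model.input_shape):
        raise ValueError(f"image shape {x.shape[1:]} != model input shape {model.input_shape}")
    probs = np.mean([m.forward(x, training=False) for m in model.members], axis=0)
    return probs[0] if _is_single(images, model) else probs


def _is_single(images, model: EnsembleModel) -> bool:
    if isinstance(images, Pseudoimage):
        return True
    arr = np.asarray(images) if isinstance(images, np.ndarray) else None
    if arr is not None:
        return arr.ndim == 2
    return False


def count_parameters(model: EnsembleModel, per_member: bool = False) -> int | list[int]:
    """Trainable weights (batch-norm gamma/beta, conv, dense) per member or total."""
    counts = [sum(v.size for v in m.params.values()) for m in model.members]
    return counts if per_member else int(sum(counts))


# -- serialization ---------------------------------------------------------

def save_ensemble(model: EnsembleModel, path: str | Path) -> None:
    """Save weights + config + class order into a single .npz archive."""
    arrays = {}
    meta = {
        "n_classes": model.n_classes,
        "input_shape": list(model.input_shape),
        "class_order": list(model.class_order),
        "n_members": len(model.members),
        "configs": [asdict(m.config) for m in model.members],
    }
    for i, m in enumerate(model.members):
        for key, value in m.params.items():
            arrays[f"member{i}/{key}"] = value
        arrays[f"member{i}/running_mean"] = m.running_mean
        arrays[f"member{i}/running_var"] = m.running_var
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_ensemble(path: str | Path) -> EnsembleModel:
    """Inverse of :func:`save_ensemble`."""
    with np.load(path) as archive:
        meta = json.loads(archive["meta_json"].tobytes().decode())
        members = []
        for i in range(meta["n_members"]):
            config = MemberConfig(**meta["configs"][i])
            member = build_member(
                config, tuple(meta["input_shape"]), meta["n_classes"],
                rng=np.random.default_rng(0),
            )
            for key in member.params:
                member.params[key] = archive[f"member{i}/{key}"]
            member.running_mean = archive[f"member{i}/running_mean"]
            member.running_var = archive[f"member{i}/running_var"]
            members.append(member)
    return EnsembleModel(
        members=members, n_classes=meta["n_classes"],
        input_shape=tuple(meta["input_shape"]), class_order=tuple(meta["class_order"]),
    )
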