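"""WGF-LN: a Lego-filter network over post-processed feature vectors.

Split–transform–merge with shared small filters: the input vector is split
into equal fragments, every fragment is multiplied against a small bank of
shared "Lego" filters, a fixed one-hot mask picks one filter per
(output slot, fragment) pair and the masked products are summed per slot:

    gamma_iota = sum_phi (delta_phi^T epsilon) Omega_iota^phi

Slots are merged by concatenation + ReLU; after the last layer each slot is
globally average-pooled and a dense softmax head produces class
probabilities.  Because the filters are shared, the convolutional parameter
count is n_lego * fragment_dim * kernel_len regardless of how many fragments
the input splits into.

Training is cross-entropy gradient descent — the explicit-Euler
discretization of the loss gradient flow, with the learning rate as the time
step — implemented with manual backpropagation in numpy (gradient-checked in
the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LegoClassifier",
    "TrainConfig",
    "PredictionSet",
    "init_network",
    "forward",
    "train",
    "predict",
]


@dataclass
class TrainConfig:
    """Optimization settings for the explicit-Euler gradient flow."""

    learning_rate: float = 0.05
    epochs: int = 300
    batch_size: int = 32
    seed: int = 0
    patience: int = 50            # early stop on no val-loss improvement

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning rate must be non-negative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class PredictionSet:
    """Per-sample class probabilities and hard labels."""

    probabilities: np.ndarray     # (n, n_classes), rows sum to 1
    labels: np.ndarray            # hard argmax labels (original class ids)
    class_ids: np.ndarray         # column order of `probabilities`


@dataclass
class LegoClassifier:
    """Parameters and architecture of the Lego-filter network."""

    lego_filters: np.ndarray              # (n_lego, fragment_dim, kernel_len)
    masks: list[np.ndarray]               # per layer: (n_out, n_frag) filter ids
    layer_dims: list[int]                 # input dim of each layer
    head_weights: np.ndarray              # (pooled_dim, n_classes)
    head_bias: np.ndarray                 # (n_classes,)
    input_dim: int
    n_classes: int
    fragment_dim: int
    kernel_len: int
    class_ids: np.ndarray | None = None   # set by train()
    fitted: bool = False
    loss_trace: dict = field(default_factory=dict)

    @property
    def n_lego(self) -> int:
        return self.lego_filters.shape[0]

    @property
    def n_conv_params(self) -> int:
        """Shared-filter parameter count: n_lego * fragment_dim * kernel_len."""
        return int(np.prod(self.lego_filters.shape))


def _layer_geometry(d: int, fragment_dim: int, outputs: int | None) -> tuple[int, int]:
    n_frag = -(-d // fragment_dim)  # ceil; tail fragment zero-padded
    n_out = n_frag if outputs is None else outputs
    return n_frag, n_out


def init_network(
    input_dim: int,
    n_classes: int,
    n_lego: int = 4,
    fragment_dim: int = 4,
    kernel_len: int = 3,
    n_layers: int = 2,
    seed: int = 0,
    outputs_per_layer: list[int] | None = None,
) -> LegoClassifier:
    """Initialize a Lego network: He-scaled Gaussian filters, balanced
    round-robin masks, zero head."""
    if n_lego < 1 or fragment_dim < 1 or kernel_len < 1 or n_layers < 1:
        raise ValueError("n_lego, fragment_dim, kernel_len, n_layers must be >= 1")
    if input_dim < fragment_dim:
        raise ValueError(
            f"input_dim {input_dim} smaller than fragment_dim {fragment_dim}"
        )
    rng = np.random.default_rng(seed)
    lego = rng.normal(
        0.0,
        np.sqrt(2.0 / (fragment_dim * kernel_len)),
        size=(n_lego, fragment_dim, kernel_len),
    )
    masks, layer_dims = [], []
    d = input_dim
    for layer in range(n_layers):
        out_spec = outputs_per_layer[layer] if outputs_per_layer else None
        n_frag, n_out = _layer_geometry(d, fragment_dim, out_spec)
        flat = np.arange(n_out * n_frag) % n_lego  # balanced: counts differ <= 1
        masks.append(flat.reshape(n_out, n_frag))
        layer_dims.append(d)
        d = n_out * kernel_len
    head = np.zeros((masks[-1].shape[0], n_classes))
    return LegoClassifier(
        lego_filters=lego,
        masks=masks,
        layer_dims=layer_dims,
        head_weights=head,
        head_bias=np.zeros(n_classes),
        input_dim=input_dim,
        n_classes=n_classes,
        fragment_dim=fragment_dim,
        kernel_len=kernel_len,
    )


def _onehot_masks(model: LegoClassifier) -> list[np.ndarray]:
    out = []
    for m in model.masks:
        oh = np.zeros((*m.shape, model.n_lego))
        n_out, n_frag = m.shape
        oh[np.arange(n_out)[:, None], np.arange(n_frag)[None, :], m] = 1.0
        out.append(oh)
    return out


def _forward_cached(model: LegoClassifier, X: np.ndarray) -> tuple[np.ndarray, list]:
    """Logits plus per-layer caches for backprop."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.input_dim:
        raise ValueError(f"feature dim {X.shape[1]} != model input_dim {model.input_dim}")
    B = X.shape[0]
    f, L = model.fragment_dim, model.kernel_len
    onehots = _onehot_masks(model)
    caches = []
    v = X
    for m_oh in onehots:
        n_out, n_frag, _ = m_oh.shape
        padded = np.zeros((B, n_frag * f))
        padded[:, : v.shape[1]] = v
        frags = padded.reshape(B, n_frag, f)
        theta = np.einsum("bpf,kfl->bpkl", frags, model.lego_filters)
        gamma = np.einsum("bpkl,opk->bol", theta, m_oh)
        act = np.maximum(gamma, 0.0)
        caches.append((frags, gamma, m_oh, v.shape[1]))
        v = act.reshape(B, n_out * L)
    pooled = v.reshape(B, -1, L).mean(axis=2)
    logits = pooled @ model.head_weights + model.head_bias
    caches.append((pooled,))
    return logits, caches


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def forward(model: LegoClassifier, features: np.ndarray) -> PredictionSet:
    """Class probabilities and argmax labels (ties to the smaller class id)."""
    logits, _ = _forward_cached(model, features)
    probs = _softmax(logits)
    idx = np.argmax(probs, axis=1)  # argmax takes the first (smallest) index on ties
    class_ids = (
        model.class_ids if model.class_ids is not None else np.arange(model.n_classes)
    )
    return PredictionSet(probabilities=probs, labels=class_ids[idx], class_ids=class_ids)


def _loss_and_grads(
    model: LegoClassifier, X: np.ndarray, y_idx: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy and gradients w.r.t. all parameters."""
    logits, caches = _forward_cached(model, X)
    probs = _softmax(logits)
    B = X.shape[0]
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(B), y_idx] + eps)))

    dlogits = probs.copy()
    dlogits[np.arange(B), y_idx] -= 1.0
    dlogits /= B
    (pooled,) = caches[-1]
    grads = {
        "head_weights": pooled.T @ dlogits,
        "head_bias": dlogits.sum(axis=0),
        "lego_filters": np.zeros_like(model.lego_filters),
    }
    L = model.kernel_len
    dpooled = dlogits @ model.head_weights.T
    d_act = np.repeat(dpooled[:, :, None] / L, L, axis=2)  # undo mean-pool
    layers = caches[:-1]
    for li in range(len(layers) - 1, -1, -1):
        frags, gamma, m_oh, in_dim = layers[li]
        dgamma = d_act * (gamma > 0)
        dtheta = np.einsum("bol,opk->bpkl", dgamma, m_oh)
        grads["lego_filters"] += np.einsum("bpf,bpkl->kfl", frags, dtheta)
        if li == 0:
            break  # no upstream activation to propagate into
        dfrags = np.einsum("bpkl,kfl->bpf", dtheta, model.lego_filters)
        dv = dfrags.reshape(B, -1)[:, :in_dim]
        d_act = dv.reshape(B, -1, L)
    return loss, grads


def _encode_labels(model: LegoClassifier, y: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(model.class_ids, y)
    if np.any(model.class_ids[idx] != y):
        raise ValueError("labels outside the training class set")
    return idx


def train(
    model: LegoClassifier,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> LegoClassifier:
    """Fit by mini-batch explicit-Euler descent on cross-entropy.

    Records per-epoch train (and validation) loss in ``model.loss_trace``;
    early-stops when validation loss has not improved for ``patience``
    epochs, restoring the best parameters.  Raises on divergence (NaN loss).
    """
    config = config or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training needs at least two classes")
    if len(classes) > model.n_classes:
        raise ValueError("more classes in labels than model outputs")
    # map sorted unique labels onto output columns; pad unused columns with
    # fresh ids so argmax over any column stays decodable
    n_extra = model.n_classes - len(classes)
    model.class_ids = np.concatenate(
        [classes, classes.max() + 1 + np.arange(n_extra)]
    )
    y_idx = _encode_labels(model, y)
    yv_idx = _encode_labels(model, np.asarray(y_val)) if y_val is not None else None

    rng = np.random.default_rng(config.seed)
    n = len(y)
    train_losses, val_losses = [], []
    best_val, best_params, patience_left = np.inf, None, config.patience
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            loss, grads = _loss_and_grads(model, X[batch], y_idx[batch])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "training diverged (non-finite loss); reduce the learning rate"
                )
            model.lego_filters -= config.learning_rate * grads["lego_filters"]
            model.head_weights -= config.learning_rate * grads["head_weights"]
            model.head_bias -= config.learning_rate * grads["head_bias"]
        ep_loss, _ = _loss_and_grads(model, X, y_idx)
        train_losses.append(ep_loss)
        if yv_idx is not None:
            vl, _ = _loss_and_grads(model, X_val, yv_idx)
            val_losses.append(vl)
            if vl < best_val - 1e-9:
                best_val = vl
                best_params = (
                    model.lego_filters.copy(),
                    model.head_weights.copy(),
                    model.head_bias.copy(),
                )
                patience_left = config.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
    if best_params is not None:
        model.lego_filters, model.head_weights, model.head_bias = best_params
    model.loss_trace = {"train": np.asarray(train_losses), "val": np.asarray(val_losses)}
    model.fitted = True
    return model


def predict(model: LegoClassifier, features: np.ndarray) -> PredictionSet:
    """Predict hard labels; requires a fitted model."""
    if not model.fitted:
        raise RuntimeError("model is not fitted; call train() first")
    return forward(model, features)
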