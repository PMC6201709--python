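"""Fully-connected tanh autoencoder for multi-omics integration.

The network is d-500-100-500-d: tanh on the three hidden layers, linear
reconstruction by default (z-scored inputs are unbounded; a tanh output
cannot reconstruct |z| > 1, so tanh output is opt-in).  Reconstruction
error is the Pseudo-Huber loss summed over input dimensions and averaged
over the minibatch, plus L1 and L2 penalties on the weights (not biases).
Training is plain minibatch gradient descent, deterministic given the
seed; the 100-unit bottleneck activations become the integrated features.

Two hyperparameter profiles are provided: ``default_profile`` (10 epochs,
batch 32, learning rate 1e-6, L1 1e-4, L2 1e-3) and ``adequate_profile``
(learning rate 1e-3, 200 epochs) for synthetic-recovery experiments where
the tiny default learning rate barely moves the Glorot-initialised
weights.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .survival import cox_univariate, logrank_two_group
from .types import OmicsMatrix, SurvivalTable

logger = logging.getLogger(__name__)


@dataclass
class AutoencoderConfig:
    """Hyperparameters of the integration autoencoder.

    ``hidden_sizes`` defaults to the 500-100-500 architecture with the
    middle entry as the bottleneck; ``delta`` is the Pseudo-Huber scale.
    """

    hidden_sizes: tuple[int, ...] = (500, 100, 500)
    output_activation: str = "linear"  # or "tanh"
    delta: float = 1.0
    l1: float = 1e-4
    l2: float = 1e-3
    learning_rate: float = 1e-6
    epochs: int = 10
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValidationError("delta must be > 0")
        if self.l1 < 0 or self.l2 < 0:
            raise ValidationError("regularization strengths must be >= 0")
        if len(self.hidden_sizes) % 2 == 0:
            raise ValidationError("hidden_sizes must have an odd length (middle = bottleneck)")
        if self.output_activation not in ("linear", "tanh"):
            raise ValidationError("output_activation must be 'linear' or 'tanh'")

    @property
    def bottleneck_index(self) -> int:
        return len(self.hidden_sizes) // 2 + 1  # layer index of bottleneck output

    @property
    def bottleneck_size(self) -> int:
        return self.hidden_sizes[len(self.hidden_sizes) // 2]


def default_profile(**overrides) -> AutoencoderConfig:
    """The default training budget: 10 epochs, batch 32, lr 1e-6."""
    return AutoencoderConfig(**overrides)


def adequate_profile(**overrides) -> AutoencoderConfig:
    """A budget that actually converges on synthetic data (lr 1e-3,
    200 epochs); all other settings as in :func:`default_profile`."""
    params = dict(learning_rate=1e-3, epochs=200)
    params.update(overrides)
    return AutoencoderConfig(**params)


@dataclass
class AutoencoderModel:
    """Trained weights plus the configuration that produced them."""

    config: AutoencoderConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feature_ids: list[str]
    training_log: list[float] = field(default_factory=list)

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]


@dataclass
class LatentMatrix:
    """Bottleneck activations per sample, with a mask of the
    survival-associated columns."""

    sample_ids: list[str]
    values: np.ndarray  # (n_samples, bottleneck)
    selected: np.ndarray  # boolean, per latent feature
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.selected = np.asarray(self.selected, dtype=bool)
        if self.values.shape[0] != len(self.sample_ids):
            raise ValidationError("latent rows must match sample count")
        if self.selected.shape != (self.values.shape[1],):
            raise ValidationError("selected mask length must equal latent width")
        if not self.feature_names:
            self.feature_names = [f"latent_{i:03d}" for i in range(self.values.shape[1])]

    def selected_values(self) -> np.ndarray:
        return self.values[:, self.selected]


def pseudo_huber_loss(x, x_prime, delta: float = 1.0) -> float:
    """Pseudo-Huber reconstruction error summed over input dimensions:
    sum_k delta^2 (sqrt(1 + ((x_k - x'_k)/delta)^2) - 1).

    Quadratic ~ r^2/2 for small residuals, linear ~ delta*|r| for large.
    """
    if delta <= 0:
        raise ValidationError("delta must be > 0")
    x = np.asarray(x, dtype=float)
    x_prime = np.asarray(x_prime, dtype=float)
    if x.shape != x_prime.shape:
        raise ValidationError("input and reconstruction shapes differ")
    r = (x - x_prime) / delta
    return float(delta ** 2 * np.sum(np.sqrt(1.0 + r ** 2) - 1.0))


def init_model(d_in: int, config: AutoencoderConfig,
               feature_ids: list[str] | None = None) -> AutoencoderModel:
    """Glorot-uniform initialisation, seeded; biases start at zero."""
    rng = np.random.default_rng(config.seed)
    sizes = [d_in, *config.hidden_sizes, d_in]
    weights, biases = [], []
    for a, b in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (a + b))
        weights.append(rng.uniform(-limit, limit, size=(a, b)))
        biases.append(np.zeros(b))
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(d_in)]
    return AutoencoderModel(config, weights, biases, list(feature_ids))


def _forward_full(model: AutoencoderModel, X: np.ndarray):
    """All layer activations for a (batch, d) input."""
    acts = [X]
    h = X
    k = len(model.weights)
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        z = h @ W + b
        if i < k - 1 or model.config.output_activation == "tanh":
            h = np.tanh(z)
        else:
            h = z
        acts.append(h)
    return acts


def forward(model: AutoencoderModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruction and bottleneck activations for a (batch, d) input."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.weights[0].shape[0]:
        raise ValidationError(
            f"input dimension {X.shape[1]} != model input {model.weights[0].shape[0]}")
    acts = _forward_full(model, X)
    return acts[-1], acts[model.config.bottleneck_index]


def loss_and_gradients(model: AutoencoderModel, X: np.ndarray):
    """Mean-over-batch Pseudo-Huber loss with L1/L2 weight penalties, and
    its analytic gradients via backprop.  Returns (loss, dW list, db list)."""
    cfg = model.config
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_batch = X.shape[0]
    acts = _forward_full(model, X)
    recon = acts[-1]
    delta = cfg.delta
    r = (recon - X) / delta
    root = np.sqrt(1.0 + r ** 2)
    data_loss = float(delta ** 2 * np.sum(root - 1.0)) / n_batch
    reg_loss = sum(cfg.l1 * np.abs(W).sum() + cfg.l2 * (W ** 2).sum()
                   for W in model.weights)
    loss = data_loss + float(reg_loss)

    # dL/d(recon): delta * r / sqrt(1+r^2), averaged over the batch
    grad_h = delta * r / root / n_batch
    k = len(model.weights)
    dW = [None] * k
    db = [None] * k
    for i in range(k - 1, -1, -1):
        h_out = acts[i + 1]
        if i < k - 1 or cfg.output_activation == "tanh":
            grad_z = grad_h * (1.0 - h_out ** 2)
        else:
            grad_z = grad_h
        dW[i] = acts[i].T @ grad_z + cfg.l1 * np.sign(model.weights[i]) \
            + 2.0 * cfg.l2 * model.weights[i]
        db[i] = grad_z.sum(axis=0)
        if i > 0:
            grad_h = grad_z @ model.weights[i].T
    return loss, dW, db


def train(data: OmicsMatrix, config: AutoencoderConfig | None = None) -> AutoencoderModel:
    """Train on an omics matrix (features x samples; samples are the
    training rows).  Minibatch shuffling and initialisation are seeded, so
    two runs with the same seed are bit-identical.  Per-epoch mean loss is
    recorded in ``model.training_log``."""
    if config is None:
        config = AutoencoderConfig()
    X = data.values.T  # samples x features
    n, d = X.shape
    model = init_model(d, config, feature_ids=data.feature_ids)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lr = config.learning_rate
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            batch = X[order[start:start + config.batch_size]]
            loss, dW, db = loss_and_gradients(model, batch)
            if not np.isfinite(loss):
                raise ValidationError(
                    f"non-finite loss at epoch {epoch}; lower the learning rate")
            for i in range(len(model.weights)):
                model.weights[i] -= lr * dW[i]
                model.biases[i] -= lr * db[i]
            epoch_losses.append(loss)
        model.training_log.append(float(np.mean(epoch_losses)))
    return model


def encode(model: AutoencoderModel, data: OmicsMatrix) -> LatentMatrix:
    """Bottleneck activations per sample; the selected mask starts
    all-false.  Feature ids must match the training matrix exactly."""
    if list(data.feature_ids) != list(model.feature_ids):
        missing = sorted(set(model.feature_ids) - set(data.feature_ids))
        extra = sorted(set(data.feature_ids) - set(model.feature_ids))
        raise ValidationError(
            f"feature mismatch with training matrix: missing {missing[:5]}, "
            f"extra {extra[:5]}, or order differs")
    _, bottleneck = forward(model, data.values.T)
    return LatentMatrix(list(data.sample_ids), bottleneck,
                        np.zeros(bottleneck.shape[1], dtype=bool))


def select_prognostic_latent(latent: LatentMatrix, surv: SurvivalTable,
                             alpha: float = 0.05,
                             method: str = "median_logrank") -> LatentMatrix:
    """Flag latent features associated with survival.

    ``median_logrank`` dichotomises each feature at its median and runs a
    two-group log-rank test against each endpoint; ``cox`` uses the
    continuous Cox score test.  A feature is selected when p < alpha for
    event-free OR overall survival.  Constant features (or median splits
    that empty a group) are excluded with a warning.
    """
    if method not in ("median_logrank", "cox"):
        raise ValidationError("method must be 'median_logrank' or 'cox'")
    endpoints = {name: surv.endpoint(name, latent.sample_ids) for name in ("efs", "os")}
    n_latent = latent.values.shape[1]
    selected = np.zeros(n_latent, dtype=bool)
    n_degenerate = 0
    for j in range(n_latent):
        x = latent.values[:, j]
        if np.ptp(x) == 0:
            n_degenerate += 1
            continue
        if method == "median_logrank":
            groups = (x > np.median(x)).astype(int)
            if groups.min() == groups.max():
                n_degenerate += 1
                continue
            ps = [logrank_two_group(groups, t, e).p_value
                  for t, e in endpoints.values()]
        else:
            ps = [cox_univariate(x, t, e).p_value for t, e in endpoints.values()]
        if min(ps) < alpha:
            selected[j] = True
    if n_degenerate:
        logger.warning("%d latent feature(s) degenerate (constant or one-sided "
                       "median split); excluded", n_degenerate)
    if not selected.any():
        raise ValidationError(
            "no latent feature is survival-associated; inspect autoencoder training")
    return dataclasses.replace(latent, selected=selected)


def gradient_check(model: AutoencoderModel, X, eps: float = 1e-6) -> float:
    """Max relative error between analytic and central-difference
    gradients over all weights and biases (used to validate backprop)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _, dW, db = loss_and_gradients(model, X)
    worst = 0.0
    for params, grads in ((model.weights, dW), (model.biases, db)):
        for P, G in zip(params, grads):
            flat = P.ravel()
            for idx in range(flat.size):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _, _ = loss_and_gradients(model, X)
                flat[idx] = orig - eps
                lm, _, _ = loss_and_gradients(model, X)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = G.ravel()[idx]
                scale = max(abs(num), abs(ana), 1e-8)
                worst = max(worst, abs(num - ana) / scale)
    return worst
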