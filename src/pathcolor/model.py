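"""Stratified splitting, MLP binary classification, and the repeated-CV driver.

The classifier is a small fully connected network (ReLU hidden layers,
inverted dropout, Adam) trained on class-weighted binary cross-entropy —
positive entries are a tiny fraction of the cross-join, so the positive
class is up-weighted by N_neg/N_pos by default.  Everything is driven by
explicit integer seeds: identical config and seed give identical weights,
splits, and predictions.

Cross-validation uses independent stratified shuffle-splits per iteration
(9:1 train/test by default) rather than disjoint folds, so repeated runs
behave like a hybrid bootstrap/jackknife resampling of the entry set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .dataset import CrossJoinDataset, LevelMap
from .errors import StratificationError, TrainingDivergenceError
from .evaluate import CVResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    test_fraction: float


@dataclass
class ModelConfig:
    hidden_sizes: tuple[int, ...] = (256, 128)
    dropout: float = 0.1
    learning_rate: float = 1e-3
    max_epochs: int = 100
    batch_size: int = 256
    positive_class_weight: float | str = "balanced"
    decision_threshold: float = 0.5
    early_stopping_patience: int = 5
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must be in (0, 1)")
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.max_epochs < 0:
            raise ValueError("learning_rate/batch_size/max_epochs out of range")


def stratified_split(labels, test_fraction: float = 0.1, seed: int = 0) -> SplitSpec:
    """Random train/test split preserving the positive proportion.

    The number of positive test entries is the integer minimizing
    ``|p_test - p_train|`` among all test sets of the requested size, then
    members are sampled uniformly within each class.  Reproducible from
    ``seed``.
    """
    y = np.asarray(labels, dtype=bool)
    n = y.size
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == n:
        raise StratificationError(
            f"labels contain a single class ({n_pos} positives of {n})"
        )
    n_test = int(round(n * test_fraction))
    n_test = min(max(n_test, 1), n - 1)
    n_train = n - n_test

    # p_test(t) = t/n_test, p_train(t) = (n_pos - t)/n_train; the real
    # minimizer of |p_test - p_train| is t* = n_pos * n_test / n.
    t_star = n_pos * n_test / n
    lo = max(0, n_test - (n - n_pos))
    hi = min(n_pos, n_test)

    def objective(t: int) -> float:
        return abs(t / n_test - (n_pos - t) / n_train)

    candidates = sorted(
        {int(np.clip(int(np.floor(t_star)), lo, hi)), int(np.clip(int(np.ceil(t_star)), lo, hi))}
    )
    t_best = min(candidates, key=lambda t: (objective(t), abs(t - t_star)))

    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    test_pos = rng.choice(pos_idx, size=t_best, replace=False)
    test_neg = rng.choice(neg_idx, size=n_test - t_best, replace=False)
    test = np.sort(np.concatenate([test_pos, test_neg]).astype(np.int64))
    mask = np.ones(n, dtype=bool)
    mask[test] = False
    train = np.flatnonzero(mask)
    return SplitSpec(train, test, seed, test_fraction)


# ---------------------------------------------------------------------------
# Minimal feed-forward network
# ---------------------------------------------------------------------------


def _init_weights(widths: list[int], rng: np.random.Generator):
    weights = []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)).astype(
            np.float32
        )
        b = np.zeros(fan_out, dtype=np.float32)
        weights.append([w, b])
    return weights


def _forward(weights, x, dropout: float = 0.0, rng: np.random.Generator | None = None):
    """Return (logits, cache of layer activations for backprop)."""
    cache = [x]
    h = x
    for layer, (w, b) in enumerate(weights):
        z = h @ w + b
        if layer < len(weights) - 1:
            h = np.maximum(z, 0.0)
            if dropout > 0.0 and rng is not None:
                mask = (rng.random(h.shape) >= dropout).astype(np.float32)
                h = h * mask / (1.0 - dropout)
            cache.append(h)
        else:
            h = z
    return h[:, 0], cache


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _weighted_bce(logits, y, sample_w):
    # softplus(z) - y*z, numerically stable
    softplus = np.logaddexp(0.0, logits)
    per = softplus - y * logits
    return float(np.sum(sample_w * per) / np.sum(sample_w))


@dataclass
class Predictor:
    """Fitted MLP state plus the config and input width it was trained with."""

    weights: list
    config: ModelConfig
    input_width: int
    training_seed: int
    history: dict = field(default_factory=dict)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 2 or x.shape[1] != self.input_width:
            raise ValueError(
                f"input width {x.shape[1] if x.ndim == 2 else x.shape} does not "
                f"match trained width {self.input_width}"
            )
        logits, _ = _forward(self.weights, x)
        return _sigmoid(logits)

    def predict(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        proba = self.predict_proba(x)
        return proba, proba >= self.config.decision_threshold


def predict(model: Predictor, entries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and boolean calls (probability >= decision threshold)."""
    return model.predict(entries)


def _fit(x, y, config: ModelConfig) -> Predictor:
    rng = np.random.default_rng(config.seed)
    n, width = x.shape
    widths = [width, *config.hidden_sizes, 1]
    weights = _init_weights(widths, rng)

    if config.positive_class_weight == "balanced":
        n_pos = max(int(y.sum()), 1)
        pos_weight = (n - n_pos) / n_pos
    else:
        pos_weight = float(config.positive_class_weight)
    sample_w = np.where(y > 0.5, pos_weight, 1.0).astype(np.float32)

    # held-out slice of the training data for early stopping
    val_idx = np.array([], dtype=np.int64)
    fit_idx = np.arange(n)
    if (
        config.validation_fraction > 0
        and config.early_stopping_patience > 0
        and 0 < int(y.sum()) < n
        and n >= 20
    ):
        try:
            vsplit = stratified_split(
                y > 0.5, config.validation_fraction, seed=config.seed + 1
            )
            fit_idx, val_idx = vsplit.train_indices, vsplit.test_indices
        except StratificationError:
            pass

    adam_m = [[np.zeros_like(w), np.zeros_like(b)] for w, b in weights]
    adam_v = [[np.zeros_like(w), np.zeros_like(b)] for w, b in weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_val = np.inf
    best_weights = [[w.copy(), b.copy()] for w, b in weights]
    patience_left = config.early_stopping_patience
    history = {"train_loss": [], "val_loss": []}

    for epoch in range(config.max_epochs):
        order = rng.permutation(fit_idx)
        epoch_loss = 0.0
        epoch_w = 0.0
        for start in range(0, order.size, config.batch_size):
            batch = order[start : start + config.batch_size]
            xb, yb, wb = x[batch], y[batch], sample_w[batch]
            logits, cache = _forward(weights, xb, config.dropout, rng)
            wsum = float(wb.sum())
            loss = _weighted_bce(logits, yb, wb)
            if not np.isfinite(loss):
                raise TrainingDivergenceError(
                    f"non-finite training loss at epoch {epoch}; config={asdict(config)}"
                )
            epoch_loss += loss * wsum
            epoch_w += wsum
            # backprop
            dz = (wb * (_sigmoid(logits) - yb) / wsum).astype(np.float32)
            grad = dz[:, None]
            step += 1
            for layer in range(len(weights) - 1, -1, -1):
                w, b = weights[layer]
                h_in = cache[layer]
                gw = h_in.T @ grad
                gb = grad.sum(axis=0)
                if layer > 0:
                    # cache holds post-ReLU/post-dropout activations: h > 0
                    # identifies kept, active units; the 1/(1-p) inverted-
                    # dropout scale must be applied in the backward pass too.
                    grad = (grad @ w.T) * (cache[layer] > 0)
                    if config.dropout > 0.0:
                        grad /= 1.0 - config.dropout
                for slot, g in ((0, gw), (1, gb)):
                    adam_m[layer][slot] = beta1 * adam_m[layer][slot] + (1 - beta1) * g
                    adam_v[layer][slot] = beta2 * adam_v[layer][slot] + (1 - beta2) * g**2
                    m_hat = adam_m[layer][slot] / (1 - beta1**step)
                    v_hat = adam_v[layer][slot] / (1 - beta2**step)
                    weights[layer][slot] -= (
                        config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
                    ).astype(np.float32)
        history["train_loss"].append(epoch_loss / max(epoch_w, 1e-12))

        if val_idx.size:
            logits, _ = _forward(weights, x[val_idx])
            val_loss = _weighted_bce(logits, y[val_idx], sample_w[val_idx])
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_weights = [[w.copy(), b.copy()] for w, b in weights]
                patience_left = config.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    weights = best_weights
                    break
    else:
        if val_idx.size and best_val < np.inf:
            logits, _ = _forward(weights, x[val_idx])
            if _weighted_bce(logits, y[val_idx], sample_w[val_idx]) > best_val:
                weights = best_weights

    return Predictor(weights, config, width, config.seed, history)


def train(
    dataset: CrossJoinDataset, split: SplitSpec, config: ModelConfig
) -> Predictor:
    """Fit the MLP on the split's training entries only."""
    x = dataset.entry_features(split.train_indices)
    y = dataset.labels[split.train_indices].astype(np.float32)
    return _fit(x, y, config)


def run_cv(
    dataset: CrossJoinDataset,
    n_iterations: int,
    config: ModelConfig,
    base_seed: int = 0,
    levels: LevelMap | None = None,
    test_fraction: float = 0.1,
) -> CVResult:
    """Repeated stratified shuffle-split cross-validation.

    Each iteration draws an independent seeded 9:1 split, trains afresh, and
    tallies test-set confusion counts overall and per compound / pathway.
    The full feature matrix is materialized once and shared across
    iterations, which bounds this driver to datasets that fit in memory.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    n_c, n_p = dataset.n_compounds, dataset.n_pathways
    x_all = dataset.entry_features(np.arange(dataset.n_entries))
    y_all = dataset.labels

    overall = np.zeros((n_iterations, 4), dtype=np.int64)
    per_compound = np.zeros((n_iterations, n_c, 4), dtype=np.int64)
    per_pathway = np.zeros((n_iterations, n_p, 4), dtype=np.int64)
    seeds = []

    for it in range(n_iterations):
        seed = int(base_seed + it) % (2**31)
        seeds.append(seed)
        split = stratified_split(y_all, test_fraction, seed=seed)
        it_config = ModelConfig(**{**asdict(config), "seed": seed})
        model = _fit(x_all[split.train_indices], y_all[split.train_indices].astype(np.float32), it_config)
        _, calls = model.predict(x_all[split.test_indices])
        y_test = y_all[split.test_indices]
        # count columns: 0=tp 1=tn 2=fp 3=fn
        cat = np.where(
            y_test & calls, 0, np.where(~y_test & ~calls, 1, np.where(calls, 2, 3))
        )
        ci, pi = dataset.entry_pair(split.test_indices)
        np.add.at(overall[it], cat, 1)
        np.add.at(per_compound[it], (ci, cat), 1)
        np.add.at(per_pathway[it], (pi, cat), 1)
        logger.info(
            "cv iteration %d/%d: test=%d, tp=%d fp=%d fn=%d",
            it + 1,
            n_iterations,
            split.test_indices.size,
            overall[it, 0],
            overall[it, 2],
            overall[it, 3],
        )

    return CVResult(
        compound_ids=list(dataset.compound_matrix.entity_ids),
        pathway_ids=list(dataset.pathway_matrix.entity_ids),
        overall_counts=overall,
        compound_counts=per_compound,
        pathway_counts=per_pathway,
        levels=levels,
        seeds=seeds,
        config=asdict(config),
    )
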