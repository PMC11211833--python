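"""Training and evaluation of the MIL model.

The objective is mean binary cross-entropy over a batch of bag-level
probabilities, minimized with Adam. Each training epoch re-applies the
dual instance sampling per bag (fresh random subset, then score-based
mining); validation loss drives early stopping with restoration of the
best parameters. Repeated experiments offset the base seed by the
repeat index so any single repeat is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autograd import Tensor
from .bags import FeatureBag
from .clustering import PrototypeSet
from .errors import ConfigError, DataError, ParameterError
from .metrics import METRIC_NAMES, binary_metrics
from .model import ModelConfig, ModelState, forward, init_model_state
from .synthetic import Cohort

__all__ = [
    "TrainConfig",
    "EvalReport",
    "cross_entropy",
    "Adam",
    "train",
    "predict_bags",
    "evaluate",
    "run_repeats",
]

EPS_CLAMP = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    epochs: int = 30
    learning_rate: float = 2e-4
    weight_decay: float = 1e-5
    early_stop_patience: int = 10
    n_repeats: int = 5
    seed: int = 0
    class_weighted: bool = False

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ParameterError("batch_size and epochs must be >= 1")
        if self.early_stop_patience > self.epochs:
            raise ParameterError("early_stop_patience must not exceed epochs")


@dataclass
class EvalReport:
    metrics: dict[str, float]
    per_bag: pd.DataFrame  # bag_id, label, prob
    metrics_sd: dict[str, float] | None = None
    per_repeat: list[dict[str, float]] = field(default_factory=list)


def cross_entropy(probs, labels, weights=None):
    """Mean binary cross-entropy of predicted positive probabilities.

    Probabilities are clamped to [eps, 1-eps] (eps = 1e-7) before the
    logarithm. Accepts a list of autograd scalars (differentiable) or a
    plain array; returns a Tensor either way (use ``.data`` for the value).
    """
    if isinstance(probs, (list, tuple)) and probs and isinstance(probs[0], Tensor):
        if len(probs) != len(labels):
            raise ParameterError("probs and labels length mismatch")
        total = None
        for k, (p, y) in enumerate(zip(probs, labels)):
            pc = p.clip(EPS_CLAMP, 1.0 - EPS_CLAMP)
            term = -(pc.log()) if y == 1 else -((1.0 - pc).log())
            if weights is not None:
                term = term * float(weights[k])
            total = term if total is None else total + term
        return total / float(len(probs))
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    if probs.shape != labels.shape:
        raise ParameterError("probs and labels length mismatch")
    pc = np.clip(probs, EPS_CLAMP, 1.0 - EPS_CLAMP)
    ll = labels * np.log(pc) + (1 - labels) * np.log(1 - pc)
    if weights is not None:
        ll = ll * np.asarray(weights, dtype=np.float64)
    return Tensor(-np.mean(ll))


class Adam:
    """Adaptive-moment gradient descent with decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * (mh / (np.sqrt(vh) + self.eps) + self.wd * p.data)


def _split_or_raise(cohort: Cohort, split: str) -> list[FeatureBag]:
    bags = cohort.split_bags(split)
    if not bags:
        raise ConfigError(f"manifest has no '{split}' split")
    return bags


def _val_loss(bags: list[FeatureBag], state: ModelState) -> float:
    probs = np.array([forward(b, state).prob_positive for b in bags])
    labels = np.array([b.label for b in bags])
    return float(cross_entropy(probs, labels).data)


def train(
    cohort: Cohort,
    prototypes: PrototypeSet | None,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
) -> tuple[ModelState, pd.DataFrame]:
    """Fit the model on the cohort's train split.

    Returns the state restored to the best validation loss and a
    history frame with per-epoch train/val losses. Deterministic given
    the config seeds.
    """
    if mcfg.prototype_mode == "cluster" and prototypes is None:
        raise ConfigError("cluster prototype mode requires a fitted PrototypeSet")
    train_bags = _split_or_raise(cohort, "train")
    val_bags = _split_or_raise(cohort, "val")

    n_protos = prototypes.L if prototypes is not None else 8
    state = init_model_state(mcfg, prototypes=prototypes, n_prototypes=n_protos)
    opt = Adam(state.trainable(), lr=tcfg.learning_rate, weight_decay=tcfg.weight_decay)
    rng = np.random.default_rng(tcfg.seed)

    weights = None
    if tcfg.class_weighted:
        labels = np.array([b.label for b in train_bags])
        freq = {y: max(1, int((labels == y).sum())) for y in (0, 1)}
        weights = {y: len(labels) / (2.0 * freq[y]) for y in (0, 1)}

    best = {"loss": np.inf, "arrays": state.clone_arrays(), "epoch": -1}
    rows = []
    bad_epochs = 0
    for epoch in range(tcfg.epochs):
        order = rng.permutation(len(train_bags))
        epoch_losses = []
        for start in range(0, len(order), tcfg.batch_size):
            batch = [train_bags[i] for i in order[start : start + tcfg.batch_size]]
            probs_t, ys, ws = [], [], []
            for b in batch:
                seed = int(rng.integers(0, 2**31 - 1))
                res = forward(b, state, training=True, seed=seed)
                probs_t.append(res._probs_t[1])
                ys.append(b.label)
                ws.append(weights[b.label] if weights else 1.0)
            loss = cross_entropy(probs_t, ys, ws if weights else None)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        vloss = _val_loss(val_bags, state)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                     "val_loss": vloss})
        if vloss < best["loss"] - 1e-12:
            best = {"loss": vloss, "arrays": state.clone_arrays(), "epoch": epoch}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= tcfg.early_stop_patience:
                break
    state.load_arrays(best["arrays"])
    return state, pd.DataFrame(rows)


def predict_bags(bags: list[FeatureBag], state: ModelState) -> pd.DataFrame:
    rows = [
        {
            "bag_id": b.bag_id,
            "label": b.label,
            "prob": forward(b, state).prob_positive,
        }
        for b in bags
    ]
    return pd.DataFrame(rows)


def evaluate(state: ModelState, cohort: Cohort, split: str = "test") -> EvalReport:
    """Predict a split and compute the full metric suite.

    Class metrics threshold at 0.5; rank metrics require both classes in
    the split (a single-class split raises :class:`DataError`).
    """
    bags = _split_or_raise(cohort, split)
    per_bag = predict_bags(bags, state)
    labels = per_bag["label"].to_numpy()
    probs = per_bag["prob"].to_numpy()
    if len(np.unique(labels)) < 2:
        raise DataError("AUROC/AUPRC undefined on a single-class split")
    return EvalReport(metrics=binary_metrics(labels, probs), per_bag=per_bag)


def run_repeats(
    cohort: Cohort,
    prototypes: PrototypeSet | None,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    split: str = "test",
) -> EvalReport:
    """Repeat train+evaluate with seed offsets; report mean and sd."""
    if tcfg.n_repeats < 1:
        raise ParameterError("n_repeats must be >= 1")
    reports = []
    for r in range(tcfg.n_repeats):
        m_r = ModelConfig(**{**mcfg.__dict__, "seed": mcfg.seed + r})
        t_r = TrainConfig(**{**tcfg.__dict__, "seed": tcfg.seed + r})
        state, _ = train(cohort, prototypes, m_r, t_r)
        reports.append(evaluate(state, cohort, split))
    mean = {k: float(np.mean([rep.metrics[k] for rep in reports])) for k in METRIC_NAMES}
    sd = {k: float(np.std([rep.metrics[k] for rep in reports])) for k in METRIC_NAMES}
    return EvalReport(
        metrics=mean,
        per_bag=reports[-1].per_bag,
        metrics_sd=sd,
        per_repeat=[rep.metrics for rep in reports],
    )
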