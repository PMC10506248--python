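"""Experiment protocol: per-target models, k-fold CV, held-out testing.

The protocol mirrors the training recipe the architectures were designed
for: one binary model per segmentation target, Adam at learning rate 1e-4,
batch size 2, smoothed Dice loss, at most 100 epochs with early stopping on
the validation Dice loss, tenfold cross-validation, and a 10% test split
reserved only when more than 100 samples are available. Everything is
deterministic given the plan seed (split) and the train seed (weights and
data order).

The module exposes both the functional surface (:func:`make_plan`,
:func:`train_model`, :func:`cross_validate`, :func:`evaluate`) and a thin
model/results pair (:class:`SegmentationExperiment` /
:class:`SegmentationResults`) for interactive use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .losses import DiceParams, dice_loss, dice_score
from .ndnn.autograd import Tensor
from .ndnn.optim import Adam
from .nets import ArchitectureCfg, binarize, build_model
from .phantoms import PhantomSample
from .preprocess import PreprocessConfig, preprocess


class PlanningError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    batch_size: int = 2
    max_epochs: int = 100
    early_stop_patience: int = 10
    seed: int = 0
    dice: DiceParams = field(default_factory=DiceParams)

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("lr must be > 0, batch_size >= 1, max_epochs >= 1")


@dataclass
class ExperimentPlan:
    target: str
    arch: ArchitectureCfg
    folds: List[np.ndarray]          # index arrays into the sample list
    test_indices: np.ndarray
    preprocess_cfg: PreprocessConfig
    n: int
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    @property
    def cv_pool_size(self) -> int:
        return sum(len(f) for f in self.folds)

    def train_indices(self, fold_index: int) -> np.ndarray:
        return np.concatenate([f for i, f in enumerate(self.folds) if i != fold_index])


@dataclass
class MetricsRecord:
    target: str
    fold_dice: List[float]
    per_sample: Dict[int, float]     # sample index -> validation Dice
    test_dice: Optional[float] = None
    best_fold: Optional[int] = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_dice))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_dice))


def make_plan(n: int, k: int = 10, seed: int = 0, target: str = "thigh_sat",
              arch: Optional[ArchitectureCfg] = None,
              preprocess_cfg: Optional[PreprocessConfig] = None) -> ExperimentPlan:
    """Deterministic shuffled split into a test set (10% iff n > 100) and k folds."""
    if arch is None:
        arch = ArchitectureCfg("ghost_unetpp")
    if preprocess_cfg is None:
        preprocess_cfg = PreprocessConfig.for_target(target)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = math.floor(0.10 * n) if n > 100 else 0
    test_idx = np.sort(perm[:n_test])
    pool = perm[n_test:]
    if len(pool) < k:
        raise PlanningError(f"cannot make {k} folds from a pool of {len(pool)} samples")
    folds = [np.sort(f) for f in np.array_split(pool, k)]
    return ExperimentPlan(target=target, arch=arch, folds=folds,
                          test_indices=test_idx, preprocess_cfg=preprocess_cfg,
                          n=n, seed=seed)


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def prepare_arrays(samples: Sequence[PhantomSample], plan: ExperimentPlan
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Preprocess every slice and stack (X, Y) as NCHW float32 arrays."""
    xs, ys = [], []
    for s in samples:
        xs.append(preprocess(s.slice, plan.preprocess_cfg).astype(np.float32))
        ys.append(s.masks[plan.target].pixels.astype(np.float32))
    return np.stack(xs)[:, None], np.stack(ys)[:, None]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _validation_loss(model, X, Y, dice: DiceParams) -> float:
    model.eval()
    losses = []
    for i in range(X.shape[0]):
        prob = model.forward(Tensor(X[i:i + 1])).data
        losses.append(dice_loss(prob[0, 0], Y[i, 0], dice))
    return float(np.mean(losses))


def train_model(plan: ExperimentPlan, fold_index: int,
                samples: Sequence[PhantomSample], cfg: TrainConfig = TrainConfig(),
                arrays: Optional[Tuple[np.ndarray, np.ndarray]] = None):
    """Train one fold; returns (model at best validation loss, history).

    ``arrays`` may carry precomputed (X, Y) from :func:`prepare_arrays` so
    repeated folds do not re-run preprocessing.
    """
    if not 0 <= fold_index < plan.k:
        raise PlanningError(f"fold_index {fold_index} out of range for k={plan.k}")
    val_idx = plan.folds[fold_index]
    train_idx = plan.train_indices(fold_index)
    if len(val_idx) == 0 or len(train_idx) == 0:
        raise PlanningError("empty training or validation fold")
    X, Y = prepare_arrays(samples, plan) if arrays is None else arrays

    model = build_model(plan.arch, seed=cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, fold_index, 911)))

    best_loss = np.inf
    best_state = model.copy_state()
    wait = 0
    history = {"train_loss": [], "val_loss": [], "stopped_epoch": None}
    for epoch in range(cfg.max_epochs):
        model.train()
        order = rng.permutation(train_idx)
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            xb = Tensor(X[batch])
            prob = model.forward(xb)
            loss = dice_loss(prob, Y[batch], cfg.dice)
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        val = _validation_loss(model, X[val_idx], Y[val_idx], cfg.dice)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val)
        if val < best_loss - 1e-12:
            best_loss = val
            best_state = model.copy_state()
            wait = 0
        else:
            wait += 1
            if wait >= cfg.early_stop_patience:
                history["stopped_epoch"] = epoch + 1
                break
    model.load_state_arrays(best_state)
    model.eval()
    return model, history


def evaluate(model, X: np.ndarray, Y: np.ndarray, threshold: float = 0.5) -> List[float]:
    """Per-sample Dice of the binarized prediction against ground truth."""
    if X.shape != Y.shape:
        raise ValueError(f"evaluate: shape mismatch {X.shape} vs {Y.shape}")
    model.eval()
    scores = []
    for i in range(X.shape[0]):
        prob = model.forward(Tensor(X[i:i + 1])).data[0, 0]
        pred = binarize(prob, threshold)
        scores.append(dice_score(pred.pixels, Y[i, 0] >= 0.5))
    return scores


def cross_validate(plan: ExperimentPlan, samples: Sequence[PhantomSample],
                   cfg: TrainConfig = TrainConfig()) -> MetricsRecord:
    """Train every fold, score each held-out fold, test the best fold model."""
    X, Y = prepare_arrays(samples, plan)
    fold_dice: List[float] = []
    per_sample: Dict[int, float] = {}
    best_fold, best_fold_loss, best_model = None, np.inf, None
    for fold in range(plan.k):
        model, history = train_model(plan, fold, samples, cfg, arrays=(X, Y))
        val_idx = plan.folds[fold]
        scores = evaluate(model, X[val_idx], Y[val_idx])
        fold_dice.append(float(np.mean(scores)))
        per_sample.update({int(i): s for i, s in zip(val_idx, scores)})
        fold_loss = min(history["val_loss"])
        if fold_loss < best_fold_loss:
            best_fold_loss, best_fold, best_model = fold_loss, fold, model
    test_dice = None
    if len(plan.test_indices):
        test_scores = evaluate(best_model, X[plan.test_indices], Y[plan.test_indices])
        test_dice = float(np.mean(test_scores))
    return MetricsRecord(target=plan.target, fold_dice=fold_dice,
                         per_sample=per_sample, test_dice=test_dice,
                         best_fold=best_fold)


# ---------------------------------------------------------------------------
# model/results front end
# ---------------------------------------------------------------------------

class SegmentationExperiment:
    """One target, one architecture, one dataset; ``fit()`` runs the CV."""

    def __init__(self, samples: Sequence[PhantomSample], plan: ExperimentPlan,
                 train_config: TrainConfig = TrainConfig()):
        self.samples = list(samples)
        if len(self.samples) != plan.n:
            raise PlanningError(f"plan was made for n={plan.n}, got {len(self.samples)} samples")
        self.plan = plan
        self.train_config = train_config

    @classmethod
    def from_samples(cls, samples: Sequence[PhantomSample], target: str,
                     arch: Optional[ArchitectureCfg] = None, k: int = 10,
                     seed: int = 0, train_config: TrainConfig = TrainConfig()):
        plan = make_plan(len(samples), k=k, seed=seed, target=target, arch=arch)
        return cls(samples, plan, train_config)

    def fit(self) -> "SegmentationResults":
        record = cross_validate(self.plan, self.samples, self.train_config)
        return SegmentationResults(self, record)


class SegmentationResults:
    def __init__(self, experiment: SegmentationExperiment, record: MetricsRecord):
        self.experiment = experiment
        self.record = record

    @property
    def mean_dice(self) -> float:
        return self.record.mean

    def summary(self) -> str:
        p = self.experiment.plan
        r = self.record
        lines = [
            "Segmentation cross-validation results",
            "=" * 45,
            f"target:          {p.target}",
            f"architecture:    {p.arch.name}  widths={list(p.arch.widths)}",
            f"samples:         {p.n}  (CV pool {p.cv_pool_size}, test {len(p.test_indices)})",
            f"folds:           {p.k}",
            f"mean Dice (CV):  {r.mean:.4f} +/- {r.sd:.4f}",
        ]
        for i, d in enumerate(r.fold_dice):
            lines.append(f"  fold {i}: Dice {d:.4f}")
        if r.test_dice is not None:
            lines.append(f"test Dice (best fold {r.best_fold}): {r.test_dice:.4f}")
        return "\n".join(lines)
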