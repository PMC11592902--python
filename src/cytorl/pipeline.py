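"""Two-stage training orchestration.

Stage 1 trains the CNN-ViT-supporter classifier with uniform class weights.
Stage 2 continues training inside the reinforcement-learning environment:
at each mini-batch the agent observes the running class statistics, adjusts
the class-weight vector, the weighted cross-entropy backpropagates, the
batch reward (minority-focused) is computed from the batch predictions, and
the DQN learns from the stored transition.  One environment step is one
mini-batch; episodes terminate at epoch boundaries.

The loss is class-weighted cross-entropy: mean_i w_{y_i} * (-log p_i[y_i]),
with the probability at the true label clamped at 1e-12.  "Best" checkpoint
selection uses validation macro-F1, matching the imbalance emphasis of the
evaluation metrics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import AugmentConfig, PreprocConfig, augment, load_pixels, preprocess
from .manifest import DatasetManifest
from .metrics import MetricsReport, confusion_matrix, macro_metrics
from .model import CytologyClassifier, ModelConfig
from .nn import Adam, Tensor
from .rl import (DQNAgent, RewardConfig, RLConfig, RunningClassStats,
                 Transition, WeightVector, apply_action, batch_reward)

__all__ = [
    "StageConfig", "Checkpoint", "ArrayDataset", "weighted_loss",
    "train_stage1", "train_stage2", "evaluate_model", "run_cv", "TrainResult",
]


@dataclass(frozen=True)
class StageConfig:
    epochs: int = 8
    batch_size: int = 16
    lr: float = 1e-3
    seed: int = 0
    stage: str = "stage1"

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if self.stage not in ("stage1", "stage2"):
            raise ValueError("stage must be 'stage1' or 'stage2'")


@dataclass
class TrainResult:
    checkpoint: "Checkpoint"
    history: list[dict]
    seen_paths: set = field(default_factory=set)
    weight_trajectory: list[dict] = field(default_factory=list)


@dataclass
class Checkpoint:
    params: dict[str, np.ndarray]
    config_fingerprint: str
    stage: str
    best_val_macro_f1: float = float("nan")

    def save(self, path: Path | str) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **self.params)
        meta = {
            "config_fingerprint": self.config_fingerprint,
            "stage": self.stage,
            "best_val_macro_f1": self.best_val_macro_f1,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        return path if path.suffix == ".npz" else path.with_suffix(".npz")

    @classmethod
    def load(cls, path: Path | str) -> "Checkpoint":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        with np.load(path) as data:
            params = {k: data[k].copy() for k in data.files}
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(params, meta["config_fingerprint"], meta["stage"],
                   meta["best_val_macro_f1"])


def config_fingerprint(cfg: ModelConfig) -> str:
    return hashlib.sha256(repr(cfg).encode()).hexdigest()[:16]


class ArrayDataset:
    """Manifest materialised as arrays: X (N, C, H, W) in [0,1], y (N,)."""

    def __init__(self, manifest: DatasetManifest, preproc: PreprocConfig):
        xs, ys = [], []
        for rec in manifest.records:
            img = preprocess(load_pixels(rec.path), preproc)
            xs.append(img.transpose(2, 0, 1))
            ys.append(rec.label)
        self.x = np.stack(xs)
        self.y = np.asarray(ys, dtype=int)
        self.paths = [str(r.path) for r in manifest.records]
        self.n_classes = int(self.y.max()) + 1 if len(ys) else 0

    def __len__(self):
        return len(self.y)


def weighted_loss(probabilities: Tensor, labels: np.ndarray,
                  weights: WeightVector) -> Tensor:
    """mean_i w_{y_i} * (-log p_i[y_i]); p clamped at 1e-12."""
    labels = np.asarray(labels, dtype=int)
    n = labels.shape[0]
    p_true = probabilities[np.arange(n), labels]
    w = weights.as_array()[labels]
    return (Tensor(w) * -(p_true.clip_min(1e-12).log())).mean()


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _augmented(x: np.ndarray, aug: AugmentConfig | None, epoch: int,
               indices: np.ndarray) -> np.ndarray:
    if aug is None:
        return x[indices]
    out = []
    for i in indices:
        hwc = x[i].transpose(1, 2, 0)
        sample_seed = epoch * 1_000_003 + int(i)
        out.append(augment(hwc, aug, sample_seed).transpose(2, 0, 1))
    return np.stack(out)


def _eval_arrays(model: CytologyClassifier, data: ArrayDataset,
                 batch_size: int = 64) -> MetricsReport:
    preds = []
    for start in range(0, len(data), batch_size):
        preds.append(model.predict(data.x[start : start + batch_size]))
    preds = np.concatenate(preds) if preds else np.empty(0, int)
    cm = confusion_matrix(preds, data.y, model.cfg.n_classes)
    return macro_metrics(cm)


def evaluate_model(model: CytologyClassifier, manifest: DatasetManifest,
                   preproc: PreprocConfig) -> MetricsReport:
    return _eval_arrays(model, ArrayDataset(manifest, preproc))


def _check_finite(loss_value: float, epoch: int) -> None:
    if not np.isfinite(loss_value):
        raise RuntimeError(
            f"training diverged: non-finite loss at epoch {epoch}"
        )


def train_stage1(model: CytologyClassifier, train_m: DatasetManifest,
                 val_m: DatasetManifest, cfg: StageConfig,
                 preproc: PreprocConfig, aug: AugmentConfig | None = None,
                 target_val_accuracy: float | None = None) -> TrainResult:
    """Uniform-weight training; returns the best-validation checkpoint.

    ``target_val_accuracy`` optionally stops early once validation accuracy
    reaches the target (the epoch budget is the cap either way).
    """
    train = ArrayDataset(train_m, preproc)
    val = ArrayDataset(val_m, preproc)
    uniform = WeightVector.uniform(model.cfg.n_classes)
    opt = Adam(model.parameters(), cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []
    best = (-np.inf, model.state_dict())
    for epoch in range(cfg.epochs):
        losses = []
        for idx in _epoch_batches(len(train), cfg.batch_size, rng):
            xb = _augmented(train.x, aug, epoch, idx)
            probs = model(Tensor(xb))
            loss = weighted_loss(probs, train.y[idx], uniform)
            _check_finite(float(loss.data), epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        rep = _eval_arrays(model, val)
        history.append({
            "epoch": epoch, "train_loss": float(np.mean(losses)),
            "val_accuracy": rep.accuracy, "val_macro_f1": rep.macro_f1,
        })
        if rep.macro_f1 > best[0]:
            best = (rep.macro_f1, model.state_dict())
        if target_val_accuracy is not None and rep.accuracy >= target_val_accuracy:
            break
    model.load_state_dict(best[1])
    ckpt = Checkpoint(best[1], config_fingerprint(model.cfg), "stage1", best[0])
    seen = set(train.paths) | set(val.paths)
    return TrainResult(ckpt, history, seen)


def train_stage2(model: CytologyClassifier, checkpoint: Checkpoint,
                 train_m: DatasetManifest, val_m: DatasetManifest,
                 cfg: StageConfig, preproc: PreprocConfig,
                 reward_cfg: RewardConfig, rl_cfg: RLConfig,
                 aug: AugmentConfig | None = None,
                 agent: DQNAgent | None = None,
                 rl_enabled: bool = True) -> TrainResult:
    """RL-reweighted continuation from a stage-1 checkpoint.

    With ``rl_enabled=False`` (or an agent frozen to the no-op action) the
    loop consumes randomness identically but leaves the weights uniform, so
    it reproduces plain continued training exactly.
    """
    if checkpoint.config_fingerprint != config_fingerprint(model.cfg):
        raise ValueError("checkpoint does not match the model configuration")
    model.load_state_dict(checkpoint.params)
    train = ArrayDataset(train_m, preproc)
    val = ArrayDataset(val_m, preproc)
    c = model.cfg.n_classes
    weights = WeightVector.uniform(c, rl_cfg.w_min, rl_cfg.w_max)
    stats = RunningClassStats(c, rl_cfg.state_window)
    if agent is None and rl_enabled:
        agent = DQNAgent(state_dim=3 * c, n_classes=c, cfg=rl_cfg, seed=cfg.seed)
    opt = Adam(model.parameters(), cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []
    trajectory: list[dict] = []
    best = (-np.inf, model.state_dict())
    step = 0
    for epoch in range(cfg.epochs):
        batches = list(_epoch_batches(len(train), cfg.batch_size, rng))
        losses, rewards = [], []
        for bi, idx in enumerate(batches):
            state = stats.state_vector(weights)
            if rl_enabled:
                action = agent.act(state)
                weights = apply_action(weights, action, rl_cfg.beta)
            else:
                action = 0
            xb = _augmented(train.x, aug, epoch, idx)
            probs = model(Tensor(xb))
            loss = weighted_loss(probs, train.y[idx], weights)
            _check_finite(float(loss.data), epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            preds = probs.data.argmax(axis=1)
            stats.update(probs.data, train.y[idx])
            reward = batch_reward(preds, train.y[idx], reward_cfg)
            next_state = stats.state_vector(weights)
            terminal = bi == len(batches) - 1
            if rl_enabled:
                agent.observe(Transition(state, action, reward,
                                         next_state, terminal))
            trajectory.append({
                "step": step, "epoch": epoch, "action": action,
                "reward": reward, **{f"w{i}": w for i, w in
                                     enumerate(weights.values)},
            })
            losses.append(float(loss.data))
            rewards.append(reward)
            step += 1
        rep = _eval_arrays(model, val)
        history.append({
            "epoch": epoch, "train_loss": float(np.mean(losses)),
            "mean_reward": float(np.mean(rewards)),
            "val_accuracy": rep.accuracy, "val_macro_f1": rep.macro_f1,
        })
        if rep.macro_f1 > best[0]:
            best = (rep.macro_f1, model.state_dict())
    model.load_state_dict(best[1])
    ckpt = Checkpoint(best[1], config_fingerprint(model.cfg), "stage2", best[0])
    seen = set(train.paths) | set(val.paths)
    return TrainResult(ckpt, history, seen, trajectory)


def save_trajectory(trajectory: list[dict], path: Path | str) -> None:
    """Audit log of (step, action, reward, weights) as CSV."""
    pd.DataFrame(trajectory).to_csv(path, index=False)


def run_cv(folds: list[tuple[DatasetManifest, DatasetManifest]],
           model_factory, cfg: StageConfig, preproc: PreprocConfig,
           aug: AugmentConfig | None = None) -> tuple[list[MetricsReport], dict]:
    """Train a fresh model per (fit, holdout) fold; aggregate mean/sd."""
    reports: list[MetricsReport] = []
    for i, (fit_m, hold_m) in enumerate(folds):
        model = model_factory(i)
        train_stage1(model, fit_m, hold_m, cfg, preproc, aug)
        reports.append(evaluate_model(model, hold_m, preproc))
    keys = ["accuracy", "macro_precision", "macro_recall", "macro_f1",
            "macro_specificity", "g_means"]
    agg = {}
    for k in keys:
        vals = np.array([getattr(r, k) for r in reports])
        agg[k] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))
                  if len(vals) > 1 else 0.0}
    return reports, agg
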