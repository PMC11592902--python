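"""Canned desk-scale experiments.

``imbalance_experiment`` is the package's core behavioural study: on a
two-class synthetic dataset with 10:1 training imbalance, it trains the
classifier conventionally (stage 1), then continues training inside the
RL reweighting environment (stage 2), and measures minority-class recall
on a balanced held-out probe set generated independently of the training
data.  The probe set gives minority recall a finer resolution than the tiny
test split would.  Run it over several paired seeds and compare the stage-2
recall to the stage-1 recall.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import PreprocConfig, SplitSpec, stratified_split
from .model import CytologyClassifier, ModelConfig
from .pipeline import ArrayDataset, StageConfig, train_stage1, train_stage2
from .rl import RewardConfig, RLConfig
from .synthetic import generate_dataset, imbalanced_pair_specs

__all__ = ["ImbalanceResult", "imbalance_experiment", "paired_imbalance_study"]

# study conditions: 10:1 imbalance, 64px renders preprocessed to 32px gray
N_MAJORITY = 200
N_MINORITY = 20
PROBE_PER_CLASS = 40
RENDER_SIZE = (64, 64)
PREPROC = PreprocConfig(target_size=(32, 32), grayscale=True)
STAGE1 = dict(epochs=8, batch_size=16, lr=3e-3)
STAGE2 = dict(epochs=20, batch_size=16, lr=2e-3)


@dataclass
class ImbalanceResult:
    seed: int
    stage1_minority_recall: float
    stage2_minority_recall: float
    stage1_majority_recall: float
    stage2_majority_recall: float
    final_weights: tuple[float, ...]
    weight_trajectory: list[dict]

    @property
    def recall_gain(self) -> float:
        return self.stage2_minority_recall - self.stage1_minority_recall


def _class_recalls(model: CytologyClassifier, data: ArrayDataset
                   ) -> dict[int, float]:
    preds = model.predict(data.x)
    return {c: float((preds[data.y == c] == c).mean())
            for c in np.unique(data.y)}


def imbalance_experiment(seed: int, work_dir: Path | str,
                         n_majority: int = N_MAJORITY,
                         n_minority: int = N_MINORITY) -> ImbalanceResult:
    """One paired stage-1 / stage-2 run at the given seed."""
    work = Path(work_dir)
    manifest = generate_dataset(
        imbalanced_pair_specs(n_majority, n_minority), seed, RENDER_SIZE,
        work / f"train_{seed}", overwrite=True,
    )
    train_m, val_m, _ = stratified_split(manifest, SplitSpec(seed=seed))
    probe_m = generate_dataset(
        imbalanced_pair_specs(PROBE_PER_CLASS, PROBE_PER_CLASS),
        seed + 10_000, RENDER_SIZE, work / f"probe_{seed}", overwrite=True,
    )
    probe = ArrayDataset(probe_m, PREPROC)

    model = CytologyClassifier(ModelConfig(n_classes=2, seed=seed))
    res1 = train_stage1(model, train_m, val_m,
                        StageConfig(seed=seed, **STAGE1), PREPROC)
    rec1 = _class_recalls(model, probe)

    reward_cfg = RewardConfig.from_frequencies({0: n_majority, 1: n_minority})
    n_steps = STAGE2["epochs"] * int(np.ceil(len(train_m) / STAGE2["batch_size"]))
    rl_cfg = RLConfig(epsilon_decay_steps=n_steps // 2)
    res2 = train_stage2(model, res1.checkpoint, train_m, val_m,
                        StageConfig(seed=seed + 1, stage="stage2", **STAGE2),
                        PREPROC, reward_cfg, rl_cfg)
    rec2 = _class_recalls(model, probe)

    last = res2.weight_trajectory[-1]
    weights = tuple(last[k] for k in sorted(last) if k.startswith("w"))
    return ImbalanceResult(seed, rec1[1], rec2[1], rec1[0], rec2[0],
                           weights, res2.weight_trajectory)


def paired_imbalance_study(seeds, work_dir: Path | str) -> list[ImbalanceResult]:
    return [imbalance_experiment(s, work_dir) for s in seeds]
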