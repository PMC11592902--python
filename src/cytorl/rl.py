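"""Deep-Q-learning machinery for class-imbalance reweighting.

The agent observes a compressed training state (per-class mean predicted
probability, per-class running recall over a sliding window, current class
weights), chooses among 2C+1 discrete actions — raise w_i, lower w_i for
each class i, or no-op — and is rewarded +1 for a correctly classified
minority sample, -1 for a misclassified minority sample, and +delta (0.1 by
default) for a correctly classified majority sample; a misclassified
majority sample earns 0.  Weight updates multiply or divide the chosen
class weight by beta, clip into [w_min, w_max] and renormalise to mean 1.

Q-learning follows the standard DQN recipe: epsilon-greedy behaviour over a
small MLP Q-network, FIFO replay buffer, Bellman targets
r + gamma * max_a' Q(s', a'; theta^-) from a periodically synced target
network, squared-error loss and SGD.  ``solve_mdp_exact`` provides the
value-iteration oracle used to validate the learner on tabular MDPs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "RewardConfig", "RLConfig", "WeightVector", "Transition",
    "compute_reward", "batch_reward", "QNetwork", "select_action",
    "apply_action", "ReplayBuffer", "bellman_target", "dqn_update",
    "TabularMDP", "solve_mdp_exact", "DQNAgent", "RunningClassStats",
]


@dataclass(frozen=True)
class RewardConfig:
    """Reward table over (correct?, minority?); delta rewards correct majority."""

    minority_classes: frozenset[int]
    n_classes: int
    r_minority_correct: float = 1.0
    r_minority_wrong: float = -1.0
    r_majority_correct: float = 0.1
    r_majority_wrong: float = 0.0

    def __post_init__(self):
        if not (self.r_minority_correct > self.r_majority_correct > 0.0
                > self.r_minority_wrong):
            raise ValueError(
                "rewards must satisfy minority_correct > majority_correct > 0 "
                "> minority_wrong"
            )
        bad = [c for c in self.minority_classes
               if not (0 <= c < self.n_classes)]
        if bad:
            raise ValueError(f"minority class ids out of range: {bad}")

    @classmethod
    def from_frequencies(cls, class_counts: dict[int, int], **kw) -> "RewardConfig":
        """Minority = classes whose frequency is below 1/C."""
        total = sum(class_counts.values())
        c = len(class_counts)
        minority = frozenset(k for k, v in class_counts.items() if v / total < 1.0 / c)
        return cls(minority_classes=minority, n_classes=c, **kw)


def compute_reward(predicted_class: int, true_class: int, cfg: RewardConfig) -> float:
    if not (0 <= true_class < cfg.n_classes and 0 <= predicted_class < cfg.n_classes):
        raise ValueError(
            f"class ids {predicted_class}, {true_class} out of range for "
            f"{cfg.n_classes} classes"
        )
    correct = predicted_class == true_class
    minority = true_class in cfg.minority_classes
    if minority:
        return cfg.r_minority_correct if correct else cfg.r_minority_wrong
    return cfg.r_majority_correct if correct else cfg.r_majority_wrong


def batch_reward(predictions, labels, cfg: RewardConfig) -> float:
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    if predictions.size == 0:
        raise ValueError("empty batch")
    return float(np.mean([compute_reward(int(p), int(y), cfg)
                          for p, y in zip(predictions, labels)]))


# ------------------------------------------------------------------ weights

@dataclass(frozen=True)
class WeightVector:
    """Positive per-class loss weights, renormalised to mean 1."""

    values: tuple[float, ...]
    w_min: float = 0.25
    w_max: float = 4.0

    def __post_init__(self):
        v = np.asarray(self.values)
        if np.any(v <= 0):
            raise ValueError("class weights must be positive")
        if abs(v.mean() - 1.0) > 1e-9:
            raise ValueError(f"class weights must have mean 1, got {v.mean()}")

    @classmethod
    def uniform(cls, n_classes: int, w_min: float = 0.25, w_max: float = 4.0):
        return cls((1.0,) * n_classes, w_min, w_max)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values)


def _project_weights(v: np.ndarray, w_min: float, w_max: float) -> np.ndarray:
    """Project onto {w_min <= w <= w_max, mean(w) = 1} (feasible since
    w_min <= 1 <= w_max): clip, then rescale the unclipped coordinates so the
    mean is restored, repeating while the rescale pushes new coordinates out
    of bounds."""
    n = v.size
    v = np.clip(v, w_min, w_max)
    for _ in range(n + 1):
        lo = v <= w_min + 1e-12
        hi = v >= w_max - 1e-12
        free = ~(lo | hi)
        deficit = n - v[lo].sum() - v[hi].sum()
        if not free.any():
            break
        scale = deficit / v[free].sum()
        v[free] *= scale
        if np.all((v >= w_min - 1e-12) & (v <= w_max + 1e-12)):
            break
        v = np.clip(v, w_min, w_max)
    v = np.clip(v, w_min, w_max)
    # final exact mean-1 touch-up on the free coordinates
    free = (v > w_min + 1e-12) & (v < w_max - 1e-12)
    if free.any():
        v[free] += (n - v.sum()) / free.sum()
    return v


def apply_action(w: WeightVector, action: int, beta: float = 1.2) -> WeightVector:
    """Action 0 is no-op; action 1+2i raises w_i, 2+2i lowers w_i.

    The chosen weight is multiplied/divided by beta, then the vector is
    projected back onto the feasible set (coordinates in [w_min, w_max],
    mean exactly 1).
    """
    c = len(w.values)
    if not (0 <= action < 2 * c + 1):
        raise ValueError(f"action {action} out of range for {2 * c + 1} actions")
    if action == 0:
        return w
    idx, direction = divmod(action - 1, 2)
    v = w.as_array().copy()
    v[idx] = v[idx] * beta if direction == 0 else v[idx] / beta
    v = v / v.mean()
    v = _project_weights(v, w.w_min, w.w_max)
    return WeightVector(tuple(v), w.w_min, w.w_max)


def n_actions(n_classes: int) -> int:
    return 2 * n_classes + 1


# -------------------------------------------------------------------- state

class RunningClassStats:
    """Sliding-window per-class mean probability and recall (the RL state)."""

    def __init__(self, n_classes: int, window: int = 256):
        self.n_classes = n_classes
        self.window = window
        self._records: deque[tuple[int, int, np.ndarray]] = deque(maxlen=window)

    def update(self, probs: np.ndarray, labels: np.ndarray) -> None:
        preds = probs.argmax(axis=1)
        for p, y, row in zip(preds, labels, probs):
            self._records.append((int(p), int(y), row.copy()))

    def state_vector(self, weights: WeightVector) -> np.ndarray:
        mean_prob = np.full(self.n_classes, 1.0 / self.n_classes)
        recall = np.zeros(self.n_classes)
        if self._records:
            probs = np.stack([r[2] for r in self._records])
            mean_prob = probs.mean(axis=0)
            for c in range(self.n_classes):
                mine = [r for r in self._records if r[1] == c]
                if mine:
                    recall[c] = np.mean([r[0] == r[1] for r in mine])
        return np.concatenate([mean_prob, recall, weights.as_array()])


@dataclass(frozen=True)
class Transition:
    state: np.ndarray
    action: int
    reward: float
    next_state: np.ndarray
    terminal: bool = False

    def __post_init__(self):
        if not np.isfinite(self.reward):
            raise ValueError("reward must be finite")


class ReplayBuffer:
    """FIFO experience store with uniform sampling."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self._buf: deque[Transition] = deque(maxlen=capacity)

    def push(self, t: Transition) -> None:
        self._buf.append(t)

    def __len__(self) -> int:
        return len(self._buf)

    def __iter__(self):
        return iter(self._buf)

    def sample(self, batch_size: int, rng: np.random.Generator) -> list[Transition]:
        idx = rng.integers(0, len(self._buf), size=batch_size)
        return [self._buf[i] for i in idx]


# ----------------------------------------------------------------- Q-network

class QNetwork(nn.Module):
    """Two-layer MLP mapping a state vector to Q-values per action."""

    def __init__(self, state_dim: int, n_act: int, hidden: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.fc1 = nn.Linear(state_dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, n_act, rng)

    def forward(self, states: Tensor) -> Tensor:
        return self.fc2(self.fc1(states).tanh())

    def q_values(self, state: np.ndarray) -> np.ndarray:
        return self.forward(Tensor(np.atleast_2d(state))).data[0]

    def clone(self) -> "QNetwork":
        out = QNetwork.__new__(QNetwork)
        rng = np.random.default_rng(0)
        out.fc1 = nn.Linear(self.fc1.weight.shape[0], self.fc1.weight.shape[1], rng)
        out.fc2 = nn.Linear(self.fc2.weight.shape[0], self.fc2.weight.shape[1], rng)
        out.load_state_dict(self.state_dict())
        return out


def select_action(qnet: QNetwork, state: np.ndarray, epsilon: float,
                  rng: np.random.Generator, n_act: int | None = None) -> int:
    """Epsilon-greedy over Q-values; greedy ties break to the lowest index."""
    if not (0.0 <= epsilon <= 1.0):
        raise ValueError("epsilon must be in [0, 1]")
    q = qnet.q_values(state)
    a_count = n_act if n_act is not None else q.shape[0]
    if epsilon > 0 and rng.random() < epsilon:
        return int(rng.integers(0, a_count))
    return int(np.argmax(q))  # np.argmax returns the first (lowest) maximiser


def softmax_policy(qnet: QNetwork, state: np.ndarray, temperature: float = 1.0
                   ) -> np.ndarray:
    """Softmax-over-Q readout of the action distribution (diagnostic only)."""
    q = qnet.q_values(state) / temperature
    e = np.exp(q - q.max())
    return e / e.sum()


def bellman_target(reward: float, next_state: np.ndarray, target_net: QNetwork,
                   gamma: float, terminal: bool = False) -> float:
    if not (0.0 <= gamma < 1.0):
        raise ValueError("gamma must be in [0, 1)")
    if terminal:
        return float(reward)
    return float(reward + gamma * target_net.q_values(next_state).max())


def dqn_update(qnet: QNetwork, target_net: QNetwork, batch: list[Transition],
               gamma: float, lr: float) -> float:
    """One SGD step on mean squared Bellman error; returns the loss value."""
    if not batch:
        raise ValueError("empty transition batch")
    states = np.stack([t.state for t in batch])
    targets = np.array([
        bellman_target(t.reward, t.next_state, target_net, gamma, t.terminal)
        for t in batch
    ])
    actions = np.array([t.action for t in batch])
    q_all = qnet(Tensor(states))
    q_sel = q_all[np.arange(len(batch)), actions]
    diff = q_sel - Tensor(targets)
    loss = (diff * diff).mean()
    qnet.zero_grad()
    loss.backward()
    opt = nn.SGD(qnet.parameters(), lr)
    opt.step()
    return float(loss.data)


@dataclass
class RLConfig:
    gamma: float = 0.9
    lr: float = 1e-2
    epsilon_start: float = 1.0
    epsilon_end: float = 0.05
    epsilon_decay_steps: int = 200
    replay_capacity: int = 2048
    batch_size: int = 32
    target_sync_period: int = 100
    beta: float = 1.2
    w_min: float = 0.25
    w_max: float = 4.0
    state_window: int = 256
    hidden: int = 32

    def __post_init__(self):
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError("gamma must be in [0, 1)")
        if self.replay_capacity < self.batch_size:
            raise ValueError("replay capacity must be >= batch size")

    def epsilon_at(self, step: int) -> float:
        if step >= self.epsilon_decay_steps:
            return self.epsilon_end
        frac = step / max(1, self.epsilon_decay_steps)
        return self.epsilon_start + frac * (self.epsilon_end - self.epsilon_start)


class DQNAgent:
    """Bundles Q-network, target network, replay buffer and schedules."""

    def __init__(self, state_dim: int, n_classes: int, cfg: RLConfig, seed: int = 0):
        self.cfg = cfg
        self.n_act = n_actions(n_classes)
        self.qnet = QNetwork(state_dim, self.n_act, cfg.hidden, seed=seed)
        self.target = self.qnet.clone()
        self.buffer = ReplayBuffer(cfg.replay_capacity)
        self.rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
        self.step_count = 0

    def act(self, state: np.ndarray, frozen_action: int | None = None) -> int:
        if frozen_action is not None:
            return frozen_action
        eps = self.cfg.epsilon_at(self.step_count)
        return select_action(self.qnet, state, eps, self.rng, self.n_act)

    def observe(self, transition: Transition) -> float | None:
        """Store a transition, learn if possible, sync the target on schedule."""
        self.buffer.push(transition)
        self.step_count += 1
        loss = None
        if len(self.buffer) >= self.cfg.batch_size:
            batch = self.buffer.sample(self.cfg.batch_size, self.rng)
            loss = dqn_update(self.qnet, self.target, batch,
                              self.cfg.gamma, self.cfg.lr)
        if self.step_count % self.cfg.target_sync_period == 0:
            self.target.load_state_dict(self.qnet.state_dict())
        return loss


# ---------------------------------------------------------- tabular oracle

@dataclass(frozen=True)
class TabularMDP:
    """Finite MDP: transition[s, a] -> s', reward[s, a] (deterministic)."""

    transitions: tuple[tuple[int, ...], ...]
    rewards: tuple[tuple[float, ...], ...]

    @property
    def n_states(self) -> int:
        return len(self.transitions)

    @property
    def n_actions(self) -> int:
        return len(self.transitions[0])


def solve_mdp_exact(mdp: TabularMDP, gamma: float, tol: float = 1e-10,
                    max_iter: int = 100000) -> np.ndarray:
    """Value iteration to a fixed point; returns the optimal Q table."""
    if gamma >= 1.0:
        raise ValueError("gamma must be < 1 for value iteration to converge")
    t = np.asarray(mdp.transitions)
    r = np.asarray(mdp.rewards)
    q = np.zeros_like(r)
    for _ in range(max_iter):
        v = q.max(axis=1)
        q_new = r + gamma * v[t]
        if np.abs(q_new - q).max() <= tol:
            return q_new
        q = q_new
    raise RuntimeError("value iteration did not converge")


def train_dqn_on_mdp(mdp: TabularMDP, gamma: float, seed: int = 0,
                     steps: int = 3000, lr: float = 5e-2,
                     batch_size: int = 32, sync_period: int = 50,
                     hidden: int = 32) -> QNetwork:
    """Run the DQN recipe on a tabular MDP with one-hot state encoding.

    Behaviour is epsilon-greedy with epsilon decaying linearly from 1 to
    0.05 over the first half of the run.  Used to validate the learner
    against the value-iteration oracle.
    """
    rng = np.random.default_rng(seed)
    n_s, n_a = mdp.n_states, mdp.n_actions
    eye = np.eye(n_s)
    qnet = QNetwork(n_s, n_a, hidden, seed=seed)
    target = qnet.clone()
    buffer = ReplayBuffer(capacity=4096)
    s = int(rng.integers(0, n_s))
    for step in range(steps):
        eps = max(0.05, 1.0 - 1.9 * step / steps)
        a = select_action(qnet, eye[s], eps, rng)
        s_next = mdp.transitions[s][a]
        r = mdp.rewards[s][a]
        buffer.push(Transition(eye[s], a, r, eye[s_next]))
        if len(buffer) >= batch_size:
            batch = buffer.sample(batch_size, rng)
            dqn_update(qnet, target, batch, gamma, lr)
        if (step + 1) % sync_period == 0:
            target.load_state_dict(qnet.state_dict())
        s = s_next
        # occasional restarts so all states keep being visited
        if rng.random() < 0.05:
            s = int(rng.integers(0, n_s))
    return qnet
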