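"""Tabular SARSA agent choosing the daily radiation dose.

The state is the pair of binned (healthy, cancer) cell counts; the action is
one of four dose levels delivered every 24 simulated hours.  The reward for
a decision window,

    r_k = -d_k / 400 + (c_k - 5 * h_k) / 100000,

trades the dose d_k (Gy) against the cancer cells killed c_k and five times
the healthy cells killed h_k in that window.  The action-value table is
updated on-policy:

    Q(s, a) <- Q(s, a) + eta * [ r + gamma * Q(s', a') - Q(s, a) ].
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SarsaConfig, StateBinning
from .radbio import SiteParams


@dataclass(frozen=True)
class DiscreteState:
    healthy_bin: int
    cancer_bin: int


@dataclass(frozen=True)
class RewardInputs:
    """One decision window's tallies: dose delivered, kills by kind."""

    d_k: float  # Gy
    c_k: int    # cancer cells killed since the previous decision
    h_k: int    # healthy cells killed since the previous decision

    def __post_init__(self) -> None:
        if self.d_k < 0 or self.c_k < 0 or self.h_k < 0:
            raise ValueError("reward inputs must be non-negative")


def reward(inputs: RewardInputs) -> float:
    """Signed per-decision reward (see module docstring)."""
    return -inputs.d_k / 400.0 + (inputs.c_k - 5.0 * inputs.h_k) / 100000.0


def discretize_state(healthy: int, cancer: int, binning: StateBinning) -> DiscreteState:
    """Total, deterministic binning of raw counts.

    Cancer bin 0 is reserved for eradication (cancer == 0) regardless of the
    healthy count bin; counts beyond the grids clip into the last bin.
    """
    if healthy < 0 or cancer < 0:
        raise ValueError("cell counts must be non-negative")
    hb = min(healthy // binning.healthy_bin_width, binning.n_healthy_bins - 1)
    cb = int(np.searchsorted(binning.cancer_edges, cancer, side="right"))
    return DiscreteState(int(hb), cb)


@dataclass
class QTable:
    """Dense action-value table; unvisited entries read 0."""

    binning: StateBinning
    n_actions: int = 4
    values: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.values is None:
            self.values = np.zeros(
                (self.binning.n_healthy_bins, self.binning.n_cancer_bins, self.n_actions)
            )
        expected = (self.binning.n_healthy_bins, self.binning.n_cancer_bins, self.n_actions)
        if self.values.shape != expected:
            raise ValueError(f"Q-table shape {self.values.shape} != binning shape {expected}")

    def row(self, s: DiscreteState) -> np.ndarray:
        return self.values[s.healthy_bin, s.cancer_bin]

    def get(self, s: DiscreteState, a: int) -> float:
        return float(self.values[s.healthy_bin, s.cancer_bin, a])

    def set(self, s: DiscreteState, a: int, v: float) -> None:
        self.values[s.healthy_bin, s.cancer_bin, a] = v

    # persistence (JSON keeps the table and its binning inseparable)
    def save(self, path: str) -> None:
        payload = {
            "binning": dataclasses.asdict(self.binning),
            "n_actions": self.n_actions,
            "values": self.values.tolist(),
        }
        payload["binning"]["cancer_edges"] = list(self.binning.cancer_edges)
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "QTable":
        with open(path) as fh:
            payload = json.load(fh)
        b = payload["binning"]
        binning = StateBinning(
            healthy_bin_width=b["healthy_bin_width"],
            n_healthy_bins=b["n_healthy_bins"],
            cancer_edges=tuple(b["cancer_edges"]),
        )
        return cls(binning=binning, n_actions=payload["n_actions"],
                   values=np.asarray(payload["values"], dtype=np.float64))


def select_action(q: QTable, s: DiscreteState, epsilon: float,
                  rng: np.random.Generator) -> int:
    """Epsilon-greedy action; greedy ties broken uniformly at random."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    if epsilon > 0 and rng.random() < epsilon:
        return int(rng.integers(q.n_actions))
    row = q.row(s)
    best = np.flatnonzero(row == row.max())
    return int(best[0]) if best.size == 1 else int(rng.choice(best))


def sarsa_update(q: QTable, s: DiscreteState, a: int, r: float,
                 s_next: DiscreteState | None, a_next: int | None,
                 eta: float, gamma: float) -> QTable:
    """One on-policy temporal-difference update, in place.

    A terminal transition is signalled with ``s_next=None`` (or
    ``a_next=None``) and bootstraps with 0.
    """
    q_next = 0.0 if s_next is None or a_next is None else q.get(s_next, a_next)
    td = r + gamma * q_next - q.get(s, a)
    q.set(s, a, q.get(s, a) + eta * td)
    return q


def epsilon_schedule(episode: int, config: SarsaConfig) -> float:
    """Linear decay from epsilon_start to epsilon_final over the first
    ``epsilon_decay_fraction`` of the episodes, flat afterwards."""
    horizon = max(1, int(config.n_episodes * config.epsilon_decay_fraction))
    t = min(1.0, episode / horizon)
    return config.epsilon_start + t * (config.epsilon_final - config.epsilon_start)


def train_agent(env_factory, sarsa_config: SarsaConfig,
                site: SiteParams | None = None) -> tuple[QTable, pd.DataFrame]:
    """Train a fresh table with on-policy SARSA over full treatment episodes.

    ``env_factory(seed)`` must return a reset environment exposing
    ``reset(seed) -> (healthy, cancer)`` and
    ``step(dose) -> object`` with attributes ``healthy, cancer,
    killed_healthy, killed_cancer, done``.  ``site`` is accepted for callers
    that build per-site factories but is otherwise unused here.

    Returns the learned table and a per-episode log (return, fractions,
    delivered dose, endpoint, epsilon).
    """
    cfg = sarsa_config
    q = QTable(binning=cfg.binning, n_actions=len(cfg.actions))
    rng = np.random.default_rng(cfg.rng_seed)
    log: list[dict] = []
    for ep in range(cfg.n_episodes):
        eps = epsilon_schedule(ep, cfg)
        env = env_factory(int(cfg.rng_seed + ep))
        healthy, cancer = env.reset(int(cfg.rng_seed + ep))
        s = discretize_state(healthy, cancer, cfg.binning)
        a = select_action(q, s, eps, rng)
        ep_return = 0.0
        doses: list[float] = []
        endpoint = "ongoing"
        while True:
            res = env.step(cfg.actions[a])
            doses.append(cfg.actions[a])
            r = reward(RewardInputs(d_k=cfg.actions[a], c_k=res.killed_cancer,
                                    h_k=res.killed_healthy))
            horizon = (cfg.max_fractions_train is not None
                       and len(doses) >= cfg.max_fractions_train)
            if res.done or horizon:
                # terminal outcome reward on top of the per-step trade-off
                if res.endpoint == "success":
                    r += cfg.success_reward
                elif res.endpoint == "failure":
                    r -= cfg.failure_penalty
                ep_return += r
                sarsa_update(q, s, a, r, None, None, cfg.eta, cfg.gamma)
                endpoint = res.endpoint if res.done else "horizon"
                break
            ep_return += r
            s_next = discretize_state(res.healthy, res.cancer, cfg.binning)
            a_next = select_action(q, s_next, eps, rng)
            sarsa_update(q, s, a, r, s_next, a_next, cfg.eta, cfg.gamma)
            s, a = s_next, a_next
        log.append({
            "episode": ep, "return": ep_return, "fractions": len(doses),
            "total_dose": float(np.sum(doses)), "endpoint": str(endpoint),
            "epsilon": eps,
        })
    return q, pd.DataFrame(log)


def greedy_policy(q: QTable, binning: StateBinning, actions: tuple,
                  rng: np.random.Generator):
    """A policy closure: greedy dose choice from a learned table."""

    def policy(healthy: int, cancer: int, k: int) -> float:
        s = discretize_state(healthy, cancer, binning)
        return actions[select_action(q, s, 0.0, rng)]

    return policy


def greedy_rollout(q: QTable, env, sarsa_config: SarsaConfig | None = None,
                   seed: int = 0):
    """Run one full treatment greedily (epsilon = 0) from a learned table.

    Returns the environment's :class:`~radfrac.experiments.TreatmentRecord`.
    """
    cfg = sarsa_config or SarsaConfig()
    rng = np.random.default_rng(seed)
    policy = greedy_policy(q, cfg.binning, cfg.actions, rng)
    from .experiments import run_treatment  # deferred: avoid import cycle

    return run_treatment(env, policy, seed)
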