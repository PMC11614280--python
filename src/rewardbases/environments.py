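"""Simulated task environments.

Three tasks exercise the agents:

* :class:`GridRoom` — a 6x6 grid with three objects, each activating its own
  reward basis. Two reward variants exist and are never mixed:
  ``"fig1"`` (free exploration: each basis pays +5 on its object's cell and
  -0.1 on every other cell) and ``"room"`` (episodic navigation: an object's
  cell pays +5 in its own dimension and -1 in the others, empty cells pay 0,
  and the episode ends when the currently valued object is reached).
* :class:`LeverTask` — two Pavlovian levers delivering juice or salt, with
  orthogonal one-hot reward bases.
* :class:`DevaluationTask` — two levers (food / sucrose) with stochastic
  outcomes: 80% the expected reward type (1 unit), 15% a switch to the other
  type (1 unit), 5% four units of the expected type.

States are flat integer indices; the grid uses row-major flattening. Actions
are the four cardinal moves and walls are absorbing-in-place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GridRoom",
    "LeverTask",
    "DevaluationTask",
    "Outcome",
    "ACTIONS",
    "grid_step",
    "reversal",
    "devaluation_trial",
    "lever_trial",
]

# action -> (d_row, d_col)
ACTIONS: dict[str, tuple[int, int]] = {
    "N": (-1, 0),
    "S": (1, 0),
    "E": (0, 1),
    "W": (0, -1),
}


@dataclass
class GridRoom:
    """Grid world with one object per reward basis.

    object_positions are flat state indices; if None they are drawn once,
    distinct, from the seeded RNG. variant selects the reward schedule
    ("fig1" or "room"); valued_dim only matters for the room variant, where
    reaching the valued object ends the episode.
    """

    width: int = 6
    height: int = 6
    n_bases: int = 3
    object_positions: tuple[int, ...] | None = None
    object_dims: tuple[int, ...] | None = None
    valued_dim: int = 0
    variant: str = "room"
    object_reward: float = 5.0
    off_dim_reward: float = -1.0  # room variant, other dimensions at an object
    step_penalty: float = -0.1  # fig1 variant, every non-object cell
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("fig1", "room"):
            raise ValueError("variant must be 'fig1' or 'room'")
        if self.object_dims is None:
            self.object_dims = tuple(range(self.n_bases))
        if self.object_positions is None:
            rng = np.random.default_rng(self.seed)
            pos = rng.choice(self.n_states, size=len(self.object_dims), replace=False)
            self.object_positions = tuple(int(p) for p in pos)
        if len(set(self.object_positions)) != len(self.object_positions):
            raise ValueError("object positions must be distinct")
        for p in self.object_positions:
            if not 0 <= p < self.n_states:
                raise ValueError(f"object position {p} out of bounds")
        if not 0 <= self.valued_dim < self.n_bases:
            raise ValueError("valued_dim out of range")

    @property
    def n_states(self) -> int:
        return self.width * self.height

    def to_cell(self, x: int) -> tuple[int, int]:
        return divmod(x, self.width)

    def from_cell(self, row: int, col: int) -> int:
        return row * self.width + col

    def reward_at(self, x: int) -> np.ndarray:
        """Reward vector received on arriving at state x."""
        r = np.zeros(self.n_bases)
        if self.variant == "fig1":
            r[:] = self.step_penalty
            for pos, dim in zip(self.object_positions, self.object_dims):
                if x == pos:
                    r[:] = self.step_penalty
                    r[dim] = self.object_reward
                    return r
            return r
        # room variant: objects only, empty squares give 0 in all dimensions
        for pos, dim in zip(self.object_positions, self.object_dims):
            if x == pos:
                r[:] = self.off_dim_reward
                r[dim] = self.object_reward
                return r
        return r

    def is_terminal(self, x: int) -> bool:
        if self.variant != "room":
            return False
        for pos, dim in zip(self.object_positions, self.object_dims):
            if x == pos and dim == self.valued_dim:
                return True
        return False

    def random_start(self, rng: np.random.Generator) -> int:
        """Uniform random cell excluding object cells (episode restart)."""
        free = [s for s in range(self.n_states) if s not in self.object_positions]
        return int(rng.choice(free))


def grid_step(
    env: GridRoom, x: int, action: str
) -> tuple[int, np.ndarray, bool]:
    """Move one cell; off-grid moves leave the position unchanged.

    Returns (x_next, reward vector at x_next, terminal flag). Terminal is True
    only in the room variant when x_next holds the valued object.
    """
    if action not in ACTIONS:
        raise ValueError(f"invalid action {action!r}; must be one of N,S,E,W")
    if not 0 <= x < env.n_states:
        raise IndexError(f"state {x} out of bounds")
    row, col = env.to_cell(x)
    drow, dcol = ACTIONS[action]
    nrow, ncol = row + drow, col + dcol
    if 0 <= nrow < env.height and 0 <= ncol < env.width:
        x_next = env.from_cell(nrow, ncol)
    else:
        x_next = x
    return x_next, env.reward_at(x_next), env.is_terminal(x_next)


def reversal(env: GridRoom, new_valued_dim: int) -> GridRoom:
    """Return a copy of the environment with only the valued dimension changed.

    Reward-bases and successor agents adapt by re-weighting; a TD agent sees a
    changed total reward and must relearn.
    """
    if not 0 <= new_valued_dim < env.n_bases:
        raise IndexError("valued dimension out of range")
    return replace(env, valued_dim=new_valued_dim)


@dataclass
class LeverTask:
    """Two Pavlovian levers: juice (basis 0) and salt (basis 1).

    Each lever's reward basis is one-hot: juice lever pays (+1 juice, 0 salt),
    salt lever pays (0 juice, +1 salt). States: 0 = juice lever, 1 = salt lever.
    """

    JUICE: int = 0
    SALT: int = 1
    n_states: int = 2
    n_bases: int = 2

    def reward_at(self, lever: int) -> np.ndarray:
        r = np.zeros(self.n_bases)
        r[lever] = 1.0
        return r


def lever_trial(
    env: LeverTask, rng: np.random.Generator
) -> tuple[int, np.ndarray]:
    """Random exposure to one of the two levers; returns (lever, reward vector)."""
    lever = int(rng.integers(2))
    return lever, env.reward_at(lever)


@dataclass(frozen=True)
class Outcome:
    """Outcome of one devaluation-task trial: reward type and amount."""

    type: str
    amount: float


@dataclass
class DevaluationTask:
    """Probabilistic two-lever task with food and sucrose rewards.

    After pressing a lever: with p_expected the lever's own reward type is
    delivered (1 unit), with p_switch the other type (1 unit), with p_more the
    own type times more_multiplier. States: 0 = food lever, 1 = sucrose lever.
    """

    FOOD: int = 0
    SUCROSE: int = 1
    levers: tuple[str, str] = ("food", "sucrose")
    p_expected: float = 0.80
    p_switch: float = 0.15
    p_more: float = 0.05
    more_multiplier: float = 4.0
    n_states: int = 2
    n_bases: int = 2

    def __post_init__(self) -> None:
        total = self.p_expected + self.p_switch + self.p_more
        if not np.isclose(total, 1.0):
            raise ValueError("outcome probabilities must sum to 1")

    def reward_vector(self, outcome: Outcome) -> np.ndarray:
        """Outcome as a (food, sucrose) reward-basis vector."""
        r = np.zeros(self.n_bases)
        r[self.levers.index(outcome.type)] = outcome.amount
        return r


def devaluation_trial(
    env: DevaluationTask, chosen_lever: int, rng: np.random.Generator
) -> Outcome:
    """Sample the outcome of pressing a lever in the devaluation task."""
    if chosen_lever not in (env.FOOD, env.SUCROSE):
        raise ValueError(f"invalid lever {chosen_lever}")
    own = env.levers[chosen_lever]
    other = env.levers[1 - chosen_lever]
    u = rng.random()
    if u < env.p_expected:
        return Outcome(own, 1.0)
    if u < env.p_expected + env.p_switch:
        return Outcome(other, 1.0)
    return Outcome(own, env.more_multiplier)
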