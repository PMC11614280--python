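"""Tabular TD learning, reward-bases agents, and softmax choice.

The agents here are tabular: a value table indexed by environmental state.
Three learning rules are provided:

* :func:`td_update` — classic temporal-difference learning on a scalar reward,
  ``delta = r + gamma*V(x') - V(x)``, ``V(x) += alpha*delta``.
* :func:`rb_update` — one TD update per reward basis, each basis i seeing only
  its component reward r_i. The acted-upon value is recovered by
  :func:`compose_value` as ``V(x) = sum_i m_i V_i(x)``.
* :func:`modulated_rb_update` — the state-modulated variant in which the
  prediction error itself is scaled by the drive, ``mod_delta_i = m_i*delta_i``,
  and the value step is ``alpha*m_i*mod_delta_i`` (gradient descent on the
  squared modulated error), i.e. an effective learning rate alpha*m_i**2.

Terminal transitions drop the discounted future-value term; terminality is an
explicit flag on the transition sample, never a magic state index. Updates are
performed in place on the value table (which is also returned).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MotivationalState",
    "ValueBasisTable",
    "ScalarValueTable",
    "AgentConfig",
    "TransitionSample",
    "td_update",
    "rb_update",
    "modulated_rb_update",
    "compose_value",
    "softmax_choice",
]


@dataclass
class MotivationalState:
    """Vector of motivational drives m_i, one per reward basis.

    Drives are dimensionless weights mapping each reward dimension to current
    utility. Negative drives are legitimate (an aversive dimension, e.g. salt
    when replete, is trained with m = -1).
    """

    m: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if self.m.ndim != 1:
            raise ValueError("drives must be a 1-D vector")
        if not np.all(np.isfinite(self.m)):
            raise ValueError("drives must be finite")

    @property
    def n_bases(self) -> int:
        return self.m.shape[0]


@dataclass
class ScalarValueTable:
    """State-indexed vector of value estimates V(x)."""

    V: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        if self.V.ndim != 1:
            raise ValueError("scalar value table must be 1-D")

    @classmethod
    def zeros(cls, n_states: int) -> "ScalarValueTable":
        return cls(np.zeros(n_states))

    @property
    def n_states(self) -> int:
        return self.V.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"state": np.arange(self.n_states), "V": self.V})


@dataclass
class ValueBasisTable:
    """Per-basis, per-state value estimates V_i(x), shape (n_bases, n_states)."""

    V: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        if self.V.ndim != 2:
            raise ValueError("value basis table must be 2-D (n_bases, n_states)")

    @classmethod
    def zeros(cls, n_bases: int, n_states: int) -> "ValueBasisTable":
        return cls(np.zeros((n_bases, n_states)))

    @property
    def n_bases(self) -> int:
        return self.V.shape[0]

    @property
    def n_states(self) -> int:
        return self.V.shape[1]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            self.V.T, columns=[f"V_{i}" for i in range(self.n_bases)]
        )
        df.insert(0, "state", np.arange(self.n_states))
        return df


@dataclass
class AgentConfig:
    """Learning hyper-parameters shared by the tabular agents.

    alpha: learning rate in (0, 1].
    gamma: discount factor in [0, 1].
    temperature: softmax temperature (> 0) for action selection.
    seed: RNG seed recorded with every experiment.
    """

    alpha: float = 0.1
    gamma: float = 0.9
    temperature: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if not self.temperature > 0.0:
            raise ValueError("temperature must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TransitionSample:
    """One environmental transition x -> x_next with reward r.

    ``r`` is a scalar for TD learning or a vector (one entry per reward basis)
    for the reward-bases rules. ``terminal`` marks episode-ending transitions;
    the discounted future term is dropped for them and ``x_next`` is ignored
    by the updates.
    """

    x: int
    x_next: int
    r: np.ndarray | float
    terminal: bool = False


def _check_state(idx: int, n_states: int, name: str) -> None:
    if not 0 <= idx < n_states:
        raise IndexError(f"{name}={idx} out of range for {n_states} states")


def td_update(
    table: ScalarValueTable, sample: TransitionSample, cfg: AgentConfig
) -> tuple[ScalarValueTable, float]:
    """Temporal-difference update of a scalar value table.

    Returns the (in-place updated) table and the prediction error
    ``delta = r + gamma*V(x') - V(x)`` (future term omitted at terminals).
    """
    r = float(np.asarray(sample.r).reshape(()))
    if not np.isfinite(r):
        raise ValueError("reward must be finite")
    _check_state(sample.x, table.n_states, "x")
    if sample.terminal:
        future = 0.0
    else:
        _check_state(sample.x_next, table.n_states, "x_next")
        future = cfg.gamma * table.V[sample.x_next]
    delta = r + future - table.V[sample.x]
    table.V[sample.x] += cfg.alpha * delta
    return table, delta


def rb_update(
    table: ValueBasisTable, sample: TransitionSample, cfg: AgentConfig
) -> tuple[ValueBasisTable, np.ndarray]:
    """Per-basis TD update: each value basis sees only its component reward.

    Returns the table and the vector of per-basis prediction errors
    ``delta_i = r_i + gamma*V_i(x') - V_i(x)``.
    """
    r = np.atleast_1d(np.asarray(sample.r, dtype=float))
    if r.shape[0] != table.n_bases:
        raise ValueError(
            f"reward has {r.shape[0]} entries but table has {table.n_bases} bases"
        )
    if not np.all(np.isfinite(r)):
        raise ValueError("reward must be finite")
    _check_state(sample.x, table.n_states, "x")
    if sample.terminal:
        future = 0.0
    else:
        _check_state(sample.x_next, table.n_states, "x_next")
        future = cfg.gamma * table.V[:, sample.x_next]
    deltas = r + future - table.V[:, sample.x]
    table.V[:, sample.x] += cfg.alpha * deltas
    return table, deltas


def modulated_rb_update(
    table: ValueBasisTable,
    sample: TransitionSample,
    m: MotivationalState,
    cfg: AgentConfig,
) -> tuple[ValueBasisTable, np.ndarray]:
    """State-modulated reward-bases update.

    The modulated error is ``mod_delta_i = m_i * delta_i`` and the value step
    is ``alpha * m_i * mod_delta_i`` — gradient descent on (1/2) mod_delta_i^2,
    giving an effective learning rate alpha*m_i^2 per basis. A satiated basis
    (m_i = 0) is frozen; a negatively valued basis (m_i = -1) still learns the
    magnitude of its reward.
    """
    if m.n_bases != table.n_bases:
        raise ValueError("drive length must equal number of bases")
    r = np.atleast_1d(np.asarray(sample.r, dtype=float))
    if r.shape[0] != table.n_bases:
        raise ValueError(
            f"reward has {r.shape[0]} entries but table has {table.n_bases} bases"
        )
    if not np.all(np.isfinite(r)):
        raise ValueError("reward must be finite")
    _check_state(sample.x, table.n_states, "x")
    if sample.terminal:
        future = 0.0
    else:
        _check_state(sample.x_next, table.n_states, "x_next")
        future = cfg.gamma * table.V[:, sample.x_next]
    deltas = r + future - table.V[:, sample.x]
    mod_deltas = m.m * deltas
    table.V[:, sample.x] += cfg.alpha * m.m * mod_deltas
    return table, mod_deltas


def compose_value(table: ValueBasisTable, m: MotivationalState) -> ScalarValueTable:
    """Drive-weighted combination V(x) = sum_i m_i V_i(x).

    This is the instant-revaluation step: no learning, just re-weighting.
    The input table is not modified.
    """
    if m.n_bases != table.n_bases:
        raise ValueError("drive length must equal number of bases")
    return ScalarValueTable(m.m @ table.V)


def softmax_choice(
    values: np.ndarray, temperature: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Softmax selection: P(k) = exp(v_k/T) / sum_j exp(v_j/T).

    Computed with max-shifting so large values cannot overflow; probabilities
    are invariant to adding a constant to all values. Returns the probability
    vector and a sampled index.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be non-empty")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if not temperature > 0:
        raise ValueError("temperature must be > 0")
    z = v / temperature
    z -= z.max()
    p = np.exp(z)
    p /= p.sum()
    choice = int(rng.choice(v.size, p=p))
    return p, choice
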