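"""Successor representation and its relation to reward bases.

The successor matrix M holds discounted expected future state occupancies
under the current policy: M = I + gamma*T + gamma^2*T^2 + ... where T is the
state-transition matrix. Values follow as V = M r for any reward vector r, so
revaluation is a matrix-vector product. M is learned online, row by row:
on a transition x -> x', row x moves toward onehot(x) + gamma * row x'.

A value basis is V_i = M r_i, so stacking M r_i over bases reproduces the
reward-bases value table; composing those with drives m equals M (sum m_i r_i)
exactly. The storage trade-off is n_states*n_bases numbers for reward bases
versus n_states**2 for the successor matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .agents import MotivationalState, ScalarValueTable, ValueBasisTable

__all__ = [
    "SuccessorMatrix",
    "RewardVector",
    "sr_update",
    "sr_value",
    "rb_from_sr",
    "memory_footprint",
]


@dataclass
class SuccessorMatrix:
    """Square state-by-state matrix of discounted expected occupancies."""

    M: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2 or self.M.shape[0] != self.M.shape[1]:
            raise ValueError("successor matrix must be square")

    @classmethod
    def zeros(cls, n_states: int) -> "SuccessorMatrix":
        return cls(np.zeros((n_states, n_states)))

    @property
    def n_states(self) -> int:
        return self.M.shape[0]


@dataclass
class RewardVector:
    """State-indexed vector of expected instantaneous rewards."""

    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 1:
            raise ValueError("reward vector must be 1-D")
        if not np.all(np.isfinite(self.r)):
            raise ValueError("reward vector must be finite")

    @property
    def n_states(self) -> int:
        return self.r.shape[0]


def sr_update(
    M: SuccessorMatrix,
    x: int,
    x_next: int,
    alpha: float,
    gamma: float,
    terminal: bool = False,
) -> SuccessorMatrix:
    """TD update of row x of the successor matrix (in place).

    row_x += alpha * (onehot(x) + gamma*row_{x'} - row_x); the one-hot is over
    the pre-transition state. Terminal transitions keep only the one-hot term,
    mirroring the agents' convention.
    """
    n = M.n_states
    if not 0 <= x < n:
        raise IndexError(f"x={x} out of range for {n} states")
    onehot = np.zeros(n)
    onehot[x] = 1.0
    if terminal:
        target = onehot
    else:
        if not 0 <= x_next < n:
            raise IndexError(f"x_next={x_next} out of range for {n} states")
        target = onehot + gamma * M.M[x_next]
    M.M[x] += alpha * (target - M.M[x])
    return M


def sr_value(M: SuccessorMatrix, r: RewardVector) -> ScalarValueTable:
    """V = M r: instant value recomputation for any reward vector."""
    if r.n_states != M.n_states:
        raise ValueError("reward vector length must equal number of states")
    return ScalarValueTable(M.M @ r.r)


def rb_from_sr(M: SuccessorMatrix, bases: Iterable[RewardVector]) -> ValueBasisTable:
    """Value bases from the successor matrix: V_i = M r_i, stacked.

    Composing the result with drives m reproduces sr_value on sum_i m_i r_i
    exactly — the reward-bases agent is a compressed successor representation
    tuned to the reward dimensions that matter.
    """
    rows = []
    for basis in bases:
        if basis.n_states != M.n_states:
            raise ValueError("basis length must equal number of states")
        rows.append(M.M @ basis.r)
    if not rows:
        raise ValueError("need at least one reward basis")
    return ValueBasisTable(np.vstack(rows))


def memory_footprint(agent_kind: str, n_states: int, n_bases: int = 1) -> int:
    """Numbers stored by each agent: n_states*n_bases (reward bases) vs
    n_states**2 (successor)."""
    if n_states <= 0 or n_bases <= 0:
        raise ValueError("n_states and n_bases must be positive")
    kind = agent_kind.replace("_", "-").lower()
    if kind in ("reward-bases", "rb"):
        return n_states * n_bases
    if kind in ("successor", "sr", "successor-representation"):
        return n_states * n_states
    raise ValueError(f"unknown agent kind: {agent_kind!r}")


def compose_from_sr(
    M: SuccessorMatrix, bases: Iterable[RewardVector], m: MotivationalState
) -> ScalarValueTable:
    """Convenience: compose_value(rb_from_sr(M, bases), m)."""
    from .agents import compose_value

    return compose_value(rb_from_sr(M, bases), m)
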