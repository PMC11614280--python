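"""Mixed-selectivity striato-dopaminergic circuit trained by feedback alignment.

The network maps a one-hot cortical stimulus to a value estimate carried by
the total striatal output, while each dopamine unit encodes its own weighted
mixture of per-dimension prediction errors. All units are linear.

Quantities computed on each trial (stimulus x, reward vector r, drives m):

* ``D^k = sum_i w_RD[k,i] m_i`` — drive mixture carried (tonically) by
  dopamine unit k;
* ``g^k = sum_i w_DS[k,i] D^i`` — gain of striatal unit k, set by its
  dopaminergic input;
* ``s^k = g^k * sum_i w_CS[k,i] x_i`` — striatal activity;
* ``delta^k = sum_i w_RD[k,i] m_i r_i - sum_i w_SD[k,i] s^i`` — the mixed
  prediction error of dopamine unit k (no future-value term: single-step
  task);
* ``S_out = sum_k sum_i w_SD[k,i] s^i`` — total striatal output received by
  the dopamine population; with all errors at zero it equals sum_i m_i r_i.

Learning minimises L = (1/2) sum_k delta_k^2. The striato-dopaminergic
weights w_SD follow the exact gradient, which is Hebbian
(alpha * delta^k * s^i). The cortico-striatal weights w_CS are trained by
feedback alignment: the dopaminergic error reaches them through the *fixed*
random feedback weights w_DS instead of the transported transpose of w_SD.
The reward-to-dopamine weights w_RD are fixed after initialisation, with each
column normalised to sum 1 so every reward basis is equally represented
across the dopamine population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MSNetwork",
    "MSActivations",
    "init_network",
    "forward",
    "loss",
    "update_weights",
    "train",
    "evaluate_stimulus",
    "alignment_correlation",
    "R1_DEFAULT",
    "R2_DEFAULT",
]

# Subjective-value schedules for the 5 stimuli (juice basis, banana basis).
R1_DEFAULT = np.array([1.0, 0.5, 0.1, 0.0, 0.0])
R2_DEFAULT = np.array([0.0, 0.0, 0.0, 0.7, 0.05])


@dataclass
class MSNetwork:
    """Weight matrices of the mixed-selectivity circuit.

    w_CS: (M, n_cortical)  cortex -> striatum (trained, feedback alignment)
    w_SD: (N, M)           striatum -> dopamine (trained, Hebbian/gradient)
    w_DS: (M, N)           dopamine -> striatum (fixed random feedback)
    w_RD: (N, n_reward)    reward -> dopamine (fixed, columns sum to 1)
    """

    w_CS: np.ndarray
    w_SD: np.ndarray
    w_DS: np.ndarray
    w_RD: np.ndarray

    def __post_init__(self) -> None:
        M, n_cortical = self.w_CS.shape
        N, M2 = self.w_SD.shape
        M3, N2 = self.w_DS.shape
        N3, n_reward = self.w_RD.shape
        if not (M == M2 == M3 and N == N2 == N3):
            raise ValueError("inconsistent layer sizes across weight matrices")

    @property
    def n_cortical(self) -> int:
        return self.w_CS.shape[1]

    @property
    def n_reward(self) -> int:
        return self.w_RD.shape[1]

    @property
    def n_striatal(self) -> int:
        return self.w_CS.shape[0]

    @property
    def n_dopamine(self) -> int:
        return self.w_SD.shape[0]

    def copy(self) -> "MSNetwork":
        return MSNetwork(
            self.w_CS.copy(), self.w_SD.copy(), self.w_DS.copy(), self.w_RD.copy()
        )


@dataclass
class MSActivations:
    """Per-trial activations of the circuit (see module docstring)."""

    x: np.ndarray  # cortical one-hot
    r: np.ndarray  # reward vector
    m: np.ndarray  # motivational drives
    D: np.ndarray  # per-dopamine drive mixture
    g: np.ndarray  # striatal gains
    s: np.ndarray  # striatal activities
    delta: np.ndarray  # dopamine prediction errors
    S_out: float  # total striatal output


def _xavier_uniform(
    rng: np.random.Generator, n_out: int, n_in: int
) -> np.ndarray:
    bound = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-bound, bound, size=(n_out, n_in))


def init_network(
    seed: int,
    n_cortical: int = 5,
    n_reward: int = 2,
    n_striatal: int = 50,
    n_dopamine: int = 10,
    min_column_sum: float = 0.5,
) -> MSNetwork:
    """Xavier-uniform initialisation of all four matrices.

    Columns of w_RD are then normalised by their signed sum so each reward
    basis is represented with total weight exactly 1 across the dopamine
    population. A column whose sum magnitude falls below ``min_column_sum``
    is redrawn before normalising: dividing by a near-zero signed sum would
    amplify the reward-to-dopamine weights enough to destabilise training,
    so the bound caps the amplification at 1/min_column_sum.
    """
    rng = np.random.default_rng(seed)
    w_CS = _xavier_uniform(rng, n_striatal, n_cortical)
    w_SD = _xavier_uniform(rng, n_dopamine, n_striatal)
    w_DS = _xavier_uniform(rng, n_striatal, n_dopamine)
    w_RD = _xavier_uniform(rng, n_dopamine, n_reward)
    bound = np.sqrt(6.0 / (n_reward + n_dopamine))
    for i in range(n_reward):
        while abs(w_RD[:, i].sum()) < min_column_sum:
            w_RD[:, i] = rng.uniform(-bound, bound, size=n_dopamine)
        w_RD[:, i] /= w_RD[:, i].sum()
    return MSNetwork(w_CS, w_SD, w_DS, w_RD)


def forward(
    net: MSNetwork, x: np.ndarray, r: np.ndarray, m: np.ndarray
) -> MSActivations:
    """One forward pass; computes D, g, s, delta and S_out in order."""
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    m = np.asarray(m, dtype=float)
    if x.shape != (net.n_cortical,):
        raise ValueError(f"x must have shape ({net.n_cortical},)")
    if r.shape != (net.n_reward,) or m.shape != (net.n_reward,):
        raise ValueError(f"r and m must have shape ({net.n_reward},)")
    D = net.w_RD @ m
    g = net.w_DS @ D
    s = g * (net.w_CS @ x)
    delta = net.w_RD @ (m * r) - net.w_SD @ s
    S_out = float(np.sum(net.w_SD @ s))
    return MSActivations(x=x, r=r, m=m, D=D, g=g, s=s, delta=delta, S_out=S_out)


def loss(acts: MSActivations) -> float:
    """L = (1/2) sum_k delta_k^2."""
    return 0.5 * float(np.sum(acts.delta**2))


def update_weights(
    net: MSNetwork, acts: MSActivations, alpha: float = 0.05
) -> MSNetwork:
    """In-place weight update from one trial's activations.

    w_SD follows the exact loss gradient (Hebbian: alpha*delta^k*s^i).
    w_CS follows the feedback-alignment rule: the error reaches striatal unit
    i through the fixed feedback weights, Delta w_CS[i,j] =
    alpha * (sum_k w_DS[i,k] delta^k) * g^i * x_j. w_DS and w_RD are fixed.
    """
    net.w_SD += alpha * np.outer(acts.delta, acts.s)
    feedback = net.w_DS @ acts.delta
    net.w_CS += alpha * np.outer(feedback * acts.g, acts.x)
    return net


def alignment_correlation(net: MSNetwork) -> float:
    """Pearson correlation between flattened w_SD and flattened w_DS^T.

    Matching index pairs (k,i) <-> (i,k): measures how far the forward
    striato-dopaminergic weights have aligned to the fixed feedback weights.
    """
    a = net.w_SD.ravel()
    b = net.w_DS.T.ravel()
    return float(np.corrcoef(a, b)[0, 1])


def train(
    net: MSNetwork | None = None,
    R1: np.ndarray | None = None,
    R2: np.ndarray | None = None,
    iters: int = 100_000,
    alpha: float = 0.05,
    seed: int = 0,
    record_every: int = 1000,
) -> tuple[MSNetwork, np.ndarray, np.ndarray]:
    """Train the circuit on the five-stimulus, two-reward-type task.

    Per iteration: a stimulus is drawn uniformly from the 5, its cortical unit
    set to 1; the reward vector is (R1[s], R2[s]) — the schedules already
    encode that only the basis matching the stimulus's reward type is nonzero;
    drives are drawn independently Uniform[0,1]; forward pass, then both
    trainable matrices update. Loss and alignment correlation are recorded
    every ``record_every`` iterations (including at iteration 0).

    Returns (network, loss trace, alignment trace).
    """
    rng = np.random.default_rng(seed)
    if net is None:
        net = init_network(seed=int(rng.integers(2**31)))
    R1 = R1_DEFAULT if R1 is None else np.asarray(R1, dtype=float)
    R2 = R2_DEFAULT if R2 is None else np.asarray(R2, dtype=float)
    n_stim = net.n_cortical
    if R1.shape != (n_stim,) or R2.shape != (n_stim,):
        raise ValueError("reward schedules must have one entry per stimulus")
    loss_trace = []
    align_trace = []
    eye = np.eye(n_stim)
    for it in range(iters):
        stim = int(rng.integers(n_stim))
        x = eye[stim]
        r = np.array([R1[stim], R2[stim]])
        m = rng.uniform(0.0, 1.0, size=net.n_reward)
        acts = forward(net, x, r, m)
        if it % record_every == 0:
            loss_trace.append(loss(acts))
            align_trace.append(alignment_correlation(net))
        update_weights(net, acts, alpha=alpha)
    return net, np.asarray(loss_trace), np.asarray(align_trace)


def evaluate_stimulus(net: MSNetwork, stimulus: int, m: np.ndarray) -> float:
    """Striatal output for a stimulus under given drives (reward ignored).

    Evaluation uses only the cortical input and the drives: D, g, s, S_out.
    A trained network returns approximately the drive-weighted subjective
    value of the stimulus.
    """
    if not 0 <= stimulus < net.n_cortical:
        raise IndexError(f"stimulus {stimulus} out of range")
    x = np.zeros(net.n_cortical)
    x[stimulus] = 1.0
    acts = forward(net, x, np.zeros(net.n_reward), np.asarray(m, dtype=float))
    return acts.S_out
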