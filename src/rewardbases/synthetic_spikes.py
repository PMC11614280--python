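"""Synthetic spike datasets with the structure the analysis pipeline assumes.

Each neuron's expected response-window spike count on a trial of condition x
follows the forward model of the value/identity regression,

    mu = b0 + b1*R(x) + b2*I(x)*R(x),

realised either as ``round(max(0, mu + N(0, sigma)))`` (gaussian-count mode,
matching surrogate construction from fitted predictions plus residual-SD
noise) or as ``Poisson(max(eps, mu))``. The realised count is placed as a
homogeneous process inside the response window, and background spikes are
laid down at ``baseline_rate`` over the remainder of the trial span, so the
windowing, smoothing and baseline-correction operations are all exercised.
Temporal microstructure within windows is uniform given the count — the
analyses only use counts.

Constructors :meth:`GeneratorConfig.null`, :meth:`GeneratorConfig.planted`
and :meth:`GeneratorConfig.anticorrelated` build the three populations the
permutation machinery is tested against: no interaction anywhere, a chosen
subset of neurons with nonzero interaction, and opposed juice/banana
selectivity (large-spread interaction coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .neural_analysis import ConditionTable, SpikeDataset, WindowSpec, DEFAULT_WINDOWS

__all__ = ["GeneratorConfig", "generate"]

_POISSON_FLOOR = 0.01


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic spike generator.

    b0, b1, b2 are per-neuron coefficient arrays (length n_neurons) of the
    forward model; scalars are broadcast. noise_model is "gaussian-count"
    (additive N(0, noise_sd) then rounded and floored at 0) or "poisson".
    baseline_rate is the background firing rate (Hz) outside the response
    window over trial_span.
    """

    n_neurons: int = 19
    trials_per_condition: int = 20
    b0: np.ndarray | float = 10.0
    b1: np.ndarray | float = 3.0
    b2: np.ndarray | float = 0.0
    noise_model: str = "gaussian-count"
    noise_sd: float = 2.0
    baseline_rate: float = 10.0
    trial_span: tuple[float, float] = (-0.5, 1.0)
    condition_offsets: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons <= 0 or self.trials_per_condition <= 0:
            raise ValueError("counts must be positive")
        if self.noise_model not in ("gaussian-count", "poisson"):
            raise ValueError("noise_model must be 'gaussian-count' or 'poisson'")
        for name in ("b0", "b1", "b2"):
            val = np.broadcast_to(
                np.asarray(getattr(self, name), dtype=float), (self.n_neurons,)
            ).copy()
            setattr(self, name, val)

    @classmethod
    def null(cls, **kw) -> "GeneratorConfig":
        """Population with no value-identity interaction (b2 = 0)."""
        kw.setdefault("b2", 0.0)
        return cls(**kw)

    @classmethod
    def planted(
        cls,
        n_significant: int = 7,
        effect: float = 2.5,
        **kw,
    ) -> "GeneratorConfig":
        """Population with the first ``n_significant`` neurons given an
        interaction of +/-``effect`` (alternating sign), the rest zero."""
        n_neurons = kw.get("n_neurons", 19)
        if n_significant > n_neurons:
            raise ValueError("n_significant cannot exceed n_neurons")
        b2 = np.zeros(n_neurons)
        signs = np.where(np.arange(n_significant) % 2 == 0, 1.0, -1.0)
        b2[:n_significant] = effect * signs
        kw["b2"] = b2
        return cls(**kw)

    @classmethod
    def stimulus_selective(
        cls,
        offsets: dict[str, float] | None = None,
        **kw,
    ) -> "GeneratorConfig":
        """Population whose condition means deviate from the value structure:
        per-condition additive offsets emulate neurons driven by the visual
        stimulus itself rather than the predicted value, so the saturated
        condition-means model genuinely differs from the value model."""
        if offsets is None:
            offsets = {"j09": 0.0, "j05": 3.0, "j02": -3.0, "b15": 3.0, "b03": -3.0}
        kw["condition_offsets"] = offsets
        return cls(**kw)

    @classmethod
    def anticorrelated(cls, spread: float = 4.0, **kw) -> "GeneratorConfig":
        """Population with opposed juice/banana selectivity: interaction
        coefficients spread widely across neurons, so responses to the top
        juice and top banana stimuli are anticorrelated across the
        population."""
        n_neurons = kw.get("n_neurons", 19)
        seed = kw.get("seed", 0)
        rng = np.random.default_rng(seed + 104729)
        kw["b2"] = rng.normal(0.0, spread, size=n_neurons)
        return cls(**kw)


def _place_uniform(
    rng: np.random.Generator, count: int, start: float, end: float
) -> np.ndarray:
    return np.sort(rng.uniform(start, end, size=count))


def generate(
    config: GeneratorConfig,
    table: ConditionTable | None = None,
    windows: WindowSpec = DEFAULT_WINDOWS,
) -> SpikeDataset:
    """Generate a spike dataset; byte-identical for identical (config, table)."""
    table = table or ConditionTable.default()
    rng = np.random.default_rng(config.seed)
    r0, r1 = windows.response
    t0, t1 = config.trial_span
    bg_span = (t1 - t0) - (r1 - r0)
    conditions = table.conditions
    reg = table.df

    rows = []
    for n in range(config.n_neurons):
        # conditions are interleaved in session order, as in a real recording
        cond_seq = rng.permutation(
            np.repeat(conditions, config.trials_per_condition)
        )
        for trial_id, cond in enumerate(cond_seq):
            R = float(reg.loc[cond, "value"])
            I = float(reg.loc[cond, "identity"])
            mu = config.b0[n] + config.b1[n] * R + config.b2[n] * I * R
            if config.condition_offsets is not None:
                mu += config.condition_offsets.get(cond, 0.0)
            if config.noise_model == "gaussian-count":
                count = int(round(max(0.0, mu + rng.normal(0.0, config.noise_sd))))
            else:
                count = int(rng.poisson(max(_POISSON_FLOOR, mu)))
            resp = _place_uniform(rng, count, r0, r1)
            n_bg = int(rng.poisson(config.baseline_rate * bg_span))
            bg = rng.uniform(t0, t1 - (r1 - r0), size=n_bg)
            bg = np.where(bg >= r0, bg + (r1 - r0), bg)  # skip response window
            spikes = np.sort(np.concatenate([resp, bg]))
            rows.append((f"n{n:03d}", trial_id, cond, tuple(spikes)))
    df = pd.DataFrame(
        rows, columns=["neuron_id", "trial_id", "condition", "spike_times"]
    )
    return SpikeDataset(df)
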