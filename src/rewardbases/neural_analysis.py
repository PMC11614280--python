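"""Spike-count regression and permutation analysis of dopamine-neuron data.

The pipeline mirrors a standard single-unit workflow for stimuli predicting
two reward types (three juice and two banana conditions, subjective values on
a 0-1 scale): spike counts in a fixed post-stimulus response window are
regressed per neuron either on the two reward-basis regressors

    S = beta1*r1(x) + beta2*r2(x) + beta0 + noise

(r1 = subjective value on juice conditions, 0 otherwise; r2 likewise for
banana), or equivalently on subjective value and its interaction with reward
identity I(x) (+1 juice, -1 banana)

    S = b1*R(x) + b2*I(x)*R(x) + b0 + noise.

The two parameterisations give identical fitted values with
b1 = (beta1+beta2)/2 and b2 = (beta1-beta2)/2; a neuron indifferent to
reward type has b2 = 0. Model comparison uses Gaussian-likelihood information
criteria summed across neurons; two permutation schemes build null
distributions by re-splitting trials (response-correlation test) or by
shuffling identity labels within neurons (interaction-count test). Model
recovery and split-half stability complete the robustness suite.

Window membership is half-open [start, end), so boundary spikes are counted
exactly once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpikeDataset",
    "ConditionTable",
    "WindowSpec",
    "RegressionFit",
    "PermutationResult",
    "ModelRecoveryResult",
    "DegenerateFitError",
    "MODEL_LABELS",
    "count_in_window",
    "smoothed_rate",
    "baseline_corrected_response",
    "fit_basis_regression",
    "fit_value_identity_regression",
    "compare_models_ic",
    "shuffle_response_correlation",
    "shuffle_interaction_count",
    "model_recovery",
    "split_half_stability",
]

MODEL_LABELS = (
    "value",
    "value+identity",
    "value+identity:value",
    "value+identity+identity:value",
    "stimulus",
)


class DegenerateFitError(ValueError):
    """Raised when a neuron's design matrix is rank deficient."""


@dataclass
class WindowSpec:
    """Analysis windows in seconds relative to stimulus onset.

    response: spike-count window used by all regressions.
    baseline: pre-stimulus window for baseline correction.
    smooth_len / smooth_stride: overlapping windows for smoothed rates.
    """

    response: tuple[float, float] = (0.150, 0.500)
    baseline: tuple[float, float] = (-0.500, 0.0)
    smooth_len: float = 0.200
    smooth_stride: float = 0.050

    def __post_init__(self) -> None:
        for name in ("response", "baseline"):
            start, end = getattr(self, name)
            if not end > start:
                raise ValueError(f"{name} window must have end > start")
        if self.smooth_stride > self.smooth_len:
            raise ValueError("stride must not exceed window length")


DEFAULT_WINDOWS = WindowSpec()


@dataclass
class ConditionTable:
    """Per-condition reward type, subjective value and derived regressors.

    ``df`` is indexed by condition label with columns reward_type and value;
    identity (+1 juice / -1 banana) and the basis regressors r1 (juice) and
    r2 (banana) are derived. Defaults follow the five-stimulus schedules:
    juice 1.0 / 0.5 / 0.1 and banana 0.7 / 0.05.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"reward_type", "value"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"condition table needs columns {required}")
        bad = set(self.df["reward_type"]) - {"juice", "banana"}
        if bad:
            raise ValueError(f"unknown reward types: {bad}")
        df = self.df.copy()
        df["identity"] = np.where(df["reward_type"] == "juice", 1.0, -1.0)
        df["r1"] = np.where(df["reward_type"] == "juice", df["value"], 0.0)
        df["r2"] = np.where(df["reward_type"] == "banana", df["value"], 0.0)
        self.df = df

    @classmethod
    def default(cls) -> "ConditionTable":
        return cls(
            pd.DataFrame(
                {
                    "reward_type": ["juice", "juice", "juice", "banana", "banana"],
                    "value": [1.0, 0.5, 0.1, 0.7, 0.05],
                },
                index=pd.Index(["j09", "j05", "j02", "b15", "b03"], name="condition"),
            )
        )

    @property
    def conditions(self) -> list[str]:
        return list(self.df.index)

    def regressors(self, conditions: Sequence[str]) -> pd.DataFrame:
        """Rows of (value, identity, r1, r2) aligned to a condition sequence."""
        missing = set(conditions) - set(self.df.index)
        if missing:
            raise ValueError(f"conditions not in table: {missing}")
        return self.df.loc[list(conditions), ["value", "identity", "r1", "r2"]]

    def to_csv(self, path) -> None:
        self.df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ConditionTable":
        return cls(pd.read_csv(path, index_col=0))


@dataclass
class SpikeDataset:
    """Long-format spike data: one row per trial.

    Columns: neuron_id, trial_id, condition, spike_times (sequence of seconds
    relative to stimulus onset at t=0).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"neuron_id", "trial_id", "condition", "spike_times"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"spike dataset needs columns {required}")
        self.df = self.df.reset_index(drop=True)
        for times in self.df["spike_times"]:
            arr = np.asarray(times, dtype=float)
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValueError("spike times must be finite")

    @property
    def neurons(self) -> list:
        return list(pd.unique(self.df["neuron_id"]))

    def trials(self, neuron_id) -> pd.DataFrame:
        return self.df[self.df["neuron_id"] == neuron_id]

    def response_counts(
        self, windows: WindowSpec = DEFAULT_WINDOWS
    ) -> pd.DataFrame:
        """Per-trial spike counts in the response window."""
        counts = [
            count_in_window(t, windows.response) for t in self.df["spike_times"]
        ]
        out = self.df[["neuron_id", "trial_id", "condition"]].copy()
        out["count"] = counts
        return out

    def to_csv(self, path) -> None:
        """Long-format CSV; spike times joined with ';' in one field."""
        out = self.df[["neuron_id", "trial_id", "condition"]].copy()
        out["spike_times"] = [
            ";".join(f"{t:.6f}" for t in np.asarray(times, dtype=float))
            for times in self.df["spike_times"]
        ]
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpikeDataset":
        df = pd.read_csv(path, dtype={"spike_times": str}, keep_default_na=False)
        df["spike_times"] = [
            tuple(float(x) for x in s.split(";")) if s else ()
            for s in df["spike_times"]
        ]
        return cls(df)

    def to_exploded(self) -> pd.DataFrame:
        """One row per spike (trials with no spikes are dropped)."""
        rows = []
        for rec in self.df.itertuples(index=False):
            for t in rec.spike_times:
                rows.append((rec.neuron_id, rec.trial_id, rec.condition, t))
        return pd.DataFrame(
            rows, columns=["neuron_id", "trial_id", "condition", "spike_time"]
        )


@dataclass
class RegressionFit:
    """OLS fit summary for one neuron and one model."""

    model: str
    neuron_id: object
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    rss: float
    n_obs: int
    df_resid: int
    aic: float
    bic: float
    fittedvalues: np.ndarray
    resid_sd: float


@dataclass
class PermutationResult:
    """Observed statistic against a permutation null.

    ``p`` is the plain empirical proportion (#null at least as extreme);
    ``p_corrected`` adds the +1 correction to numerator and denominator.
    """

    observed: float
    null: np.ndarray
    p: float
    p_corrected: float
    tail: str


@dataclass
class ModelRecoveryResult:
    """Summed-AIC differences (stimulus minus value+interaction) for
    surrogate datasets generated from each candidate model, and the fraction
    of surrogates from each generator falling inside the other's range."""

    delta_aic: dict[str, np.ndarray]
    overlap: float
    observed_delta: float


# ---------------------------------------------------------------------------
# windowed counting


def count_in_window(spike_times, window: tuple[float, float]) -> int:
    """Number of spikes t with start <= t < end (half-open)."""
    start, end = window
    if not end > start:
        raise ValueError("window must have end > start")
    t = np.asarray(spike_times, dtype=float)
    if t.size == 0:
        return 0
    return int(np.count_nonzero((t >= start) & (t < end)))


def smoothed_rate(
    spike_times,
    window_len: float = 0.2,
    stride: float = 0.05,
    trange: tuple[float, float] = (-0.5, 1.0),
) -> pd.DataFrame:
    """Firing rate in overlapping windows; timestamps at window starts."""
    t0, t1 = trange
    if not t1 > t0:
        raise ValueError("range must have end > start")
    starts = []
    s = t0
    while s + window_len <= t1 + 1e-12:
        starts.append(s)
        s += stride
    rates = [
        count_in_window(spike_times, (s, s + window_len)) / window_len
        for s in starts
    ]
    return pd.DataFrame({"t": starts, "rate": rates})


def baseline_corrected_response(
    spike_times, spec: WindowSpec = DEFAULT_WINDOWS
) -> float:
    """rate(response window) - rate(baseline window), in Hz."""
    r0, r1 = spec.response
    b0, b1 = spec.baseline
    resp = count_in_window(spike_times, spec.response) / (r1 - r0)
    base = count_in_window(spike_times, spec.baseline) / (b1 - b0)
    return resp - base


# ---------------------------------------------------------------------------
# OLS engine (shared by the user-facing fits and the permutation loops)


def _ic(rss: float, n: int, n_coef: int) -> tuple[float, float]:
    """Gaussian maximum-likelihood information criteria.

    n*ln(RSS/n) + penalty, with k counting the coefficients plus the residual
    variance. Differs from the full-log-likelihood convention by an additive
    constant that cancels in model comparisons at fixed n.
    """
    k = n_coef + 1
    rss = max(rss, n * 1e-300)
    base = n * np.log(rss / n)
    return base + 2 * k, base + k * np.log(n)


def _ols(X: np.ndarray, y: np.ndarray):
    """Plain OLS: returns (beta, se, t, p, rss, fitted, df_resid)."""
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise DegenerateFitError(
            f"design matrix rank {rank} < {p} columns (degenerate fit)"
        )
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    df_resid = n - p
    if df_resid > 0:
        sigma2 = rss / df_resid
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    else:
        se = np.full(p, np.nan)
        tvals = np.full(p, np.nan)
        pvals = np.full(p, np.nan)
    return beta, se, tvals, pvals, rss, fitted, df_resid


def _design(
    label: str, reg: pd.DataFrame, conditions: Sequence[str], all_conditions: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for one model label.

    All models except the saturated 'stimulus' model carry an explicit
    intercept; the stimulus model is parameterised directly as the five
    condition means.
    """
    R = reg["value"].to_numpy()
    I = reg["identity"].to_numpy()
    ones = np.ones_like(R)
    if label == "value":
        return np.column_stack([R, ones]), ["value", "const"]
    if label == "value+identity":
        return np.column_stack([R, I, ones]), ["value", "identity", "const"]
    if label == "value+identity:value":
        return (
            np.column_stack([R, I * R, ones]),
            ["value", "identity:value", "const"],
        )
    if label == "value+identity+identity:value":
        return (
            np.column_stack([R, I, I * R, ones]),
            ["value", "identity", "identity:value", "const"],
        )
    if label == "stimulus":
        cols = [
            (np.asarray(conditions) == c).astype(float) for c in all_conditions
        ]
        return np.column_stack(cols), [f"cond[{c}]" for c in all_conditions]
    raise ValueError(f"unknown model label {label!r}; choose from {MODEL_LABELS}")


def _neuron_arrays(
    dataset: SpikeDataset,
    neuron_id,
    table: ConditionTable,
    windows: WindowSpec,
) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """(counts, aligned regressors, condition labels) for one neuron."""
    sub = dataset.trials(neuron_id)
    if sub.empty:
        raise ValueError(f"no trials for neuron {neuron_id!r}")
    y = np.array(
        [count_in_window(t, windows.response) for t in sub["spike_times"]],
        dtype=float,
    )
    conds = list(sub["condition"])
    reg = table.regressors(conds)
    return y, reg, conds


def _make_fit(
    label: str,
    neuron_id,
    names: list[str],
    ols_out,
) -> RegressionFit:
    beta, se, tvals, pvals, rss, fitted, df_resid = ols_out
    n = fitted.shape[0]
    aic, bic = _ic(rss, n, len(names))
    idx = pd.Index(names)
    return RegressionFit(
        model=label,
        neuron_id=neuron_id,
        params=pd.Series(beta, index=idx),
        bse=pd.Series(se, index=idx),
        tvalues=pd.Series(tvals, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        rss=rss,
        n_obs=n,
        df_resid=df_resid,
        aic=aic,
        bic=bic,
        fittedvalues=fitted,
        resid_sd=float(np.sqrt(rss / n)),
    )


# ---------------------------------------------------------------------------
# regressions


def fit_basis_regression(
    dataset: SpikeDataset,
    neuron_id,
    table: ConditionTable | None = None,
    windows: WindowSpec = DEFAULT_WINDOWS,
) -> RegressionFit:
    """Per-trial response-window counts regressed on the two reward bases.

    S = beta1*r1 + beta2*r2 + beta0. Requires trials in at least three
    distinct conditions (otherwise the design is rank deficient).
    """
    table = table or ConditionTable.default()
    y, reg, conds = _neuron_arrays(dataset, neuron_id, table, windows)
    if len(set(conds)) < 3:
        raise DegenerateFitError(
            f"neuron {neuron_id!r} has trials in fewer than 3 conditions"
        )
    X = np.column_stack(
        [reg["r1"].to_numpy(), reg["r2"].to_numpy(), np.ones(len(y))]
    )
    return _make_fit(
        "basis", neuron_id, ["r1", "r2", "const"], _ols(X, y)
    )


def fit_value_identity_regression(
    dataset: SpikeDataset,
    neuron_id,
    table: ConditionTable | None = None,
    model: str = "value+identity:value",
    windows: WindowSpec = DEFAULT_WINDOWS,
) -> RegressionFit:
    """Value/identity regressions of per-trial spike counts.

    ``model`` is one of value | value+identity | value+identity:value |
    value+identity+identity:value | stimulus (the last is the saturated
    5-condition-means model). The value+identity:value model is the exact
    reparameterisation of the basis regression: b1 = (beta1+beta2)/2 and
    b2 = (beta1-beta2)/2.
    """
    table = table or ConditionTable.default()
    y, reg, conds = _neuron_arrays(dataset, neuron_id, table, windows)
    X, names = _design(model, reg, conds, table.conditions)
    return _make_fit(model, neuron_id, names, _ols(X, y))


def compare_models_ic(
    dataset: SpikeDataset,
    table: ConditionTable | None = None,
    criterion: str = "AIC",
    models: Sequence[str] = MODEL_LABELS,
    windows: WindowSpec = DEFAULT_WINDOWS,
) -> pd.DataFrame:
    """Information criterion summed across neurons, per model.

    Neurons on which any model is degenerate are excluded (with a warning)
    from every model's sum so the comparison stays balanced. Returns a
    DataFrame indexed by model, sorted ascending (winner first).
    """
    if criterion not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    table = table or ConditionTable.default()
    sums = {m: 0.0 for m in models}
    used = 0
    for nid in dataset.neurons:
        try:
            fits = {
                m: fit_value_identity_regression(
                    dataset, nid, table, model=m, windows=windows
                )
                for m in models
            }
        except DegenerateFitError as err:
            warnings.warn(f"excluding neuron {nid!r}: {err}")
            continue
        used += 1
        for m, fit in fits.items():
            sums[m] += fit.aic if criterion == "AIC" else fit.bic
    out = pd.DataFrame(
        {criterion: [sums[m] for m in models], "n_neurons": used},
        index=pd.Index(models, name="model"),
    )
    return out.sort_values(criterion)


# ---------------------------------------------------------------------------
# permutation tests


def shuffle_response_correlation(
    dataset: SpikeDataset,
    cond_a: str = "j09",
    cond_b: str = "b15",
    reps: int = 1000,
    rng: np.random.Generator | None = None,
    windows: WindowSpec = DEFAULT_WINDOWS,
) -> PermutationResult:
    """Across-neuron correlation of responses to two conditions vs a
    trial-resplit null.

    Observed: Pearson correlation, across neurons, of mean baseline-corrected
    responses to cond_a vs cond_b. Null: per iteration, each neuron's trials
    from the two conditions are pooled and randomly re-split into two groups
    of the original sizes before recomputing the correlation. The test is
    one-sided for the observed correlation being *lower* than the null
    (distinct reward-type selectivities push the correlation down).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    neurons = dataset.neurons
    if len(neurons) < 3:
        raise ValueError("need at least 3 neurons for a correlation")
    resp_a, resp_b = [], []
    for nid in neurons:
        sub = dataset.trials(nid)
        a = [
            baseline_corrected_response(t, windows)
            for t in sub.loc[sub["condition"] == cond_a, "spike_times"]
        ]
        b = [
            baseline_corrected_response(t, windows)
            for t in sub.loc[sub["condition"] == cond_b, "spike_times"]
        ]
        if not a or not b:
            raise ValueError(
                f"neuron {nid!r} lacks trials in {cond_a!r} or {cond_b!r}"
            )
        resp_a.append(np.asarray(a))
        resp_b.append(np.asarray(b))
    obs = float(
        np.corrcoef([r.mean() for r in resp_a], [r.mean() for r in resp_b])[0, 1]
    )
    null = np.empty(reps)
    pooled = [np.concatenate([a, b]) for a, b in zip(resp_a, resp_b)]
    sizes = [a.size for a in resp_a]
    for i in range(reps):
        ma, mb = [], []
        for pool, na in zip(pooled, sizes):
            perm = rng.permutation(pool)
            ma.append(perm[:na].mean())
            mb.append(perm[na:].mean())
        null[i] = np.corrcoef(ma, mb)[0, 1]
    k = int(np.sum(null <= obs))
    return PermutationResult(
        observed=obs,
        null=null,
        p=k / reps,
        p_corrected=(k + 1) / (reps + 1),
        tail="lower",
    )


def shuffle_interaction_count(
    dataset: SpikeDataset,
    table: ConditionTable | None = None,
    reps: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    windows: WindowSpec = DEFAULT_WINDOWS,
) -> PermutationResult:
    """Count of neurons with a significant value-identity interaction vs an
    identity-shuffle null.

    Observed: number of neurons whose interaction coefficient in
    S = b1*R + b2*I*R + b0 is significant (two-sided t, p < alpha,
    uncorrected). Null: per iteration the identity labels are permuted across
    trials within each neuron, the model refitted, and significant
    interactions recounted. One-sided for the observed count being *higher*.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    table = table or ConditionTable.default()
    per_neuron = []
    for nid in dataset.neurons:
        y, reg, conds = _neuron_arrays(dataset, nid, table, windows)
        per_neuron.append(
            (y, reg["value"].to_numpy(), reg["identity"].to_numpy())
        )

    def count_significant(identities: list[np.ndarray]) -> int:
        n_sig = 0
        for (y, R, _), I in zip(per_neuron, identities):
            X = np.column_stack([R, I * R, np.ones_like(R)])
            try:
                _, _, _, pvals, _, _, _ = _ols(X, y)
            except DegenerateFitError:
                continue
            if pvals[1] < alpha:
                n_sig += 1
        return n_sig

    obs = count_significant([I for (_, _, I) in per_neuron])
    null = np.empty(reps)
    for i in range(reps):
        null[i] = count_significant(
            [rng.permutation(I) for (_, _, I) in per_neuron]
        )
    k = int(np.sum(null >= obs))
    return PermutationResult(
        observed=float(obs),
        null=null,
        p=k / reps,
        p_corrected=(k + 1) / (reps + 1),
        tail="upper",
    )


# ---------------------------------------------------------------------------
# model recovery and stability


def model_recovery(
    dataset: SpikeDataset,
    table: ConditionTable | None = None,
    n_surrogates: int = 1000,
    rng: np.random.Generator | None = None,
    windows: WindowSpec = DEFAULT_WINDOWS,
    models: tuple[str, str] = ("value+identity:value", "stimulus"),
) -> ModelRecoveryResult:
    """Can the summed AIC tell the two candidate models apart on data of this
    size?

    For each generating model, surrogate per-trial counts are simulated as
    that model's fitted prediction plus Gaussian noise with the neuron's
    residual SD; both candidates are refitted and the summed-AIC difference
    (stimulus minus value+interaction) recorded. Low overlap between the two
    resulting distributions means the criterion is diagnostic.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    table = table or ConditionTable.default()
    model_vi, model_stim = models

    # per neuron: designs for both candidates, fitted values + resid SD per generator
    neurons = []
    observed_delta = 0.0
    for nid in dataset.neurons:
        y, reg, conds = _neuron_arrays(dataset, nid, table, windows)
        X_vi, names_vi = _design(model_vi, reg, conds, table.conditions)
        X_st, names_st = _design(model_stim, reg, conds, table.conditions)
        out_vi = _ols(X_vi, y)
        out_st = _ols(X_st, y)
        n = len(y)
        aic_vi, _ = _ic(out_vi[4], n, X_vi.shape[1])
        aic_st, _ = _ic(out_st[4], n, X_st.shape[1])
        observed_delta += aic_st - aic_vi
        # residual makers for fast columnwise RSS on surrogate matrices
        annihilators = {}
        for label, X in ((model_vi, X_vi), (model_stim, X_st)):
            H = X @ np.linalg.pinv(X)
            annihilators[label] = np.eye(n) - H
        neurons.append(
            {
                "n": n,
                "k": {model_vi: X_vi.shape[1], model_stim: X_st.shape[1]},
                "annihilator": annihilators,
                "gen": {
                    model_vi: (out_vi[5], np.sqrt(out_vi[4] / n)),
                    model_stim: (out_st[5], np.sqrt(out_st[4] / n)),
                },
            }
        )

    delta = {}
    for gen_label in (model_vi, model_stim):
        summed = {model_vi: np.zeros(n_surrogates), model_stim: np.zeros(n_surrogates)}
        for info in neurons:
            fitted, sd = info["gen"][gen_label]
            n = info["n"]
            Y = fitted[:, None] + sd * rng.standard_normal((n, n_surrogates))
            for label in (model_vi, model_stim):
                resid = info["annihilator"][label] @ Y
                rss = np.einsum("ij,ij->j", resid, resid)
                k = info["k"][label] + 1
                summed[label] += n * np.log(np.maximum(rss, n * 1e-300) / n) + 2 * k
        delta[gen_label] = summed[model_stim] - summed[model_vi]

    d_vi, d_st = delta[model_vi], delta[model_stim]
    overlap = 0.5 * (
        float(np.mean(d_vi <= d_st.max())) + float(np.mean(d_st >= d_vi.min()))
    )
    return ModelRecoveryResult(
        delta_aic=delta, overlap=overlap, observed_delta=observed_delta
    )


def split_half_stability(
    dataset: SpikeDataset,
    table: ConditionTable | None = None,
    windows: WindowSpec = DEFAULT_WINDOWS,
) -> tuple[pd.Series, pd.Series, float, float]:
    """Interaction coefficients fitted on first vs second half of each
    neuron's trials (by trial order), with their across-neuron Pearson r.

    Neurons with a rank-deficient half are excluded with a warning. Returns
    (coefficients first half, coefficients second half, r, two-sided p).
    """
    table = table or ConditionTable.default()
    first, second = {}, {}
    for nid in dataset.neurons:
        sub = dataset.trials(nid).sort_values("trial_id")
        half = len(sub) // 2
        coeffs = []
        try:
            for part in (sub.iloc[:half], sub.iloc[half:]):
                y = np.array(
                    [
                        count_in_window(t, windows.response)
                        for t in part["spike_times"]
                    ],
                    dtype=float,
                )
                reg = table.regressors(list(part["condition"]))
                X = np.column_stack(
                    [
                        reg["value"].to_numpy(),
                        reg["identity"].to_numpy() * reg["value"].to_numpy(),
                        np.ones(len(y)),
                    ]
                )
                beta, *_ = _ols(X, y)
                coeffs.append(beta[1])
        except DegenerateFitError as err:
            warnings.warn(f"excluding neuron {nid!r}: {err}")
            continue
        first[nid], second[nid] = coeffs
    if len(first) < 3:
        raise ValueError("need at least 3 usable neurons")
    s1 = pd.Series(first, name="interaction_first_half")
    s2 = pd.Series(second, name="interaction_second_half")
    r, p = stats.pearsonr(s1.to_numpy(), s2.to_numpy())
    return s1, s2, float(r), float(p)
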