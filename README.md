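# rewardbases

Model-free reinforcement learning that adapts instantly to physiological
state. Animals revalue outcomes the moment their needs change — salt-deprived
rats approach a salt lever they have only ever experienced as aversive —
which classic temporal-difference (TD) learning cannot do, because its value
function only moves when rewards are re-experienced. This package implements
the *reward bases* account of that ability, for computational neuroscientists
who want to simulate it, compare it against alternatives, and test its
neural predictions on spike data.

## The model

Decompose the reward over environmental states x into reward bases weighted
by motivational drives:

    r(x) = Σᵢ mᵢ rᵢ(x)

learn one value basis per dimension with its own TD error,

    δᵢ = rᵢ(x) + γVᵢ(x′) − Vᵢ(x),    ΔVᵢ(x) = α δᵢ

and compose the acted-upon value function at decision time:

    V(x) = Σᵢ mᵢ Vᵢ(x).

With constant drives this is exactly TD learning on the summed reward; when
the drives change, every state is revalued instantly with zero learning
updates. The package also provides:

* the **state-modulated** rule δ̃ᵢ = mᵢδᵢ with ΔVᵢ = αmᵢδ̃ᵢ (learning rate
  scales with need);
* a **mixed-selectivity striato-dopaminergic circuit** in which each
  dopamine unit carries a weighted mixture of per-dimension prediction
  errors, output weights learn Hebbian-style (the exact loss gradient) and
  cortico-striatal weights learn by **feedback alignment** through fixed
  random dopamine-to-striatum weights;
* a **successor representation** comparator (V = M·r; a value basis is
  M·rᵢ), with the storage trade-off n_states·n_bases vs n_states²;
* the three task environments (grid room with reversals, salt/juice levers,
  probabilistic devaluation levers);
* a **spike-count analysis pipeline**: windowed rates, the two equivalent
  per-neuron regressions (reward bases ↔ value × identity), AIC/BIC model
  comparison, trial-shuffle permutation nulls, model recovery, split-half
  stability — plus a synthetic spike generator so the whole pipeline is
  testable without any recordings.

## Worked example

Instant salt revaluation from the command line:

```sh
$ rewardbases salt --out-dir out/salt
salt: RB salt-lever value -0.997 (normal) -> 0.499 (depleted); TD unchanged at -0.997
```

After 100 Pavlovian exposures the reward-bases agent holds a salt value
basis of ≈ +1 learned under a drive of −1, so its composed salt-lever value
is ≈ −1 (aversive). Setting the salt drive to +0.5 — no further learning —
flips the composed value to ≈ +0.5, while the TD agent's value cannot move.
The same mechanics from Python:

```python
import numpy as np
from rewardbases import (
    AgentConfig, MotivationalState, TransitionSample, ValueBasisTable,
    compose_value, modulated_rb_update,
)

cfg = AgentConfig(alpha=0.1, gamma=0.0)
table = ValueBasisTable.zeros(n_bases=2, n_states=2)   # (juice, salt) x levers
training_drives = MotivationalState(np.array([1.0, -1.0]))
for _ in range(100):
    lever = np.random.default_rng().integers(2)
    r = np.eye(2)[lever]                               # lever pays its own basis
    modulated_rb_update(table, TransitionSample(lever, lever, r, terminal=True),
                        training_drives, cfg)

compose_value(table, training_drives).V                # salt lever ~ -1
compose_value(table, MotivationalState(np.array([1.0, 0.5]))).V  # ~ +0.5
```

Other entry points: `rewardbases fig1` (value-surface decomposition; prints
`max |composed - TD| = 2.22e-16` on the shared trajectory), `rewardbases
room` (reversal task: TD vs reward bases vs successor), `rewardbases
devaluation` (dopamine readouts and drive-ratio fit; the shipped synthetic
demo targets recover `fitted R=2.00 K=0.997`), `rewardbases
mixed-selectivity`, and `rewardbases neural-analysis` (spike pipeline demo
on a planted-effect population).

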