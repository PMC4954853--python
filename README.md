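# bgspike

A spiking basal-ganglia model of reward-driven action selection with
dopamine-modulated Bayesian (BCPNN) plasticity, including lesion and
dopamine-depletion (Parkinson's disease) experiments.

## The problem

How do the direct (D1) and indirect (D2) striatal pathways cooperate to
select rewarded actions when the reward contingencies keep changing, and
how does each pathway's loss — or the gradual death of dopaminergic
neurons — degrade that ability? `bgspike` addresses this with a network of
leaky integrate-and-fire neurons: cortical state populations project onto
D1 and D2 matrisomal MSN populations that respectively inhibit and excite
the GPi/SNr output of their action; the least active output population is
the most likely to be selected (softmax over negated normalized spike
counts). Striosomal populations, gated by state and an efference copy of
the selected action, learn reward predictions and feed them back onto the
dopaminergic population, whose filtered activity `q` encodes the reward
prediction error

    kappa = (sigma_dopa * (beta_dopa + q)) ** lambda

with `lambda = 7` (sign-preserving) for matrisomes and `lambda = 2`
(non-negative) for striosomes. All plastic synapses use a four-factor
spike-based BCPNN rule — exponentially smoothed traces `Z -> E -> P` with
log-odds weights `w_ij = log(P_ij / (P_i P_j))` and bias
`beta_j = log(P_j)` — where `kappa` acts as the learning rate: D1 synapses
update only on positive RPE, D2 only on negative, and the
reward-prediction pathway on both.

The task: in state `i` at block `b`, action `j` is rewarded iff
`(i + b) mod 3 == j`; the mapping shifts at every 40-trial block. Lesion
presets (`noD1`, `noD2`, `noRP`, `noEfference`, `noSF`, `noLI`) silence a
pathway's output while leaving the population active; `PD16/33/66` delete
that percentage of dopaminergic neurons mid-session with the RPE baseline
frozen, reproducing the Parkinsonian learning deficit.

Intended users: computational neuroscientists studying basal-ganglia
reinforcement learning, dopamine signalling and its degeneration.

## Worked example

```bash
bgspike run --condition intact --blocks 6 --seed 7 --out demo
```

prints per-block progress and a final summary:

```
bgspike.task block 4: success 0.82
bgspike.task block 5: success 0.80
condition=intact mean success (last-20) = 0.900
```

meaning the model, after learning each block's new reward mapping,
averages 90% correct over the last 20 trials of each block (chance is
1/3, maximum 1). `demo/trials.csv` holds one row per trial (state,
selected action, reward, the RPE excursion of the learning phase and a
10-trial moving average of success); `demo/weights.csv` the mean plastic
weights of the D1, D2 and reward-prediction pathways sampled every
250 ms; `demo/summary.json` the windowed condition summary:

```json
{ "condition": "intact", "window": "last-20", "mean": 0.9, "sd": 0.0,
  "seed": 7, "beta_dopa": -491.32, "blocks": 6, "trials_per_block": 40 }
```

The same machinery is available as a library:

```python
from bgspike import SessionConfig, NetworkConfig, LesionSpec, run_session
from bgspike.analysis import summarize_condition

res = run_session(SessionConfig(network=NetworkConfig.desk_scale(),
                                lesion=LesionSpec.from_name("PD33"),
                                seed=1))
print(summarize_condition([res.trials_frame()], condition="PD33",
                          window_spec="last", min_block=8))
```

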