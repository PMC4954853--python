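# Methods

## The model

`bgspike` simulates reward-driven action selection in a spiking network of
the basal ganglia. Three cortical state populations (Poisson generators,
30 Hz when active, 3 Hz background) project through plastic synapses onto
six matrisomal MSN populations — one D1 (direct-pathway) and one D2
(indirect-pathway) population per action. D1 matrisomes inhibit and D2
matrisomes excite the GPi/SNr output population of their action, which is
otherwise driven to a tonic ~35 Hz; the action whose output population is
*least* active during the 500 ms selection window is the most likely to be
selected (softmax over the negated, normalized spike counts). An efference
copy (one Poisson source per action) informs the striatum of the selected
action, and nine striosomal subpopulations — one per (state, action) pair,
gated by the conjunction of state input and a delayed efference volley —
implement the reward-prediction (RP) pathway: they project with learned,
sign-inverted weights onto the dopaminergic population.

Dopaminergic neurons fire ~10 Hz at baseline, and their external drive is
switched to produce ~14 Hz on reward and ~6 Hz on reward omission. Their
summed spiking is low-pass filtered (time constant `tau_q` = 100 ms) into
a volume-transmitter trace `q`, and the reward prediction error is

    kappa = (sigma * (beta_dopa + q)) ** lambda

with `beta_dopa` calibrated once on the intact network so kappa is zero at
baseline. Matrisomes use `lambda` = 7 (odd: the sign of the deviation is
kept, small fluctuations are crushed); striosomes use `lambda` = 2 (even:
their learning rate is non-negative, so the RP pathway learns from bursts
and dips alike).

### Plasticity

All plastic synapses follow spike-based BCPNN: fast `Z` traces (low-pass
spike trains normalized so sustained firing at `f_max` = 30 Hz gives
Z ~ 1), eligibility traces `E` (low-pass of `Z_i`, `Z_j`, `Z_i Z_j`,
`tau_e` = 100 ms), and probability traces `P` that relax toward their `E`
at rate `kappa / tau_p` (`tau_p` = 1000 ms). Weights are the log-odds
read-out `w = log(P_ij / (P_i P_j))`; the post-synaptic bias
`beta_j = log(P_j)` enters the neuron as a hyperpolarizing current scaled
by `phi`. Receptor gating: D1 synapses update only on positive kappa, D2
only on negative (magnitude as rate), RP always. Cortico-matrisomal
weights are clamped at 0 from below; RP weights may turn negative, in
which case striosomal spikes excite rather than inhibit dopamine
(inverted sign convention), encoding "expected omission".

A spike is a rectangular pulse of duration 1 ms and height
`1/(f_max * delta_t)`, so the time-averaged Z of a neuron firing at rate
r approaches `r / f_max + eps`. Note a consequence of the doubt floor
`eps`: a silent partner sits exactly at its independence level, so
pre-only firing leaves the weight near zero; weights turn negative only
under genuinely anti-correlated firing.

### Neurons and integration

Leaky integrate-and-fire with alpha-function conductances (C_m = 250 pF,
g_L = 16.7 nS, E_L = V_reset = −70 mV, V_th = −55 mV, E_ex = 0 mV,
E_inh = −80 mV, t_ref = 2 ms, tau_syn = 3 ms); thresholds, resets,
initial potentials, static weights and delays are sampled from Gaussians.
All state updates use exponential-Euler closed forms (exact for
piecewise-constant drive); the alpha kernel is integrated with its exact
two-state propagator. The reference kernels live in `plasticity.py` /
`neurons.py`; the network loop is a single compiled (numba) integrator
whose equivalence with the reference kernels on recorded spike trains is
asserted by the test suite. The time step is 0.1 ms at full scale and
0.5 ms for the reduced-scale session experiments.

## Calibration instead of hand-set constants

Absolute synaptic strengths are under-determined by the published
population-level description of this class of model. The package
therefore fixes the *operating points* (GPi/SNr 35 Hz without matrisomal
input; dopamine 10/14/6 Hz; gated striosome ~15 Hz; matrisome < 1 Hz
spontaneous, ~25 Hz under the efference copy, ~8 Hz from a learned state
input) and solves for drive rates and peak conductances by bisection
against a compiled LIF-pool oracle. Conductance scales for the plastic
pathways are referenced to the log-odds equilibria the BCPNN statistics
actually produce (w ~ 1.0 for D1, ~0.6 for D2, ~0.4 for RP): D2 weights
equilibrate lower than D1 weights because omission events are
self-limiting, and RP weights are compressed because dopamine never stops
firing (the log-odds range against a tonic 10 Hz partner is only a few
tenths). Giving the D2 and RP pathways stronger conductances per weight
unit is therefore a calibration necessity, and is consistent with the
higher intrinsic excitability reported for indirect-pathway MSNs.

Two gains shape the learning signal, in units of the full burst/dip
deviation (±4 Hz per dopaminergic neuron): `gain_matrisome` = 1.2 with a
kappa clamp of 3, and `gain_striosome` = 0.4. The striosomal gain is
deliberately small: each trial's learning phase erodes every RP
prediction by a factor `exp(-kappa_str * 0.4 s / tau_p)`, and a state
recurs only every third trial, so prediction memory must outlive several
erosion windows or reward cancellation can never operate. With 0.4 the
prediction survives ~10 trials and repeated rewards are visibly damped;
with gains near 1 the RP pathway forgets faster than it is consulted.

## Trial protocol and sessions

A trial lasts 1.5 s: selection (500 ms), efference (300 ms), learning
(400 ms, dopamine switched by the outcome of `(i + b) mod 3 == j`), reset
(300 ms). The efference-to-striosome delay is locked to the efference
phase duration, so the striosomal volley reaches the dopaminergic neurons
together with the outcome-dependent drive. States are presented
round-robin; a session is 15 blocks of 40 trials with the mapping
shifting every block. Mean plastic weights are logged every 250 ms, and
per-synapse D1/D2 snapshots at every trial end provide the per-trial
|Δw| statistics. Dopaminergic deletion (16/33/66%) removes the selected
neurons' external drive, their striosomal input and their contribution to
`q` at the start of block 8, with `beta_dopa` frozen at its intact value.
A 300 ms settling run precedes the first trial so conductance charge-up
does not masquerade as a negative prediction error.

## Problem sizes

The full network (3 states x 40, 6 matrisomes x 30, 9 striosomes x 20,
3 outputs x 40, 125 dopamine = 725 neurons, ~70,000 synapses) is used for
structural audits and the population-rate measurements. Session-level
experiments run on a reduced network with identical topology (16/12/8/16
per population, 50 dopaminergic neurons, 290 neurons total, dt = 0.5 ms);
a 600-trial session takes roughly half a minute of CPU. All operating
points are re-calibrated per configuration, so the reduced network hits
the same rates as the full one.

## What the simulations do and do not show

Reproduced: within-block learning to ≥ 0.85–0.95 end-of-block success
with remapping every 40 trials; chance-level performance without the
efference copy or without the D2 pathway (with the characteristic D2
perseveration); the lesion ordering intact ≈ noRP ≥ noD1/noSF > chance;
graded impairment with dopaminergic loss ordered 16% > 33% > 66% and the
partial rescue of blocks whose mapping matches the last intact one; and
larger per-trial D1 weight changes when plasticity follows the absolute
reward value (noRP) than when it follows the prediction error.

Known deviations at the reduced scale. The absolute post-deletion success
levels run ~0.15–0.25 below the full-scale literature values (0.75/0.51/
0.38): with the 7th-power nonlinearity, the tonic negative deviation left
by freezing `beta_dopa` after 33–66% deletion saturates the learning-rate
clamp, which erodes D2 weight structure faster than in the original
regime; the same erosion makes the rescued blocks *more* rescued (~0.9 vs
0.717) because no residual D2 structure remains to hinder the frozen D1
policy, and it prevents the 33% condition from profiting from 80-trial
blocks. The per-trial |Δw| scale (~0.1 log-odds units) is far below the
printed full-scale values (1.6–3.5), which imply near one-shot probability
tracking; in that regime our calibration could not sustain stable
learning, so the package operates at a lower learning rate and reproduces
the direction, not the magnitude, of the comparison. The noLI (no lateral
inhibition) condition is indistinguishable from intact here rather than
mildly impaired. Synthetic-protocol results transfer to the real system
only insofar as the operating points above are the right abstraction;
no claim is made about spike-timing phenomena finer than the 0.5 ms grid
or about dopamine dynamics beyond the single filtered population trace.
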