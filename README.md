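# bgselect

A firing-rate model of action selection in the basal ganglia, built as a
tested simulator library with a command-line interface.

## The scientific problem

The basal ganglia (BG) gate which of several candidate actions, proposed by
the cortex, is actually executed. `bgselect` implements a parsimonious
neural-mass model of this circuit: `N` segregated action channels (default
`N = 4`) run through motor cortex (C), the striatum split into D1 ("Go") and
D2 ("NoGo") populations, external and internal globus pallidus (GPe, GPi),
and thalamus (T), closed by a thalamo-cortical positive loop. Two global
scalar units act on all channels at once: the subthalamic nucleus (STN),
driven by a conflict-energy readout of the cortex
(E = Σ<sub>i≠j</sub> y<sup>C</sup><sub>i</sub> y<sup>C</sup><sub>j</sub>),
and a striatal cholinergic interneuron (ChI) inhibited by dopamine.

Each unit is a leaky integrator with a sigmoidal rate function:

    τ du/dt = −u + x,    y = 1 / (1 + exp(−a (u − u₀)))

with dopamine (DA) entering the net input `x` of the striatal populations —
a signed contrast-enhancement term α·DA·(y<sup>G</sup> − ϑ<sub>G</sub>) on
Go units, a plain inhibition β·DA on NoGo units, and γ·DA on the ChI.
Phasic dopamine events (a reward peak to 0.9, a punishment dip to 0, in a
100–150 ms window) displace striatal activity away from its tonic working
point near 0.5, which drives learning through a thresholded two-term Hebb
rule on the four striatal input matrices:

    Δw_ij = σ · [y_pre,j − ϑ_PRE]₊ · (y_post,i − ϑ_POST),   0 ≤ w ≤ w_max

with no explicit dopamine factor. Tonic dopamine sets the operating point;
lowering it reproduces Parkinsonian traits (slower responses, neglect of
weak stimuli), raising it reproduces hypersensitivity.

The package is intended for computational and cognitive neuroscientists who
want a transparent, fully parameterised circuit to simulate action
selection, conflict resolution (the "hold your horses" role of the STN),
reward/punishment learning, and dopamine-depletion experiments.

## Worked example

```python
import numpy as np
from bgselect import (default_weights, simulate_trial, detect_gating,
                      DopamineSchedule, LesionSpec)

w = default_weights()

# Default gating: the channel with the strongest stimulus wins.
trace = simulate_trial(w, [0.3, 0.8, 0.3, 0.2])
print(detect_gating(trace).to_dict())
# {'gated': [2], 'winner': 2, 'latency_ms': {'2': 50.7}}

# A strong three-way conflict: the STN brake enforces a single choice...
trace = simulate_trial(w, [0.85, 0.9, 0.85, 0.1])
print(detect_gating(trace).to_dict())
# {'gated': [2], 'winner': 2, 'latency_ms': {'2': 353.3}}

# ...and without it, three contradictory responses are gated at once.
trace = simulate_trial(w, [0.85, 0.9, 0.85, 0.1],
                       lesions=LesionSpec(stn_off=True))
print(detect_gating(trace).to_dict())
# {'gated': [1, 2, 3], 'winner': 2, 'latency_ms': {'1': 34.2, '2': 29.9, '3': 34.2}}
```

The winner's latency is the first time (ms from stimulus onset) its
cortical unit crosses the action threshold 0.95. Note the conflict trial is
slower (353 ms vs 51 ms): the STN holds all channels back until cortical
competition resolves, trading speed for a single coherent choice.

Training re-maps a stimulus–response association through rewards and
punishments:

```python
from bgselect import run_training, TrainingConfig

h = run_training(w, [0.15, 0.15, 0.9, 0.7], TrainingConfig(seed=0))
wt = h.final_weights(w)
print(wt.W_NC[3, 3], wt.W_GC[3, 3])   # 0.0 1.2
print(detect_gating(simulate_trial(wt, [0.15, 0.15, 0.9, 0.7])).winner)  # 4
```

After 100 noisy epochs rewarding channel 4 and punishing anything else, the
cortex-to-NoGo weight of channel 4 sits at the lower clip (0.0), the
cortex-to-Go weight at the upper clip (w_max = 1.2), and the network now
gates channel 4 instead of the initially prepotent channel 3.

The same experiments are available from a shell:

```bash
bgselect --out out default
bgselect --out out conflict --no-stn
bgselect --out out feedback --kind punishment --no-chi
bgselect --out out train --seed 0 --epochs 100
bgselect --out out da-sweep --levels 0.35,0.45,0.55
bgselect --out out latency-curve --levels 0.35,0.4,0.45,0.55
```

Each command writes long-format trace CSVs, gating JSONs and a run
manifest into `--out`.

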