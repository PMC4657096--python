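# Methods

## Model

Every population is a neural-mass unit: net input `x` is a weighted sum of
presynaptic activities plus tonic drives, the membrane state obeys
`τ du/dt = −u + x` (τ = 10 ms; the cortical lateral-inhibition state uses
τ_L = 50 ms), and the normalized rate is `y = 1/(1 + e^{−a(u−u₀)})` with
a = 4, u₀ = 1, so a silent unit (u = 0) has rate ≈ 0.018 and rate 0.5 is
reached at u = 1.

Per action channel `i` (N = 4 by default) the couplings are:

| target | net input |
|---|---|
| lateral state L | Σ_{j≠i} l_ij y^C_j (l = −1.2, enters cortex unfiltered) |
| cortex C | (W^CS s)_i + u^L_i + w^CT y^T_i |
| Go | (W^GS s)_i + w^GC y^C_i + α·DA·(y^G_i − ϑ_G) + w^GH y^H |
| NoGo | (W^NS s)_i + w^NC y^C_i + β·DA + w^NH y^H |
| GPe | w^EN y^N_i + w^ESTN y^STN + I^E |
| GPi | w^IG y^G_i + w^IE y^E_i + w^ISTN y^STN + I^I |
| thalamus T | w^TI y^I_i + w^TC y^C_i |
| STN (scalar) | k^E E + Σ_j w^STNE_j y^E_j, with E = Σ_{i≠j} y^C_i y^C_j |
| ChI (scalar) | I^H + γ·DA |

Defaults (`default_params()`, `default_weights()`): ϑ_G = 0.3, α = 1,
β = −1, γ = −1, I^E = 1, I^I = 3, I^H = 1.25; diagonal matrices
W^CT = 4, W^GC = 0.48, W^NC = 1.08, W^EN = −2.2, W^IE = −3, W^IG = −12,
W^TC = 3, W^TI = −3; full matrices W^CS (1.1 diagonal / 0.2 off),
W^GS (0.9 / 0), W^NS (0.1 / 0); scalars w^ESTN = 1, w^ISTN = 14, k^E = 7,
W^STNE = −1 (per GPe unit), w^GH = −1, w^NH = 1. A response counts as
gated when its cortical unit reaches the action threshold 0.95 and is
still above it at trial end; the winner is the earliest-crossing gated
channel, ties broken toward the lowest index (the equations never produce
exact ties; the rule only fixes determinism).

The conflict energy is summed over *ordered* pairs, so each unordered pair
contributes twice; the gain k^E absorbs this convention.

Dopamine is an external signal, not a simulated nucleus: a tonic level
(0.45 = healthy; 0.35 parkinsonian-low; 0.55 medicated-high) plus an
optional rectangular phasic event — reward raises DA to 0.9, punishment
drops it to 0, both over the 100–150 ms window. Lesions are activity
clamps applied after each step: `stn_off` pins y^STN = 0; `chi_clamped`
pins y^H at its analytic tonic fixed point `σ(I^H + γ·DA_tonic)`, so the
clamp level stays consistent across tonic-dopamine conditions.

## Plasticity

The four striatal input matrices W^GC, W^NC (diagonal; only diagonals
train — channel segregation) and W^GS, W^NS (full) update by

    Δw_ij = σ [y_pre,j − ϑ_PRE]_+ (y_post,i − ϑ_POST),  clip to [0, w_max]

with σ = 0.1, ϑ_PRE = ϑ_POST = 0.5. `w_max = 1.2`: the bound must sit
above every pretraining weight, and the largest (W^NC diagonal) is 1.08;
with any smaller bound the clip itself would rewrite untrained synapses on
the first update. The trained Go weight of a consistently rewarded channel
saturates at w_max; the exact ceiling value only scales how strongly that
channel is facilitated post-training, not the qualitative outcome.

A training epoch: add N(0, 0.25) noise to each stimulus element, clamp to
[0, 1]; run a 300 ms tonic trial; if some channel gated, deliver reward
(target channel) or punishment (any other channel) as a phasic event in a
second trial with the same stimulus, and apply one Hebb update to all four
matrices from activities sampled at t = 150 ms — the end of the phasic
window, where striatal displacement from ϑ_POST is maximal. Epochs where
nothing gates deliver no feedback and change no weight (a config flag can
force the update; it is negligible by construction, ≲ 0.01 per entry,
because the tonic winner striatal activities sit near ϑ_POST). The run is
driven by a single seeded generator recorded in the `WeightHistory`.

## Numerical choices

- Explicit Euler, dt = 0.1 ms (validated: halving dt changes end-of-trial
  activities by < 10⁻³; the scheme's O(dt) error halves with dt on the
  closed-form single-unit relaxation). The constructor enforces
  dt ≤ τ/10.
- Initial state: all membrane states zero (activities ≈ 0.018, the silent
  baseline); the stimulus is on for the whole trial.
- Default trial length 600 ms. The intact-conflict trial resolves with the
  winner crossing threshold at ≈ 353 ms, so 300 ms would truncate it;
  600 ms leaves every paradigmatic scenario at steady state. Training
  trials use 300 ms (their gating resolves before the 100 ms feedback
  onset).
- The sigmoid argument is clamped at ±500 before exponentiation; this is
  far outside the operating range and only guards degenerate configs.
- The inner loop is JIT-compiled (numba); a plain-numpy loop is kept as
  the readable reference and the suite asserts the two agree to machine
  precision.
- Non-finite states abort the trial with the first offending population
  and time.

## What the simulations do and do not show

All reported behaviors are properties of this circuit with the default
tables: single-response gating with the stimulus-congruent winner;
three simultaneous responses when the STN is removed under conflict versus
exactly one with it intact; Go↑ / NoGo↓ / ChI↓ ordering with tonic
dopamine; longer latencies and neglect of stimuli weaker than ≈ 0.8 at
low dopamine; the training endpoint (rewarded channel's NoGo weight at the
lower clip, Go weight at the ceiling, response re-mapped) stable across
seeds. Stimuli are abstract 4-vectors in [0, 1], not sensory input; there
is no trial-to-trial carryover (each trial restarts from the silent
state), no reward-expectation discounting, and no orthogonalization of
overlapping stimuli — interference between multiple learned associations
is untested.

Two deliberate scopings found during validation:

- With the ChI pinned, learning is slower and cortico-striatal / Go-path
  weight changes are smaller, as expected. The stimulus→NoGo matrix W^NS
  is the exception at the *whole-run* level: the slow-learning clamped
  network keeps being punished, and every punishment potentiates W^NS
  from the still-high stimulus elements, so its cumulative change can
  exceed the intact run's. The per-update attenuation (matched stimulus
  and feedback) holds for every matrix and is what the suite asserts;
  the whole-run comparison is asserted for W^GC, W^NC and W^GS.
- The tonic ("no feedback") would-be Hebb update is bounded by 0.01 per
  entry under the protocol masks, about 1% of a typical weight — small,
  but not literally zero, because at the 150 ms sampling instant the
  winner Go unit sits slightly above ϑ_POST (≈ 0.62 for the training
  stimulus) before relaxing to its steady state.

## Known limitations

- Rate-model abstraction: no spiking, no conductances, no within-nucleus
  heterogeneity; STN and ChI are single global units by design.
- Dopamine phasic events are rectangular and externally scheduled; there
  is no reward-prediction-error machinery, so repeated rewards never
  attenuate (the late-training drift of W^NS toward 0 is a direct
  consequence).
- Parameters are the published heuristic set; no fitting interface is
  provided, though every constant is exposed via the YAML/JSON config.
- Gating latencies depend on the integration step only at O(dt) but on
  the threshold convention directly; comparisons across conditions
  (orderings) are robust, absolute latencies are convention-laden.
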