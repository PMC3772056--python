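# valueframe

Analysis pipeline for studying **frames of reference in value-guided
choice** with source-level MEG-style oscillatory data. When people choose
between two risky prospects (a reward magnitude paired with a reward
probability), the comparison can be computed in *goods space* — values
attached to the options themselves (chosen vs unchosen) — or in *action
space* — values attached to the movements that obtain them (contralateral vs
ipsilateral response). Which frame the brain uses may depend on how the
decision is presented: both options at once ("comparison" trials) or one
after the other ("sequential" trials). `valueframe` implements the complete
statistical machinery for asking that question, together with a synthetic
generator so that every stage can be validated against known ground truth —
useful both as a reference implementation and as a teaching/benchmarking
harness for time-frequency group statistics.

## What the package computes

**Behaviour.** Each subject's choices are fit with a three-parameter
prospect-theory/softmax model: utility u(r) = r^α, probability weighting
w(p) = p^γ / (p^γ + (1−p)^γ)^(1/γ), subjective expected value
V = w(p)·u(r), and choice probabilities P_i = exp(βV_i) / Σ_j exp(βV_j)
with inverse temperature β. Fitting is by maximum likelihood
(multi-restart bounded quasi-Newton), compared against a one-parameter
objective-EV baseline with BIC = k·ln n + 2·NLL. A logistic regression of
choice on standardized attribute differences (p₁−p₂, r₁−r₂, EV₁−EV₂, plus
a bias constant) with group-level one-sample and paired T-tests
characterises what drives behaviour in each trial type.

**Oscillatory effects.** Single-trial epochs are decomposed with complex
Morlet wavelets (40 bins, 1–40 Hz, Morlet factor 5) into instantaneous
power, which is regressed at every (frequency, time) bin on a trial-wise
design — a constant, standardized value regressors, and a ±1 categorical
choice term. The per-subject summary is the variance-normalized effect
β̂/SE. Group inference uses a sign-flip cluster-based permutation test:
subject maps are randomly multiplied by ±1, the one-sample T-map is
recomputed, and the maximum supra-threshold cluster extent (|T| > 2.0)
builds a null distribution that corrects p-values across the whole
time-frequency plane. Peak latencies per subject feed paired latency
tests (does the value signal precede the categorical choice signal?) and a
2×2 region-by-trial-type repeated-measures interaction on peak effect
sizes.

**Synthesis.** The generator produces sessions of 324 trials per trial
type, choices from a prospect-theory agent, and single-virtual-channel
epochs at 200 Hz whose beta-band (13–30 Hz) carrier power is modulated by
value and choice regressors at controlled latencies through a raised-cosine
envelope, on top of 1/f plus white noise — negative modulation models the
movement-related beta desynchronization, positive modulation the
prefrontal beta synchronization.

## Worked example

Fit one synthetic subject's behaviour, then run the group time-frequency
analysis on 12 subjects with an injected desynchronising value effect
(g = −0.3 at 500 ms, 20 Hz):

```python
import numpy as np
from valueframe import (GroundTruth, ProspectModel, ClusterConfig, GroupStack,
                        cluster_permutation_test, sample_subject_truths,
                        generate_stimulus_set, simulate_choices, simulate_epochs,
                        TFConfig, DesignMatrix, TrialPowerRegression,
                        morlet_power, peak_latency)

truth = GroundTruth(seed=42)          # beta-band desynchronisation, g = -0.3
trials = generate_stimulus_set(n_per_type=324, seed=1)
trials = simulate_choices(trials, truth.prospect, seed=2)
print(ProspectModel(trials).fit(n_restarts=10, seed=0).summary())

maps = []
for t in sample_subject_truths(truth, n_subjects=12, seed=3):
    rng = np.random.default_rng(t.seed)
    tr = generate_stimulus_set(n_per_type=162, seed=int(rng.integers(2**31-1)))
    tr = simulate_choices(tr, t.prospect, seed=int(rng.integers(2**31-1)))
    seq = tr[tr.trial_type == "sequential"]
    dv = (seq.sv1 - seq.sv2).to_numpy()
    z = (dv - dv.mean()) / dv.std()
    c = np.where(seq.choice == 1, 1.0, -1.0)
    ep = simulate_epochs(z, c, t, fs=200.0, window_ms=(-500.0, 1500.0),
                         seed=int(rng.integers(2**31-1)))
    power = morlet_power(ep, TFConfig(freqs=np.arange(13.0, 31.0))).crop(0, 1000)
    design = DesignMatrix(X=np.column_stack([np.ones(z.size), z, c]),
                          names=["const", "value", "choice"],
                          standardized=["value"])
    maps.append(TrialPowerRegression(power, design).fit().effect_map("value"))

stack = GroupStack.from_effect_maps(maps)
print(cluster_permutation_test(stack, ClusterConfig(n_permutations=1000,
                                                    seed=0)).summary())
peaks = [peak_latency(m, (13, 30), (0, 1000), sign=-1, subject=str(i))
         for i, m in enumerate(maps)]
print(f"group median value-effect latency: "
      f"{np.median([p.latency_ms for p in peaks]):.0f} ms (truth 500 ms)")
```

Output:

```
prospect choice model (3 free parameters)
  n_trials   648
  alpha      0.7651
  gamma      0.6577
  beta       4.5597
  NLL        22.9987
  BIC        65.4192
  converged  True (10 restarts)
cluster permutation test (df=11, threshold=2.0, 1000 permutations, tail=both)
  sign -1  extent  209  peak T -7.18  p = 0.0030 *
  sign -1  extent   13  peak T -5.17  p = 0.6474
  sign +1  extent    1  peak T +2.49  p = 1.0000
  ...
group median value-effect latency: 538 ms (truth 500 ms)
```

The generating agent (α = 0.8, γ = 0.7, β = 3) is recovered to within
sampling error; the injected desynchronisation appears as one large
negative cluster surviving multiple-comparisons correction (p = 0.003)
while the scattered one- and two-bin clusters do not, and the group median
peak latency lands within 40 ms of the injected 500 ms.

There is also a shell interface mirroring the pipeline stages
(`valueframe simulate | fit-behavior | tf-regress | cluster-test |
latency`), each a thin wrapper over the functions above.

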