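# hm-mindy

Blind identification of latent regime switches and excitatory/inhibitory
mesoscale neural dynamics from multichannel electrophysiology.

Brain dynamics are nonstationary: arousal, eye state, task engagement and
neuromodulation reconfigure circuit dynamics on timescales much slower
than the dynamics themselves, and the switches are usually unlabeled.
This package fits, from a raw multichannel recording alone, a switching
nonlinear state-space model in which

    x_{t+1} = (W ⊙ Γ_{s_t}) tanh(S x_t + V) + D x_t + C + ε_t
    y_t     = H x_t + ν_t,          H = [H_exc  0]

— a base excitatory/inhibitory connectivity `W` (signed block structure,
diagonal inhibitory-source blocks, 75% sparse excitatory blocks) that is
elementwise rescaled per regime by a nonnegative rank-1 modulation
`Γ_i = g_i g_iᵀ`, with the active regime `s_t` following a hidden Markov
chain `(A, π)`. Inhibitory populations never reach the sensors (`H` has a
zero inhibitory block), so the estimation is a *triune* problem: the
regime path, the regime-conditional model parameters, and the hidden
neural states are inferred jointly — an extended Kalman filter with
backpropagated parameter gradients (NAdam) as the inner loop, and
inverted Kalman residuals feeding forward–backward / Baum–Welch regime
inference, with a K-means fallback against posterior collapse, as the
outer loop. It is aimed at EEG-scale data (one E and one I population per
channel) but is agnostic to the recording modality.

See `docs/methods.md` for the estimation procedure, the synthetic
ground-truth generator, identifiability analysis and limitations.

## Worked example

Generate a ground-truth switching recording, fit it blindly, and compare
with the truth:

```python
import numpy as np
from hmmindy import HMMindy
from hmmindy.synth import SynthSpec, generate_dataset
from hmmindy.evaluate import aligned_accuracy

ds = generate_dataset(SynthSpec(n_exc=8, T=8000), seed=42)
model = HMMindy(ds.Y, fs=250.0, n_regimes=2, observation=ds.obs,
                mask=ds.params.mask)
res = model.fit(seed=0)
print(res.summary())
acc, perm, conf = aligned_accuracy(res.labels, ds.labels, 2)
print(f"aligned state accuracy vs ground truth: {acc:.3f}")
```

Output:

```
          Blind switching E/I dynamics fit
==========================================================
Channels:                 8    Populations:         16
Timepoints:            8000    Regimes (m):          2
Outer iterations:         8    Converged:         True
Filter loss:            3827.5537
Mean posterior entropy: 0.0877  (threshold 0.15)
----------------------------------------------------------
Transition matrix A (column-stochastic) and occupancy:
  [0.9998  0.0009]   regime 0:  83.8%
  [0.0002  0.9991]   regime 1:  16.2%
==========================================================
aligned state accuracy vs ground truth: 0.977
```

The fit ran eight outer iterations and stopped on the mean-entropy
criterion (0.088 < 0.15): the regime posterior is confident at nearly
every timepoint. The estimated transition matrix is near-diagonal — a
slow switching process — with regime occupancies of 84%/16%, and after
resolving the label permutation 97.7% of timepoints carry the correct
hidden regime. `res.mparams` holds the fitted `W`, modulation vectors,
decay, slope, offset and bias; `res.regime_probs` the posterior regime
probabilities; `res.simulate()` generates new data from the fitted model.

Labels are `0..m-1` throughout (arrays and serialized outputs).

## Command line

```
hm-mindy simulate --n-exc 8 --t 8000 --seed 1 --out sim/
hm-mindy fit --data sim/data.tsv --m 2 --seed 1 --out fit/
hm-mindy evaluate --labels sim/labels.tsv --fitdir fit/
hm-mindy baseline --labels sim/labels.tsv --kind random-hmm
```

`fit` accepts EDF files directly (`--data rec.edf`, optionally
`--band 8 12` for alpha-band analysis of eyes-open/eyes-closed
recordings) or a delimited matrix with a YAML sidecar, and writes
`labels.tsv`, `hmm.json`, `params.h5` and `diagnostics.tsv`. A flat YAML
config can override every outer- and inner-loop setting.

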