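# Methods

## The model

Neural activity is described at the mesoscale: each recording channel is
assigned one excitatory and one inhibitory population, giving `n = 2c`
populations for `c` channels. The activity vector `x_t` evolves as a
discrete-time map

    x_{t+1} = (W ⊙ Γ_{s_t}) tanh(S x_t + V) + D x_t + C + ε_t,   ε_t ~ N(0, Q)

and is observed through a lead field acting on the excitatory populations
only,

    y_t = H x_t + ν_t,   H = [H_exc  0],   ν_t ~ N(0, R).

`W` is a signed base connectivity with block structure
`[[Wee, −Wie], [Wei, −Wii]]` over the `[E; I]` ordering: excitatory source
columns are nonnegative, inhibitory source columns nonpositive, and the
inhibitory-source blocks are diagonal (inhibition is local). A fixed
binary mask zeroes 75% of the off-diagonal `Wee`/`Wei` entries. `D` is a
per-population retention multiplier (a leak: values below one), `S` and
`V` shape the tanh activation, `C` is a bias.

The regime index `s_t ∈ {0..m−1}` follows a hidden Markov chain with
column-stochastic transition matrix `A` and initial distribution `π`, and
selects a nonnegative rank-1 modulation `Γ_i = g_i g_iᵀ` that elementwise
rescales `W` without changing any connection's sign. One reading of the
update equation treats the recurrence as a difference (`x_{t+1} − x_t =
…`); with retention values of 0.65–0.82 that form is explosive, so the
map form above, with `D` as the retention multiplier, is used throughout.

## Triune estimation

Three things are estimated jointly from `y_{1:T}` alone: the regime path,
the regime-conditional model parameters, and the hidden state trajectory
(the inhibitory populations are never observed, so the system is a
dimension expansion rather than a reduction).

**Inner loop — backpropagated Kalman filtering.** Given a regime label
per timepoint, an extended Kalman filter (linearized at the posterior
mean; `F = (W⊙Γ) diag(S(1−tanh²)) + diag(D)`) produces one-step
predictions. The parameters `{W, g_i, D, C, S, V}` descend a prediction
loss with NAdam, one update per 250-sample chunk, with the structural
constraints re-projected after every update. Three losses are available;
the default is the innovation-covariance-weighted (Mahalanobis) squared
innovation `Σ_t ỹ_tᵀ S_t⁻¹ ỹ_t`, which weights channels by their
predicted uncertainty; unweighted innovations and a-posteriori residuals
are options. Two differentiation modes exist: `detached` (default)
computes gains and covariances exactly forward and holds them constant in
the hand-derived backward pass; `full` keeps the covariance recursion
inside a tape-based reverse-mode graph. The detached mode is roughly two
orders of magnitude faster in this pure-NumPy/numba implementation and is
what all large fits use; the full mode backs the gradient-correctness
tests. The learning rate (default 1e-2) decays by 0.88 per outer
iteration to a floor of 1e-3: a constant step size leaves the parameters
diffusing along weakly-curved directions of the loss, which measurably
degrades parameter recovery without improving the fit.

**Outer loop — blind regime inference.** Labels are initialized by
simulating the prior chain (near-diagonal `A`, stay probability 0.9995;
uniform `π`). Each iteration: (1) one inner-loop fitting pass under the
current labels; (2) if the regime posterior is not yet confident (mean
Shannon entropy above ε = 0.15, natural log), the whole sequence is
filtered once per regime with that regime's `Γ` held active, and the
emission weight of regime `i` at time `t` is the inverted residual norm
`ℓ_t(i) = 1 / max(‖ỹ_t(i)‖₂, 10⁻⁸)`; (3) forward–backward (scaled,
per-step normalization) yields posteriors `γ_t(i)`; (4) if every regime's
posterior has temporal variance below δ = 0.1 — the signature of a
collapse onto a single regime — the labels are re-seeded by K-means
(k = m) on the residual traces smoothed with a 250-sample moving average,
with clusters mapped to regimes by a bijective minimum-mean-residual
assignment; otherwise labels are the posterior argmax; (5) one Baum–Welch
M-step updates `(A, π)`, leaving the column of `A` for any unvisited
regime unchanged. Convergence is declared when the entropy criterion is
met by a posterior that did not come from a K-means re-seed; five further
inner-loop iterations (four passes each) then refine the parameters under
the frozen labels. The loop is capped at 50 iterations and returns the
best-so-far state with a convergence flag if the cap is reached.

## Identifiability and canonicalization

The modulated model carries an exact continuous degeneracy: for any
positive vector `u`,

    (W, g_1, …, g_m)  →  (W ⊘ uuᵀ, g_1∘u, …, g_m∘u)

leaves every effective matrix `W ⊙ Γ_i` — and hence the likelihood —
unchanged. The per-population *common* level of the modulation vectors is
therefore not estimable from data; only the differences between regimes
are. Two measures address this. During fitting, a light ridge
(`FitConfig.g_anchor`, default 100 per sweep) pulls `g` toward 1,
preventing noise-driven drift along the flat directions. After fitting,
the closed-form canonicalization `u_j = Σ_i g_ij / Σ_i g_ij²` selects the
representative of the equivalence class whose modulations are nearest
unity — the convention that modulation rescales the base connectivity by
amounts close to 1. Both operations are likelihood-invariant. A related
degeneracy ties the inhibitory columns of `Wei`/`Wii` to the unobserved
inhibitory state scale through the slope `S`; it is mitigated but not
removed by initializing `S` at the generative values (2.5 excitatory, 1
inhibitory). These degeneracies cap how well the modulation matrices and
the excitatory-to-inhibitory weights can correlate with a particular
ground-truth draw even when the fit is predictively exact; the state
segmentation is unaffected.

## Synthetic ground truth

The generator draws random constrained models and simulates switching
recordings; its defaults are the study conditions everywhere in the test
suite and the acceptance script.

- `Wee`, `Wei`: sparse part with entries `0.8·U(0,1)³`, plus a rank-`n/4`
  backbone `W_l1 W_l2ᵀ` with factor entries `U(0,1)³ + 0.2·U(0,1)`, plus a
  `U(0,1)³` diagonal; a random mask then zeroes 75% of each block's
  off-diagonal entries (the mask is part of the ground truth and is given
  to the fitter in recovery experiments, so that true connections are
  never forcibly zeroed in the fit).
- `Wie`, `Wii` diagonals: `U(0.9, 1.1)` times the corresponding row's
  total excitatory input. The source material does not state a law for
  these; drawing inhibition commensurate with excitation (E/I balance) is
  the standard assumption for this model class. With much weaker
  inhibition the simulated networks saturate the tanh essentially always
  and degenerate into quasi-binary attractor dynamics, which no longer
  resemble population recordings.
- Slopes 2.5 (E) and 1 (I); retention `0.65 + 0.02 U` (E) and
  `0.8 + 0.02 U` (I), one draw per block; `V = C = 0`.
- Modulations: per regime, mean `μ_i ~ N(1, 0.1)`; a fair coin selects a
  uniform family (width `~N(0.4, 0.1)`, `g ~ U(μ−w/2, μ+w/2)`) or a
  normal family (variance `~N(0.05, 0.01)`). A correlated mode instead
  draws, per population, the m regime values jointly from a multivariate
  normal whose off-diagonal cross-covariance ρ sets how similar the
  regimes are (admissible `|ρ| ≲ √(σ_iσ_j)`).
- Observation: random dense `H_exc` with `N(0,1)` entries (hidden
  inhibitory block zero), process noise `Q = 0.25 I`, measurement noise
  `R = (0.2 + 0.1U) I`.
- Switching: stay probability 0.9995, uniform initial distribution,
  20000 timepoints by default (80 s at 250 Hz); models whose noise-free
  probe simulation diverges are redrawn (rare by construction, since
  retention is below one and tanh is bounded).

What the generator does *not* emulate: volume-conduction structure in the
lead field beyond a random mixing, 1/f spectral backgrounds, artifacts,
nonstationarity within a regime, or continuous (non-discrete) regime
mixing. Passing the synthetic recovery suite therefore demonstrates
correct joint inference under the model's own assumptions, not robustness
to the full phenomenology of real recordings; the EEG path (EDF reading,
band-pass + median/MAD normalization, the fixed `I − 0.05·11ᵀ` surrogate
lead field with `Q = 0.25 I`, `R = 1.2 I`) is exercised for correctness of
the pipeline, not for accuracy claims.

## Problem sizes and numerical choices

Recovery experiments in the tests and the acceptance script use 8-channel
models (16 populations) simulated for 8000 timepoints, ten models per
experiment and five per correlation level — sizes chosen so that the full
Monte-Carlo protocol runs comfortably on a single CPU; the pipeline is
identical at larger sizes, and spot checks at 16 channels / 20000
timepoints reproduce the same qualitative behavior. Other defaults:
filter initialization `x̂₀ = 0`, `P₀ = I`; covariance symmetrized each
step; gradient norm clipped at 10; K-means uses five restarts;
correlations are Pearson over vectorized submatrix entries with the
truth mask applied and truth-zero entries excluded. Randomness is
NumPy `default_rng` throughout; every public entry point takes a seed,
and a given (configuration, seed) pair is bit-reproducible.

## Known limitations

- The common-mode component of the modulation vectors is unidentifiable
  (see above); reported modulation matrices are canonical representatives.
- Excitatory-to-inhibitory weights are identified only through their
  closed-loop effect on observed channels and recover substantially less
  accurately than excitatory-to-excitatory weights.
- The outer loop can fail to reach the entropy criterion when the two
  regimes' likelihood contrast is weak even though the hard labels are
  already accurate; such runs return `converged=False` with usable labels.
- `m` must be specified in advance; overspecification is tolerated (the
  spare regime empties), underspecification is not detected.
- Inference is retrospective (whole-recording); no online variant.
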