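# Model and methods

## Circuit and dynamics

The model is a deterministic rate-coded network with six stages. A
tonotopic cortical array CTX of `n_channels = 20` cells maps linearly
onto a 0–2500 Hz frequency axis (125 Hz half-open bins, 0-based
channels). CTX projects topographically to an LA array, LA to a BA
array; the whole LA array converges on one ITCd cell and the whole BA
array on one ITCv cell. ITCd inhibits ITCv, ITCv inhibits CeM, and CeM
receives the mean BA activity as excitation. Thalamic afferents, CeL
dynamics, and spiking or conductance detail are deliberately out of
scope: the aim is to study what the connectivity itself can do.

Every unit obeys a shunting equation

    dx/dt = -A x + (B - x) [e]+ - (x + D) [h]+

with passive decay `A`, excitatory saturation at `B`, and drives
rectified at zero. The units differ only in their drives:

| unit | excitatory drive `e` | inhibitory drive `h` |
| --- | --- | --- |
| CTX_i | `E_i + f_E (K_E x_ctx)_i` | `f_I (K_I x_ctx)_i` |
| LA_i  | `w_cl_i x_ctx_i` | — |
| BA_i  | `w_lb_i x_la_i` | — |
| ITCd  | `g_il E_ILd + g_la_itcd Σ_i w_ld_i x_la_i` | — |
| ITCv  | `[g_il E_ILv + g_ba_itcv Σ_i w_bv_i x_ba_i − g_itcd_itcv x_itcd]+` | — |
| CeM   | `[g_ba_cem mean_i(x_ba_i) − g_itcv_cem x_itcv]+` | — |

Two forms of inhibition appear. The cortical off-surround uses the full
two-term shunting form with a nonzero lower-bound offset `D`: because the
inhibitory term is multiplied by `(x + D)`, surround inhibition has a
subtractive component and can silence a weakly driven channel outright.
This gives the network a quenching threshold — at `f_I = 3.0` the flanks
of a CS band are fully suppressed, at `f_I = 0.3` they stay active and
spread — which is what makes attention an effective dial on
generalization. Pure divisive inhibition (the `D = 0` limit) compresses
but never silences, and was found to cap the contrast between the two
attention regimes at about a factor of two. Activities are clamped at
zero after each step (firing rates are non-negative), so all state stays
in `[0, B]`.

For the ITCv and CeM cells, inhibition instead enters subtractively
inside a single rectified net drive. This is the regime the circuit's
function needs: a sufficiently active ITCd must be able to *veto* ITCv
(disinhibiting CeM during acquisition and in the cautious mode), and a
sufficiently active ITCv must veto CeM (extinction), rather than merely
scaling them down.

CeM uses the *mean* over BA rather than the sum so that the response
threshold keeps its meaning if the array size changes.

The recurrent kernels `K_E` (σ_E = 1 channel) and `K_I` (σ_I = 6
channels) are Gaussians in channel distance, each row normalized to unit
sum, so `f_E` and `f_I` alone set the recurrent gains.

## Teaching signals and plasticity

`R+` (US presence) and `R-` (US-omission prediction error) are
exogenous gates in [0, 1], never simultaneously positive, active during
the final `t_teach = 2` time units of each CS-on interval (a
delay-conditioning layout: the teaching window sits at the end of the
10-unit CS). They gate plasticity only — neither signal excites any unit
directly, so CS-evoked activity on trial 1 comes from the nonzero
initial weights `w0`, and the prediction error is supplied by the
protocol rather than computed by the circuit (extending the model to
compute `R-` endogenously from its own US expectation is an open
direction).

The four learning rules are given in the README. Design choices worth
recording:

- **Depression is Hebbian-gated.** ITC weights depress when their
  potentiation condition fails *and* the presynaptic cell is active.
  Without the presynaptic factor, weights would erode during intertrial
  intervals and between unrelated trials.
- **Depression floors at `w0`, not zero.** Both fast weight vectors relax
  toward their initial value, mirroring the slow weights' decay target,
  so baseline responsiveness is never erased and the circuit remains
  re-trainable from any history. This also ties the two ITC lesion
  phenotypes together: freezing LA→ITCd learning and letting it decay
  naturally both leave the pathway at `w0`, and the observed responses
  differ only through what the rest of the circuit learned meanwhile.
- **Synchronous update order.** Each step advances activities first, then
  updates weights from the pre-step activities; runs are bit-reproducible.
- **Gates are graded.** `R+`/`R-` multiply the learning terms, so graded
  teaching signals are legal; the shipped protocols use 0/1.

## Response readout

A trial's conditioned response (CR) is the CeM activity at the end of
the pre-US portion of CS-on (`cr_cem`); `responded` means
`cr_cem > theta_response`. Scoring before US onset keeps the readout
free of plasticity unfolding inside the teaching window (which can,
e.g., lift CeM within the very first retrieval trial), and taking the
settled late-window level rather than the whole-interval peak discards
the transient at CS onset — the rate-coded analogue of an orienting
response, which freezing scores in real protocols also exclude. The
whole-window peak is still recorded per trial (`peak_cem`) for
inspection.

## Parameters

Defaults shipped in `CircuitParameters`; all tunable via config.

| parameter | default | units | role |
| --- | --- | --- | --- |
| `n_channels` | 20 | — | tonotopic array size |
| `A` | 1.0 | 1/time | passive decay rate |
| `B` | 1.0 | activity | activity ceiling |
| `D` | 0.2 | activity | lower shunting offset (CTX quenching threshold) |
| `f_E`, `sigma_E` | 0.5, 1 | —, channels | on-center recurrence |
| `f_I`, `sigma_I` | 3.0, 6 | —, channels | off-surround recurrence (attention dial) |
| `E_ILd`, `E_ILv` | 0, 2 | drive | tonic IL bias to ITCd / ITCv |
| `g_il` | 1.0 | — | IL afferent gain |
| `g_la_itcd` | 0.7 | — | LA→ITCd afferent gain |
| `g_ba_itcv` | 5.0 | — | BA→ITCv afferent gain |
| `g_itcd_itcv` | 20.0 | — | ITCd→ITCv inhibition |
| `g_itcv_cem` | 1.15 | — | ITCv→CeM inhibition |
| `g_ba_cem` | 10.5 | — | BA→CeM excitation |
| `w0`, `w_max` | 0.05, 1.0 | weight | initial value / ceiling |
| `lambda_slow` | 0.4 | 1/time | LA/BA potentiation rate |
| `lambda_fast` | 5.0 | 1/time | ITC learning rate (12.5× slow) |
| `mu_d`, `mu_v` | 0.15, 0.05 | — | ITCd / ITCv depression scale |
| `delta_slow` | 1e-5 | 1/time | slow-weight decay |
| `dt` | 0.001 | time | Euler step |
| `t_cs`, `t_teach` | 10, 2 | time | CS-on and teaching-window durations |
| `theta_response` | 0.1 | activity | CR threshold ("fear response") |

The caption-level settings (`f_I`, `E_ILd`, `E_ILv`, lesion flags,
which CSs are extinguished) live in the protocol presets; the ten
shipped presets differ only in those five entries. The remaining gains
and rates were calibrated jointly, once, so that the default
configuration exhibits the full behavioral repertoire with comfortable
margins — the property battery (`amygsim suite`) is the executable
definition of that repertoire, and the thresholds baked into it (5%
slow-weight drift, the 50% lesion deficit, the 2× generalization ratio,
the 0.1 spurious-potentiation bound) are calibrations of qualitative
terms ("almost unchanged", "appreciable", "partial") against this
configuration; they are config-coupled, not universal constants.

## Protocols and the synthetic stimuli

The generator produces exactly the study conditions the experiments
need: two CS bands of 500–1500 Hz and 1000–2000 Hz (channels 4–11 and
8–15, overlap 8–11) at unit drive amplitude, presented in strict
alternation, 15 trials per epoch, four epochs (acquisition, extinction,
retrieval, extinction retrieval). During acquisition and retrieval every
trial is US-paired; in extinction epochs both CSs receive omission
trials, except in the "confusing"/"phobic" presets where only CS1 is
extinguished while CS2 remains paired. Intertrial intervals are
represented by resetting all activities to zero (only weights persist),
not by simulating wall-clock gaps. What this synthetic world omits —
stimulus noise, variable inter-trial intervals, context, habituation,
individual variability — bounds what passing the battery shows: the
circuit logic is sufficient for the phenomena, on clean inputs; nothing
here validates robustness to noisy or contextual data.

One documented ambiguity: the normal-mode experiment extinguishes both
CSs, while the confusing-outcomes experiments extinguish only one; where
a source is ambiguous about which variant a figure used, the presets
follow the behavior described for that experiment (both-CS extinction
for normal mode, single-CS for confusing mode).

## Numerics

Explicit forward Euler with fixed `dt = 0.001` (no adaptive stepping, for
determinism). The step is far inside the stability region (the fastest
local rate is `A + e + h ≲ 25`), and halving `dt` moves a trained-trial
trajectory by less than 1e-3 sup-norm (measured: ≈ 6e-4). The Euler
fixed point coincides with the ODE fixed point, so equilibria are
dt-insensitive up to the stopping tolerance. The isolated-unit
equilibrium reproduces the closed form `B E / (A + E)` to machine
precision. `equilibrate` stops when the per-step sup-norm change falls
below `tol` or a time budget expires, and reports which condition fired;
any activity exceeding `B` beyond tolerance raises a numerical error
carrying the offending trial index. Inner loops are numba-jitted; the
Python wrappers validate shapes, parameter invariants and weight bounds
on every trial.

## Known limitations

- The teaching signals are exogenous; nothing is learned about *when*
  the US should occur within a trial.
- A single ITC cell per cluster: no within-cluster diversity, and the
  ITCd→CeL pathway is absent along with CeL itself.
- The two lesion phenotypes and the partial-extinction regime sit on
  quantitative gain balances; they are robust under the shipped
  configuration (the battery checks them with explicit margins) but are
  not structural identities of the circuit.
- Model time is abstract; no mapping to seconds is claimed.
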