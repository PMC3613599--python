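# amygsim

A rate-coded simulator of the amygdala local circuit for Pavlovian fear
conditioning: acquisition, extinction, savings, top-down (infralimbic)
biasing, intercalated-cell lesions, and attention-dependent
generalization — all from synthetic tonotopic stimuli, with no external
data.

## The scientific problem

During fear conditioning an initially neutral cue (the conditioned
stimulus, CS) comes to predict an aversive event (the unconditioned
stimulus, US, e.g. a footshock), and afterwards drives defensive behavior
such as freezing. Extinction — presenting the CS without the US — 
suppresses the response without erasing the underlying memory: animals
reacquire fear much faster than they learned it (savings), and prefrontal
(infralimbic, IL) input can bias how readily they let their guard down.

`amygsim` implements a circuit-level account of these phenomena. A
20-channel tonotopic cortical array (CTX), wired as a distance-dependent
on-center off-surround shunting network, projects topographically to the
lateral amygdala (LA) and onward to the basal nucleus (BA). The LA array
converges onto a single dorsal intercalated cell (ITCd), the BA array
onto a single ventral intercalated cell (ITCv). ITCd inhibits ITCv; ITCv
inhibits the output cell of the medial central nucleus (CeM), whose
supra-threshold activity stands in for the freezing response. Both ITC
cells receive tonic excitation from IL (`E_ILd`, `E_ILv`).

Every unit `x` follows a shunting (Grossberg-form) rate equation

    dx/dt = -A x + (B - x)[excitation]+ - (x + D)[inhibition]+

so activity is automatically bounded. Two teaching signals gate Hebbian
plasticity: `R+` (US presence) and `R-` (US-omission prediction error).
Four weight vectors learn — CTX→LA (`w_cl`) and LA→BA (`w_lb`) slowly
under `R+` and decaying only negligibly; LA→ITCd (`w_ld`) and BA→ITCv
(`w_bv`) quickly, tracking the current CS-US contingency:

    dw_cl/dt = λs R+ x_ctx (wmax - w_cl) - δ (w_cl - w0)
    dw_lb/dt = λs R+ x_la  (wmax - w_lb) - δ (w_lb - w0)
    dw_ld/dt = λf x_la [R+ (wmax - w_ld) - μd (1 - R+)(w_ld - w0)]
    dw_bv/dt = λf x_ba [R- (wmax - w_bv) - μv (1 - R-)(w_bv - w0)]

The timescale separation (λf ≫ λs) is what produces savings: extinction
reverses the fast ITC weights while the slow CS-US memory in `w_cl`,
`w_lb` survives. The off-surround gain `f_I` of the cortical network acts
as an attention dial — strong inhibition sharpens the CS representation,
weak inhibition lets activity spread and the US become associated with
frequencies that were never presented.

## Worked example

Run the standard four-epoch experiment (acquisition → extinction →
retrieval → extinction retrieval, two overlapping CSs of 500–1500 Hz and
1000–2000 Hz presented in alternation, 15 trials per epoch):

```sh
amygsim run --preset normal --seed 1 --out demo
```

which prints `wrote demo/normal_seed1_summary.csv (60 trials)`. The
summary table holds one row per trial; selecting CS1's first and last
trial of each epoch:

```
 trial                epoch  cs   cr_cem  responded
     0          acquisition CS1 0.000000      False
    14          acquisition CS1 0.412880       True
    15           extinction CS1 0.425984       True
    29           extinction CS1 0.000000      False
    30            retrieval CS1 0.000000      False
    44            retrieval CS1 0.465667       True
    45 extinction_retrieval CS1 0.467331       True
    59 extinction_retrieval CS1 0.000000      False
```

`cr_cem` is the conditioned-response readout: CeM activity at the end of
the pre-US portion of CS-on. The naive circuit is silent (trial 0), fear
is acquired (0.41 > the 0.1 response threshold), extinguished back to
zero, re-acquired during retrieval — in 3 trials instead of the original
4, the savings signature — and re-extinguished. Adding `--plot` writes
heatmaps of the CTX/LA/BA arrays and line plots of ITCd/ITCv/CeM;
`amygsim presets` lists all ten shipped experiments (normal, cautious,
rapid_switch, two lesions, three confusing-outcome variants,
generalization, phobic), and `amygsim sweep --param E_ILd --values
0,2.5,5` maps out the infralimbic bias curve.

The whole behavioral repertoire is checked in one command:

```sh
amygsim suite --out suite_out      # prints 22/22 properties passed
```

which runs every preset plus the IL sweeps and writes a pass/fail report
(`suite_report.csv`), exiting nonzero if any property fails.

## Layout

| module | contents |
| --- | --- |
| `amygsim.circuit` | parameter/state types, shunting dynamics, equilibration |
| `amygsim.plasticity` | gated Hebbian rules, lesion masks, drift summaries |
| `amygsim.protocols` | CS patterns, trial/epoch schedules, the ten presets |
| `amygsim.runner` | protocol execution, trial records, summary metrics |
| `amygsim.suite` | the named property battery behind `amygsim suite` |
| `amygsim.config` / `amygsim.cli` | YAML configs, precedence, CLI entry points |
| `amygsim.plotting` | figure-style heatmaps and time-course plots |

See `docs/methods.md` for the full model description, parameter table and
numerical choices.
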