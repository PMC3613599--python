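"""The behavioral and numerical property battery.

Every qualitative claim the model makes — four-phase learning, savings,
IL biasing, lesion phenotypes, confusing-outcome synergy, attention-
dependent generalization — is operationalized here as a named, machine-
checkable property evaluated on the shipped default configuration. The
battery is what the ``amygsim suite`` command runs and what the
acceptance tests assert.

All response magnitudes are conditioned-response (CR) levels: CeM
activity at the end of the pre-US window (see :mod:`amygsim.runner`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .circuit import (CircuitParameters, StimulusPattern, WeightState,
                      equilibrate, kernel_matrix)
from .plasticity import weight_drift
from .protocols import ProtocolSpec, build_preset, make_cs_pattern
from .runner import (NOT_REACHED, SimulationResult, discrimination_check,
                     generalization_index, run_protocol, savings_index,
                     trials_to_criterion)

__all__ = ["PropertyResult", "BatteryReport", "run_battery",
           "run_all_presets"]

#: channels covered by the union of the two shipped CS bands
PRESENTED_CHANNELS = tuple(range(4, 16))


@dataclass(frozen=True)
class PropertyResult:
    name: str
    passed: bool
    value: float
    detail: str = ""


@dataclass
class BatteryReport:
    results: list
    seed: int = 0

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.results)

    @property
    def n_failed(self) -> int:
        return sum(not r.passed for r in self.results)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"property": [r.name for r in self.results],
             "passed": [r.passed for r in self.results],
             "value": [r.value for r in self.results],
             "detail": [r.detail for r in self.results]})

    def __getitem__(self, name: str) -> PropertyResult:
        for r in self.results:
            if r.name == name:
                return r
        raise KeyError(name)


def _with_bias(protocol: ProtocolSpec, **bias) -> ProtocolSpec:
    return ProtocolSpec(
        epochs=protocol.epochs, stimuli=protocol.stimuli,
        f_I=bias.get("f_I", protocol.f_I),
        E_ILd=bias.get("E_ILd", protocol.E_ILd),
        E_ILv=bias.get("E_ILv", protocol.E_ILv),
        lesions=protocol.lesions, seed=protocol.seed,
        name=protocol.name)


def run_all_presets(params: CircuitParameters | None = None,
                    trials_per_epoch: int = 15, seed: int = 0) -> dict:
    """Run the ten shipped presets once; keyed by preset name."""
    from .protocols import PRESET_NAMES
    return {name: run_protocol(build_preset(name, trials_per_epoch, seed),
                               params=params)
            for name in PRESET_NAMES}


def _final_cr(result: SimulationResult, epoch: str,
              cs: str | None = None) -> float:
    return result.epoch_records(epoch, cs)[-1].cr_cem


def _epoch_max_cr(result: SimulationResult, epoch: str) -> float:
    return max(r.cr_cem for r in result.epoch_records(epoch))


def run_battery(params: CircuitParameters | None = None,
                trials_per_epoch: int = 15,
                seed: int = 0) -> BatteryReport:
    """Evaluate every property on one configuration; ~15 s on one core."""
    params = params or CircuitParameters()
    theta = params.theta_response
    results: list[PropertyResult] = []

    def check(name, passed, value, detail=""):
        results.append(PropertyResult(name, bool(passed), float(value),
                                      detail))

    runs = run_all_presets(params, trials_per_epoch, seed)
    nrm = runs["normal"]

    # -- four-phase learning: acquire / extinguish / retrieve / re-extinguish
    for cs in ("CS1", "CS2"):
        ttc = {
            "a": trials_to_criterion(nrm, "acquisition", "acquire", cs),
            "e": trials_to_criterion(nrm, "extinction", "extinguish", cs),
            "r": trials_to_criterion(nrm, "retrieval", "acquire", cs),
            "er": trials_to_criterion(nrm, "extinction_retrieval",
                                      "extinguish", cs),
        }
        first = nrm.epoch_records("acquisition", cs)[0].responded
        ok = (all(v != NOT_REACHED for v in ttc.values())
              and ttc["a"] >= 1 and not first)
        check(f"four_phase_{cs.lower()}", ok, ttc["a"],
              f"trials-to-criterion {ttc}")

    # -- savings: faster reacquisition than acquisition
    si = savings_index(nrm)
    check("savings_index", si < 1.0, si,
          "retrieval/acquisition trials-to-criterion ratio")

    # -- slow weights persist through extinction; fast weights reverse
    acq_w = nrm.epoch_records("acquisition")[-1].weights
    ext_w = nrm.epoch_records("extinction")[-1].weights
    drift = weight_drift(acq_w, ext_w)
    slow = max(drift.max_rel["w_cl"], drift.max_rel["w_lb"])
    check("slow_weight_persistence", slow <= 0.05, slow,
          "max relative |dw| of w_cl, w_lb across extinction")
    cs_ch = np.array(PRESENTED_CHANNELS)
    rev = (np.all(ext_w.w_ld[cs_ch] < acq_w.w_ld[cs_ch])
           and np.all(ext_w.w_bv[cs_ch] > acq_w.w_bv[cs_ch]))
    check("fast_weight_reversal", rev, float(rev),
          "w_ld falls and w_bv rises on CS channels during extinction")

    # -- IL biasing
    caut_ttc = trials_to_criterion(runs["cautious"], "extinction",
                                   "extinguish")
    check("cautious_no_extinction", caut_ttc == NOT_REACHED,
          min(r.cr_cem for r in runs["cautious"].epoch_records("extinction")),
          "extinction criterion never reached at E_ILd=5")
    nrm_ttc = trials_to_criterion(nrm, "extinction", "extinguish")
    rap_ttc = trials_to_criterion(runs["rapid_switch"], "extinction",
                                  "extinguish")
    check("rapid_switch_fewer_trials", rap_ttc < nrm_ttc, rap_ttc,
          f"extinction in {rap_ttc} vs {nrm_ttc} trials at E_ILv=5")
    base = build_preset("normal", trials_per_epoch, seed)
    sweep_d = [_final_cr(run_protocol(_with_bias(base, E_ILd=v), params),
                         "extinction") for v in (0.0, 2.5, 5.0)]
    sweep_v = [_final_cr(run_protocol(_with_bias(base, E_ILv=v), params),
                         "extinction") for v in (2.0, 3.5, 5.0)]
    eps = 1e-12
    check("bias_monotonic_itcd",
          sweep_d[0] <= sweep_d[1] + eps and sweep_d[1] <= sweep_d[2] + eps,
          sweep_d[2] - sweep_d[0],
          f"final-extinction CR over E_ILd 0/2.5/5: {np.round(sweep_d, 3)}")
    check("bias_monotonic_itcv",
          sweep_v[0] >= sweep_v[1] - eps and sweep_v[1] >= sweep_v[2] - eps,
          sweep_v[0] - sweep_v[2],
          f"final-extinction CR over E_ILv 2/3.5/5: {np.round(sweep_v, 3)}")

    # -- lesions
    intact_acq = _epoch_max_cr(nrm, "acquisition")
    led = _epoch_max_cr(runs["lesion_itcd"], "acquisition")
    check("lesion_itcd_acquisition_deficit", led <= 0.5 * intact_acq,
          led / intact_acq,
          "max acquisition CR with frozen w_ld, relative to intact")
    lev = _final_cr(runs["lesion_itcv"], "extinction")
    check("lesion_itcv_partial_extinction",
          theta < lev < intact_acq, lev,
          "final-extinction CR with frozen w_bv sits between threshold "
          "and the intact acquisition response")

    # -- confusing outcomes and ITC synergy
    def ext_margin(res):
        d = discrimination_check(res)
        e = d[d.epoch == "extinction"]
        return (float(e[e.cs == "CS2"].cr_cem.iloc[0])
                - float(e[e.cs == "CS1"].cr_cem.iloc[0]))

    conf = discrimination_check(runs["confusing"])
    ce = conf[conf.epoch == "extinction"]
    cs1_on = bool(ce[ce.cs == "CS1"].responded.iloc[0])
    cs2_on = bool(ce[ce.cs == "CS2"].responded.iloc[0])
    check("confusing_discrimination", (not cs1_on) and cs2_on,
          ext_margin(runs["confusing"]),
          "extinguished CS silent, non-extinguished CS responding")
    dv = discrimination_check(runs["confusing_lesion_itcv"])
    ev = dv[dv.epoch == "extinction"]
    check("confusing_lesion_itcv_no_extinction",
          bool(ev[ev.cs == "CS1"].responded.iloc[0]),
          float(ev[ev.cs == "CS1"].cr_cem.iloc[0]),
          "with frozen w_bv the extinguished CS keeps responding")
    m_both = ext_margin(runs["confusing"])
    m_ld = ext_margin(runs["confusing_lesion_itcd"])
    m_lv = ext_margin(runs["confusing_lesion_itcv"])
    check("itc_synergy", m_both > m_ld and m_both > m_lv, m_both,
          f"discrimination margin both-on {m_both:.3f} vs "
          f"frozen-w_ld {m_ld:.3f} / frozen-w_bv {m_lv:.3f}")

    # -- attention and generalization
    gi_gen = generalization_index(runs["generalization"],
                                  PRESENTED_CHANNELS)
    gi_nrm = generalization_index(nrm, PRESENTED_CHANNELS)
    check("generalization_spread", gi_gen >= 2.0 * gi_nrm, gi_gen,
          f"spurious w_cl potentiation {gi_gen:.3f} at f_I=0.3 vs "
          f"{gi_nrm:.3f} at f_I=3.0")
    check("normal_spread_bounded", gi_nrm <= 0.1, gi_nrm,
          "spurious potentiation under sharp tuning stays small")
    dp = discrimination_check(runs["phobic"])
    ep = dp[dp.epoch == "extinction"]
    check("phobic_extinction_failure",
          bool(ep[ep.cs == "CS1"].responded.iloc[0]),
          float(ep[ep.cs == "CS1"].cr_cem.iloc[0]),
          "single-CS extinction fails under low attention (f_I=0.3)")

    # -- numerics
    trace_run = run_protocol(build_preset("normal", 2, seed), params,
                             record_trace=True, trace_stride=50)
    lo = min(float(X.min()) for _, X in trace_run.traces)
    hi = max(float(X.max()) for _, X in trace_run.traces)
    check("activity_bounds", lo >= -1e-12 and hi <= params.B + 1e-9, hi,
          f"all recorded activities within [0, B]; range [{lo:.2g},{hi:.3f}]")

    iso = params.with_overrides(f_E=0.0, f_I=0.0)
    E = 0.7
    stim = StimulusPattern(np.concatenate(
        ([E], np.zeros(params.n_channels - 1))))
    eq = equilibrate(stim, WeightState.initial(iso), params=iso,
                     tol=1e-12, t_max=100.0)
    err = abs(eq.state.x_ctx[0] - iso.B * E / (iso.A + E))
    check("single_unit_fixed_point", err < 1e-6, err,
          "isolated-channel equilibrium vs closed form B*E/(A+E)")

    err_dt = _dt_halving_error(params)
    check("dt_halving", err_dt < 1e-3, err_dt,
          "sup-norm trajectory difference between dt and dt/2, one trial")

    contrasts = []
    cs1 = make_cs_pattern(500.0, 1500.0)
    for f_I in (0.3, 1.0, 3.0):
        pc = params.with_overrides(f_I=f_I)
        st = equilibrate(cs1, WeightState.initial(pc), params=pc,
                         tol=1e-10, t_max=100.0).state
        sup = cs1.support
        flank = float(np.delete(st.x_ctx, sup).max())
        contrasts.append(float(st.x_ctx[sup].max()) / max(flank, 1e-12))
    check("contrast_monotonic",
          contrasts[0] <= contrasts[1] <= contrasts[2], contrasts[0],
          f"peak/flank contrast over f_I 0.3/1/3: "
          f"{[f'{c:.3g}' for c in contrasts]}")

    again = run_protocol(build_preset("normal", trials_per_epoch, seed),
                         params)
    check("determinism", nrm.to_frame().equals(again.to_frame()), 1.0,
          "byte-identical summary tables across repeated runs")

    return BatteryReport(results=results, seed=seed)


def _dt_halving_error(params: CircuitParameters) -> float:
    """Sup-norm difference of one trained trial at dt versus dt/2."""
    prot = build_preset("normal")
    trained = run_protocol(prot, params)
    weights = trained.epoch_records("acquisition")[-1].weights
    stim = prot.stimuli["CS1"]
    n = params.n_channels
    KE = kernel_matrix(n, params.sigma_E)
    KI = kernel_matrix(n, params.sigma_I)

    def traj(dt, stride):
        p = params.with_overrides(dt=dt)
        n_steps = int(round(p.t_cs / dt))
        teach = n_steps - int(round(p.t_teach / dt))
        x = np.zeros(3 * n + 3)
        w = weights.copy()
        tr = np.empty((-(-n_steps // stride), x.shape[0]))
        _kernels.run_trial(x, stim.drive, w.w_cl, w.w_lb, w.w_ld, w.w_bv,
                           KE, KI, p.pvec(), p.lvec(), n_steps, teach,
                           1.0, 0.0, True, np.zeros(4, dtype=np.int64),
                           tr, stride, True)
        return tr

    a = traj(params.dt, 10)
    b = traj(params.dt / 2.0, 20)
    m = min(a.shape[0], b.shape[0])
    return float(np.abs(a[:m] - b[:m]).max())
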