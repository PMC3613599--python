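"""Protocol execution and the summary metrics read off the CeM output.

A "fear response" on a trial is defined as the CeM conditioned-response
level — its activity at the end of the pre-US portion of CS-on, after the
onset transient has settled — exceeding ``theta_response``. Freezing in
rodents is likewise scored over the CS interval before US delivery, which
keeps the readout free of both the orienting transient at CS onset and of
US-driven plasticity within the teaching window. All metrics operate on
the per-trial records, never on raw traces, so they are invariant to
whether a full trace was kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels, __version__
from .circuit import (ActivityState, CircuitParameters, WeightState,
                      kernel_matrix)
from .errors import ConfigurationError, NumericalError, StructuralError
from .protocols import ProtocolSpec

__all__ = [
    "TrialRecord", "SimulationResult", "run_protocol",
    "trials_to_criterion", "savings_index", "generalization_index",
    "discrimination_check", "NOT_REACHED",
]

#: Sentinel returned by :func:`trials_to_criterion` when the criterion is
#: never met; compares greater than any real trial count.
NOT_REACHED = float("inf")


@dataclass(frozen=True)
class TrialRecord:
    index: int                  # 0-based position within the protocol
    epoch: str
    trial_in_epoch: int         # 1-based position within its epoch
    cs_label: str
    cr_cem: float               # CeM level at the end of the CR window
    peak_cem: float             # max CeM over the CR window
    peak_itcd: float
    peak_itcv: float
    responded: bool             # cr_cem > theta_response
    weights: WeightState        # snapshot at trial end


@dataclass
class SimulationResult:
    """Ordered trial records plus (optionally) full activity traces."""

    records: list
    protocol: ProtocolSpec
    params: CircuitParameters
    seed: int
    traces: list | None = None      # per trial: (times, states) arrays

    def __post_init__(self):
        if len(self.records) != self.protocol.n_trials:
            raise StructuralError("record count does not match protocol")

    def epoch_records(self, epoch: str, cs_label: str | None = None):
        recs = [r for r in self.records if r.epoch == epoch]
        if cs_label is not None:
            recs = [r for r in recs if r.cs_label == cs_label]
        if not recs:
            raise ConfigurationError(f"no trials in epoch {epoch!r}")
        return recs

    def final_weights(self) -> WeightState:
        return self.records[-1].weights

    def to_frame(self) -> pd.DataFrame:
        """One row per trial; the CSV-facing summary table."""
        return pd.DataFrame({
            "trial": [r.index for r in self.records],
            "epoch": [r.epoch for r in self.records],
            "trial_in_epoch": [r.trial_in_epoch for r in self.records],
            "cs": [r.cs_label for r in self.records],
            "cr_cem": [r.cr_cem for r in self.records],
            "peak_cem": [r.peak_cem for r in self.records],
            "peak_itcd": [r.peak_itcd for r in self.records],
            "peak_itcv": [r.peak_itcv for r in self.records],
            "responded": [r.responded for r in self.records],
        })

    def metadata(self) -> dict:
        from dataclasses import asdict
        return {
            "version": __version__,
            "seed": self.seed,
            "preset": self.protocol.name,
            "params": asdict(self.params),
            "f_I": self.protocol.f_I,
            "E_ILd": self.protocol.E_ILd,
            "E_ILv": self.protocol.E_ILv,
            "lesions": asdict(self.protocol.lesions),
            "trials": self.protocol.n_trials,
        }

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\r\n")

    def write_metadata(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2, sort_keys=True)


def run_protocol(protocol: ProtocolSpec,
                 params: CircuitParameters | None = None,
                 record_trace: bool = False,
                 trace_stride: int = 20) -> SimulationResult:
    """Execute a protocol trial by trial.

    Each trial: reset activities to zero, integrate the CS-on interval
    with its teaching timeline while updating weights every step
    (respecting lesions), then record the peaks and a weight snapshot.
    Fully deterministic given (protocol, params, seed).
    """
    resolved = protocol.resolve_params(params)
    n = resolved.n_channels
    KE = kernel_matrix(n, resolved.sigma_E)
    KI = kernel_matrix(n, resolved.sigma_I)
    pvec = resolved.pvec()
    lvec = resolved.lvec()
    freeze = protocol.lesions.flags()
    weights = WeightState.initial(resolved)
    records = []
    traces = [] if record_trace else None
    dummy = np.empty((1, 1))
    index = 0
    for epoch in protocol.epochs:
        for t_in_epoch, trial in enumerate(epoch.trials, start=1):
            stim = protocol.stimuli[trial.cs_label]
            if stim.n_channels != n:
                raise StructuralError(
                    f"stimulus {trial.cs_label!r} has wrong length")
            n_steps = int(round(trial.t_cs / resolved.dt))
            teach_start = n_steps - int(round(trial.t_teach / resolved.dt))
            x = np.zeros(3 * n + 3)       # activities reset to zero
            if record_trace:
                n_rec = -(-n_steps // trace_stride)
                trace = np.empty((n_rec, x.shape[0]))
            else:
                trace = dummy
            cr_c, peak_c, peak_d, peak_v, ok = _kernels.run_trial(
                x, stim.drive, weights.w_cl, weights.w_lb, weights.w_ld,
                weights.w_bv, KE, KI, pvec, lvec, n_steps, teach_start,
                1.0 if trial.paired_with_us else 0.0,
                1.0 if trial.omission_signal else 0.0,
                True, freeze, trace, trace_stride, record_trace)
            if not ok:
                raise NumericalError(
                    f"numerical divergence in trial {index}",
                    trial_index=index)
            weights.check_bounds(resolved)
            records.append(TrialRecord(
                index=index, epoch=epoch.label, trial_in_epoch=t_in_epoch,
                cs_label=trial.cs_label, cr_cem=cr_c, peak_cem=peak_c,
                peak_itcd=peak_d, peak_itcv=peak_v,
                responded=bool(cr_c > resolved.theta_response),
                weights=weights.copy()))
            if record_trace:
                times = np.arange(trace.shape[0]) * trace_stride \
                    * resolved.dt
                traces.append((times, trace))
            index += 1
    return SimulationResult(records=records, protocol=protocol,
                            params=resolved, seed=protocol.seed,
                            traces=traces)


def trials_to_criterion(result: SimulationResult, epoch: str,
                        direction: str,
                        cs_label: str | None = None) -> float:
    """1-based index of the first trial meeting the criterion *stably*.

    ``direction`` is "acquire" (responded becomes true) or "extinguish"
    (responded becomes false); the status must persist for the remainder
    of the epoch, which avoids counting transient flickers. Returns
    :data:`NOT_REACHED` if the criterion is never stably met.
    """
    if direction not in ("acquire", "extinguish"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    target = direction == "acquire"
    recs = result.epoch_records(epoch, cs_label)
    status = [r.responded for r in recs]
    for k in range(len(status)):
        if all(s == target for s in status[k:]):
            return k + 1
    return NOT_REACHED


def savings_index(result: SimulationResult) -> float:
    """Trials-to-reacquisition over trials-to-acquisition (< 1 = savings)."""
    acq = trials_to_criterion(result, "acquisition", "acquire")
    if acq == NOT_REACHED:
        raise ConfigurationError(
            "savings index undefined: acquisition criterion never reached")
    ret = trials_to_criterion(result, "retrieval", "acquire")
    return ret / acq


def generalization_index(result: SimulationResult,
                         presented_channels) -> float:
    """Normalized spurious CTX->LA potentiation outside the presented set.

    max over non-presented channels of (w_cl - w0) / (w_max - w0); zero
    for an untrained network, approaching one where never-presented
    channels were fully associated with the US.
    """
    presented = np.asarray(sorted(set(int(c) for c in presented_channels)))
    n = result.params.n_channels
    outside = np.setdiff1d(np.arange(n), presented)
    if outside.size == 0:
        raise ConfigurationError(
            "presented set covers every channel; index undefined")
    w = result.final_weights().w_cl
    p = result.params
    return float(np.max((w[outside] - p.w0) / (p.w_max - p.w0)))


def discrimination_check(result: SimulationResult) -> pd.DataFrame:
    """Final-trial response status per CS per epoch (two-CS protocols).

    Operationalizes discrimination between an extinguished and a
    non-extinguished CS: one row per (epoch, cs) with the peak CeM and
    responded flag of that CS's last trial in the epoch.
    """
    labels = sorted({r.cs_label for r in result.records})
    if len(labels) < 2:
        raise ConfigurationError("discrimination requires two CSs")
    rows = []
    for epoch in dict.fromkeys(r.epoch for r in result.records):
        for cs in labels:
            last = result.epoch_records(epoch, cs)[-1]
            rows.append({"epoch": epoch, "cs": cs,
                         "cr_cem": last.cr_cem,
                         "peak_cem": last.peak_cem,
                         "responded": last.responded})
    return pd.DataFrame(rows)
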