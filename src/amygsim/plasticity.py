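"""Gated Hebbian plasticity with slow (LA/BA) and fast (ITC) timescales.

Four weight vectors learn; everything else is fixed. The slow pathway
(CTX->LA and LA->BA) potentiates only when presynaptic activity coincides
with the US gate ``r_plus`` and decays at a negligible rate ``delta_slow``
toward its initial value, so CS-US associations survive extinction (the
savings substrate). The fast pathway tracks current contingency: LA->ITCd
potentiates under ``r_plus`` and depresses (Hebbian-gated, so only while
the presynaptic cell is active) whenever the US is absent; BA->ITCv does
the mirror image under the omission gate ``r_minus``.

    dw_cl/dt = lambda_slow r+ x_ctx (w_max - w_cl) - delta_slow (w_cl - w0)
    dw_lb/dt = lambda_slow r+ x_la  (w_max - w_lb) - delta_slow (w_lb - w0)
    dw_ld/dt = lambda_fast x_la [r+ (w_max - w_ld) - mu_d (1 - r+) w_ld]
    dw_bv/dt = lambda_fast x_ba [r- (w_max - w_bv) - mu_v (1 - r-) w_bv]
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .circuit import (ActivityState, CircuitParameters, TeachingSignals,
                      WeightState)
from .errors import NumericalError, StructuralError

__all__ = ["LesionSpec", "update_weights", "weight_drift", "WeightDrift"]


@dataclass(frozen=True)
class LesionSpec:
    """Flags that freeze selected weight vectors (learning knock-outs)."""

    freeze_w_cl: bool = False
    freeze_w_lb: bool = False
    freeze_w_ld: bool = False
    freeze_w_bv: bool = False

    def flags(self) -> np.ndarray:
        """0/1 vector ordered (w_cl, w_lb, w_ld, w_bv) for the kernels."""
        return np.array([self.freeze_w_cl, self.freeze_w_lb,
                         self.freeze_w_ld, self.freeze_w_bv],
                        dtype=np.int64)

    @property
    def any(self) -> bool:
        return any(self.flags())


LesionSpec.NONE = LesionSpec()


def update_weights(weights: WeightState, state: ActivityState,
                   teaching: TeachingSignals,
                   lesions: LesionSpec = LesionSpec.NONE,
                   params: CircuitParameters | None = None) -> WeightState:
    """One Euler step of the four learning rules; returns a new WeightState.

    Frozen vectors are returned bit-identical. Results are clipped to
    ``[0, w_max]``; a weight escaping that interval beyond rounding
    tolerance raises :class:`NumericalError`.
    """
    params = params or CircuitParameters()
    n = params.n_channels
    if any(v.shape[0] != n for v in
           (*weights.as_tuple(), state.x_ctx, state.x_la, state.x_ba)):
        raise StructuralError(f"weight/state vectors must have length {n}")
    out = weights.copy()
    _kernels.step_weights(out.w_cl, out.w_lb, out.w_ld, out.w_bv,
                          state.pack(), teaching.r_plus, teaching.r_minus,
                          params.lvec(), params.dt, lesions.flags(), n)
    out.check_bounds(params)
    return out


@dataclass(frozen=True)
class WeightDrift:
    """Max and mean relative absolute change, per weight vector."""

    max_rel: dict
    mean_rel: dict

    def __getitem__(self, name: str) -> float:
        return self.max_rel[name]


def weight_drift(weights_before: WeightState,
                 weights_after: WeightState) -> WeightDrift:
    """Relative change summary used to assert persistence of slow weights.

    Relative change is |after - before| / max(|before|, eps) per synapse,
    summarized by its max and mean over each vector.
    """
    eps = 1e-12
    max_rel = {}
    mean_rel = {}
    for name, b, a in zip(("w_cl", "w_lb", "w_ld", "w_bv"),
                          weights_before.as_tuple(),
                          weights_after.as_tuple()):
        if b.shape != a.shape:
            raise StructuralError("weight vectors have mismatched lengths")
        rel = np.abs(a - b) / np.maximum(np.abs(b), eps)
        max_rel[name] = float(rel.max(initial=0.0))
        mean_rel[name] = float(rel.mean()) if rel.size else 0.0
    return WeightDrift(max_rel, mean_rel)
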