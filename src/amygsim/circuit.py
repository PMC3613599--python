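"""Core state types and deterministic rate dynamics of the amygdala circuit.

The model is a rate-coded network of six stages: a tonotopic cortical array
(CTX) wired as a distance-dependent on-center off-surround shunting network,
topographic arrays in the lateral (LA) and basal (BA) amygdala, single
dorsal and ventral intercalated cells (ITCd, ITCv), and the medial central
nucleus output cell (CeM). Every unit obeys a shunting (Grossberg-form)
equation

    dx/dt = -A x + (B - x) [excitatory drive]+ - (x + D) [inhibitory drive]+

integrated with fixed-step forward Euler. For the CTX array the excitatory
drive is the external stimulus plus on-center recurrence and the inhibitory
drive is the off-surround recurrence scaled by ``f_I``; for ITCv and CeM the
single bracketed drive is the net (excitation minus inhibition) passed
through rectification, so sufficiently strong inhibition silences the unit
outright. LA, BA and ITCd receive purely excitatory drives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np

from . import _kernels
from .errors import NumericalError, ParameterError, StructuralError

__all__ = [
    "CircuitParameters",
    "StimulusPattern",
    "TeachingSignals",
    "ActivityState",
    "WeightState",
    "EquilibrationResult",
    "distance_kernel",
    "kernel_matrix",
    "step_circuit",
    "equilibrate",
    "reset_activities",
]


@dataclass(frozen=True)
class CircuitParameters:
    """All dynamical, kernel, gain and learning-rate constants.

    Rates are in units of inverse model time, activities are bounded by
    ``B``, and plastic weights live in ``[0, w_max]``. ``f_I`` is the
    off-surround inhibitory gain (the attention/contrast dial); ``E_ILd``
    and ``E_ILv`` are the tonic infralimbic drives onto the intercalated
    cells that bias the circuit between "cautious" and "rapid switch"
    modes.
    """

    n_channels: int = 20
    A: float = 1.0
    B: float = 1.0
    D: float = 0.2
    f_E: float = 0.5
    f_I: float = 3.0
    sigma_E: float = 1.0
    sigma_I: float = 6.0
    E_ILd: float = 0.0
    E_ILv: float = 2.0
    g_il: float = 1.0
    g_la_itcd: float = 0.7
    g_ba_itcv: float = 5.0
    g_itcd_itcv: float = 20.0
    g_itcv_cem: float = 1.15
    g_ba_cem: float = 10.5
    w0: float = 0.05
    w_max: float = 1.0
    lambda_slow: float = 0.4
    lambda_fast: float = 5.0
    mu_d: float = 0.15
    mu_v: float = 0.05
    delta_slow: float = 1e-5
    dt: float = 0.001
    t_cs: float = 10.0
    t_teach: float = 2.0
    theta_response: float = 0.1

    def __post_init__(self):
        strictly_positive = (
            "A", "B", "sigma_E", "sigma_I", "g_il", "g_la_itcd",
            "g_ba_itcv", "g_itcd_itcv", "g_itcv_cem", "g_ba_cem", "w_max",
            "lambda_slow", "lambda_fast", "mu_d", "mu_v", "dt", "t_cs",
            "t_teach",
        )
        for name in strictly_positive:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        # f_E and f_I may be zero: an isolated channel with no recurrence
        # is a useful analytic limit (its fixed point is B E/(A+E))
        for name in ("f_E", "f_I", "E_ILd", "E_ILv", "delta_slow", "D",
                     "w0"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.n_channels < 1:
            raise ParameterError("n_channels must be a positive integer")
        if self.sigma_I <= self.sigma_E:
            raise ParameterError("sigma_I must exceed sigma_E")
        if self.lambda_fast <= self.lambda_slow:
            raise ParameterError("lambda_fast must exceed lambda_slow")
        if not (self.w_max > self.w0 >= 0):
            raise ParameterError("w_max > w0 >= 0 required")
        if self.dt >= 1.0 / self.A:
            raise ParameterError("dt must be smaller than 1/A for stability")
        if not (0 < self.theta_response < self.B):
            raise ParameterError("theta_response must lie in (0, B)")
        if self.t_teach > self.t_cs:
            raise ParameterError("teaching window cannot exceed CS duration")

    def with_overrides(self, **kwargs) -> "CircuitParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        unknown = set(kwargs) - {f.name for f in fields(self)}
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **kwargs)

    def pvec(self) -> np.ndarray:
        """Pack the dynamics constants for the compiled kernels."""
        v = np.empty(_kernels.N_PVEC)
        v[0] = self.A
        v[1] = self.B
        v[2] = self.D
        v[3] = self.f_E
        v[4] = self.f_I
        v[5] = self.E_ILd
        v[6] = self.E_ILv
        v[7] = self.g_la_itcd
        v[8] = self.g_ba_itcv
        v[9] = self.g_itcd_itcv
        v[10] = self.g_itcv_cem
        v[11] = self.g_ba_cem
        v[12] = self.dt
        v[13] = self.g_il
        return v

    def lvec(self) -> np.ndarray:
        """Pack the learning constants for the compiled kernels."""
        return np.array([
            self.lambda_slow, self.lambda_fast, self.mu_d, self.mu_v,
            self.delta_slow, self.w0, self.w_max,
        ])


@dataclass(frozen=True)
class StimulusPattern:
    """Per-channel external drive E_i representing one CS on the array."""

    drive: np.ndarray
    label: str = "CS"

    def __post_init__(self):
        object.__setattr__(self, "drive",
                           np.asarray(self.drive, dtype=float))
        if self.drive.ndim != 1:
            raise StructuralError("stimulus drive must be a 1-D vector")
        if np.any(self.drive < 0):
            raise ParameterError("stimulus drives must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.drive.shape[0]

    @property
    def support(self) -> np.ndarray:
        """Indices of channels with non-zero drive."""
        return np.flatnonzero(self.drive > 0)

    @property
    def is_off(self) -> bool:
        """An all-zero pattern encodes "CS off"."""
        return not bool(np.any(self.drive > 0))

    @classmethod
    def off(cls, n_channels: int) -> "StimulusPattern":
        return cls(np.zeros(n_channels), label="off")


@dataclass(frozen=True)
class TeachingSignals:
    """Plasticity gates: US presence (r_plus) and US omission (r_minus).

    Both are multiplicative factors in [0, 1] and are never simultaneously
    positive — the US cannot be both present and unexpectedly absent.
    """

    r_plus: float = 0.0
    r_minus: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.r_plus <= 1.0 and 0.0 <= self.r_minus <= 1.0):
            raise ParameterError("teaching gates must lie in [0, 1]")
        if self.r_plus > 0 and self.r_minus > 0:
            raise ParameterError(
                "r_plus and r_minus may not both be positive")


OFF = TeachingSignals(0.0, 0.0)


@dataclass
class ActivityState:
    """Instantaneous firing-rate activities of every unit."""

    x_ctx: np.ndarray
    x_la: np.ndarray
    x_ba: np.ndarray
    x_itcd: float = 0.0
    x_itcv: float = 0.0
    x_cem: float = 0.0

    @classmethod
    def zeros(cls, n_channels: int) -> "ActivityState":
        return cls(np.zeros(n_channels), np.zeros(n_channels),
                   np.zeros(n_channels))

    def pack(self) -> np.ndarray:
        n = self.x_ctx.shape[0]
        if self.x_la.shape[0] != n or self.x_ba.shape[0] != n:
            raise StructuralError("activity vectors have mismatched lengths")
        out = np.empty(3 * n + 3)
        out[0:n] = self.x_ctx
        out[n:2 * n] = self.x_la
        out[2 * n:3 * n] = self.x_ba
        out[3 * n] = self.x_itcd
        out[3 * n + 1] = self.x_itcv
        out[3 * n + 2] = self.x_cem
        return out

    @classmethod
    def unpack(cls, v: np.ndarray) -> "ActivityState":
        n = (v.shape[0] - 3) // 3
        return cls(v[0:n].copy(), v[n:2 * n].copy(), v[2 * n:3 * n].copy(),
                   float(v[3 * n]), float(v[3 * n + 1]), float(v[3 * n + 2]))

    def max_activity(self) -> float:
        return max(float(self.x_ctx.max(initial=0.0)),
                   float(self.x_la.max(initial=0.0)),
                   float(self.x_ba.max(initial=0.0)),
                   self.x_itcd, self.x_itcv, self.x_cem)


@dataclass
class WeightState:
    """The four plastic weight vectors; all other gains are constants.

    ``w_cl``: CTX->LA, ``w_lb``: LA->BA (slow, savings substrate),
    ``w_ld``: LA->ITCd, ``w_bv``: BA->ITCv (fast, contingency trackers).
    """

    w_cl: np.ndarray
    w_lb: np.ndarray
    w_ld: np.ndarray
    w_bv: np.ndarray

    @classmethod
    def initial(cls, params: CircuitParameters) -> "WeightState":
        n = params.n_channels
        return cls(*(np.full(n, params.w0) for _ in range(4)))

    def copy(self) -> "WeightState":
        return WeightState(self.w_cl.copy(), self.w_lb.copy(),
                           self.w_ld.copy(), self.w_bv.copy())

    def as_tuple(self):
        return (self.w_cl, self.w_lb, self.w_ld, self.w_bv)

    def check_bounds(self, params: CircuitParameters, tol: float = 1e-9):
        for name, w in zip(("w_cl", "w_lb", "w_ld", "w_bv"),
                           self.as_tuple()):
            if np.any(w < -tol) or np.any(w > params.w_max + tol):
                raise NumericalError(f"{name} left [0, w_max]")


def distance_kernel(i: int, j: int, sigma: float) -> float:
    """Gaussian distance falloff exp(-(i-j)^2 / (2 sigma^2)).

    Symmetric in its channel arguments and maximal (1.0) at i == j.
    """
    if sigma <= 0:
        raise ParameterError("sigma must be strictly positive")
    d = float(i) - float(j)
    return math.exp(-(d * d) / (2.0 * sigma * sigma))


def kernel_matrix(n: int, sigma: float) -> np.ndarray:
    """Row-normalized Gaussian kernel matrix over ``n`` channels.

    Each row sums to one so that ``f_E`` and ``f_I`` alone set the total
    recurrent gain; rows near the array edges are renormalized over the
    channels that exist.
    """
    idx = np.arange(n, dtype=float)
    K = np.exp(-((idx[:, None] - idx[None, :]) ** 2) / (2.0 * sigma ** 2))
    return K / K.sum(axis=1, keepdims=True)


def _check_lengths(state: ActivityState, stimulus: StimulusPattern,
                   weights: WeightState, params: CircuitParameters):
    n = params.n_channels
    vectors = (state.x_ctx, state.x_la, state.x_ba, stimulus.drive,
               weights.w_cl, weights.w_lb, weights.w_ld, weights.w_bv)
    if any(v.shape[0] != n for v in vectors):
        raise StructuralError(
            f"state/stimulus/weight vectors must all have length {n}")


def step_circuit(state: ActivityState, stimulus: StimulusPattern,
                 weights: WeightState, teaching: TeachingSignals,
                 params: CircuitParameters) -> ActivityState:
    """Advance every unit one explicit Euler step of the shunting equations.

    The teaching gates do not enter the rate dynamics (they only gate
    plasticity) but are accepted here so dynamics and learning share one
    call signature. Weights are read, never written.
    """
    _check_lengths(state, stimulus, weights, params)
    x = state.pack()
    if not np.all(np.isfinite(x)):
        raise NumericalError("state contains NaN/Inf before stepping")
    out = np.empty_like(x)
    _kernels.step_activities(
        x, stimulus.drive, weights.w_cl, weights.w_lb, weights.w_ld,
        weights.w_bv, kernel_matrix(params.n_channels, params.sigma_E),
        kernel_matrix(params.n_channels, params.sigma_I),
        params.pvec(), out)
    if not np.all(np.isfinite(out)):
        raise NumericalError("integration produced NaN/Inf")
    return ActivityState.unpack(out)


@dataclass
class EquilibrationResult:
    state: ActivityState
    converged: bool
    t: float
    final_delta: float


def equilibrate(stimulus: StimulusPattern, weights: WeightState,
                teaching: TeachingSignals = OFF,
                params: CircuitParameters | None = None,
                tol: float = 1e-9, t_max: float = 200.0,
                ) -> EquilibrationResult:
    """Iterate the dynamics from the zero state to a fixed point.

    Stops when the max absolute per-step state change falls below ``tol``
    or ``t_max`` model-time is exhausted, and reports which condition
    fired via ``converged``. Weights are held fixed throughout.
    """
    if tol <= 0:
        raise ParameterError("tol must be strictly positive")
    params = params or CircuitParameters()
    _check_lengths(ActivityState.zeros(params.n_channels), stimulus,
                   weights, params)
    KE = kernel_matrix(params.n_channels, params.sigma_E)
    KI = kernel_matrix(params.n_channels, params.sigma_I)
    pvec = params.pvec()
    x = np.zeros(3 * params.n_channels + 3)
    out = np.empty_like(x)
    n_steps = int(round(t_max / params.dt))
    t = 0.0
    delta = np.inf
    converged = False
    for k in range(n_steps):
        _kernels.step_activities(
            x, stimulus.drive, weights.w_cl, weights.w_lb, weights.w_ld,
            weights.w_bv, KE, KI, pvec, out)
        delta = float(np.max(np.abs(out - x)))
        x, out = out, x
        t += params.dt
        if not np.all(np.isfinite(x)) or np.max(x) > params.B + 10 * tol:
            raise NumericalError(f"divergence during equilibration at t={t}")
        if delta < tol:
            converged = True
            break
    return EquilibrationResult(ActivityState.unpack(x), converged, t, delta)


def reset_activities(state: ActivityState) -> ActivityState:
    """Return the all-zero activity state (end-of-trial reset).

    Connection weights are not part of the activity state and therefore
    persist across trials untouched.
    """
    n = state.x_ctx.shape[0]
    return ActivityState.zeros(n)
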