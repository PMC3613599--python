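"""Numba-compiled inner loops for the circuit dynamics and plasticity.

These functions operate on bare float64 arrays so they can be jitted; the
public API in :mod:`amygsim.circuit`, :mod:`amygsim.plasticity` and
:mod:`amygsim.runner` wraps them with the dataclass types.

Parameter-vector layout (``pvec``, float64, length ``N_PVEC``)::

    0  A            passive decay rate
    1  B            upper activity bound
    2  D            lower shunting bound offset
    3  f_E          on-center excitatory gain
    4  f_I          off-surround inhibitory gain
    5  E_ILd        tonic IL drive to ITCd
    6  E_ILv        tonic IL drive to ITCv
    7  g_la_itcd    fixed afferent gain on the LA->ITCd weight sum
    8  g_ba_itcv    fixed afferent gain on the BA->ITCv weight sum
    9  g_itcd_itcv  fixed ITCd->ITCv inhibitory gain
    10 g_itcv_cem   fixed ITCv->CeM inhibitory gain
    11 g_ba_cem     fixed BA->CeM excitatory gain
    12 dt           integration step
    13 g_il         fixed IL afferent gain applied to E_ILd and E_ILv

Learning-vector layout (``lvec``, float64, length ``N_LVEC``)::

    0 lambda_slow  1 lambda_fast  2 mu_d  3 mu_v  4 delta_slow
    5 w0           6 w_max

State-vector layout (length ``3 n + 3``): ``[ctx, la, ba, itcd, itcv, cem]``.
"""

import numpy as np
from numba import njit

N_PVEC = 14
N_LVEC = 7


@njit(cache=True)
def step_activities(x, stim, w_cl, w_lb, w_ld, w_bv, KE, KI, pvec, out):
    """One forward-Euler step of the shunting rate equations.

    Reads ``x``, writes the advanced state into ``out``. Both may not alias.
    """
    n = stim.shape[0]
    A = pvec[0]
    B = pvec[1]
    D = pvec[2]
    fE = pvec[3]
    fI = pvec[4]
    dt = pvec[12]

    ctx = x[0:n]
    la = x[n:2 * n]
    ba = x[2 * n:3 * n]
    itcd = x[3 * n]
    itcv = x[3 * n + 1]
    cem = x[3 * n + 2]

    exc_rec = KE @ ctx
    inh_rec = KI @ ctx
    for i in range(n):
        e = stim[i] + fE * exc_rec[i]
        if e < 0.0:
            e = 0.0
        h = fI * inh_rec[i]
        if h < 0.0:
            h = 0.0
        v = ctx[i] + dt * (-A * ctx[i] + (B - ctx[i]) * e
                           - (ctx[i] + D) * h)
        # firing rates are non-negative: the D-offset surround term can
        # drive the net change below zero, which silences the channel
        out[i] = v if v > 0.0 else 0.0

    for i in range(n):
        e = w_cl[i] * ctx[i]
        if e < 0.0:
            e = 0.0
        out[n + i] = la[i] + dt * (-A * la[i] + (B - la[i]) * e)
        e2 = w_lb[i] * la[i]
        if e2 < 0.0:
            e2 = 0.0
        out[2 * n + i] = ba[i] + dt * (-A * ba[i] + (B - ba[i]) * e2)

    drive_d = pvec[13] * pvec[5] + pvec[7] * np.dot(w_ld, la)
    if drive_d < 0.0:
        drive_d = 0.0
    v = itcd + dt * (-A * itcd + (B - itcd) * drive_d)
    out[3 * n] = v if v > 0.0 else 0.0

    drive_v = pvec[13] * pvec[6] + pvec[8] * np.dot(w_bv, ba) - pvec[9] * itcd
    if drive_v < 0.0:
        drive_v = 0.0
    v = itcv + dt * (-A * itcv + (B - itcv) * drive_v)
    out[3 * n + 1] = v if v > 0.0 else 0.0

    mean_ba = 0.0
    for i in range(n):
        mean_ba += ba[i]
    mean_ba /= n
    drive_c = pvec[11] * mean_ba - pvec[10] * itcv
    if drive_c < 0.0:
        drive_c = 0.0
    v = cem + dt * (-A * cem + (B - cem) * drive_c)
    out[3 * n + 2] = v if v > 0.0 else 0.0


@njit(cache=True)
def step_weights(w_cl, w_lb, w_ld, w_bv, x, r_plus, r_minus,
                 lvec, dt, freeze, n):
    """One Euler step of the four plastic weight vectors, in place.

    ``freeze`` is a 4-vector of 0/1 flags ordered (w_cl, w_lb, w_ld, w_bv).
    Uses pre-step activities in ``x``.
    """
    lam_s = lvec[0]
    lam_f = lvec[1]
    mu_d = lvec[2]
    mu_v = lvec[3]
    delta_s = lvec[4]
    w0 = lvec[5]
    w_max = lvec[6]

    ctx = x[0:n]
    la = x[n:2 * n]
    ba = x[2 * n:3 * n]

    for i in range(n):
        if freeze[0] == 0:
            dw = lam_s * r_plus * ctx[i] * (w_max - w_cl[i]) \
                - delta_s * (w_cl[i] - w0)
            w_cl[i] += dt * dw
            if w_cl[i] < 0.0:
                w_cl[i] = 0.0
            elif w_cl[i] > w_max:
                w_cl[i] = w_max
        if freeze[1] == 0:
            dw = lam_s * r_plus * la[i] * (w_max - w_lb[i]) \
                - delta_s * (w_lb[i] - w0)
            w_lb[i] += dt * dw
            if w_lb[i] < 0.0:
                w_lb[i] = 0.0
            elif w_lb[i] > w_max:
                w_lb[i] = w_max
        if freeze[2] == 0:
            # depression floors at w0 so baseline responsiveness survives
            dw = lam_f * la[i] * (r_plus * (w_max - w_ld[i])
                                  - mu_d * (1.0 - r_plus) * (w_ld[i] - w0))
            w_ld[i] += dt * dw
            if w_ld[i] < 0.0:
                w_ld[i] = 0.0
            elif w_ld[i] > w_max:
                w_ld[i] = w_max
        if freeze[3] == 0:
            dw = lam_f * ba[i] * (r_minus * (w_max - w_bv[i])
                                  - mu_v * (1.0 - r_minus) * (w_bv[i] - w0))
            w_bv[i] += dt * dw
            if w_bv[i] < 0.0:
                w_bv[i] = 0.0
            elif w_bv[i] > w_max:
                w_bv[i] = w_max


@njit(cache=True)
def run_trial(x, stim, w_cl, w_lb, w_ld, w_bv, KE, KI, pvec, lvec,
              n_steps, teach_start, r_plus_on, r_minus_on, plastic,
              freeze, trace, stride, record):
    """Integrate one CS-on interval, interleaving dynamics and plasticity.

    Activities advance first; weights are then updated from the pre-step
    activities (synchronous scheme). Returns ``(cr_cem, peak_cem,
    peak_itcd, peak_itcv, ok)`` where ``cr_cem`` is the CeM level at the
    end of the pre-US (conditioned-response) window and ``ok`` is 0 on
    NaN/divergence. ``x`` and the weight vectors are mutated in place;
    ``trace`` (shape ``(ceil(n_steps/stride), len(x))``) is filled when
    ``record`` is true.
    """
    n = stim.shape[0]
    B = pvec[1]
    dt = pvec[12]
    buf = np.empty_like(x)
    cr_c = 0.0
    peak_c = 0.0
    peak_d = 0.0
    peak_v = 0.0
    ok = 1
    row = 0
    for k in range(n_steps):
        if record and k % stride == 0:
            for j in range(x.shape[0]):
                trace[row, j] = x[j]
            row += 1
        if k >= teach_start:
            rp = r_plus_on
            rm = r_minus_on
        else:
            rp = 0.0
            rm = 0.0
        step_activities(x, stim, w_cl, w_lb, w_ld, w_bv, KE, KI, pvec, buf)
        if plastic:
            step_weights(w_cl, w_lb, w_ld, w_bv, x, rp, rm, lvec, dt,
                         freeze, n)
        for j in range(x.shape[0]):
            x[j] = buf[j]
            if not np.isfinite(x[j]) or x[j] > B + 1e-6:
                ok = 0
        if ok == 0:
            break
        # peaks and the CR level are read from the pre-US portion of
        # CS-on only, so the readout is not contaminated by plasticity
        # unfolding within the teaching window itself; cr_cem samples the
        # settled response just before US onset, discarding the initial
        # orienting transient at CS onset
        if k < teach_start:
            if x[3 * n + 2] > peak_c:
                peak_c = x[3 * n + 2]
            if x[3 * n] > peak_d:
                peak_d = x[3 * n]
            if x[3 * n + 1] > peak_v:
                peak_v = x[3 * n + 1]
        if k == teach_start - 1:
            cr_c = x[3 * n + 2]
    return cr_c, peak_c, peak_d, peak_v, ok
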