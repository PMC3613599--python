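"""Unit and property tests for the shunting rate dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amygsim import (ActivityState, CircuitParameters, NumericalError,
                     ParameterError, StimulusPattern, StructuralError,
                     TeachingSignals, WeightState, distance_kernel,
                     equilibrate, kernel_matrix, make_cs_pattern,
                     reset_activities, step_circuit)

OFF = TeachingSignals()


class TestDistanceKernel:
    @pytest.mark.parametrize("i,j,sigma,expected", [
        (5, 5, 2.0, 1.0),                       # zero-distance identity
        (0, 2, 2.0, math.exp(-0.5)),            # direct evaluation
        (3, 7, 1.5, math.exp(-16 / 4.5)),
    ])
    def test_values(self, i, j, sigma, expected):
        assert distance_kernel(i, j, sigma) == pytest.approx(expected,
                                                             abs=1e-12)

    def test_symmetry(self):
        for i in range(6):
            for j in range(6):
                assert distance_kernel(i, j, 2.0) == \
                    distance_kernel(j, i, 2.0)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ParameterError):
            distance_kernel(0, 1, 0.0)

    def test_kernel_matrix_rows_normalized(self):
        K = kernel_matrix(20, 6.0)
        assert np.allclose(K.sum(axis=1), 1.0)
        assert np.all(K >= 0)


class TestParameterValidation:
    def test_defaults_valid(self):
        CircuitParameters()

    @pytest.mark.parametrize("kwargs", [
        {"sigma_I": 0.5},                # must exceed sigma_E
        {"lambda_fast": 0.1},            # must exceed lambda_slow
        {"w0": 2.0},                     # w_max > w0 required
        {"dt": 1.5},                     # stability bound
        {"theta_response": 0.0},
        {"A": -1.0},
        {"t_teach": 50.0},               # window within CS-on
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            CircuitParameters(**kwargs)

    def test_unknown_override_rejected(self):
        with pytest.raises(ParameterError):
            CircuitParameters().with_overrides(nonsense=1.0)


class TestStepCircuit:
    def test_quiescence_fixed_point(self, params):
        p = params.with_overrides(E_ILd=0.0, E_ILv=0.0)
        state = ActivityState.zeros(p.n_channels)
        stim = StimulusPattern.off(p.n_channels)
        w = WeightState.initial(p)
        for _ in range(50):
            state = step_circuit(state, stim, w, OFF, p)
        assert state.max_activity() == 0.0

    def test_mismatched_lengths_rejected(self, params):
        state = ActivityState.zeros(10)
        stim = StimulusPattern.off(params.n_channels)
        with pytest.raises(StructuralError):
            step_circuit(state, stim, WeightState.initial(params), OFF,
                         params)

    def test_nan_state_rejected(self, params):
        state = ActivityState.zeros(params.n_channels)
        state.x_ctx[0] = np.nan
        with pytest.raises(NumericalError):
            step_circuit(state, StimulusPattern.off(params.n_channels),
                         WeightState.initial(params), OFF, params)

    @settings(max_examples=25, deadline=None)
    @given(data=st.data())
    def test_bound_preservation(self, params, data):
        """Non-negative inputs keep every activity inside [0, B]."""
        n = params.n_channels
        drive = data.draw(st.lists(
            st.floats(0.0, 2.0), min_size=n, max_size=n))
        wval = data.draw(st.floats(0.0, params.w_max))
        stim = StimulusPattern(np.array(drive))
        w = WeightState(*(np.full(n, wval) for _ in range(4)))
        state = ActivityState.zeros(n)
        for _ in range(400):
            state = step_circuit(state, stim, w, OFF, params)
        packed = state.pack()
        assert np.all(packed >= 0.0)
        assert np.all(packed <= params.B + 1e-9)


class TestEquilibrate:
    def test_zero_stimulus_converges_immediately(self, params):
        res = equilibrate(StimulusPattern.off(params.n_channels),
                          WeightState.initial(params),
                          params=params.with_overrides(E_ILd=0.0,
                                                       E_ILv=0.0))
        assert res.converged
        assert res.state.max_activity() == 0.0

    def test_single_unit_closed_form(self):
        """Isolated-channel equilibrium matches B*E/(A+E)."""
        p = CircuitParameters(f_E=0.0, f_I=0.0)
        for E in (0.2, 0.7, 1.5):
            drive = np.zeros(p.n_channels)
            drive[0] = E
            res = equilibrate(StimulusPattern(drive),
                              WeightState.initial(p), params=p,
                              tol=1e-12, t_max=100.0)
            assert res.state.x_ctx[0] == pytest.approx(
                p.B * E / (p.A + E), abs=1e-6)

    def test_equilibrium_independent_of_dt(self, params):
        """Step-halving consistency: the fixed point is dt-insensitive.

        The Euler fixed point coincides with the ODE fixed point, so the
        two equilibria differ only through the stopping rule: a per-step
        change below tol leaves the state within ~tol/(dt*A) of the true
        fixed point.
        """
        tol = 1e-9
        cs = make_cs_pattern(500.0, 1500.0)
        w = WeightState.initial(params)
        a = equilibrate(cs, w, params=params, tol=tol).state.pack()
        fine = params.with_overrides(dt=params.dt / 2)
        b = equilibrate(cs, w, params=fine, tol=tol).state.pack()
        assert np.abs(a - b).max() < 3 * tol / (params.dt * params.A)

    def test_invalid_tol_rejected(self, params):
        with pytest.raises(ParameterError):
            equilibrate(StimulusPattern.off(params.n_channels),
                        WeightState.initial(params), params=params,
                        tol=0.0)


class TestContrast:
    def test_contrast_monotone_in_inhibition(self, params):
        """Stronger off-surround sharpens the peak/flank ratio."""
        cs = make_cs_pattern(500.0, 1500.0)
        contrasts = []
        for f_I in (0.3, 1.0, 3.0):
            p = params.with_overrides(f_I=f_I)
            st_ = equilibrate(cs, WeightState.initial(p), params=p,
                              tol=1e-10).state
            flank = float(np.delete(st_.x_ctx, cs.support).max())
            contrasts.append(float(st_.x_ctx[cs.support].max())
                             / max(flank, 1e-12))
        assert contrasts[0] <= contrasts[1] <= contrasts[2]

    def test_weak_inhibition_spreads_activity(self, params):
        """Flank channels stay active at f_I=0.3 but not at f_I=3.0."""
        cs = make_cs_pattern(500.0, 1500.0)
        flanks = {}
        for f_I in (0.3, 3.0):
            p = params.with_overrides(f_I=f_I)
            st_ = equilibrate(cs, WeightState.initial(p), params=p,
                              tol=1e-10).state
            flanks[f_I] = float(np.delete(st_.x_ctx, cs.support).max())
        assert flanks[0.3] > 0.01
        assert flanks[3.0] < flanks[0.3] / 2


class TestDisinhibition:
    def test_itcd_suppresses_itcv_and_releases_cem(self, params):
        """More ITCd drive -> less ITCv -> more CeM (disinhibition chain)."""
        n = params.n_channels
        w = WeightState(*(np.full(n, 0.9) for _ in range(4)))
        cs = make_cs_pattern(500.0, 1500.0)
        itcv, cem = [], []
        for e_ild in (0.0, 2.0, 4.0):
            p = params.with_overrides(E_ILd=e_ild)
            st_ = equilibrate(cs, w, params=p, tol=1e-10).state
            itcv.append(st_.x_itcv)
            cem.append(st_.x_cem)
        assert itcv[0] >= itcv[1] >= itcv[2]
        assert cem[0] <= cem[1] <= cem[2]


class TestReset:
    def test_reset_zeroes_activities_and_is_idempotent(self, params):
        state = ActivityState(np.random.default_rng(0).random(20),
                              np.zeros(20), np.zeros(20), 0.3, 0.2, 0.1)
        r1 = reset_activities(state)
        assert r1.max_activity() == 0.0
        r2 = reset_activities(r1)
        assert np.array_equal(r1.pack(), r2.pack())

    def test_weights_survive_reset(self, params):
        w = WeightState.initial(params)
        before = w.w_ld.copy()
        reset_activities(ActivityState.zeros(params.n_channels))
        assert np.array_equal(w.w_ld, before)
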