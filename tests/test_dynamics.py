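"""Unit and property tests for the dynamical primitives."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stresswm.dynamics import (
    CurrentComponents,
    DendriteNonlinearity,
    NeuronParams,
    NeuronState,
    SimulationError,
    SpineCounts,
    StressScaling,
    SynapseParams,
    SynapseState,
    ampa_current_ext,
    ampa_current_rec,
    dendrite_to_soma,
    effective_synapse_counts,
    gaba_current,
    membrane_step,
    nmda_current,
    stp_step,
    total_current,
)

V_REST = -70.0


# ---------------------------------------------------------------------------
# spine counts -> effective synapse counts
# ---------------------------------------------------------------------------

class TestEffectiveSynapseCounts:
    def test_hand_evaluated_control_case(self):
        mu = effective_synapse_counts(SpineCounts(EXN=100, EXN_IN=0.2, fac=0.0))
        assert mu.mu_e_NMDA == pytest.approx(40.0)
        assert mu.mu_e_AMPA == pytest.approx(40.0)
        assert mu.mu_e_GABA == pytest.approx(20.0)

    def test_interneuron_entries_halved_form(self):
        mu = effective_synapse_counts(
            SpineCounts(BP=40, MP=60, BP_IN=0.35, MP_IN=0.25))
        expected = 40 * 0.65 * 0.5 + 60 * 0.75 * 0.5
        assert mu.mu_i_NMDA == mu.mu_i_AMPA == mu.mu_i_GABA == pytest.approx(expected)

    @given(fac=st.floats(0.0, 1.0), exn=st.floats(0.0, 1000.0),
           exn_in=st.floats(0.0, 1.0))
    def test_spine_loss_scales_every_excitatory_entry(self, fac, exn, exn_in):
        base = effective_synapse_counts(SpineCounts(EXN=exn, EXN_IN=exn_in, fac=0.0))
        lost = effective_synapse_counts(SpineCounts(EXN=exn, EXN_IN=exn_in, fac=fac))
        for name in ("mu_e_NMDA", "mu_e_AMPA", "mu_e_GABA"):
            assert getattr(lost, name) == pytest.approx(
                (1 - fac) * getattr(base, name), abs=1e-12)
        for name in ("mu_i_NMDA", "mu_i_AMPA", "mu_i_GABA"):
            assert getattr(lost, name) == getattr(base, name)

    def test_chronic_sixteen_percent_reduction(self):
        base = effective_synapse_counts(SpineCounts())
        chronic = effective_synapse_counts(dataclasses.replace(SpineCounts(), fac=0.16))
        assert chronic.mu_e_NMDA / base.mu_e_NMDA == pytest.approx(0.84)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            SpineCounts(EXN=-1.0)
        with pytest.raises(ValueError):
            SpineCounts(EXN_IN=1.5)


# ---------------------------------------------------------------------------
# short-term plasticity
# ---------------------------------------------------------------------------

def _integrate_stp(state, p, dt, n_steps, spike_steps=()):
    out = [state]
    for k in range(n_steps):
        state = stp_step(state, k in spike_steps, p, dt)
        out.append(state)
    return out


class TestShortTermPlasticity:
    def test_no_spike_relaxation_matches_closed_form(self):
        """u, x and the gatings relax exponentially to (U, 1, 0)."""
        p = SynapseParams()
        s0 = SynapseState(s_AMPA=0.5, s_NMDA=0.8, s_GABA=0.3, u=0.6, x=0.3)
        dt, T = 0.5, 60.0
        n = int(T / dt)
        final = _integrate_stp(s0, p, dt, n)[-1]
        assert final.s_AMPA == pytest.approx(0.5 * math.exp(-T / p.tau_AMPA), rel=1e-6)
        assert final.s_NMDA == pytest.approx(0.8 * math.exp(-T / p.tau_NMDA), rel=1e-6)
        assert final.s_GABA == pytest.approx(0.3 * math.exp(-T / p.tau_GABA), rel=1e-6)
        assert final.u == pytest.approx(0.15 + 0.45 * math.exp(-T / p.tau_u), rel=1e-6)
        assert final.x == pytest.approx(1.0 - 0.7 * math.exp(-T / p.tau_x), rel=1e-6)

    def test_u_converges_to_baseline_utilization(self):
        p = SynapseParams()
        final = _integrate_stp(SynapseState(u=0.6), p, 5.0, 4000)[-1]  # 20 s
        assert final.u == pytest.approx(0.15, abs=1e-6)

    def test_x_recovers_with_its_time_constant(self):
        p = SynapseParams()
        # after one time constant, (1 - x) should have shrunk by 1/e
        state = SynapseState(x=0.3)
        final = _integrate_stp(state, p, 0.01, 200)[-1]  # 2 ms = tau_x
        assert 1 - final.x == pytest.approx(0.7 / math.e, rel=1e-4)

    def test_single_spike_utilization_jump(self):
        p = SynapseParams()
        dt = 1e-9  # negligible decay so the jump dominates
        after = stp_step(SynapseState(u=0.15, x=1.0), True, p, dt)
        assert after.u == pytest.approx(0.15 + 0.15 * 0.85, rel=1e-9)
        # x decremented with the post-jump u; s gets x*u_post worth of gating
        assert after.x == pytest.approx(1.0 - after.u * 1.0, rel=1e-9)
        assert after.s_AMPA == pytest.approx(1.0 * after.u * p.gamma_AMPA, rel=1e-9)

    def test_inhibitory_spike_touches_only_gaba(self):
        p = SynapseParams(gamma_I=0.7)
        before = SynapseState(u=0.4, x=0.9)
        after = stp_step(before, True, p, 1e-9, is_inhibitory=True)
        assert after.s_GABA == pytest.approx(0.7, rel=1e-9)
        assert after.u == pytest.approx(0.4, rel=1e-6)
        assert after.x == pytest.approx(0.9, rel=1e-6)
        assert after.s_AMPA == 0.0

    @settings(max_examples=50, deadline=None)
    @given(train=st.lists(st.booleans(), min_size=1, max_size=300),
           gamma=st.floats(0.1, 1.0))
    def test_nmda_gating_never_exceeds_one(self, train, gamma):
        """The (1 - s) factor keeps s_NMDA in [0, 1] for any spike train."""
        p = SynapseParams(gamma_NMDA=gamma)
        state = SynapseState()
        for spiked in train:
            state = stp_step(state, spiked, p, 0.5)
            assert 0.0 <= state.s_NMDA <= 1.0
            assert 0.15 <= state.u <= 1.0 + 1e-12
            assert 0.0 <= state.x <= 1.0 + 1e-12

    def test_vectorized_matches_scalar(self, rng):
        p = SynapseParams()
        n = 7
        state_v = SynapseState(s_AMPA=np.zeros(n), s_NMDA=np.zeros(n),
                               s_GABA=np.zeros(n), u=np.full(n, 0.15),
                               x=np.ones(n))
        states_s = [SynapseState() for _ in range(n)]
        is_inh = np.array([False] * 4 + [True] * 3)
        for _ in range(40):
            spikes = rng.random(n) < 0.3
            state_v = stp_step(state_v, spikes, p, 0.5, is_inh)
            states_s = [stp_step(s, bool(spikes[i]), p, 0.5, bool(is_inh[i]))
                        for i, s in enumerate(states_s)]
        for i, s in enumerate(states_s):
            for name in ("s_AMPA", "s_NMDA", "s_GABA", "u", "x"):
                assert getattr(state_v, name)[i] == pytest.approx(
                    getattr(s, name), rel=1e-12)


# ---------------------------------------------------------------------------
# synaptic currents
# ---------------------------------------------------------------------------

class TestCurrents:
    p = SynapseParams(g_AMPA_ext=2.0, g_AMPA_rec=0.5, g_NMDA_rec=0.3, g_GABA=0.8)

    def test_all_currents_vanish_at_rest(self, rng):
        s = rng.random(5)
        w = rng.random(5)
        u = rng.random(5)
        assert nmda_current(V_REST, s, w, u, 40.0, self.p) == 0.0
        assert ampa_current_ext(V_REST, s, self.p) == 0.0
        assert ampa_current_rec(V_REST, s, w, u, 40.0, self.p) == 0.0
        assert gaba_current(V_REST, s, 20.0, self.p) == 0.0

    def test_zero_gating_gives_zero_current(self):
        z = np.zeros(4)
        w = np.ones(4)
        assert nmda_current(-55.0, z, w, np.ones(4), 40.0, self.p) == 0.0
        assert gaba_current(-55.0, z, 20.0, self.p) == 0.0

    def test_nmda_hand_evaluated_single_synapse(self):
        V, w, s, u, mu = -55.0, 1.3, 0.4, 0.8, 10.0
        got = nmda_current(V, np.array([s]), np.array([w]), np.array([u]),
                           mu, self.p)
        block = 1.0 / (1.0 + 0.2801 * math.exp(-0.062 * V))
        expected = mu * 0.3 * (V - V_REST) * block * (w * s * u)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_recurrent_currents_hand_evaluated_two_synapses(self):
        V = -58.0
        s = np.array([0.2, 0.7])
        w = np.array([1.5, 0.5])
        u = np.array([0.3, 0.9])
        got_a = ampa_current_rec(V, s, w, u, 12.0, self.p)
        assert got_a == pytest.approx(
            12.0 * 0.5 * (V - V_REST) * (w * s * u).sum(), rel=1e-12)
        got_g = gaba_current(V, s, 20.0, self.p)
        assert got_g == pytest.approx(20.0 * 0.8 * (V - V_REST) * s.sum(), rel=1e-12)
        got_e = ampa_current_ext(V, s, self.p)
        assert got_e == pytest.approx(2.0 * (V - V_REST) * s.sum(), rel=1e-12)

    @pytest.mark.parametrize("factor", [0.5, 2.0, 3.7])
    def test_linearity_in_gating(self, factor, rng):
        s = rng.random(6)
        w = rng.random(6)
        u = rng.random(6)
        for fn in (
            lambda ss: nmda_current(-55.0, ss, w, u, 40.0, self.p),
            lambda ss: ampa_current_rec(-55.0, ss, w, u, 40.0, self.p),
            lambda ss: gaba_current(-55.0, ss, 20.0, self.p),
            lambda ss: ampa_current_ext(-55.0, ss, self.p),
        ):
            assert fn(factor * s) == pytest.approx(factor * fn(s), rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nmda_current(-55.0, np.ones(3), np.ones(4), np.ones(3), 1.0, self.p)
        with pytest.raises(ValueError):
            ampa_current_rec(-55.0, np.ones(3), np.ones(3), np.ones(2), 1.0, self.p)

    def test_matrix_weights_match_per_neuron_loop(self, rng):
        """The vectorized (post x pre) form equals row-by-row evaluation."""
        W = rng.random((4, 6)) * (rng.random((4, 6)) < 0.6)
        s, u = rng.random(6), rng.random(6)
        V = np.full(4, -56.0)
        mu = np.array([40.0, 40.0, 35.5, 35.5])
        vec = nmda_current(V, s, W, u, mu, self.p)
        for i in range(4):
            row = nmda_current(-56.0, s, W[i], u, mu[i], self.p)
            assert vec[i] == pytest.approx(row, rel=1e-12)


class TestDendriteTransfer:
    nl = DendriteNonlinearity(c1=60.0, c2=5.0, c3=-0.5, c4=-40.0, c5=250.0, c6=500.0)

    def test_output_bounded_by_gain(self, rng):
        exc = rng.uniform(-1e4, 1e4, 100)
        inh = rng.uniform(0, 1e3, 100)
        out = dendrite_to_soma(exc, inh, self.nl)
        assert np.all(out >= self.nl.c2 - abs(self.nl.c1) - 1e-9)
        assert np.all(out <= self.nl.c2 + abs(self.nl.c1) + 1e-9)

    def test_saturation_limit(self):
        assert dendrite_to_soma(1e9, 100.0, self.nl) == pytest.approx(
            self.nl.c1 + self.nl.c2)

    def test_hand_evaluated_point(self):
        exc, inh = 300.0, 80.0
        arg = (exc + self.nl.c3 * inh + self.nl.c4) / (
            self.nl.c5 * math.exp(-inh / self.nl.c6))
        expected = self.nl.c1 * math.tanh(arg) + self.nl.c2
        assert dendrite_to_soma(exc, inh, self.nl) == pytest.approx(expected, rel=1e-12)

    def test_invalid_shape_constants_rejected(self):
        with pytest.raises(ValueError):
            DendriteNonlinearity(c5=0.0)


class TestTotalCurrent:
    def test_zero_components_sum_to_zero(self):
        assert total_current(CurrentComponents()) == 0.0

    def test_control_scaling_is_plain_sum(self):
        c = CurrentComponents(nmda_rec=10.0, ampa_ext=5.0, ampa_rec=3.0,
                              gaba=-4.0, soma_dend=2.0, background=1.0)
        assert total_current(c, StressScaling()) == pytest.approx(17.0)

    def test_swim_stress_betas_scale_glutamate_terms_exactly(self):
        beta_n, beta_a = 425.0 / 197.0, 98.8 / 58.6
        c = CurrentComponents(nmda_rec=10.0, ampa_rec=4.0)
        scaled = total_current(c, StressScaling(beta_NMDA=beta_n, beta_AMPA=beta_a))
        assert scaled == pytest.approx(10.0 * beta_n + 4.0 * beta_a, rel=1e-12)


# ---------------------------------------------------------------------------
# membrane
# ---------------------------------------------------------------------------

class TestMembrane:
    p = NeuronParams()

    def test_rest_is_a_fixed_point(self):
        s = membrane_step(NeuronState(V_soma=-70.0), 0.0, self.p, 0.05)
        assert s.V_soma == -70.0
        assert not s.spiked

    @pytest.mark.parametrize("dt", [0.2, 0.1, 0.05, 0.025])
    def test_relaxation_matches_analytic_exponential(self, dt):
        tau = self.p.C_m / self.p.g_L  # 20 ms
        state = NeuronState(V_soma=-60.0)
        T = 10.0
        t = 0.0
        while t < T - 1e-9:
            state = membrane_step(state, 0.0, self.p, dt, t)
            t += dt
        exact = -70.0 + 10.0 * math.exp(-T / tau)
        assert state.V_soma == pytest.approx(exact, abs=0.05)

    def test_euler_error_is_first_order_in_dt(self):
        tau = self.p.C_m / self.p.g_L
        errs = []
        for dt in (0.4, 0.2, 0.1, 0.05):
            state = NeuronState(V_soma=-60.0)
            t = 0.0
            while t < 10.0 - 1e-9:
                state = membrane_step(state, 0.0, self.p, dt, t)
                t += dt
            errs.append(abs(state.V_soma - (-70.0 + 10.0 * math.exp(-10.0 / tau))))
        ratios = [errs[i] / errs[i + 1] for i in range(3)]
        assert all(1.6 < r < 2.4 for r in ratios)  # halving dt halves the error

    def test_subrheobase_drive_never_spikes(self):
        # rheobase = g_L (V_th - V_L) = 200 pA
        state = NeuronState(V_soma=-70.0)
        t = 0.0
        for _ in range(20000):
            state = membrane_step(state, 195.0, self.p, 0.05, t)
            t += 0.05
            assert not state.spiked
        assert state.V_soma < -50.0

    def test_spike_resets_and_respects_refractoriness(self):
        state = NeuronState(V_soma=-50.5)
        state = membrane_step(state, 5000.0, self.p, 0.05, 0.0)
        assert state.spiked and state.V_soma == self.p.V_reset
        # clamped at reset during the refractory period, even with huge drive
        s2 = membrane_step(state, 1e6, self.p, 0.05, 0.05)
        assert not s2.spiked and s2.V_soma == self.p.V_reset

    def test_suprathreshold_isi_matches_lif_closed_form(self):
        I = 400.0  # pA, twice rheobase
        dt = 0.005
        state = NeuronState(V_soma=-60.0, refractory_until=-np.inf)
        spikes = []
        t = 0.0
        for _ in range(int(200 / dt)):
            state = membrane_step(state, I, self.p, dt, t)
            t += dt
            if state.spiked:
                spikes.append(t)
        isi = np.diff(spikes)
        tau = self.p.C_m / self.p.g_L
        V_inf = -70.0 + I / self.p.g_L
        expected = self.p.t_ref + tau * math.log(
            (V_inf - self.p.V_reset) / (V_inf - self.p.V_th))
        assert np.mean(isi) == pytest.approx(expected, rel=0.02)

    def test_non_finite_drive_raises_with_context(self):
        with pytest.raises(SimulationError, match="non-finite"):
            membrane_step(NeuronState(V_soma=-60.0), np.nan, self.p, 0.05, 3.0)

    def test_invariants_rejected(self):
        with pytest.raises(ValueError):
            NeuronParams(C_m=0.0)
        with pytest.raises(ValueError):
            NeuronParams(V_reset=-40.0, V_th=-50.0)
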