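"""Unit and property tests of the state, regulation and derivative layer."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from kaiclock import (FeedbackSpec, HTD_HU, activation_factor, free_kaia,
                      full_derivatives, pto_derivatives, regulator_concentration,
                      repression_factor, ttfl_derivatives)
from kaiclock.model import (CH, CB, CP, I_A, I_MA, I_MBC, N_STATE,
                            PerturbationOverrides, make_rhs)
from kaiclock.params import PHOSPHO_STATES


def state_with(ch=(0, 0, 0, 0), cb=(0, 0, 0, 0), cp=(0, 0, 0, 0),
               mA=0.0, mBC=0.0, A=0.0):
    y = np.zeros(N_STATE)
    y[CH], y[CB], y[CP] = ch, cb, cp
    y[I_MA], y[I_MBC], y[I_A] = mA, mBC, A
    return y


def random_state(rng, scale=3.0):
    return rng.uniform(0.0, scale, N_STATE)


# ---------------------------------------------------------------------------
# free KaiA
# ---------------------------------------------------------------------------

class TestFreeKaiA:
    def test_no_kaia_gives_zero(self, pto):
        assert free_kaia(state_with(ch=(1, 1, 1, 1)), pto) == 0.0

    def test_no_binding_partners_gives_half_total(self, pto):
        a = free_kaia(state_with(A=1.8), pto)
        assert a == pytest.approx(0.9)

    def test_result_bounded_by_dimer_total(self, pto, rng):
        for _ in range(50):
            y = random_state(rng)
            assert 0.0 <= free_kaia(y, pto) <= y[I_A] / 2 + 1e-12

    def test_agrees_with_bisection_oracle(self, pto, rng):
        """1000 random draws against naive interval bisection on the
        scalar mass balance."""
        for _ in range(1000):
            y = random_state(rng)
            Kd = rng.uniform(0.01, 5.0)
            Ks = rng.uniform(1e-4, 1.0)
            p = replace(pto, K_dim=Kd, K_seq=Ks)
            H, S_B, at2 = y[CH].sum() / 6, y[CB][3], y[I_A] / 2

            def g(a):
                return a + H * a / (Kd + a) + S_B * a / (Ks + a) - at2

            lo, hi = 0.0, at2
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if g(mid) > 0:
                    hi = mid
                else:
                    lo = mid
            assert free_kaia(y, p) == pytest.approx(0.5 * (lo + hi), abs=1e-9)

    def test_negative_input_rejected(self, pto):
        y = state_with(A=1.0)
        y[0] = -0.1
        with pytest.raises(ValueError):
            free_kaia(y, pto)


# ---------------------------------------------------------------------------
# Regulation factors
# ---------------------------------------------------------------------------

class TestRegulationFactors:
    def test_activation_limits_and_midpoint(self):
        assert activation_factor(0.0, 0.8, 6.0) == 1.0
        assert activation_factor(1e9, 0.8, 6.0) == pytest.approx(6.0, rel=1e-6)
        assert activation_factor(0.8, 0.8, 6.0) == pytest.approx(3.5)

    def test_repression_limits_and_midpoint(self):
        assert repression_factor(0.0, 0.5, 0.1) == 1.0
        assert repression_factor(1e9, 0.5, 0.1) == pytest.approx(0.1, rel=1e-6)
        assert repression_factor(0.5, 0.5, 0.1) == pytest.approx(0.55)

    def test_neutral_repressor_is_identity(self):
        y = np.linspace(0, 50, 101)
        assert np.allclose(repression_factor(y, 1.0, 1.0), 1.0)

    @given(st.floats(0.01, 100), st.floats(1.1, 50))
    @settings(deadline=None, max_examples=50)
    def test_activation_bounded_and_monotone(self, K, lam):
        x = np.linspace(0, 1000, 501)
        f = activation_factor(x, K, lam)
        assert np.all((1 - 1e-12 <= f) & (f <= lam + 1e-12))
        assert np.all(np.diff(f) >= -1e-12)

    @given(st.floats(0.01, 100), st.floats(0.001, 1.0))
    @settings(deadline=None, max_examples=50)
    def test_repression_bounded_and_monotone(self, K, lam):
        y = np.linspace(0, 1000, 501)
        f = repression_factor(y, K, lam)
        assert np.all((lam - 1e-12 <= f) & (f <= 1 + 1e-12))
        assert np.all(np.diff(f) <= 1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            activation_factor(-1.0, 1.0, 2.0)
        with pytest.raises(ValueError):
            repression_factor(-1.0, 1.0, 0.5)


# ---------------------------------------------------------------------------
# Regulator selection and feedback specs
# ---------------------------------------------------------------------------

class TestFeedbackSpec:
    def test_regulator_concentrations_by_definition(self):
        y = state_with(ch=(1, 2, 3, 4), cb=(1, 2, 3, 4))
        assert regulator_concentration(y, HTD_HU, "activator") == 5.0
        assert regulator_concentration(y, HTD_HU, "repressor") == 1.0
        b_p = FeedbackSpec.from_name("HU+_BP-")
        assert regulator_concentration(y, b_p, "repressor") == 9.0

    def test_invalid_role_rejected(self):
        with pytest.raises(ValueError):
            regulator_concentration(state_with(), HTD_HU, "cofactor")

    @pytest.mark.parametrize("name", ["HTD+_HU-", "HP+_HU-", "HU+_BP-",
                                      "HD+_BT-", "HTD+_BSU-"])
    def test_name_round_trip(self, name):
        assert FeedbackSpec.from_name(name).name == name

    @pytest.mark.parametrize("bad", [
        dict(activator_states=frozenset({"U", "T"}), repressor_pool="hexamer",
             repressor_states=frozenset({"U"})),   # UT activator not allowed
        dict(activator_states=frozenset({"T"}), repressor_pool="hexamer",
             repressor_states=frozenset({"S", "U"})),  # SU only in complex
        dict(activator_states=frozenset({"T"}), repressor_pool="membrane",
             repressor_states=frozenset({"U"})),
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            FeedbackSpec(**bad)


# ---------------------------------------------------------------------------
# Derivatives
# ---------------------------------------------------------------------------

def _oracle_pto(y, p):
    """Independent loop-based scalar transcription of the KaiC dynamics,
    written against the model description rather than the implementation."""
    ch = {s: y[i] for i, s in enumerate(PHOSPHO_STATES)}
    cb = {s: y[4 + i] for i, s in enumerate(PHOSPHO_STATES)}
    cp = {s: y[8 + i] for i, s in enumerate(PHOSPHO_STATES)}
    d_ch = dict.fromkeys(PHOSPHO_STATES, 0.0)
    d_cb = dict.fromkeys(PHOSPHO_STATES, 0.0)
    d_cp = dict.fromkeys(PHOSPHO_STATES, 0.0)

    a = free_kaia(y, p)
    sat = a / (p.K_half + a) if a > 0 else 0.0
    cycle = list(PHOSPHO_STATES) + ["U"]
    for i in range(4):
        src, dst = cycle[i], cycle[i + 1]
        fh = (p.tH_basal[i] + p.tH_kaiA[i] * sat) * ch[src]
        d_ch[src] -= fh
        d_ch[dst] += fh
        fb = p.tB_basal[i] * cb[src]
        d_cb[src] -= fb
        d_cb[dst] += fb
    for i, s in enumerate(PHOSPHO_STATES):
        b = p.beta_plus * p.kaiB_gate[i] * ch[s]
        u = p.beta_minus * cb[s]
        d_ch[s] += u - b
        d_cb[s] += b - u
    cp_tot = sum(cp.values())
    if cp_tot > 0:
        for rate, x in ((p.c_U, "U"), (p.c_D, "D"), (p.c_S, "S")):
            for other in PHOSPHO_STATES:
                if other == x:
                    continue
                flux = rate * (cp[x] / cp_tot) * ch[other]
                d_ch[other] -= flux
                d_ch[x] += flux
                d_cp[x] -= flux
                d_cp[other] += flux
        sat5 = (cp_tot / (p.K_P + cp_tot)) ** 5
        for s in PHOSPHO_STATES:
            asm = p.k_hex * cp[s] * sat5
            d_cp[s] -= asm
            d_ch[s] += asm
    for s in PHOSPHO_STATES:
        d_cp[s] += p.k_dis * (ch[s] + cb[s])
        d_ch[s] -= p.k_dis * ch[s]
        d_cb[s] -= p.k_dis * cb[s]
    d_cp["U"] += p.k_2bc * y[I_MBC]
    for s in PHOSPHO_STATES:
        d_ch[s] -= p.k_4bc * ch[s]
        d_cb[s] -= p.k_4bc * cb[s]
        d_cp[s] -= p.k_4bc * cp[s]
    out = np.zeros(N_STATE)
    for i, s in enumerate(PHOSPHO_STATES):
        out[i], out[4 + i], out[8 + i] = d_ch[s], d_cb[s], d_cp[s]
    return out


class TestPtoDerivatives:
    def test_empty_system_is_static(self, pto):
        assert np.all(pto_derivatives(state_with(), pto) == 0.0)

    def test_mass_conservation_without_turnover(self, pto, rng):
        p = replace(pto, k_2bc=0.0, k_4bc=0.0)
        for _ in range(20):
            y = random_state(rng)
            dy = pto_derivatives(y, p)
            assert abs(dy[0:12].sum()) < 1e-12

    def test_exchange_and_kaib_terms_conserve_each_pool(self, pto, rng):
        """Monomer exchange keeps each pool total fixed; KaiB binding and
        dissociation only move mass between hexamer and complex pools."""
        p = replace(pto, k_2bc=0.0, k_4bc=0.0)
        y = random_state(rng)
        dy = pto_derivatives(y, p)
        # switching off everything except exchange: compare against params
        # with KaiB/assembly/decomposition disabled numerically
        p_exch = replace(p, beta_plus=1e-12, beta_minus=1e-12, k_hex=1e-12,
                         k_dis=1e-12, tH_basal=(0,)*4, tH_kaiA=(0,)*4,
                         tB_basal=(0,)*4)
        d_exch = pto_derivatives(y, p_exch)
        assert abs(d_exch[CH].sum()) < 1e-9
        assert abs(d_exch[CP].sum()) < 1e-9
        assert np.allclose(d_exch[CB], 0.0, atol=1e-9)
        # KaiB binding/dissociation alone conserves hexamer+complex mass
        p_b = replace(p_exch, beta_plus=pto.beta_plus, beta_minus=pto.beta_minus,
                      c_U=1e-12, c_S=1e-12, c_D=1e-12)
        d_b = pto_derivatives(y, p_b)
        assert abs(d_b[CH].sum() + d_b[CB].sum()) < 1e-9
        assert abs(dy[0:12].sum()) < 1e-12

    def test_matches_independent_loop_oracle(self, pto, ttfl, rng):
        for _ in range(50):
            y = random_state(rng)
            ref = _oracle_pto(y, pto)
            got = pto_derivatives(y, pto)
            assert np.allclose(got, ref, rtol=1e-8, atol=1e-12)

    def test_fast_rhs_matches_reference(self, pto, ttfl, rng):
        rhs = make_rhs(pto, ttfl, HTD_HU)
        for _ in range(50):
            y = random_state(rng)
            ref = full_derivatives(y, pto, ttfl, HTD_HU)
            assert np.allclose(rhs(0.0, y), ref, rtol=1e-9, atol=1e-12)


class TestTtflDerivatives:
    def test_mrna_fixed_point(self, pto, ttfl):
        y = state_with(mA=ttfl.k_1a / ttfl.k_3, A=1.0)
        dy = ttfl_derivatives(y, ttfl, HTD_HU, pto)
        assert dy[I_MA] == pytest.approx(0.0, abs=1e-14)

    def test_unregulated_basal_rate(self, pto, ttfl):
        dy = ttfl_derivatives(state_with(), ttfl, HTD_HU, pto)
        assert dy[I_MBC] == pytest.approx(ttfl.k_1bc)

    def test_matches_direct_formula(self, pto, ttfl, rng):
        for _ in range(30):
            y = random_state(rng)
            dy = ttfl_derivatives(y, ttfl, HTD_HU, pto)
            x = y[1] + y[2]
            rep = y[0]
            expected_mbc = (ttfl.k_1bc
                            * (1 + ttfl.lam_act * x / ttfl.K_act) / (1 + x / ttfl.K_act)
                            * (1 + ttfl.lam_rep * rep / ttfl.K_rep) / (1 + rep / ttfl.K_rep)
                            - ttfl.k_3 * y[I_MBC])
            assert dy[I_MBC] == pytest.approx(expected_mbc, rel=1e-12)
            assert dy[I_MA] == pytest.approx(ttfl.k_1a - ttfl.k_3 * y[I_MA], rel=1e-12)
            assert dy[I_A] == pytest.approx(ttfl.k_2 * y[I_MA] - ttfl.k_4 * y[I_A], rel=1e-12)


class TestFullDerivatives:
    def test_identity_overrides_sum_parts(self, pto, ttfl, rng):
        y = random_state(rng)
        total = full_derivatives(y, pto, ttfl, HTD_HU)
        assert np.allclose(total, pto_derivatives(y, pto)
                           + ttfl_derivatives(y, ttfl, HTD_HU, pto))

    def test_knockout_override_makes_mrna_pure_decay(self, pto, ttfl, rng):
        y = random_state(rng)
        dy = full_derivatives(y, pto, ttfl, HTD_HU,
                              PerturbationOverrides(scale_k_1a=0.0))
        assert dy[I_MA] == pytest.approx(-ttfl.k_3 * y[I_MA], rel=1e-12)

    def test_zero_components_never_pushed_negative(self, pto, ttfl, rng):
        for _ in range(50):
            y = random_state(rng)
            zeros = rng.integers(0, N_STATE, size=4)
            y[zeros] = 0.0
            dy = full_derivatives(y, pto, ttfl, HTD_HU)
            assert np.all(dy[zeros] >= -1e-12)
            assert np.all(np.isfinite(dy))
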