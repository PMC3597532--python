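"""State layout and right-hand sides of the 15-ODE clock model.

State vector layout (monomer-equivalent concentrations, a.u.):

====  =======================================================
slot  variable
====  =======================================================
0-3   CH — free KaiC hexamer pool, phospho-states (U, T, D, S)
4-7   CB — KaiB-bound complex pool, phospho-states (U, T, D, S)
8-11  CP — free monomer pool, phospho-states (U, T, D, S)
12    mA — kaiA mRNA
13    mBC — kaiBC mRNA
14    A — total KaiA protein (monomer equivalents)
====  =======================================================

The phosphorylation cycle is strictly cyclic, U -> T -> D -> S -> U, in
the hexamer and complex pools; the KaiA-dependent increments to the
hexamer-pool phosphorylation steps scale with the saturation of hexamers
by free KaiA dimers.  Free KaiA is an algebraic quantity: total KaiA is
partitioned at quasi-equilibrium between free dimers, dimers bound to
hexamers (A2C6 complexes) and dimers sequestered by serine-state KaiC in
KaiB-bound complexes.  Sequestration of KaiA by S-state complexes is what
switches the system into its dephosphorylation phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import FeedbackSpec, PTOParameters, TTFLParameters

N_STATE = 15
CH = slice(0, 4)
CB = slice(4, 8)
CP = slice(8, 12)
I_MA, I_MBC, I_A = 12, 13, 14

#: Channel names of the full state vector, in slot order.
STATE_NAMES = (
    "CH_U", "CH_T", "CH_D", "CH_S",
    "CB_U", "CB_T", "CB_D", "CB_S",
    "CP_U", "CP_T", "CP_D", "CP_S",
    "mA", "mBC", "A",
)


@dataclass(frozen=True)
class PerturbationOverrides:
    """Multiplicative rescaling of the perturbable rates.

    ``scale_k_1a`` rescales kaiA transcription (0 = knockout, >1 =
    overexpression); ``scale_k_2bc`` rescales KaiC translation.
    """

    scale_k_1a: float = 1.0
    scale_k_2bc: float = 1.0

    def __post_init__(self):
        if self.scale_k_1a < 0 or self.scale_k_2bc < 0:
            raise ValueError("override scale factors must be non-negative")


IDENTITY_OVERRIDES = PerturbationOverrides()


def default_initial_state() -> np.ndarray:
    """A generic non-negative starting state; transients are discarded
    by burn-in, so only non-degeneracy matters."""
    y0 = np.zeros(N_STATE)
    y0[0] = 2.0   # U hexamers
    y0[8] = 0.5   # U monomers
    y0[I_MA] = 0.5
    y0[I_MBC] = 1.0
    y0[I_A] = 0.8
    return y0


# ---------------------------------------------------------------------------
# Free KaiA
# ---------------------------------------------------------------------------

def free_kaia(state: np.ndarray, p: PTOParameters) -> float:
    """Free KaiA dimer concentration at binding quasi-equilibrium.

    Solves the scalar balance

        a + H * a/(K_dim + a) + S_B * a/(K_seq + a) = A/2

    for ``a`` where ``H`` is the hexamer concentration (CH total / 6) and
    ``S_B`` the serine-state monomer-equivalents in KaiB-bound complexes
    (one sequestered dimer per S monomer-equivalent).  The left side is
    strictly increasing in ``a``, so the non-negative root is unique and
    lies in [0, A/2].
    """
    state = np.asarray(state, dtype=float)
    if np.any(state[[*range(12), I_A]] < 0):
        raise ValueError("free_kaia requires a non-negative state")
    A_tot = state[I_A]
    if A_tot == 0.0:
        return 0.0
    a_tot = A_tot / 2.0  # dimers
    H = state[CH].sum() / 6.0
    S_B = state[CB][3]
    if H == 0.0 and S_B == 0.0:
        return a_tot
    Kd, Ks = p.K_dim, p.K_seq

    def balance(a: float) -> float:
        return a + H * a / (Kd + a) + S_B * a / (Ks + a) - a_tot

    if balance(a_tot) <= 0.0:  # numerically all free (degenerate)
        return a_tot
    return brentq(balance, 0.0, a_tot, xtol=1e-14, rtol=1e-12)


# ---------------------------------------------------------------------------
# Regulation factors (thermodynamic fold-change forms)
# ---------------------------------------------------------------------------

def activation_factor(x: float, K_act: float, lam_act: float):
    """Fold-change of simple transcriptional activation.

    ``(1 + lam_act * x/K) / (1 + x/K)``: 1 with no activator, ``lam_act``
    at saturation, the midpoint ``(1 + lam_act)/2`` at ``x = K``.
    Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("activator concentration must be non-negative")
    r = x / K_act
    out = (1.0 + lam_act * r) / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def repression_factor(y: float, K_rep: float, lam_rep: float):
    """Fold-change of simple transcriptional repression.

    ``(1 + lam_rep * y/K) / (1 + y/K)``: 1 with no repressor, approaching
    ``lam_rep`` (< 1) at saturation.  ``lam_rep = 1`` is the identity;
    ``lam_rep -> 0`` recovers the pure ``1/(1 + y/K)`` form.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("repressor concentration must be non-negative")
    r = y / K_rep
    out = (1.0 + lam_rep * r) / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def regulator_concentration(state: np.ndarray, spec: FeedbackSpec, role: str) -> float:
    """Concentration of the transcriptional activator or repressor species.

    The activator is always read from the hexamer pool; the repressor from
    the pool the feedback wiring selects.
    """
    state = np.asarray(state, dtype=float)
    if role == "activator":
        return float(state[CH][list(spec.activator_indices)].sum())
    if role == "repressor":
        pool = state[CH] if spec.repressor_pool == "hexamer" else state[CB]
        return float(pool[list(spec.repressor_indices)].sum())
    raise ValueError(f"role must be 'activator' or 'repressor', got {role!r}")


# ---------------------------------------------------------------------------
# Derivatives
# ---------------------------------------------------------------------------

def _cyclic_flux(pool: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """Net derivative from cyclic U->T->D->S->U transitions."""
    out = rates * pool          # flux leaving each state along the cycle
    return np.roll(out, 1) - out


def pto_derivatives(state: np.ndarray, p: PTOParameters,
                    overrides: PerturbationOverrides = IDENTITY_OVERRIDES) -> np.ndarray:
    """Derivatives of the 12 KaiC components (mRNA/KaiA slots zero).

    Terms per pool: cyclic phospho-transitions (hexamer steps boosted by
    KaiA saturation), KaiB binding/dissociation, hexamer/monomer-pool
    monomer exchange, hexamer assembly with fifth-power monomer
    saturation, decomposition, synthesis from kaiBC mRNA into monomeric U,
    and uniform degradation.
    """
    state = np.asarray(state, dtype=float)
    tH_b, tH_a, tB, gate = p.arrays()
    ch, cb, cp = state[CH], state[CB], state[CP]
    dy = np.zeros(N_STATE)

    a_free = free_kaia(state, p)
    sat = a_free / (p.K_half + a_free) if a_free > 0 else 0.0

    d_ch = _cyclic_flux(ch, tH_b + tH_a * sat)
    d_cb = _cyclic_flux(cb, tB)
    d_cp = np.zeros(4)

    # KaiB binding (composition-gated) and dissociation, component-wise
    bind = p.beta_plus * gate * ch
    unbind = p.beta_minus * cb
    d_ch += unbind - bind
    d_cb += bind - unbind

    # Monomer exchange between hexamers and the free-monomer pool: a free
    # monomer in state X (X in {U, D, S}; T monomers do not insert)
    # replaces a hexamer-bound monomer in state Y at rate
    # c_X * (CP_X / CP_total) * CH_Y.  This synchronises the hexamer
    # population and is the dephosphorylation route for T-state hexamer
    # sites once KaiA is sequestered.  Each pool's total is conserved.
    cp_tot0 = cp.sum()
    if cp_tot0 > 0:
        frac = cp / cp_tot0
        for rate, xi in ((p.c_U, 0), (p.c_D, 2), (p.c_S, 3)):
            ins = rate * frac[xi]
            for yi in range(4):
                if yi == xi:
                    continue
                flux = ins * ch[yi]
                d_ch[yi] -= flux
                d_ch[xi] += flux
                d_cp[xi] -= flux
                d_cp[yi] += flux

    # hexamer assembly: a monomer joins a hexamer only when five partners
    # are available -> fifth power of the monomer-pool saturation
    cp_tot = cp.sum()
    if cp_tot > 0:
        assembly = p.k_hex * cp * (cp_tot / (p.K_P + cp_tot)) ** 5
        d_cp -= assembly
        d_ch += assembly

    # decomposition of hexamers and complexes into free monomers
    d_cp += p.k_dis * (ch + cb)
    d_ch -= p.k_dis * ch
    d_cb -= p.k_dis * cb

    # synthesis into monomeric U, uniform degradation
    d_cp[0] += overrides.scale_k_2bc * p.k_2bc * state[I_MBC]
    d_ch -= p.k_4bc * ch
    d_cb -= p.k_4bc * cb
    d_cp -= p.k_4bc * cp

    dy[CH], dy[CB], dy[CP] = d_ch, d_cb, d_cp
    return dy


def ttfl_derivatives(state: np.ndarray, q: TTFLParameters, spec: FeedbackSpec,
                     p: PTOParameters,
                     overrides: PerturbationOverrides = IDENTITY_OVERRIDES) -> np.ndarray:
    """Derivatives of the mRNA and KaiA slots (KaiC slots zero)."""
    state = np.asarray(state, dtype=float)
    dy = np.zeros(N_STATE)
    x = regulator_concentration(state, spec, "activator")
    y = regulator_concentration(state, spec, "repressor")
    dy[I_MA] = overrides.scale_k_1a * q.k_1a - q.k_3 * state[I_MA]
    dy[I_MBC] = (q.k_1bc
                 * activation_factor(x, q.K_act, q.lam_act)
                 * repression_factor(y, q.K_rep, q.lam_rep)
                 - q.k_3 * state[I_MBC])
    dy[I_A] = q.k_2 * state[I_MA] - q.k_4 * state[I_A]
    return dy


def full_derivatives(state: np.ndarray, p: PTOParameters, q: TTFLParameters,
                     spec: FeedbackSpec,
                     overrides: PerturbationOverrides = IDENTITY_OVERRIDES) -> np.ndarray:
    """All 15 derivatives: element-wise sum of the PTO and TTFL parts."""
    return (pto_derivatives(state, p, overrides)
            + ttfl_derivatives(state, q, spec, p, overrides))


def _free_kaia_scalar(at2: float, H: float, S_B: float, Kd: float,
                      Ks: float) -> float:
    """Root of the free-KaiA balance by safeguarded Newton iteration.

    Same equation as :func:`free_kaia`; written with scalar arithmetic for
    the integrator hot path.
    """
    if at2 <= 0.0:
        return 0.0
    if H <= 0.0 and S_B <= 0.0:
        return at2
    lo, hi = 0.0, at2
    a = at2 / 2.0
    for _ in range(60):
        g = a + H * a / (Kd + a) + S_B * a / (Ks + a) - at2
        if g > 0.0:
            hi = a
        else:
            lo = a
        dg = 1.0 + H * Kd / (Kd + a) ** 2 + S_B * Ks / (Ks + a) ** 2
        step = g / dg
        a_new = a - step
        if not (lo < a_new < hi):
            a_new = 0.5 * (lo + hi)
        if abs(a_new - a) < 1e-14 * (1.0 + a):
            return a_new
        a = a_new
    return a


def make_rhs(p: PTOParameters, q: TTFLParameters, spec: FeedbackSpec,
             overrides: PerturbationOverrides = IDENTITY_OVERRIDES):
    """Return an ``f(t, y)`` callable for the ODE integrator.

    The closure is a scalar-arithmetic transcription of
    :func:`full_derivatives` (the two are cross-checked in the test
    suite), avoiding small-array overhead in the integrator hot path.
    The integrator may probe slightly negative states; those are clipped
    to zero before evaluating the mass-action terms so the right-hand
    side stays defined and pushes trajectories back to the non-negative
    orthant.
    """
    tHb = tuple(p.tH_basal)
    tHa = tuple(p.tH_kaiA)
    tB = tuple(p.tB_basal)
    gate = tuple(p.kaiB_gate)
    bp, bm = p.beta_plus, p.beta_minus
    k_hex, K_P, k_dis = p.k_hex, p.K_P, p.k_dis
    Kd, Ks, Kh = p.K_dim, p.K_seq, p.K_half
    k_2bc = p.k_2bc * overrides.scale_k_2bc
    k_4bc = p.k_4bc
    exchange = ((p.c_U, 0), (p.c_D, 2), (p.c_S, 3))
    act_idx = spec.activator_indices
    rep_idx = spec.repressor_indices
    rep_offset = 0 if spec.repressor_pool == "hexamer" else 4
    k_1a = q.k_1a * overrides.scale_k_1a
    k_1bc, k_2, k_3, k_4 = q.k_1bc, q.k_2, q.k_3, q.k_4
    lam_a, K_a, lam_r, K_r = q.lam_act, q.K_act, q.lam_rep, q.K_rep

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        ch = [y[0] if y[0] > 0 else 0.0, y[1] if y[1] > 0 else 0.0,
              y[2] if y[2] > 0 else 0.0, y[3] if y[3] > 0 else 0.0]
        cb = [y[4] if y[4] > 0 else 0.0, y[5] if y[5] > 0 else 0.0,
              y[6] if y[6] > 0 else 0.0, y[7] if y[7] > 0 else 0.0]
        cp = [y[8] if y[8] > 0 else 0.0, y[9] if y[9] > 0 else 0.0,
              y[10] if y[10] > 0 else 0.0, y[11] if y[11] > 0 else 0.0]
        ma = y[12] if y[12] > 0 else 0.0
        mbc = y[13] if y[13] > 0 else 0.0
        A = y[14] if y[14] > 0 else 0.0

        a_free = _free_kaia_scalar(A / 2.0, sum(ch) / 6.0, cb[3], Kd, Ks)
        sat = a_free / (Kh + a_free) if a_free > 0 else 0.0

        fh = [(tHb[i] + tHa[i] * sat) * ch[i] for i in range(4)]
        fb = [tB[i] * cb[i] for i in range(4)]
        d_ch = [fh[3] - fh[0], fh[0] - fh[1], fh[1] - fh[2], fh[2] - fh[3]]
        d_cb = [fb[3] - fb[0], fb[0] - fb[1], fb[1] - fb[2], fb[2] - fb[3]]
        d_cp = [0.0, 0.0, 0.0, 0.0]

        for i in range(4):
            b = bp * gate[i] * ch[i]
            u = bm * cb[i]
            d_ch[i] += u - b
            d_cb[i] += b - u

        cp_tot = cp[0] + cp[1] + cp[2] + cp[3]
        if cp_tot > 0.0:
            for rate, xi in exchange:
                ins = rate * cp[xi] / cp_tot
                if ins > 0.0:
                    for yi in range(4):
                        if yi == xi:
                            continue
                        flux = ins * ch[yi]
                        d_ch[yi] -= flux
                        d_ch[xi] += flux
                        d_cp[xi] -= flux
                        d_cp[yi] += flux
            sat5 = (cp_tot / (K_P + cp_tot)) ** 5
            for i in range(4):
                asm = k_hex * cp[i] * sat5
                d_cp[i] -= asm
                d_ch[i] += asm

        for i in range(4):
            d_cp[i] += k_dis * (ch[i] + cb[i])
            d_ch[i] -= k_dis * ch[i]
            d_cb[i] -= k_dis * cb[i]

        d_cp[0] += k_2bc * mbc
        for i in range(4):
            d_ch[i] -= k_4bc * ch[i]
            d_cb[i] -= k_4bc * cb[i]
            d_cp[i] -= k_4bc * cp[i]

        x = 0.0
        for i in act_idx:
            x += ch[i]
        yr = 0.0
        pool = ch if rep_offset == 0 else cb
        for i in rep_idx:
            yr += pool[i]
        ra = x / K_a
        rr = yr / K_r
        d_mbc = (k_1bc * ((1.0 + lam_a * ra) / (1.0 + ra))
                 * ((1.0 + lam_r * rr) / (1.0 + rr)) - k_3 * mbc)

        out = np.empty(N_STATE)
        out[0:4] = d_ch
        out[4:8] = d_cb
        out[8:12] = d_cp
        out[12] = k_1a - k_3 * ma
        out[13] = d_mbc
        out[14] = k_2 * ma - k_4 * A
        return out

    return rhs
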