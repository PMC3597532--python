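"""Parameter containers and feedback-variant specifications.

The model splits into a post-translational oscillator (PTO) — the KaiC
phosphorylation cycle running over three pools (free hexamers, KaiB-bound
complexes, free monomers) — and a transcriptional/translational feedback
loop (TTFL) for the kaiA and kaiBC transcripts and the KaiA protein.

All concentrations are in arbitrary units (a.u.) normalised so that the
wild-type mean kaiBC mRNA level is ~1; all rates are per hour.

The default PTO rate set shipped here is *calibrated, not taken from any
publication*: it was tuned so that the full model with the TD-activator /
U-repressor feedback wiring sustains a limit cycle with a ~25 h period and
the canonically observed phase relations (see docs/methods.md).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

#: Order of KaiC phospho-states everywhere in the package:
#: U (unphosphorylated), T (Thr-432~P), D (doubly phosphorylated),
#: S (Ser-431~P).  The phosphorylation cycle runs U -> T -> D -> S -> U.
PHOSPHO_STATES: tuple[str, ...] = ("U", "T", "D", "S")

_STATE_INDEX = {s: i for i, s in enumerate(PHOSPHO_STATES)}


def _as_rate_vector(v: Iterable[float], name: str, allow_zero: bool = True) -> np.ndarray:
    arr = np.asarray(tuple(v), dtype=float)
    if arr.shape != (4,):
        raise ValueError(f"{name} must have exactly 4 entries (U->T, T->D, D->S, S->U)")
    if np.any(arr < 0) or (not allow_zero and np.any(arr == 0)):
        raise ValueError(f"{name} entries must be {'non-negative' if allow_zero else 'positive'}")
    return arr


@dataclass(frozen=True)
class PTOParameters:
    """Rate constants of the post-translational KaiC phosphorylation cycle.

    Attributes
    ----------
    tH_basal, tH_kaiA:
        Basal and KaiA-dependent cyclic transition rates in the free
        hexamer pool, ordered (U->T, T->D, D->S, S->U), 1/h.  The KaiA
        increments act in proportion to the free-KaiA saturation factor
        ``a / (K_half + a)``.
    tB_basal:
        Transition rates in the KaiB-bound complex pool (entries may be 0;
        complexes mostly dephosphorylate).
    beta_plus, beta_minus:
        KaiB binding (hexamer -> complex) and dissociation rates, 1/h.
        Binding is gated by phospho-composition via ``kaiB_gate``.
    kaiB_gate:
        Per-state weights in [0, 1] multiplying ``beta_plus``; KaiB binds
        preferentially to D/S-rich hexamers late in the phosphorylation
        phase.
    k_hex, K_P:
        Hexamer assembly rate from free monomers and the Michaelis constant
        of assembly; the flux carries a fifth-power saturation factor — a
        monomer only assembles when five partners are available.
    k_dis:
        First-order decomposition of hexamers and complexes back into free
        monomers.
    c_U, c_S, c_D:
        Monomer-exchange rates between hexamers and the free-monomer
        pool: a free monomer in state U/S/D replaces a hexamer-bound
        monomer of any other state in proportion to its share of the
        monomer pool.  Exchange synchronises the hexamer population (and
        clears T-state hexamer sites once KaiA is sequestered); each
        pool's total is conserved.  There is no c_T: T monomers do not
        insert.
    K_dim:
        Dissociation constant of the KaiA(2)·KaiC(6) hexamer complex
        (controls how much KaiA is stored on hexamers).
    K_half:
        Half-saturation of the KaiA-dependent phosphorylation boost,
        ``a / (K_half + a)`` in free dimer concentration; small values
        make the phosphorylation switch sharp.
    K_seq:
        Dissociation constant of KaiA sequestration by serine-state KaiC
        in KaiB-bound complexes (one dimer per S monomer-equivalent).
    k_2bc:
        KaiC synthesis rate per unit kaiBC mRNA, feeding the monomer-pool
        U state.
    k_4bc:
        Common first-order degradation of all twelve KaiC components.
    """

    tH_basal: tuple[float, float, float, float]
    tH_kaiA: tuple[float, float, float, float]
    tB_basal: tuple[float, float, float, float]
    beta_plus: float
    beta_minus: float
    kaiB_gate: tuple[float, float, float, float]
    k_hex: float
    K_P: float
    k_dis: float
    c_U: float
    c_S: float
    c_D: float
    K_dim: float
    K_seq: float
    K_half: float
    k_2bc: float
    k_4bc: float

    def __post_init__(self):
        _as_rate_vector(self.tH_basal, "tH_basal")
        _as_rate_vector(self.tH_kaiA, "tH_kaiA")
        _as_rate_vector(self.tB_basal, "tB_basal")
        gate = _as_rate_vector(self.kaiB_gate, "kaiB_gate")
        if np.any(gate > 1):
            raise ValueError("kaiB_gate weights must lie in [0, 1]")
        for name in ("beta_plus", "beta_minus", "k_hex", "K_P", "k_dis",
                     "c_U", "c_S", "c_D", "K_dim", "K_seq", "K_half"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # synthesis/degradation may be switched off entirely (closed system)
        if self.k_2bc < 0 or self.k_4bc < 0:
            raise ValueError("k_2bc and k_4bc must be non-negative")

    # cached arrays for the ODE right-hand side
    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return (np.asarray(self.tH_basal), np.asarray(self.tH_kaiA),
                np.asarray(self.tB_basal), np.asarray(self.kaiB_gate))


@dataclass(frozen=True)
class TTFLParameters:
    """Rate and regulation constants of the gene-expression loop.

    ``k_1a`` — constant kaiA transcription (a.u./h); ``k_1bc`` — basal
    kaiBC transcription; ``lam_act`` (> 1) and ``K_act`` — fold-change and
    half-saturation of transcriptional activation; ``lam_rep`` (in (0, 1])
    and ``K_rep`` — same for repression; ``k_2`` — KaiA translation per
    unit kaiA mRNA; ``k_3`` — mRNA degradation; ``k_4`` — KaiA protein
    degradation (all first order, 1/h).
    """

    k_1a: float
    k_1bc: float
    lam_act: float
    K_act: float
    lam_rep: float
    K_rep: float
    k_2: float
    k_3: float
    k_4: float

    def __post_init__(self):
        for name in ("k_1a", "k_1bc", "lam_act", "K_act", "lam_rep", "K_rep",
                     "k_2", "k_3", "k_4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lam_act <= 1:
            raise ValueError("lam_act must exceed 1 (activation fold-change)")
        if self.lam_rep > 1:
            raise ValueError("lam_rep must be <= 1 (repression fold-change)")


_ALLOWED_ACTIVATORS = [frozenset(s) for s in
                       ({"U"}, {"T"}, {"D"}, {"S"}, {"T", "D"}, {"T", "D", "S"})]
_ALLOWED_REPRESSORS = [frozenset(s) for s in
                       ({"U"}, {"T"}, {"D"}, {"S"}, {"T", "D", "S"})]
_SU = frozenset({"S", "U"})


def _species_label(states: frozenset[str]) -> str:
    if states == frozenset({"T", "D", "S"}):
        return "P"
    if states == frozenset({"T", "D"}):
        return "TD"
    if states == _SU:
        return "SU"
    return next(iter(states))


@dataclass(frozen=True)
class FeedbackSpec:
    """One two-loop wiring of the kaiBC promoter.

    A phospho-species of the free hexamer pool activates transcription
    (``activator_states``); a phospho-species of the hexamer or the
    KaiB-complex pool represses it (``repressor_pool``,
    ``repressor_states``).  Named in the H^X+ / H^Y- / B^Y- convention,
    e.g. ``HTD+_HU-`` for the TD-hexamer activator / U-hexamer repressor
    model.
    """

    activator_states: frozenset[str]
    repressor_pool: str  # "hexamer" | "complex"
    repressor_states: frozenset[str]

    def __post_init__(self):
        act = frozenset(self.activator_states)
        rep = frozenset(self.repressor_states)
        object.__setattr__(self, "activator_states", act)
        object.__setattr__(self, "repressor_states", rep)
        if act not in _ALLOWED_ACTIVATORS:
            raise ValueError(f"activator states {set(act)} not an allowed selection")
        if self.repressor_pool not in ("hexamer", "complex"):
            raise ValueError("repressor_pool must be 'hexamer' or 'complex'")
        if rep not in _ALLOWED_REPRESSORS and not (
                rep == _SU and self.repressor_pool == "complex"):
            raise ValueError(f"repressor states {set(rep)} not an allowed selection")

    @property
    def name(self) -> str:
        act = _species_label(self.activator_states)
        rep = _species_label(self.repressor_states)
        pool = "H" if self.repressor_pool == "hexamer" else "B"
        return f"H{act}+_{pool}{rep}-"

    @property
    def activator_indices(self) -> tuple[int, ...]:
        return tuple(sorted(_STATE_INDEX[s] for s in self.activator_states))

    @property
    def repressor_indices(self) -> tuple[int, ...]:
        return tuple(sorted(_STATE_INDEX[s] for s in self.repressor_states))

    @classmethod
    def from_name(cls, name: str) -> "FeedbackSpec":
        """Parse names like ``HTD+_HU-`` or ``HD+_BT-``."""
        try:
            act_part, rep_part = name.split("_")
            if not (act_part.startswith("H") and act_part.endswith("+")
                    and rep_part.endswith("-")):
                raise ValueError
            act = _label_states(act_part[1:-1])
            pool = {"H": "hexamer", "B": "complex"}[rep_part[0]]
            rep = _label_states(rep_part[1:-1])
        except (ValueError, KeyError, IndexError) as exc:
            raise ValueError(f"cannot parse feedback spec name {name!r}") from exc
        return cls(activator_states=act, repressor_pool=pool, repressor_states=rep)


def _label_states(label: str) -> frozenset[str]:
    mapping = {"U": {"U"}, "T": {"T"}, "D": {"D"}, "S": {"S"},
               "TD": {"T", "D"}, "P": {"T", "D", "S"}, "SU": {"S", "U"}}
    if label not in mapping:
        raise ValueError(f"unknown phospho-species label {label!r}")
    return frozenset(mapping[label])


# ---------------------------------------------------------------------------
# Calibrated defaults (tuned, not from any publication; see docs/methods.md)
# ---------------------------------------------------------------------------

def default_pto() -> PTOParameters:
    """Calibrated default PTO rate set (a.u., 1/h).

    Tuned so the full model with the ``HTD+_HU-`` wiring sustains a
    ~25 h limit cycle with U-KaiC peaking in the early subjective day,
    phosphorylated KaiC in the early subjective night, and kaiBC mRNA
    in between.  Not measured values.
    """
    return PTOParameters(
        tH_basal=(0.002, 0.004, 0.153, 0.056),
        tH_kaiA=(0.477, 0.357, 0.0, 2.126),
        tB_basal=(0.0, 0.0, 0.225, 0.0385),
        beta_plus=0.894,
        beta_minus=0.19,
        kaiB_gate=(0.0, 0.0, 0.15, 1.0),
        k_hex=1.2,
        K_P=0.2,
        k_dis=0.118,
        c_U=0.145,
        c_S=0.145,
        c_D=0.145,
        K_dim=2.0,
        K_seq=0.001,
        K_half=0.037,
        k_2bc=0.244,
        k_4bc=0.038,
    )


def default_ttfl() -> TTFLParameters:
    """Calibrated default TTFL parameter set (see docs/methods.md)."""
    return TTFLParameters(
        k_1a=0.268,
        k_1bc=0.546,
        lam_act=4.0,
        K_act=0.5,
        lam_rep=0.03,
        K_rep=1.0,
        k_2=0.25,
        k_3=0.6,
        k_4=0.171,
    )


#: The mechanism the screening funnel selects: TD-hexamer activation,
#: U-hexamer repression of kaiBC.
HTD_HU = FeedbackSpec(frozenset({"T", "D"}), "hexamer", frozenset({"U"}))
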