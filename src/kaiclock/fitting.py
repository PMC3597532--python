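"""Cost function, stochastic global fitting and the two-loop screening funnel.

Fitting follows the study design for this system: the PTO rates are held
fixed (they come from the calibrated core-oscillator set), the TTFL
parameters are fitted to an observed time course by a budgeted
simulated-annealing search repeated from three initial conditions, and
the best set per feedback variant is selected by its rhythm phenotype
first and its cost second.  The screen then subjects every good-fit
variant to the in-silico mutant battery (kaiA knockout, kaiA
overexpression scan, KaiC overexpression) in funnel order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import metrics, simulate
from .params import (FeedbackSpec, PTOParameters, TTFLParameters,
                     default_pto, default_ttfl)

#: TTFL fields adjusted by the fitter (log10 space).
FIT_PARAM_NAMES = ("k_1bc", "lam_act", "K_act", "lam_rep", "K_rep", "k_3", "k_4")

#: Cost assigned when a candidate parameter set cannot be integrated.
PENALTY_COST = 1.0e6

#: Mutant-test protocol constants used by the screen.
OXKAIA_FOLD_GRID = (2.0, 4.0, 6.0, 8.0, 10.0)
OXKAIA_ELEVATION_FOLD = 2.0
OXKAIC_FOLD = 5.0
#: "Suppressed" means the perturbed mean falls below this fraction of the
#: wild-type mean kaiBC mRNA.
OXKAIC_SUPPRESSION_FACTOR = 0.8


@dataclass(frozen=True)
class SimOptions:
    """Integration settings for fitting and screening runs."""

    burn_in: float = 240.0
    record: float = 120.0
    rtol: float = 1e-8
    atol: float = 1e-10

    def faster(self) -> "SimOptions":
        return replace(self, rtol=max(self.rtol, 1e-6), atol=max(self.atol, 1e-9))


@dataclass
class FitResult:
    spec: FeedbackSpec
    params: TTFLParameters
    cost: float
    diagnostics: metrics.RhythmDiagnostics | None
    classification: metrics.FitClassification
    seed: int
    start_index: int
    n_evaluations: int = 0

    @property
    def good(self) -> bool:
        return self.classification.good


# ---------------------------------------------------------------------------
# Cost
# ---------------------------------------------------------------------------

def _observed_channels(series: simulate.TimeSeries, t_data: np.ndarray
                       ) -> dict[str, np.ndarray]:
    mbc = np.interp(t_data, series.t, series["mBC"])
    mean = mbc.mean()
    u = np.interp(t_data, series.t, series["UKaiC_frac"])
    return {"mBC_rel": mbc / mean if mean > 0 else mbc,
            "UKaiC_frac": u, "PKaiC_frac": 1.0 - u}


def cost(params: TTFLParameters, data: simulate.TimeSeries, p: PTOParameters,
         spec: FeedbackSpec, sim: SimOptions = SimOptions()) -> float:
    """Equally weighted sum of squared residuals against an observed table.

    The model is run to its settled cycle, the simulated kaiBC mRNA is
    standardised to mean 1 over the comparison time points, and squared
    residuals are summed over the three observable channels at the data
    times.  Integration failures return a large finite penalty instead of
    raising, so a global optimizer can move through bad regions.
    """
    t_data = np.asarray(data.t, dtype=float)
    try:
        res = simulate.run_experiment(p, params, spec, burn_in=sim.burn_in,
                                      record=max(sim.record, t_data[-1] + 1.0),
                                      rtol=sim.rtol, atol=sim.atol)
    except (simulate.IntegrationError, ValueError):
        return PENALTY_COST
    sim_ch = _observed_channels(res.wild_type, t_data)
    total = 0.0
    for name in ("mBC_rel", "UKaiC_frac", "PKaiC_frac"):
        r = sim_ch[name] - np.asarray(data[name], dtype=float)
        if not np.all(np.isfinite(r)):
            return PENALTY_COST
        total += float(np.sum(r * r))
    return total


# ---------------------------------------------------------------------------
# Bounds and parameter vectorisation
# ---------------------------------------------------------------------------

def default_bounds(q0: TTFLParameters,
                   names: Sequence[str] = FIT_PARAM_NAMES,
                   decades: float = 2.0) -> dict[str, tuple[float, float]]:
    """Log-uniform search box: +/- ``decades`` around the reference values,
    clipped to the validity constraints (lam_act > 1, lam_rep <= 1)."""
    bounds = {}
    for name in names:
        v = getattr(q0, name)
        lo, hi = v * 10.0 ** (-decades), v * 10.0 ** decades
        if name == "lam_act":
            lo, hi = max(lo, 1.05), max(hi, 1.5)
        if name == "lam_rep":
            hi = min(hi, 1.0)
        bounds[name] = (lo, hi)
    return bounds


def _to_theta(q: TTFLParameters, names: Sequence[str]) -> np.ndarray:
    return np.log10([getattr(q, n) for n in names])


def _from_theta(theta: np.ndarray, q0: TTFLParameters,
                names: Sequence[str]) -> TTFLParameters:
    return replace(q0, **{n: float(10.0 ** th) for n, th in zip(names, theta)})


# ---------------------------------------------------------------------------
# Simulated annealing
# ---------------------------------------------------------------------------

def _anneal(objective, theta0: np.ndarray, lo: np.ndarray, hi: np.ndarray,
            budget: int, rng: np.random.Generator
            ) -> tuple[np.ndarray, float, int]:
    """Budgeted simulated annealing with geometric cooling in a box.

    One coordinate is perturbed per move with a step size that shrinks
    with the temperature; the best point ever seen is returned.
    """
    theta = theta0.copy()
    f = objective(theta)
    n_eval = 1
    best_theta, best_f = theta.copy(), f
    t0 = max(abs(f), 1.0) * 0.3
    t_end = t0 * 1e-4
    alpha = (t_end / t0) ** (1.0 / max(budget - 1, 1))
    temp = t0
    n_dim = len(theta)
    for _ in range(max(budget - 1, 0)):
        j = int(rng.integers(n_dim))
        step = 0.03 + 0.20 * (temp / t0)
        cand = theta.copy()
        cand[j] = np.clip(cand[j] + rng.normal(0.0, step), lo[j], hi[j])
        fc = objective(cand)
        n_eval += 1
        if fc <= f or rng.random() < math.exp(-(fc - f) / temp):
            theta, f = cand, fc
            if f < best_f:
                best_theta, best_f = theta.copy(), f
        temp *= alpha
    return best_theta, best_f, n_eval


def fit(spec: FeedbackSpec, data: simulate.TimeSeries, p: PTOParameters,
        q0: TTFLParameters | None = None, n_starts: int = 3,
        seed: int = 0, budget: int = 2000,
        bounds: dict[str, tuple[float, float]] | None = None,
        names: Sequence[str] = FIT_PARAM_NAMES,
        sim: SimOptions = SimOptions(),
        classify_sim: SimOptions | None = None) -> list[FitResult]:
    """Multi-start annealing fit of the TTFL parameters to observed data.

    Start 0 begins at the reference values ``q0``; further starts begin
    at seeded random points inside the search box.  Deterministic given
    ``seed``.  Returns one :class:`FitResult` per start, each carrying
    rhythm diagnostics and the wild-type phenotype classification of its
    best parameters.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    q0 = default_ttfl() if q0 is None else q0
    bounds = default_bounds(q0, names) if bounds is None else bounds
    lo = np.log10([bounds[n][0] for n in names])
    hi = np.log10([bounds[n][1] for n in names])
    theta_ref = np.clip(_to_theta(q0, names), lo, hi)

    results: list[FitResult] = []
    seeds = np.random.SeedSequence(seed).spawn(n_starts)
    for i in range(n_starts):
        rng = np.random.default_rng(seeds[i])
        if i == 0:
            theta0 = theta_ref.copy()
        else:
            theta0 = theta_ref + rng.uniform(-0.4, 0.4, size=len(names))
            theta0 = np.clip(theta0, lo, hi)

        def objective(theta):
            return cost(_from_theta(theta, q0, names), data, p, spec, sim)

        theta_best, f_best, n_eval = _anneal(objective, theta0, lo, hi,
                                             budget, rng)
        q_best = _from_theta(theta_best, q0, names)
        diag, classification = _classify_candidate(
            p, q_best, spec, classify_sim or sim)
        results.append(FitResult(spec=spec, params=q_best, cost=float(f_best),
                                 diagnostics=diag, classification=classification,
                                 seed=seed, start_index=i,
                                 n_evaluations=n_eval))
    if all(r.cost >= PENALTY_COST for r in results):
        raise simulate.IntegrationError(
            f"all {n_starts} fit starts failed integration for {spec.name}")
    return results


def _classify_candidate(p, q, spec, sim: SimOptions):
    try:
        res = simulate.run_experiment(p, q, spec, burn_in=sim.burn_in,
                                      record=sim.record, rtol=sim.rtol,
                                      atol=sim.atol)
    except (simulate.IntegrationError, ValueError):
        return None, metrics.FitClassification("reject", ["integration failure"])
    diag = metrics.diagnose(res.wild_type)
    return diag, metrics.classify_wildtype(diag)


def select_optimal(fits: Sequence[FitResult]) -> FitResult:
    """Pick the phenotype-best fit: lowest cost among good-fit-classified
    results; if none classifies good, the lowest-cost reject (caller can
    see the verdict on the returned object).  Ties break toward the lower
    start index."""
    if not fits:
        raise ValueError("select_optimal needs at least one fit")
    good = [f for f in fits if f.good]
    pool = good if good else list(fits)
    return min(pool, key=lambda f: (f.cost, f.start_index))


# ---------------------------------------------------------------------------
# Variant enumeration
# ---------------------------------------------------------------------------

#: (repressor label, activator labels) rows of the candidate table, in
#: presentation order.  The same rows apply to both repressor pools.
_TABLE_ROWS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("P", ("U",)),
    ("U", ("T", "D", "S", "TD", "P")),
    ("T", ("U", "D", "S")),
    ("D", ("U", "T", "S")),
    ("S", ("U", "T", "D", "TD")),
)

_LABEL_STATES = {"U": {"U"}, "T": {"T"}, "D": {"D"}, "S": {"S"},
                 "TD": {"T", "D"}, "P": {"T", "D", "S"}}

#: Activators paired with the supplementary SU-repressor (complex pool).
_SUPPLEMENTARY_ACTIVATORS = ("TD", "P", "D")


def enumerate_specs(include_supplementary: bool = False) -> list[FeedbackSpec]:
    """All candidate two-loop feedback variants.

    16 hexamer-pool-repressor variants (Group I) and 16 complex-pool
    variants (Group II); ``include_supplementary`` appends the three
    extra variants with the combined S/U repressor read from the complex
    pool.
    """
    specs: list[FeedbackSpec] = []
    for pool in ("hexamer", "complex"):
        for rep_label, act_labels in _TABLE_ROWS:
            for act_label in act_labels:
                specs.append(FeedbackSpec(
                    activator_states=frozenset(_LABEL_STATES[act_label]),
                    repressor_pool=pool,
                    repressor_states=frozenset(_LABEL_STATES[rep_label])))
    if include_supplementary:
        for act_label in _SUPPLEMENTARY_ACTIVATORS:
            specs.append(FeedbackSpec(
                activator_states=frozenset(_LABEL_STATES[act_label]),
                repressor_pool="complex",
                repressor_states=frozenset({"S", "U"})))
    return specs


def spec_group(spec: FeedbackSpec) -> str:
    if spec.repressor_states == frozenset({"S", "U"}):
        return "supplementary"
    return "I" if spec.repressor_pool == "hexamer" else "II"


# ---------------------------------------------------------------------------
# Mutant battery
# ---------------------------------------------------------------------------

@dataclass
class MutantTests:
    kaia_knockout: metrics.FitClassification | None = None
    oxkaia_threshold: float | None = None
    oxkaia_pass: bool | None = None
    oxkaia_reasons: list[str] = field(default_factory=list)
    oxkaic_pass: bool | None = None
    oxkaic_reasons: list[str] = field(default_factory=list)

    @property
    def all_passed(self) -> bool:
        return bool(self.kaia_knockout and self.kaia_knockout.good
                    and self.oxkaia_pass and self.oxkaic_pass)


def run_mutant_battery(p: PTOParameters, q: TTFLParameters,
                       spec: FeedbackSpec, sim: SimOptions = SimOptions(),
                       funnel: bool = True) -> MutantTests:
    """kaiA knockout, kaiA-overexpression scan and KaiC overexpression.

    With ``funnel=True`` later stages run only if the earlier ones
    passed, mirroring the selection workflow.
    """
    out = MutantTests()
    sim_f = sim.faster()

    ko = simulate.run_experiment(
        p, q, spec, simulate.PerturbationProtocol("knockout_kaiA", 0.0),
        burn_in=sim.burn_in, record=max(sim.record, 200.0),
        rtol=sim_f.rtol, atol=sim_f.atol)
    out.kaia_knockout = metrics.classify_kaia_knockout(
        ko.wild_type, ko.perturbed, ko.trigger_time)
    if funnel and not out.kaia_knockout.good:
        return out

    threshold = metrics.arrhythmicity_fold_threshold(
        p, q, spec, "overexpress_kaiA", OXKAIA_FOLD_GRID,
        burn_in=sim.burn_in, record=max(sim.record, 140.0),
        rtol=sim_f.rtol, atol=sim_f.atol)
    out.oxkaia_threshold = threshold
    reasons = []
    if threshold is None:
        reasons.append(f"rhythm survives {OXKAIA_FOLD_GRID[-1]:g}-fold kaiA")
    ox = simulate.run_experiment(
        p, q, spec,
        simulate.PerturbationProtocol("overexpress_kaiA", OXKAIA_ELEVATION_FOLD),
        burn_in=sim.burn_in, record=max(sim.record, 140.0),
        rtol=sim_f.rtol, atol=sim_f.atol)
    post = ox.perturbed.window(ox.trigger_time, ox.perturbed.t[-1])
    if np.mean(post["mBC"]) <= np.mean(ox.wild_type["mBC"]):
        reasons.append("kaiBC not elevated by excess KaiA")
    out.oxkaia_pass = not reasons
    out.oxkaia_reasons = reasons
    if funnel and not out.oxkaia_pass:
        return out

    oxc = simulate.run_experiment(
        p, q, spec, simulate.PerturbationProtocol("overexpress_kaiC", OXKAIC_FOLD),
        burn_in=sim.burn_in, record=max(sim.record, 200.0),
        rtol=sim_f.rtol, atol=sim_f.atol)
    postc = oxc.perturbed.window(oxc.trigger_time, oxc.perturbed.t[-1])
    tail = postc.window(min(30.0, postc.t[-1] / 3), postc.t[-1])
    reasons = []
    if metrics.amplitude_decay_ratio(tail.t, tail["mBC"]) >= metrics.SUSTAINED_RATIO:
        reasons.append("rhythm survives KaiC overexpression")
    if np.mean(postc["mBC"]) >= OXKAIC_SUPPRESSION_FACTOR * np.mean(oxc.wild_type["mBC"]):
        reasons.append("kaiBC not suppressed by excess KaiC")
    out.oxkaic_pass = not reasons
    out.oxkaic_reasons = reasons
    return out


# ---------------------------------------------------------------------------
# Screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenRow:
    spec: FeedbackSpec
    group: str
    best: FitResult | None
    error: str | None = None
    mutants: MutantTests | None = None

    @property
    def wildtype_good(self) -> bool:
        return bool(self.best and self.best.good)

    @property
    def survives_funnel(self) -> bool:
        return bool(self.wildtype_good and self.mutants
                    and self.mutants.all_passed)


@dataclass
class ScreenReport:
    rows: list[ScreenRow]
    seed: int

    def good_fit_count(self, group: str | None = None) -> int:
        return sum(1 for r in self.rows if r.wildtype_good
                   and (group is None or r.group == group))

    @property
    def survivors(self) -> list[str]:
        return [r.spec.name for r in self.rows if r.survives_funnel]


def screen(data: simulate.TimeSeries, p: PTOParameters,
           q0: TTFLParameters | None = None, seed: int = 0,
           budget: int = 2000, n_starts: int = 3,
           include_supplementary: bool = False,
           sim: SimOptions = SimOptions(),
           fit_sim: SimOptions | None = None) -> ScreenReport:
    """Fit and phenotype-test every candidate feedback variant.

    For each variant: multi-start fit, phenotype-based selection,
    wild-type classification; variants whose best fit classifies good
    proceed to the mutant battery.  Per-variant failures are recorded in
    the report, never raised.
    """
    q0 = default_ttfl() if q0 is None else q0
    fit_sim = sim.faster() if fit_sim is None else fit_sim
    rows: list[ScreenRow] = []
    spec_seeds = np.random.SeedSequence(seed).generate_state(64)
    for i, fspec in enumerate(enumerate_specs(include_supplementary)):
        row = ScreenRow(spec=fspec, group=spec_group(fspec), best=None)
        try:
            fits = fit(fspec, data, p, q0=q0, n_starts=n_starts,
                       seed=int(spec_seeds[i] % (2 ** 31)), budget=budget,
                       sim=fit_sim, classify_sim=sim)
            row.best = select_optimal(fits)
            if row.best.good:
                row.mutants = run_mutant_battery(p, row.best.params, fspec,
                                                 sim=sim)
        except (simulate.IntegrationError, ValueError) as exc:
            row.error = str(exc)
        rows.append(row)
    return ScreenReport(rows=rows, seed=seed)
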