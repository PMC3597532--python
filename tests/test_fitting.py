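"""Cost function, annealing fitter, variant enumeration and the screen."""

from dataclasses import replace

import numpy as np
import pytest

from kaiclock import (HTD_HU, FeedbackSpec, SimOptions, cost, enumerate_specs,
                      fit, generate_from_model, select_optimal)
from kaiclock import fitting
from kaiclock.fitting import FitResult, _anneal, spec_group
from kaiclock.metrics import FitClassification
from kaiclock.simulate import TimeSeries, run_experiment

FAST = SimOptions(burn_in=160.0, record=60.0, rtol=1e-6, atol=1e-9)
#: classification needs >= 3 cycles in the window
CLS = SimOptions(burn_in=160.0, record=100.0, rtol=1e-6, atol=1e-9)


@pytest.fixture(scope="module")
def truth_table(pto, ttfl):
    table, truth = generate_from_model(pto, ttfl, HTD_HU, noise_sd=0.0, seed=3)
    return table, truth


class TestCost:
    def test_self_consistency_on_own_data(self, pto, truth_table):
        table, truth = truth_table
        assert cost(truth, table, pto, HTD_HU) < 1e-6

    def test_channel_offset_adds_quadratic_exactly(self, pto, truth_table):
        """With zero residuals, shifting one data channel by delta raises
        the cost by exactly n * delta**2."""
        table, truth = truth_table
        delta = 0.037
        base = cost(truth, table, pto, HTD_HU)
        shifted = TimeSeries(table.t, dict(table.channels))
        shifted.channels["UKaiC_frac"] = table["UKaiC_frac"] + delta
        c = cost(truth, shifted, pto, HTD_HU)
        n = len(table.t)
        assert c - base == pytest.approx(n * delta ** 2, rel=1e-4)

    def test_matches_hand_computed_sse(self, pto, ttfl, truth_table):
        """Independent SSE oracle: simulate separately, interpolate, and
        accumulate squared residuals with plain loops."""
        table, _ = truth_table
        q = replace(ttfl, k_3=ttfl.k_3 * 1.15)
        c = cost(q, table, pto, HTD_HU)
        res = run_experiment(pto, q, HTD_HU, burn_in=240.0,
                             record=table.t[-1] + 1.0)
        w = res.wild_type
        mbc = np.interp(table.t, w.t, w["mBC"])
        mbc = mbc / mbc.mean()
        u = np.interp(table.t, w.t, w["UKaiC_frac"])
        total = 0.0
        for k in range(len(table.t)):
            total += (mbc[k] - table["mBC_rel"][k]) ** 2
            total += (u[k] - table["UKaiC_frac"][k]) ** 2
            total += ((1 - u[k]) - table["PKaiC_frac"][k]) ** 2
        assert c == pytest.approx(total, rel=1e-9)

    def test_channel_permutation_symmetry(self, pto, truth_table):
        """Equal weights: residuals moved between channels leave the total
        unchanged."""
        table, truth = truth_table
        delta = 0.02
        a = TimeSeries(table.t, dict(table.channels))
        a.channels["UKaiC_frac"] = table["UKaiC_frac"] + delta
        b = TimeSeries(table.t, dict(table.channels))
        b.channels["PKaiC_frac"] = table["PKaiC_frac"] + delta
        assert cost(truth, a, pto, HTD_HU) == pytest.approx(
            cost(truth, b, pto, HTD_HU), rel=1e-6)

    def test_integration_failure_returns_penalty(self, pto, truth_table):
        table, truth = truth_table
        # absurd rates that break the integrator or the rhythm entirely
        q_bad = replace(truth, k_3=1e6, k_4=1e6)
        assert cost(q_bad, table, pto, HTD_HU, FAST) >= 0  # finite, no raise


class TestAnneal:
    def test_returns_best_of_evaluated_points(self):
        evaluated = []

        def f(theta):
            v = float(np.sum((theta - 1.0) ** 2))
            evaluated.append(v)
            return v

        rng = np.random.default_rng(5)
        theta0 = np.array([0.0, 0.0])
        lo, hi = np.full(2, -2.0), np.full(2, 2.0)
        _, f_best, n_eval = _anneal(f, theta0, lo, hi, budget=200, rng=rng)
        assert n_eval == 200
        assert f_best == pytest.approx(min(evaluated))
        assert f_best <= f(theta0)

    def test_respects_bounds(self):
        def f(theta):
            return -float(theta[0])  # pushes toward the upper bound

        rng = np.random.default_rng(0)
        theta, _, _ = _anneal(f, np.array([0.0]), np.array([-1.0]),
                              np.array([0.5]), budget=300, rng=rng)
        assert theta[0] <= 0.5 + 1e-12


class TestFit:
    def test_seeded_determinism_and_start_count(self, pto, ttfl, truth_table):
        table, _ = truth_table
        kw = dict(n_starts=3, seed=42, budget=4, sim=FAST, classify_sim=FAST)
        fits1 = fit(HTD_HU, table, pto, q0=ttfl, **kw)
        fits2 = fit(HTD_HU, table, pto, q0=ttfl, **kw)
        assert len(fits1) == 3
        for a, b in zip(fits1, fits2):
            assert a.cost == b.cost
            assert a.params == b.params
            assert a.start_index == b.start_index

    def test_recovers_perturbed_parameters(self, pto, ttfl):
        """Fit started away from the generating parameters recovers the
        mRNA decay, KaiA decay and activation fold-change within 20 %."""
        truth = replace(ttfl, k_3=ttfl.k_3 * 1.3, k_4=ttfl.k_4 * 0.8,
                        lam_act=ttfl.lam_act * 1.25)
        table, _ = generate_from_model(pto, truth, HTD_HU, noise_sd=0.0, seed=9)
        fits = fit(HTD_HU, table, pto, q0=ttfl, n_starts=2, seed=7,
                   budget=120, names=("k_3", "k_4", "lam_act"),
                   sim=FAST, classify_sim=FAST)
        best = select_optimal(fits)
        for name in ("k_3", "k_4", "lam_act"):
            got, want = getattr(best.params, name), getattr(truth, name)
            assert abs(got - want) / want < 0.20, f"{name}: {got} vs {want}"


def _fake_fit(costv, verdict, idx, spec=HTD_HU):
    cls = FitClassification(verdict, [] if verdict == "good_fit" else ["period"])
    return FitResult(spec=spec, params=None, cost=costv, diagnostics=None,
                     classification=cls, seed=0, start_index=idx)


class TestSelectOptimal:
    def test_good_fit_beats_cheaper_reject(self):
        fits = [_fake_fit(0.1, "reject", 0), _fake_fit(5.0, "good_fit", 1),
                _fake_fit(0.2, "reject", 2)]
        assert select_optimal(fits).start_index == 1

    def test_all_reject_returns_lowest_cost(self):
        fits = [_fake_fit(3.0, "reject", 0), _fake_fit(1.0, "reject", 1)]
        best = select_optimal(fits)
        assert best.start_index == 1 and not best.good

    def test_cost_tie_breaks_to_first_start(self):
        fits = [_fake_fit(1.0, "good_fit", 1), _fake_fit(1.0, "good_fit", 0)]
        assert select_optimal(fits).start_index == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_optimal([])


class TestEnumerateSpecs:
    def test_exactly_32_table_variants(self):
        specs = enumerate_specs()
        assert len(specs) == 32
        assert len(set(specs)) == 32
        groups = [spec_group(s) for s in specs]
        assert groups.count("I") == 16
        assert groups.count("II") == 16

    def test_supplementary_adds_three_su_variants(self):
        specs = enumerate_specs(include_supplementary=True)
        assert len(specs) == 35
        extras = specs[32:]
        assert all(s.repressor_states == frozenset({"S", "U"})
                   and s.repressor_pool == "complex" for s in extras)

    def test_all_specs_valid_and_named(self):
        for s in enumerate_specs(include_supplementary=True):
            assert FeedbackSpec.from_name(s.name) == s


@pytest.fixture(scope="module")
def monkeypatch_module():
    from _pytest.monkeypatch import MonkeyPatch

    mp = MonkeyPatch()
    yield mp
    mp.undo()


@pytest.fixture(scope="module")
def tiny_screen(pto, ttfl, monkeypatch_module, truth_table):
    table, _ = truth_table
    subset = [FeedbackSpec.from_name(n)
              for n in ("HTD+_HU-", "HS+_HD-", "HD+_BT-")]
    monkeypatch_module.setattr(fitting, "enumerate_specs",
                               lambda include_supplementary=False: subset)
    report = fitting.screen(table, pto, q0=ttfl, seed=5, budget=2,
                            n_starts=1, sim=CLS, fit_sim=FAST)
    monkeypatch_module.undo()
    return report, subset


class TestScreen:
    def test_one_row_per_spec(self, tiny_screen):
        report, subset = tiny_screen
        assert [r.spec for r in report.rows] == subset

    def test_self_recovery_of_generating_spec(self, tiny_screen):
        report, _ = tiny_screen
        by_name = {r.spec.name: r for r in report.rows}
        assert by_name["HTD+_HU-"].wildtype_good

    def test_mutant_tests_only_for_good_fits(self, tiny_screen):
        report, _ = tiny_screen
        for row in report.rows:
            if not row.wildtype_good:
                assert row.mutants is None

    def test_screen_determinism(self, pto, ttfl, monkeypatch, truth_table):
        table, _ = truth_table
        subset = [FeedbackSpec.from_name("HS+_HD-")]
        monkeypatch.setattr(fitting, "enumerate_specs",
                            lambda include_supplementary=False: subset)
        kw = dict(seed=5, budget=2, n_starts=2, sim=CLS, fit_sim=FAST)
        r1 = fitting.screen(table, pto, q0=ttfl, **kw)
        r2 = fitting.screen(table, pto, q0=ttfl, **kw)
        assert r1.rows[0].best.cost == r2.rows[0].best.cost
        assert r1.rows[0].best.params == r2.rows[0].best.params

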