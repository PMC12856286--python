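"""Strategy allocation, per-1000 outcomes, reclassification, curves."""

import numpy as np
import pandas as pd
import pytest

import dxtwin as dx
from dxtwin.strategies import (
    Strategy,
    expected_outcome,
    reclassification_summary,
    reclassification_table,
    standard_strategies,
)


@pytest.fixture(scope="module")
def strategies_05():
    return standard_strategies(0.05)


def test_treat_none_is_all_zero(mindact_model, strategies_05):
    o = expected_outcome(mindact_model, strategies_05["treat_none"])
    assert o.prevented_events == 0 and o.n_treated == 0 and o.n_tests == 0
    assert o.net_benefit == 0.0


def test_treat_all_nb_linear_in_threshold(mindact_model):
    """Treat-all NB is prevented - 1000*t: exactly linear with slope -1000."""
    ts = np.array([0.01, 0.05, 0.10, 0.15, 0.20])
    nbs = np.array([expected_outcome(mindact_model,
                                     Strategy("all", "treat_all", threshold=t)
                                     ).net_benefit for t in ts])
    slopes = np.diff(nbs) / np.diff(ts)
    assert np.allclose(slopes, -1000.0, atol=1e-9)


def test_nb_identity_on_every_reported_row(mindact_model, mindact_cohort):
    """Net Benefit always equals prevented - w * treated (pre-rounding)."""
    for mode, cohort in (("expected", None), ("realized", mindact_cohort)):
        tab = dx.outcome_table(mindact_model, threshold=0.05, cohort=cohort,
                               mode=mode if cohort is not None else "expected")
        lhs = tab["net_benefit"]
        rhs = tab["prevented_events"] - 0.05 * tab["n_treated"]
        assert np.max(np.abs(lhs - rhs)) < 1e-9


def test_events_plus_prevented_is_baseline(mindact_model):
    """Expected events + prevented events = treat-none events, per row."""
    tab = dx.outcome_table(mindact_model, threshold=0.05)
    base = tab.loc[tab.strategy == "treat_none", "expected_events"].iloc[0]
    total = tab["expected_events"] + tab["prevented_events"]
    assert np.max(np.abs(total - base)) < 1e-9


def test_expected_outcomes_match_cohort_averages(mindact_model,
                                                 mindact_cohort):
    """Analytic quadrature vs 100k-cohort averages, strategy by strategy."""
    for key, strat in standard_strategies(0.05).items():
        eo = expected_outcome(mindact_model, strat)
        co = dx.evaluate(mindact_model, mindact_cohort, strat,
                         mode="expected")
        assert eo.n_treated == pytest.approx(co.n_treated, abs=5.0), key
        assert eo.prevented_events == pytest.approx(
            co.prevented_events, abs=1.0), key
        assert eo.n_tests == pytest.approx(co.n_tests, abs=6.0), key
        assert eo.net_benefit == pytest.approx(co.net_benefit, abs=1.0), key


def test_realized_converges_to_expected(mindact_model, mindact_params):
    """Realized-mode tallies approach expected-mode as the cohort grows."""
    strat = standard_strategies(0.05)["clinical"]
    gaps = {}
    for n in (2_000, 50_000):
        coh = dx.generate_cohort(
            dx.CohortConfig("mindact", n, seed=17, params=mindact_params),
            model=mindact_model)
        exp = dx.evaluate(mindact_model, coh, strat, mode="expected")
        real = dx.evaluate(mindact_model, coh, strat, mode="realized")
        gaps[n] = abs(real.expected_events - exp.expected_events)
        # binomial error bound on the per-1000 event count
        se = 1000 * np.sqrt(0.11 * 0.89 / n)
        assert gaps[n] < 4 * se, n


def test_oracle_decision_rule_dominates_references(mindact_model):
    """Using the true conditional benefit can never do worse than the
    treat-none/treat-all references (expected mode)."""
    for t in (0.02, 0.05, 0.10):
        strats = standard_strategies(t)
        nb_all = expected_outcome(mindact_model, strats["treat_all"]).net_benefit
        for key in ("clinical", "mp", "otbin", "otcont"):
            nb = expected_outcome(mindact_model, strats[key]).net_benefit
            assert nb >= max(0.0, nb_all) - 1e-9, (t, key)


def test_continuous_ot_dominates_binary(mindact_model):
    """Discarding the score's continuous information cannot help."""
    curve = dx.decision_curve(mindact_model,
                              thresholds=[0.02, 0.05, 0.08, 0.12])
    piv = curve.pivot(index="threshold", columns="strategy",
                      values="delta_nb")
    assert (piv["otcont"] >= piv["otbin"] - 1e-9).all()
    assert (piv["otbin"] >= -1e-9).all()


def test_hr_one_strategies():
    """Ineffective chemotherapy: nothing prevented anywhere, and the
    threshold rules treat no one."""
    p = dx.default_params("mindact").replace(hr_chemo=1.0)
    model = dx.BenefitModel(p, profile="fast")
    for key, strat in standard_strategies(0.05).items():
        o = expected_outcome(model, strat)
        assert o.prevented_events == pytest.approx(0.0, abs=1e-9), key
        assert o.net_benefit == pytest.approx(-0.05 * o.n_treated,
                                              abs=1e-9), key
        if strat.rule == "benefit_threshold":
            assert o.n_treated == 0.0


def test_allocation_flags(mindact_model, mindact_cohort, strategies_05):
    treat, tested = dx.allocate(mindact_model, mindact_cohort,
                                strategies_05["mindact"])
    ch = mindact_cohort["clinical_high"].to_numpy()
    mp = mindact_cohort["mp_high"].to_numpy()
    assert (treat == (ch & mp)).all()
    assert (tested == ch).all()
    # threshold strategies: tested patients lie inside the window only
    treat, tested = dx.allocate(mindact_model, mindact_cohort,
                                strategies_05["mp"])
    win = dx.testing_window(mindact_model, "clinical+mp", 0.05)
    inside = ((mindact_cohort["z_c"] > win.z_lower)
              & (mindact_cohort["z_c"] <= win.z_upper)).to_numpy()
    assert (tested == inside).all()


class TestReclassification:
    def test_zero_effect_marker_reclassifies_nobody(self, mindact_params,
                                                    mindact_cohort):
        p = mindact_params.replace(beta_mp=0.0, beta_ot=0.0)
        model = dx.BenefitModel(p, profile="fast")
        summ = reclassification_summary(model, "clinical+mp", 0.05)
        assert summ["total"] == 0.0

    def test_fractions_sum_to_one(self, mindact_model, mindact_cohort,
                                  strategies_05):
        rec = reclassification_table(mindact_model, mindact_cohort,
                                     strategies_05["clinical"],
                                     strategies_05["mp"])
        assert rec.table["fraction"].sum() == pytest.approx(1.0, abs=1e-12)
        assert rec.total_reclassified == pytest.approx(
            rec.to_treat + rec.to_no_treat, abs=1e-12)
        assert rec.correct + rec.incorrect == pytest.approx(
            rec.total_reclassified, abs=1e-12)

    def test_expected_matches_realized_marginals(self, mindact_model,
                                                 mindact_cohort,
                                                 strategies_05):
        summ = reclassification_summary(mindact_model, "clinical+mp", 0.05)
        rec = reclassification_table(mindact_model, mindact_cohort,
                                     strategies_05["clinical"],
                                     strategies_05["mp"])
        n = len(mindact_cohort)
        for a, b in ((summ["to_treat"], rec.to_treat),
                     (summ["to_no_treat"], rec.to_no_treat)):
            se = np.sqrt(a * (1 - a) / n)
            assert abs(a - b) < 3 * se + 1e-3

    def test_threshold_mismatch_rejected(self, mindact_model,
                                         mindact_cohort):
        with pytest.raises(ValueError):
            reclassification_table(
                mindact_model, mindact_cohort,
                standard_strategies(0.05)["clinical"],
                standard_strategies(0.03)["mp"])


def test_decision_curve_structure(mindact_model):
    grid = [0.01, 0.05, 0.10]
    curve = dx.decision_curve(mindact_model, thresholds=grid)
    assert set(curve["strategy"]) == set(standard_strategies(0.05))
    assert len(curve) == len(grid) * 7
    none = curve[curve.strategy == "treat_none"]
    assert (none["net_benefit"] == 0).all()
    clin = curve[curve.strategy == "clinical"]
    assert clin["delta_nb"].isna().all()
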