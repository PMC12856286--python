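"""Treatment decision-making strategies and their population outcomes.

Four families of rules are evaluated:

* ``treat_none`` / ``treat_all`` — the two decision-curve reference
  strategies;
* ``mindact_rule`` — test every clinical-high patient with MammaPrint and
  treat those who are both clinical-high and MammaPrint-high;
* ``benefit_threshold`` — treat a patient iff their estimated benefit
  under a chosen information set strictly exceeds the treatment
  threshold.  Genomic strategies test only patients inside the testing
  window (where a result could still flip the clinical-only decision);
  everyone else keeps the clinical-only decision.

Outcomes are reported per 1000 patients in two modes: *expected*
(deterministic sums of true risks, the default, matching how expected
counts are tabulated) and *realized* (counts of simulated potential
outcomes on the appropriate digital twin).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .benefit import (
    BenefitModel,
    InformationSet,
    GENOMIC_SETS,
    conditional_benefit,
    testing_window,
)
from .risk import net_benefit_per_1000

RULES = ("treat_none", "treat_all", "mindact_rule", "benefit_threshold")


@dataclasses.dataclass(frozen=True)
class Strategy:
    """A decision rule: information set + threshold (where applicable)."""

    label: str
    rule: str
    info: InformationSet | None = None
    threshold: float = 0.05

    def __post_init__(self):
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.rule == "benefit_threshold" and self.info is None:
            raise ValueError("benefit_threshold requires an information set")


@dataclasses.dataclass(frozen=True)
class StrategyOutcome:
    """Population tallies of a strategy, per 1000 patients."""

    label: str
    mode: str                 # "expected" | "realized"
    expected_events: float
    prevented_events: float
    n_treated: float
    n_tests: float
    net_benefit: float
    threshold: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def standard_strategies(threshold: float = 0.05) -> dict:
    """The seven strategies reported in the outcome tables."""
    t = float(threshold)
    return {
        "treat_none": Strategy("Treat none", "treat_none", threshold=t),
        "treat_all": Strategy("Treat all", "treat_all", threshold=t),
        "mindact": Strategy("Treat C-H/G-H risk", "mindact_rule", threshold=t),
        "clinical": Strategy("Clinical risk assessment, continuous",
                             "benefit_threshold", InformationSet.CLINICAL, t),
        "mp": Strategy("Clinical + binary MammaPrint",
                       "benefit_threshold", InformationSet.CLINICAL_MP, t),
        "otbin": Strategy("Clinical + binary OncotypeDX",
                          "benefit_threshold",
                          InformationSet.CLINICAL_OT_BINARY, t),
        "otcont": Strategy("Clinical + continuous OncotypeDX",
                           "benefit_threshold",
                           InformationSet.CLINICAL_OT_CONTINUOUS, t),
    }


# ---------------------------------------------------------------------- #
# expected-mode outcomes by quadrature (no cohort required)


def _threshold_regions(model: BenefitModel, strategy: Strategy):
    """Per-state clinical-score decision boundaries for threshold rules."""
    t = strategy.threshold
    if strategy.info is InformationSet.CLINICAL:
        return {"clin": model.crossing("clin", t)}
    if strategy.info is InformationSet.CLINICAL_MP:
        return {0: model.crossing(("mp", 0), t), 1: model.crossing(("mp", 1), t)}
    if strategy.info is InformationSet.CLINICAL_OT_BINARY:
        return {0: model.crossing(("otbin", 0), t),
                1: model.crossing(("otbin", 1), t)}
    raise ValueError(strategy.info)


def expected_outcome(model: BenefitModel, strategy: Strategy) -> StrategyOutcome:
    """Deterministic population outcome of a strategy (per 1000)."""
    p = model.params
    t = w = strategy.threshold
    m = model.moments()
    e_r0 = m["e_r0"]

    if strategy.rule == "treat_none":
        treated = prevented = tests = 0.0
    elif strategy.rule == "treat_all":
        treated, prevented, tests = 1.0, m["e_benefit"], 0.0
    elif strategy.rule == "mindact_rule":
        c = p.clinical_high_cutoff
        tests = model.zc_prob(c, np.inf)
        treated = model.zc_integral(p.p_mp_high_given_zc, c, np.inf)
        prevented = model.zc_integral(
            lambda z: p.p_mp_high_given_zc(z) * model.lookup(("mp", 1), z),
            c, np.inf)
    elif strategy.info is InformationSet.CLINICAL:
        z_star = _threshold_regions(model, strategy)["clin"]
        treated = model.zc_prob(z_star, np.inf)
        prevented = model.zc_integral(lambda z: model.lookup("clin", z),
                                      z_star, np.inf)
        tests = 0.0
    elif strategy.info in (InformationSet.CLINICAL_MP,
                           InformationSet.CLINICAL_OT_BINARY):
        bounds = _threshold_regions(model, strategy)
        key = "mp" if strategy.info is InformationSet.CLINICAL_MP else "otbin"
        if key == "mp":
            p_state = {1: p.p_mp_high_given_zc,
                       0: lambda z: 1.0 - p.p_mp_high_given_zc(z)}
        else:
            p_state = {1: p.p_ot_high_given_zc,
                       0: lambda z: 1.0 - p.p_ot_high_given_zc(z)}
        treated = sum(model.zc_integral(p_state[s], bounds[s], np.inf)
                      for s in (0, 1))
        prevented = sum(
            model.zc_integral(
                lambda z, s=s: p_state[s](z) * model.lookup((key, s), z),
                bounds[s], np.inf)
            for s in (0, 1))
        tests = testing_window(model, strategy.info, t).fraction_tested
    else:  # continuous OncotypeDX
        win = testing_window(model, strategy.info, t)
        z_clin = model.crossing("clin", t)
        tests = win.fraction_tested
        if tests == 0.0:
            treated = model.zc_prob(z_clin, np.inf)
            prevented = model.zc_integral(lambda z: model.lookup("clin", z),
                                          z_clin, np.inf)
        else:
            z_lo, z_hi = win.z_lower, win.z_upper
            z, zw = model.zc_nodes(z_lo, z_hi)
            s_lo, s_hi = model.zot_treat_interval(z, t)
            treated = float(np.sum(model.p_zot_between(z, s_lo, s_hi) * zw))
            prevented = float(np.sum(
                model.expect_benefit_zot_between(z, s_lo, s_hi) * zw))
            # outside the window the clinical-only decision stands
            segments = [(max(z_clin, z_hi), np.inf)]
            if z_clin < z_lo:
                segments.append((z_clin, z_lo))
            for lo, hi in segments:
                treated += model.zc_prob(lo, hi)
                prevented += model.zc_integral(
                    lambda z: model.lookup("clin", z), lo, hi)

    events = e_r0 - prevented
    nb = net_benefit_per_1000(1000.0 * prevented, 1000.0 * treated, w)
    return StrategyOutcome(
        label=strategy.label, mode="expected",
        expected_events=1000.0 * events,
        prevented_events=1000.0 * prevented,
        n_treated=1000.0 * treated,
        n_tests=1000.0 * tests,
        net_benefit=float(nb), threshold=t)


# ---------------------------------------------------------------------- #
# per-patient allocation and cohort-based evaluation


def allocate(model: BenefitModel, cohort: pd.DataFrame, strategy: Strategy):
    """Treatment indication and tested flag for every patient.

    Returns ``(treat, tested)`` boolean arrays.  Decisions are
    deterministic functions of the observed scores, so the allocation is
    identical in expected and realized mode.
    """
    p = model.params
    z_c = cohort["z_c"].to_numpy()
    t = strategy.threshold
    n = len(cohort)
    tested = np.zeros(n, dtype=bool)

    if strategy.rule == "treat_none":
        return np.zeros(n, dtype=bool), tested
    if strategy.rule == "treat_all":
        return np.ones(n, dtype=bool), tested
    if strategy.rule == "mindact_rule":
        ch = cohort["clinical_high"].to_numpy().astype(bool)
        mp = cohort["mp_high"].to_numpy().astype(bool)
        return ch & mp, ch

    info = strategy.info
    if info is InformationSet.CLINICAL:
        treat = z_c > model.crossing("clin", t)
        return treat, tested
    if info in (InformationSet.CLINICAL_MP, InformationSet.CLINICAL_OT_BINARY):
        bounds = _threshold_regions(model, strategy)
        if info is InformationSet.CLINICAL_MP:
            state = cohort["mp_high"].to_numpy().astype(int)
        else:
            state = cohort["ot_high"].to_numpy().astype(int)
        z_state = np.where(state == 1, bounds[1], bounds[0])
        treat = z_c > z_state
        z_lo, z_hi = min(bounds[1], bounds[0]), max(bounds[1], bounds[0])
        tested = (z_c > z_lo) & (z_c <= z_hi) & (bounds[1] < bounds[0])
        return treat, tested
    # continuous OncotypeDX
    win = testing_window(model, info, t)
    z_clin = model.crossing("clin", t)
    clin_treat = z_c > z_clin
    if win.fraction_tested == 0.0:
        return clin_treat, tested
    tested = (z_c > win.z_lower) & (z_c <= win.z_upper)
    treat = clin_treat.copy()
    if tested.any():
        b = model.benefit_cont(z_c[tested], cohort["z_ot"].to_numpy()[tested])
        treat[tested] = b > t
    return treat, tested


def evaluate(model: BenefitModel, cohort: pd.DataFrame, strategy: Strategy,
             mode: str = "expected") -> StrategyOutcome:
    """Cohort-based outcome of a strategy, per 1000 patients.

    Expected mode sums true risk pairs; realized mode counts the outcome
    of the appropriate digital twin (treated twin if treated).
    """
    if mode not in ("expected", "realized"):
        raise ValueError(f"unknown mode {mode!r}")
    treat, tested = allocate(model, cohort, strategy)
    n = len(cohort)
    if mode == "expected":
        r0 = cohort["r0"].to_numpy()
        r1 = cohort["r1"].to_numpy()
        events = np.where(treat, r1, r0).sum() / n
        prevented = (treat * (r0 - r1)).sum() / n
    else:
        y0 = cohort["y0"].to_numpy().astype(float)
        y1 = cohort["y1"].to_numpy().astype(float)
        events = np.where(treat, y1, y0).sum() / n
        prevented = (treat * (y0 - y1)).sum() / n
    w = strategy.threshold
    nb = net_benefit_per_1000(1000.0 * prevented, 1000.0 * treat.mean(), w)
    return StrategyOutcome(
        label=strategy.label, mode=mode,
        expected_events=1000.0 * events,
        prevented_events=1000.0 * prevented,
        n_treated=1000.0 * treat.mean(),
        n_tests=1000.0 * tested.mean(),
        net_benefit=float(nb), threshold=w)


# ---------------------------------------------------------------------- #
# reports


def outcome_table(model: BenefitModel, threshold: float = 0.05,
                  cohort: pd.DataFrame | None = None,
                  mode: str = "expected") -> pd.DataFrame:
    """Seven-row strategy outcome table (the main per-1000 summary).

    Without a cohort, outcomes are exact expectations by quadrature; with
    one, they are cohort averages in the requested mode.
    """
    rows = []
    for key, strat in standard_strategies(threshold).items():
        if cohort is None:
            o = expected_outcome(model, strat)
        else:
            o = evaluate(model, cohort, strat, mode=mode)
        rows.append({"strategy": key, "label": strat.label,
                     **{k: v for k, v in o.as_dict().items()
                        if k not in ("label",)}})
    return pd.DataFrame(rows)


def format_outcome_table(table: pd.DataFrame) -> pd.DataFrame:
    """Presentation rounding: integer counts, one-decimal Net Benefit."""
    out = table.copy()
    for col in ("expected_events", "prevented_events", "n_treated", "n_tests"):
        out[col] = out[col].round(0).astype(int)
    out["net_benefit"] = out["net_benefit"].round(1)
    return out


@dataclasses.dataclass(frozen=True)
class ReclassificationTable:
    """Cross-classification of pre- vs post-test treatment decisions.

    Fractions are of the total population, split by the untreated twin's
    event status.  A reclassification is *correct* when it moves the
    decision toward that twin's outcome: to-treat for an event, to-no-treat
    for a non-event.
    """

    info: InformationSet
    threshold: float
    table: pd.DataFrame          # columns: pre_treat, post_treat, event_untreated, fraction
    total_reclassified: float
    to_treat: float
    to_no_treat: float
    correct: float
    incorrect: float


def reclassification_table(model: BenefitModel, cohort: pd.DataFrame,
                           base: Strategy, genomic: Strategy) -> ReclassificationTable:
    """Realized-mode reclassification cross-tab between two strategies."""
    if base.threshold != genomic.threshold:
        raise ValueError("strategies must share the treatment threshold")
    pre, _ = allocate(model, cohort, base)
    post, _ = allocate(model, cohort, genomic)
    y0 = cohort["y0"].to_numpy().astype(bool)
    n = len(cohort)
    rows = []
    for a in (False, True):
        for b in (False, True):
            for e in (False, True):
                frac = np.sum((pre == a) & (post == b) & (y0 == e)) / n
                rows.append({"pre_treat": a, "post_treat": b,
                             "event_untreated": e, "fraction": frac})
    df = pd.DataFrame(rows)
    to_treat = float(np.mean(~pre & post))
    to_no = float(np.mean(pre & ~post))
    correct = float(np.mean((~pre & post & y0) | (pre & ~post & ~y0)))
    incorrect = to_treat + to_no - correct
    return ReclassificationTable(
        info=genomic.info, threshold=genomic.threshold, table=df,
        total_reclassified=to_treat + to_no, to_treat=to_treat,
        to_no_treat=to_no, correct=correct, incorrect=incorrect)


def reclassification_summary(model: BenefitModel, info: InformationSet,
                             threshold: float) -> dict:
    """Expected-mode reclassification marginals (population fractions)."""
    p = model.params
    t = float(threshold)
    info = InformationSet(info)
    z_clin = model.crossing("clin", t)
    if info in (InformationSet.CLINICAL_MP, InformationSet.CLINICAL_OT_BINARY):
        strat = Strategy("tmp", "benefit_threshold", info, t)
        bounds = _threshold_regions(model, strat)
        if info is InformationSet.CLINICAL_MP:
            p_hi = p.p_mp_high_given_zc
        else:
            p_hi = p.p_ot_high_given_zc
        to_treat = model.zc_integral(p_hi, bounds[1], min(z_clin, bounds[0]))
        to_no = model.zc_integral(lambda z: 1.0 - p_hi(z),
                                  max(z_clin, bounds[1]), bounds[0])
    elif info is InformationSet.CLINICAL_OT_CONTINUOUS:
        win = testing_window(model, info, t)
        if win.fraction_tested == 0.0:
            to_treat = to_no = 0.0
        else:
            def frac_treat(z):
                return model.p_zot_between(z, *model.zot_treat_interval(z, t))
            to_treat = model.zc_integral(frac_treat, win.z_lower,
                                         min(z_clin, win.z_upper))
            to_no = model.zc_integral(lambda z: 1.0 - frac_treat(z),
                                      max(z_clin, win.z_lower), win.z_upper)
    else:
        raise ValueError("reclassification requires a genomic information set")
    return {"to_treat": float(to_treat), "to_no_treat": float(to_no),
            "total": float(to_treat + to_no)}


def decision_curve(model: BenefitModel, thresholds=None,
                   cohort: pd.DataFrame | None = None,
                   mode: str = "expected") -> pd.DataFrame:
    """Net Benefit of every standard strategy across a threshold grid.

    Strategies are re-derived at every threshold (both the decision rule
    and the testing window depend on it).  ``delta_nb`` is the improvement
    of each genomic strategy over clinical-only at the same threshold.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.005, 0.2001, 0.005), 10)
    rows = []
    for t in np.atleast_1d(thresholds):
        strats = standard_strategies(float(t))
        outs = {}
        for key, strat in strats.items():
            if cohort is None:
                outs[key] = expected_outcome(model, strat)
            else:
                outs[key] = evaluate(model, cohort, strat, mode=mode)
        nb_clin = outs["clinical"].net_benefit
        for key, o in outs.items():
            delta = (o.net_benefit - nb_clin
                     if key in ("mp", "otbin", "otcont") else np.nan)
            rows.append({"threshold": float(t), "strategy": key,
                         "net_benefit": o.net_benefit, "delta_nb": delta,
                         "n_treated": o.n_treated, "n_tests": o.n_tests,
                         "prevented_events": o.prevented_events})
    return pd.DataFrame(rows)
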