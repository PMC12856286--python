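"""Uncertainty by trial-sized subsampling, and input sensitivity grids.

The subsampling interval answers whether one genomic test convincingly
outperforms another at realistic trial sizes: the difference in Net
Benefit between two strategies is re-estimated in many subsamples of the
synthetic cohort drawn without replacement at the trial's sample size,
and summarised by a percentile interval.  Decisions are fixed from the
full-cohort benefit model; only the outcome and treatment tallies are
resampled, mirroring re-estimation of the Net Benefit rather than of the
model.

The sensitivity grid varies the quality of the clinical reference model
(a multiplier on its log-hazard coefficient, with baseline survival
re-solved so the cohort event rate is unchanged) and the chemotherapy
hazard ratio, and reports how much each genomic test adds to Net Benefit
in every cell.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize

from .benefit import BenefitModel
from .params import DGPParams
from .strategies import Strategy, allocate, expected_outcome, standard_strategies

#: Default ranges of the sensitivity grid.
HR_VALUES = (0.64, 0.70, 0.76, 0.82, 1.0)
CLINICAL_MULTIPLIERS = (0.75, 1.0, 1.25, 1.5)


@dataclasses.dataclass(frozen=True)
class SubsampleCI:
    """Percentile CI of a between-strategy Net Benefit difference."""

    thresholds: np.ndarray
    mean: np.ndarray
    lower: np.ndarray       # 2.5th percentile
    upper: np.ndarray       # 97.5th percentile
    full_cohort: np.ndarray
    n_subsample: int
    n_replicates: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds, "delta_nb_mean": self.mean,
            "ci_lower": self.lower, "ci_upper": self.upper,
            "delta_nb_full": self.full_cohort,
        })


def subsample_ci(model: BenefitModel, cohort: pd.DataFrame,
                 strategy_pair=("otcont", "mp"), thresholds=None,
                 n_sub: int = 6693, n_rep: int = 1000,
                 seed: int = 0) -> SubsampleCI:
    """Subsampled 95% CI of ΔNB between two strategies across thresholds.

    ``strategy_pair`` names two standard strategies (first minus second).
    Subsamples are drawn without replacement; with ``n_sub`` equal to the
    cohort size the interval collapses onto the full-cohort value.
    """
    n = len(cohort)
    if n_sub > n:
        raise ValueError(f"n_sub={n_sub} exceeds cohort size {n}")
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 0.2001, 0.01), 10)
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    y0 = cohort["y0"].to_numpy().astype(float)
    y1 = cohort["y1"].to_numpy().astype(float)

    rng = np.random.default_rng(seed)
    if n_sub == n:
        idx = np.broadcast_to(np.arange(n), (n_rep, n))
    else:
        idx = np.empty((n_rep, n_sub), dtype=np.int64)
        for r in range(n_rep):
            idx[r] = rng.choice(n, size=n_sub, replace=False)

    mean = np.empty_like(thresholds)
    lower = np.empty_like(thresholds)
    upper = np.empty_like(thresholds)
    full = np.empty_like(thresholds)
    for j, t in enumerate(thresholds):
        strats = standard_strategies(float(t))
        contrib = np.zeros(n)
        for sign, key in ((1.0, strategy_pair[0]), (-1.0, strategy_pair[1])):
            treat, _ = allocate(model, cohort, strats[key])
            # per-patient NB contribution: prevented minus weighted treatment
            contrib += sign * (treat * (y0 - y1) - t * treat)
        full[j] = 1000.0 * contrib.mean()
        reps = 1000.0 * contrib[idx].mean(axis=1)
        mean[j] = reps.mean()
        lower[j], upper[j] = np.percentile(reps, [2.5, 97.5])
    return SubsampleCI(thresholds=thresholds, mean=mean, lower=lower,
                       upper=upper, full_cohort=full, n_subsample=n_sub,
                       n_replicates=n_rep, seed=seed)


# ---------------------------------------------------------------------- #
# sensitivity grid


def _solve_s0_for_event_rate(params: DGPParams, target_e_r0: float,
                             profile: str = "fast") -> DGPParams:
    """Re-solve the baseline survival so E[r0] matches a target rate.

    Used when rescaling the clinical coefficient, isolating the model's
    discrimination from the cohort's baseline risk.
    """
    def gap(s0):
        m = BenefitModel(params.replace(s0_10=s0), profile=profile).moments()
        return m["e_r0"] - target_e_r0

    s0 = optimize.brentq(gap, 0.60, 0.995, xtol=1e-10)
    return params.replace(s0_10=float(s0))


def sensitivity_grid(base: DGPParams, hr_values=HR_VALUES,
                     clinical_multipliers=CLINICAL_MULTIPLIERS,
                     threshold: float = 0.05,
                     profile: str = "fast") -> pd.DataFrame:
    """ΔNB of each genomic strategy over a (HR, clinical-strength) grid.

    Every cell reports the expected-mode improvement in Net Benefit of
    the three genomic strategies over clinical-only decisions at the
    given threshold.  The untreated event rate is held at the base
    cohort's value in every cell.
    """
    base_beta_c = base.beta_c
    target = BenefitModel(base, profile=profile).moments()["e_r0"]
    rows = []
    for mult in clinical_multipliers:
        scaled = base.replace(beta_c=base_beta_c * float(mult))
        scaled = _solve_s0_for_event_rate(scaled, target, profile=profile)
        for hr in hr_values:
            p = scaled.replace(hr_chemo=float(hr))
            model = BenefitModel(p, profile=profile)
            outs = {k: expected_outcome(model, s)
                    for k, s in standard_strategies(threshold).items()}
            nb_clin = outs["clinical"].net_benefit
            rows.append({
                "hr_chemo": float(hr),
                "clinical_multiplier": float(mult),
                "s0_10": p.s0_10,
                "nb_clinical": nb_clin,
                "delta_nb_mp": outs["mp"].net_benefit - nb_clin,
                "delta_nb_otbin": outs["otbin"].net_benefit - nb_clin,
                "delta_nb_otcont": outs["otcont"].net_benefit - nb_clin,
                "prevented_treat_all": outs["treat_all"].prevented_events,
            })
    return pd.DataFrame(rows)
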