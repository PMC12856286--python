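"""Synthetic digital-twin cohorts.

Each patient is a draw of three correlated latent scores; the observed
test results (continuous clinical risk, binary MammaPrint, 0-100
OncotypeDX) are deterministic functions of the latents.  Every patient is
cloned into a treated and an untreated twin whose 10-year potential
outcomes are coupled through one shared uniform draw, so the treated
twin's event indicator can never exceed the untreated twin's and the
per-pair "event prevented by treatment" indicator is exactly ``y0 - y1``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .benefit import BenefitModel
from .params import DGPParams, InvalidParameterError, ot_score_from_latent
from .risk import apply_treatment_effect, ten_year_risk

COHORT_NAMES = ("mindact", "tailorx")

#: Column order of a cohort table.  z-scores are latent; the rest are
#: observed results, true risk pairs, and coupled potential outcomes.
COHORT_COLUMNS = [
    "id", "z_c", "z_mp", "z_ot",
    "clinical_risk_score", "clinical_high",
    "mp_high", "ot_score", "ot_high",
    "r0", "r1", "y0", "y1",
]


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Which cohort to generate, how large, and from which seed."""

    name: str
    n_patients: int = 1_000_000
    seed: int = 0
    params: DGPParams = dataclasses.field(default_factory=DGPParams)

    def __post_init__(self):
        if self.name not in COHORT_NAMES:
            raise ValueError(f"cohort name must be one of {COHORT_NAMES}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


def sample_latents(config: CohortConfig) -> pd.DataFrame:
    """Draw correlated latent scores for every patient.

    The clinical score has margin ``N(mu_c, sigma_c^2)`` on the reference
    scale; the genomic latents follow their fixed conditional law given
    the clinical score (standard-normal margins when the cohort is the
    reference one).
    """
    p = config.params
    p.validate()
    rng = np.random.default_rng(config.seed)
    eps = rng.standard_normal((config.n_patients, 3))
    z_c = p.mu_c + p.sigma_c * eps[:, 0]
    z_mp = p.rho_c_mp * z_c + p.s_mp_given_c * eps[:, 1]
    z_ot = (p.rho_c_ot * z_c
            + p.l32 * eps[:, 1]
            + p.l33 * eps[:, 2])
    return pd.DataFrame({
        "id": np.arange(config.n_patients),
        "z_c": z_c, "z_mp": z_mp, "z_ot": z_ot,
    })


def derive_scores(latents: pd.DataFrame, params: DGPParams,
                  model: BenefitModel | None = None) -> pd.DataFrame:
    """Attach the observed test results to a latent table.

    ``clinical_risk_score`` is the observable continuous clinical risk,
    defined as the expected untreated 10-year risk given the clinical
    latent (looked up on the benefit model's grid).
    """
    df = latents.copy()
    df["mp_high"] = df["z_mp"].to_numpy() > params.mp_latent_cutoff
    ot = ot_score_from_latent(df["z_ot"].to_numpy(), params.ot_a,
                              params.ot_b, exact=True)
    if np.any(ot < 0.0) or np.any(ot > 100.0):
        raise InvalidParameterError("OncotypeDX scores fell outside [0,100]")
    df["ot_score"] = ot
    df["ot_high"] = ot >= 26.0
    df["clinical_high"] = df["z_c"].to_numpy() > params.clinical_high_cutoff
    if model is None:
        model = BenefitModel(params)
    df["clinical_risk_score"] = model.lookup("r0_clin", df["z_c"].to_numpy())
    return df


def assign_risks(scores: pd.DataFrame, params: DGPParams) -> pd.DataFrame:
    """True 10-year risk with and without chemotherapy for every patient."""
    df = scores.copy()
    ot_std = (df["ot_score"].to_numpy() - params.ot_mean) / params.ot_sd
    lp = (params.beta_c * df["z_c"].to_numpy()
          + params.beta_mp * df["mp_high"].to_numpy().astype(float)
          + params.beta_ot * ot_std)
    r0 = ten_year_risk(lp, params.s0_10)
    df["r0"] = r0
    df["r1"] = apply_treatment_effect(r0, params.hr_chemo)
    return df


def simulate_outcomes(cohort: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Coupled potential outcomes for both twins of every patient.

    One uniform draw per pair: ``y0 = u < r0`` and ``y1 = u < r1``, so
    ``y1 <= y0`` holds with probability one (monotone coupling).
    """
    df = cohort.copy()
    rng = np.random.default_rng(seed)
    u = rng.random(len(df))
    df["y0"] = u < df["r0"].to_numpy()
    df["y1"] = u < df["r1"].to_numpy()
    return df


def generate_cohort(config: CohortConfig,
                    model: BenefitModel | None = None) -> pd.DataFrame:
    """Full pipeline: latents -> scores -> risks -> coupled outcomes.

    The outcome seed is derived from the config seed so that one seed
    reproduces the whole table bit-identically.
    """
    if model is None:
        model = BenefitModel(config.params)
    df = sample_latents(config)
    df = derive_scores(df, config.params, model=model)
    df = assign_risks(df, config.params)
    df = simulate_outcomes(df, seed=config.seed + 1)
    df.attrs["config"] = config
    return df[COHORT_COLUMNS]


def cross_cohort_adjust(params: DGPParams,
                        target_low_fraction: float) -> DGPParams:
    """Shift the clinical margin so P(clinical low) hits a target fraction.

    Only ``mu_c`` moves; the genomic conditional law and the marker
    coefficients are unchanged, so the genomic score distributions shift
    implicitly through their correlation with the clinical score.  This
    is how a cohort with, e.g., 70% clinical-low patients is derived from
    the reference parameters.
    """
    if not (0.0 < target_low_fraction < 1.0):
        raise InvalidParameterError(
            f"target_low_fraction must be in (0,1), got {target_low_fraction}")
    mu_new = (params.clinical_high_cutoff
              - params.sigma_c * float(stats.norm.ppf(target_low_fraction)))
    if np.isclose(mu_new, params.mu_c, atol=1e-12):
        return params
    return params.replace(mu_c=mu_new)


# ---------------------------------------------------------------------- #
# cohort I/O: CSV table + JSON sidecar with config, params and seed


def _config_hash(config: CohortConfig) -> str:
    payload = {"name": config.name, "n_patients": config.n_patients,
               "seed": config.seed, "params": config.params.to_dict()}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    path = Path(path)
    cohort.to_csv(path, index=False)
    config = cohort.attrs.get("config")
    if config is not None:
        sidecar = {
            "name": config.name, "n_patients": config.n_patients,
            "seed": config.seed, "params": config.params.to_dict(),
            "config_hash": _config_hash(config),
            "columns": list(cohort.columns),
        }
        path.with_suffix(".json").write_text(
            json.dumps(sidecar, indent=2) + "\n")


def read_cohort(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        df.attrs["config"] = CohortConfig(
            name=meta["name"], n_patients=meta["n_patients"],
            seed=meta["seed"], params=DGPParams.from_dict(meta["params"]))
    return df
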