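"""Parameters of the data-generating process behind the synthetic twin cohorts.

The generator couples three scores through a trivariate Gaussian copula:

* a continuous latent clinical prognostic score ``z_c`` (margin
  ``N(mu_c, sigma_c^2)`` on a fixed reference scale, with the MINDACT-like
  cohort as the reference at ``mu_c = 0, sigma_c = 1``),
* a latent MammaPrint score ``z_mp``, dichotomised at ``mp_latent_cutoff``
  into the observed high/low MammaPrint result,
* a latent OncotypeDX score ``z_ot``, mapped through a Beta(ot_a, ot_b)
  marginal onto the observed 0-100 recurrence score (dichotomised at 25/26).

Cohort shifts (e.g. a population with more clinical low-risk patients) move
only the ``z_c`` margin; the conditional law of the genomic latents given
``z_c`` is held fixed, so the genomic score distributions shift implicitly
through their correlation with clinical risk while the prognostic model
itself is unchanged.
"""

from __future__ import annotations

import dataclasses
import json
import math
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import special, stats


class InvalidParameterError(ValueError):
    """A parameter set violates its domain constraints."""


#: Standard-normal quantile giving a 50.1% clinical-high fraction on the
#: reference scale (the MINDACT-like split of the clinical score).
CLINICAL_HIGH_CUTOFF_DEFAULT = float(stats.norm.ppf(1.0 - 0.501))


@dataclasses.dataclass(frozen=True)
class DGPParams:
    """All coefficients, correlations, thresholds and baseline survival.

    The proportional-hazards outcome model is
    ``S(10 | lp) = s0_10 ** exp(lp)`` with linear predictor
    ``lp = beta_c * z_c + beta_mp * mp_high + beta_ot * ot_std`` where
    ``ot_std`` is the observed OncotypeDX score standardised by the
    reference Beta marginal's mean and SD.  Chemotherapy multiplies the
    hazard by ``hr_chemo``.
    """

    # survival model
    s0_10: float = 0.89       # baseline 10-year event-free probability at lp = 0
    beta_c: float = 0.70      # log-hazard per reference SD of the clinical score
    beta_mp: float = 0.40     # log-hazard for MammaPrint high vs low
    beta_ot: float = 0.50     # log-hazard per reference SD of the OncotypeDX score
    hr_chemo: float = 0.64    # chemotherapy hazard ratio
    # latent correlations (Gaussian copula)
    rho_c_mp: float = 0.55
    rho_c_ot: float = 0.55
    rho_mp_ot: float = 0.75
    # observation cutoffs
    mp_latent_cutoff: float = 0.10
    clinical_high_cutoff: float = CLINICAL_HIGH_CUTOFF_DEFAULT
    # OncotypeDX marginal: Beta(ot_a, ot_b) scaled to [0, 100], cut at 26.
    # Shape anchored to the published TAILORx recurrence-score
    # distribution: P(score <= 10) = 0.17 and P(score >= 26) = 0.14.
    ot_a: float = 4.007084847356822
    ot_b: float = 18.95232851182243
    # cohort shift of the clinical margin on the reference scale
    mu_c: float = 0.0
    sigma_c: float = 1.0

    # ------------------------------------------------------------------ #
    # validation

    def validate(self) -> None:
        if not (0.0 < self.s0_10 < 1.0):
            raise InvalidParameterError(f"s0_10 must be in (0,1), got {self.s0_10}")
        if not (0.0 < self.hr_chemo <= 1.0):
            raise InvalidParameterError(f"hr_chemo must be in (0,1], got {self.hr_chemo}")
        for name in ("beta_c", "beta_mp", "beta_ot"):
            if getattr(self, name) < 0.0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.sigma_c <= 0.0:
            raise InvalidParameterError("sigma_c must be > 0")
        if self.ot_a <= 0.0 or self.ot_b <= 0.0:
            raise InvalidParameterError("Beta marginal parameters must be > 0")
        for name in ("rho_c_mp", "rho_c_ot", "rho_mp_ot"):
            if not (-1.0 < getattr(self, name) < 1.0):
                raise InvalidParameterError(f"{name} must be in (-1,1)")
        if np.linalg.eigvalsh(self.corr_matrix).min() < -1e-10:
            raise InvalidParameterError("latent correlation matrix is not PSD")
        if self.l33_sq <= 1e-12:
            raise InvalidParameterError(
                "correlations leave no residual variance for the OncotypeDX latent"
            )

    @property
    def corr_matrix(self) -> np.ndarray:
        """3x3 correlation matrix of (z_c_std, z_mp, z_ot) on the reference scale."""
        return np.array(
            [
                [1.0, self.rho_c_mp, self.rho_c_ot],
                [self.rho_c_mp, 1.0, self.rho_mp_ot],
                [self.rho_c_ot, self.rho_mp_ot, 1.0],
            ]
        )

    # ------------------------------------------------------------------ #
    # conditional-Gaussian constants (derived from the copula)

    @property
    def s_mp_given_c(self) -> float:
        """SD of z_mp | z_c."""
        return math.sqrt(1.0 - self.rho_c_mp**2)

    @property
    def s_ot_given_c(self) -> float:
        """SD of z_ot | z_c."""
        return math.sqrt(1.0 - self.rho_c_ot**2)

    @property
    def l32(self) -> float:
        """Loading of z_ot on the mp-specific innovation (Cholesky term)."""
        return (self.rho_mp_ot - self.rho_c_mp * self.rho_c_ot) / self.s_mp_given_c

    @property
    def l33_sq(self) -> float:
        return 1.0 - self.rho_c_ot**2 - self.l32**2

    @property
    def l33(self) -> float:
        """SD of z_ot | (z_c, z_mp)."""
        return math.sqrt(max(self.l33_sq, 0.0))

    @property
    def kappa_ot(self) -> float:
        """Regression slope of z_mp on z_ot given z_c."""
        return (self.rho_mp_ot - self.rho_c_mp * self.rho_c_ot) / (1.0 - self.rho_c_ot**2)

    @property
    def s_mp_given_c_ot(self) -> float:
        """SD of z_mp | (z_c, z_ot)."""
        var = 1.0 - self.rho_c_mp**2 - self.kappa_ot**2 * (1.0 - self.rho_c_ot**2)
        return math.sqrt(max(var, 0.0))

    # ------------------------------------------------------------------ #
    # OncotypeDX marginal

    @property
    def ot_mean(self) -> float:
        """Reference mean of the 0-100 OncotypeDX score."""
        return 100.0 * self.ot_a / (self.ot_a + self.ot_b)

    @property
    def ot_sd(self) -> float:
        """Reference SD of the 0-100 OncotypeDX score."""
        a, b = self.ot_a, self.ot_b
        return 100.0 * math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))

    @property
    def ot_cut_z(self) -> float:
        """Latent cutoff equivalent to OncotypeDX score >= 26."""
        return float(special.ndtri(special.betainc(self.ot_a, self.ot_b, 0.26)))

    # ------------------------------------------------------------------ #
    # conditional probabilities

    def p_mp_high_given_zc(self, z_c):
        """P(MammaPrint high | z_c) on the reference scale."""
        z_c = np.asarray(z_c, dtype=float)
        return special.ndtr(
            (self.rho_c_mp * z_c - self.mp_latent_cutoff) / self.s_mp_given_c
        )

    def p_ot_high_given_zc(self, z_c):
        """P(OncotypeDX >= 26 | z_c)."""
        z_c = np.asarray(z_c, dtype=float)
        return special.ndtr((self.rho_c_ot * z_c - self.ot_cut_z) / self.s_ot_given_c)

    def p_mp_high_given_zc_zot(self, z_c, z_ot):
        """P(MammaPrint high | z_c, z_ot)."""
        z_c = np.asarray(z_c, dtype=float)
        z_ot = np.asarray(z_ot, dtype=float)
        mean = self.rho_c_mp * z_c + self.kappa_ot * (z_ot - self.rho_c_ot * z_c)
        return special.ndtr((mean - self.mp_latent_cutoff) / self.s_mp_given_c_ot)

    # ------------------------------------------------------------------ #
    # marginal fractions (closed forms)

    @property
    def frac_clinical_high(self) -> float:
        """P(clinical high) = P(z_c > clinical_high_cutoff)."""
        return float(
            special.ndtr((self.mu_c - self.clinical_high_cutoff) / self.sigma_c)
        )

    @property
    def frac_mp_high(self) -> float:
        """Marginal P(MammaPrint high) under the cohort's z_c margin."""
        num = self.rho_c_mp * self.mu_c - self.mp_latent_cutoff
        den = math.sqrt(self.rho_c_mp**2 * self.sigma_c**2 + 1.0 - self.rho_c_mp**2)
        return float(special.ndtr(num / den))

    @property
    def frac_ot_high(self) -> float:
        """Marginal P(OncotypeDX >= 26) under the cohort's z_c margin."""
        num = self.rho_c_ot * self.mu_c - self.ot_cut_z
        den = math.sqrt(self.rho_c_ot**2 * self.sigma_c**2 + 1.0 - self.rho_c_ot**2)
        return float(special.ndtr(num / den))

    # ------------------------------------------------------------------ #
    # utilities

    def replace(self, **changes) -> "DGPParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DGPParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "DGPParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------- #
# OncotypeDX latent -> score transform

@lru_cache(maxsize=8)
def _ot_transform_table(a: float, b: float):
    """Dense monotone table of 100 * BetaInv(Phi(z); a, b) for fast lookup."""
    z = np.linspace(-9.0, 9.0, 6001)
    score = 100.0 * special.betaincinv(a, b, special.ndtr(z))
    return z, score


def ot_score_from_latent(z_ot, a: float, b: float, exact: bool = False):
    """Map a standard-normal OncotypeDX latent onto the 0-100 score scale.

    The exact path evaluates the inverse regularised incomplete beta
    function; the default path interpolates a cached 6001-point table
    (max absolute error ~1e-3 on the 0-100 scale), which is what the
    quadrature engine uses in its inner loops.
    """
    if exact:
        u = special.ndtr(np.asarray(z_ot, dtype=float))
        return 100.0 * special.betaincinv(a, b, u)
    zt, st = _ot_transform_table(float(a), float(b))
    return np.interp(z_ot, zt, st)
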