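"""Risk arithmetic shared by every stage of the pipeline.

All survival-time machinery is collapsed to the 10-year cumulative risk:
the proportional-hazards model enters only through
``S(10 | lp) = s0_10 ** exp(lp)``, and a treatment hazard ratio ``hr``
acts on the survival scale as ``S -> S ** hr``.  Every quantity the
pipeline reports is a 10-year event count, so this collapse leaves all
expectations unchanged while avoiding time-to-event draws.
"""

from __future__ import annotations

import numpy as np

from .params import InvalidParameterError

__all__ = [
    "ten_year_risk",
    "apply_treatment_effect",
    "treatment_benefit",
    "net_benefit_per_1000",
    "threshold_to_weight",
]

# exp(lp) overflows past ~709; beyond this the survival probability is
# already an exact 0 in double precision, so clipping is lossless.
_LP_MAX = 500.0


def _event_free(lp, s0_10: float):
    """S(10) = s0_10 ** exp(lp), numerically safe for extreme lp."""
    lp = np.asarray(lp, dtype=float)
    return np.exp(np.exp(np.minimum(lp, _LP_MAX)) * np.log(s0_10))


def ten_year_risk(lp, s0_10: float):
    """10-year event risk ``1 - s0_10 ** exp(lp)``.

    Strictly increasing in the linear predictor ``lp``; ``s0_10`` is the
    event-free probability of a patient with ``lp = 0``.
    """
    if not (0.0 < s0_10 < 1.0):
        raise InvalidParameterError(f"s0_10 must be in (0,1), got {s0_10}")
    out = 1.0 - _event_free(lp, s0_10)
    return float(out) if np.isscalar(lp) else out


def apply_treatment_effect(r0, hr: float):
    """Treated risk ``r1 = 1 - (1 - r0) ** hr`` for a hazard ratio ``hr``."""
    if hr <= 0.0:
        raise InvalidParameterError(f"hazard ratio must be > 0, got {hr}")
    r0_arr = np.asarray(r0, dtype=float)
    if np.any(r0_arr < 0.0) or np.any(r0_arr > 1.0):
        raise InvalidParameterError("r0 must lie in [0,1]")
    out = 1.0 - (1.0 - r0_arr) ** hr
    return float(out) if np.isscalar(r0) else out


def treatment_benefit(lp, s0_10: float, hr: float):
    """Absolute risk reduction ``r0 - r1 = S**hr - S`` at a given lp.

    Used in the quadrature engine's inner loops; identical to
    ``ten_year_risk(lp) - apply_treatment_effect(ten_year_risk(lp))``.
    """
    s = _event_free(lp, s0_10)
    return s**hr - s


def net_benefit_per_1000(prevented, treated, w: float):
    """Net Benefit = prevented events - w * treatments given, per 1000.

    ``w`` is the exchange rate between one treatment and one prevented
    event and equals the treatment threshold.
    """
    if not (0.0 <= w <= 1.0):
        raise InvalidParameterError(f"weight w must be in [0,1], got {w}")
    return prevented - w * np.asarray(treated, dtype=float)


def threshold_to_weight(t: float):
    """Map a risk-reduction threshold to (weight, number willing to treat).

    A 5% threshold means accepting 20 treatments to prevent one event:
    weight 0.05, number-willing-to-treat 20.
    """
    if t <= 0.0:
        raise InvalidParameterError(f"threshold must be > 0, got {t}")
    if t > 1.0:
        raise InvalidParameterError(f"threshold must be <= 1, got {t}")
    return t, 1.0 / t
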