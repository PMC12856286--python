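"""Expected treatment benefit under partial information, by exact conditioning.

A decision maker sees only part of a patient's profile (the clinical score
alone, or the clinical score plus one genomic result).  The best estimate
of that patient's chemotherapy benefit is then the conditional expectation
of the true absolute risk reduction ``r0 - r1`` given what is observed,
integrating the unobserved latent scores over their exact Gaussian
conditional distribution.  This module evaluates those conditional
expectations by deterministic quadrature (Gauss-Hermite for unbounded
conditionals, Gauss-Legendre in probability space for truncated ones),
tabulates them on a dense clinical-score grid with monotone cubic
interpolation for per-patient lookup, and derives the *testing windows*:
the interval of clinical-only benefit within which a genomic result could
still flip the treatment decision, so that only patients inside the window
are tested.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
from scipy import optimize, special
from scipy.interpolate import PchipInterpolator

from ._quad import gauss_hermite, trunc_midq_nodes, trunc_normal_nodes
from .params import DGPParams, ot_score_from_latent
from .risk import _event_free


class ConfigurationError(ValueError):
    """The quadrature configuration violates an accuracy contract."""


class InformationSet(str, enum.Enum):
    """What the decision maker observes when estimating benefit."""

    CLINICAL = "clinical"
    CLINICAL_MP = "clinical+mp"
    CLINICAL_OT_BINARY = "clinical+ot_binary"
    CLINICAL_OT_CONTINUOUS = "clinical+ot_continuous"


GENOMIC_SETS = (
    InformationSet.CLINICAL_MP,
    InformationSet.CLINICAL_OT_BINARY,
    InformationSet.CLINICAL_OT_CONTINUOUS,
)


@dataclasses.dataclass(frozen=True)
class TestingWindow:
    """Clinical-benefit interval in which a genomic test could flip the decision."""

    info: InformationSet
    threshold: float
    lower: float            # clinical-only benefit at the lower edge
    upper: float            # clinical-only benefit at the upper edge
    fraction_tested: float  # population mass inside the window
    z_lower: float          # same edges on the latent clinical scale
    z_upper: float


#: Central conditional-probability span deemed "achievable" for the
#: continuous OncotypeDX result when deciding who to test; extreme tail
#: results outside it are treated as unable to flip the decision.
CONT_OT_ACHIEVABLE = (0.005, 0.995)

_PROFILES = {
    # n_grid: z_c tabulation grid; k_state: truncated-latent nodes;
    # n_inner: inner Gauss-Hermite / truncated z_ot nodes;
    # n_gh: z_c nodes for population moments; n_trunc: z_c nodes for
    # truncated population integrals (decision regions).
    "fast": dict(n_grid=768, k_state=12, n_inner=24, n_gh=96, n_trunc=512),
    "full": dict(n_grid=2048, k_state=16, n_inner=32, n_gh=96, n_trunc=1024),
}

_FIELDS = ("benefit", "r0", "r1")


class BenefitModel:
    """Quadrature engine for conditional benefit under each information set.

    Parameters
    ----------
    params
        Data-generating parameters (validated on entry).
    profile
        ``"full"`` (default, reporting accuracy) or ``"fast"`` (used inside
        calibration loops).
    n_quad
        Override for the inner quadrature order; orders below 8 violate
        the accuracy contract and raise :class:`ConfigurationError`.
    z_span
        Half-width of the tabulation grid in cohort SDs.
    """

    def __init__(self, params: DGPParams, profile: str = "full",
                 n_quad: int | None = None, z_span: float = 8.5):
        params.validate()
        if profile not in _PROFILES:
            raise ConfigurationError(f"unknown profile {profile!r}")
        opts = dict(_PROFILES[profile])
        if n_quad is not None:
            if n_quad < 8:
                raise ConfigurationError(
                    f"quadrature order must be >= 8, got {n_quad}"
                )
            opts["n_inner"] = n_quad
        self.params = params
        self.profile = profile
        self._opts = opts
        self._gh_inner = gauss_hermite(opts["n_inner"])
        lo = params.mu_c - z_span * params.sigma_c
        hi = params.mu_c + z_span * params.sigma_c
        self.zgrid = np.linspace(lo, hi, opts["n_grid"])
        self._curves: dict = {}
        self._interps: dict = {}
        self._moments: dict | None = None
        self._build_curves()

    # ------------------------------------------------------------------ #
    # conditional expectations at arbitrary clinical-score values

    def cond_given_mp(self, z_c) -> dict:
        """E[field | z_c, mp_high=s] for field in (benefit, r0, r1).

        Returns a dict of arrays with shape ``(2, len(z_c))`` indexed by
        the MammaPrint state ``s``.  The unobserved MammaPrint latent is
        integrated over its truncated conditional (mid-quantile nodes) and
        the OncotypeDX latent over its Gaussian conditional given
        ``(z_c, z_mp)`` (Gauss-Hermite).
        """
        p = self.params
        z_c = np.atleast_1d(np.asarray(z_c, dtype=float))
        k = self._opts["k_state"]
        ghz, ghw = self._gh_inner
        m_mp = p.rho_c_mp * z_c
        a = special.ndtr((p.mp_latent_cutoff - m_mp) / p.s_mp_given_c)  # P(low|z_c)
        out = {f: np.empty((2, z_c.size)) for f in _FIELDS}
        zeros = np.zeros_like(a)
        ones = np.ones_like(a)
        for s, (lo, hi) in ((0, (zeros, a)), (1, (a, ones))):
            z_mp = trunc_midq_nodes(m_mp, p.s_mp_given_c, lo, hi, k)
            m_ot = p.rho_c_ot * z_c[:, None] + p.l32 * (z_mp - m_mp[:, None]) / p.s_mp_given_c
            z_ot = m_ot[..., None] + p.l33 * ghz          # (n, k, n_inner)
            vals = self._fields_at(z_c[:, None, None], s, z_ot)
            for f in _FIELDS:
                out[f][s] = np.mean(vals[f] @ ghw, axis=1)
        return out

    def cond_given_othigh(self, z_c) -> dict:
        """E[field | z_c, ot_high=h]; the unseen MammaPrint state is mixed
        with its exact conditional probability given ``(z_c, z_ot)``."""
        p = self.params
        z_c = np.atleast_1d(np.asarray(z_c, dtype=float))
        k = self._opts["n_inner"]
        m_ot = p.rho_c_ot * z_c
        a = special.ndtr((p.ot_cut_z - m_ot) / p.s_ot_given_c)  # P(ot low | z_c)
        out = {f: np.empty((2, z_c.size)) for f in _FIELDS}
        zeros = np.zeros_like(a)
        ones = np.ones_like(a)
        for h, (lo, hi) in ((0, (zeros, a)), (1, (a, ones))):
            z_ot = trunc_midq_nodes(m_ot, p.s_ot_given_c, lo, hi, k)  # (n, k)
            vals = self.cont_fields(z_c[:, None], z_ot)
            for f in _FIELDS:
                out[f][h] = np.mean(vals[f], axis=1)
        return out

    def cont_fields(self, z_c, z_ot) -> dict:
        """E[field | z_c, z_ot]: only the binary MammaPrint is unobserved."""
        p = self.params
        p1 = p.p_mp_high_given_zc_zot(z_c, z_ot)
        vals0 = self._fields_at(z_c, 0, z_ot)
        vals1 = self._fields_at(z_c, 1, z_ot)
        return {f: (1.0 - p1) * vals0[f] + p1 * vals1[f] for f in _FIELDS}

    def benefit_cont(self, z_c, z_ot):
        """Expected benefit under clinical + continuous OncotypeDX."""
        return self.cont_fields(z_c, z_ot)["benefit"]

    def benefit_full(self, z_c, mp_high, z_ot):
        """True per-patient benefit r0 - r1 (all three scores observed)."""
        vals = self._fields_at(np.asarray(z_c, dtype=float),
                               np.asarray(mp_high, dtype=float), z_ot)
        return vals["benefit"]

    def _fields_at(self, z_c, mp_state, z_ot) -> dict:
        """Closed-form risk quantities at fully specified latent values."""
        p = self.params
        ot_std = (ot_score_from_latent(z_ot, p.ot_a, p.ot_b) - p.ot_mean) / p.ot_sd
        lp = p.beta_c * z_c + p.beta_mp * mp_state + p.beta_ot * ot_std
        s = _event_free(lp, p.s0_10)
        s_tr = s**p.hr_chemo
        return {"benefit": s_tr - s, "r0": 1.0 - s, "r1": 1.0 - s_tr}

    # ------------------------------------------------------------------ #
    # tabulated curves over the clinical-score grid

    def _build_curves(self) -> None:
        p = self.params
        z = self.zgrid
        mp = self.cond_given_mp(z)
        p1 = p.p_mp_high_given_zc(z)
        self._curves[("mp", 0)] = mp["benefit"][0]
        self._curves[("mp", 1)] = mp["benefit"][1]
        self._curves["clin"] = (1.0 - p1) * mp["benefit"][0] + p1 * mp["benefit"][1]
        self._curves["r0_clin"] = (1.0 - p1) * mp["r0"][0] + p1 * mp["r0"][1]
        ot = self.cond_given_othigh(z)
        self._curves[("otbin", 0)] = ot["benefit"][0]
        self._curves[("otbin", 1)] = ot["benefit"][1]
        lo_q, hi_q = CONT_OT_ACHIEVABLE
        for key, q in (("cont_lo", lo_q), ("cont_hi", hi_q)):
            z_ot_q = p.rho_c_ot * z + p.s_ot_given_c * special.ndtri(q)
            self._curves[key] = self.benefit_cont(z, z_ot_q)
        for key, y in self._curves.items():
            self._interps[key] = PchipInterpolator(z, y, extrapolate=False)

    def curve(self, key) -> np.ndarray:
        return self._curves[key]

    def lookup(self, key, z):
        """Evaluate a tabulated curve, clipping to the grid support."""
        zc = np.clip(z, self.zgrid[0], self.zgrid[-1])
        return self._interps[key](zc)

    def crossing(self, key, t: float) -> float:
        """Smallest grid point where a tabulated curve first exceeds ``t``.

        Returns ``-inf`` if the curve starts above ``t`` and ``+inf`` if it
        never exceeds it.  The curves are increasing over the clinically
        relevant range; the first upward crossing defines the decision
        boundary ``treat iff benefit > t``.
        """
        y = self._curves[key]
        above = y > t
        if not above.any():
            return np.inf
        i = int(np.argmax(above))
        if i == 0:
            return -np.inf
        itp = self._interps[key]
        return float(optimize.brentq(lambda x: itp(x) - t,
                                     self.zgrid[i - 1], self.zgrid[i],
                                     xtol=1e-12))

    # ------------------------------------------------------------------ #
    # population integrals over the cohort's clinical margin

    def zc_integral(self, fn, lo: float = -np.inf, hi: float = np.inf) -> float:
        """``E[fn(z_c) * 1{lo < z_c < hi}]`` under the cohort margin."""
        p = self.params
        if lo >= hi:
            return 0.0
        z, w = trunc_normal_nodes(p.mu_c, p.sigma_c, lo, hi, self._opts["n_trunc"])
        return float(np.sum(fn(z) * w))

    def zc_nodes(self, lo: float = -np.inf, hi: float = np.inf):
        """Quadrature nodes/weights of the cohort margin restricted to (lo, hi)."""
        p = self.params
        return trunc_normal_nodes(p.mu_c, p.sigma_c, lo, hi, self._opts["n_trunc"])

    def zc_prob(self, lo: float = -np.inf, hi: float = np.inf) -> float:
        p = self.params
        if lo >= hi:
            return 0.0
        a = special.ndtr((lo - p.mu_c) / p.sigma_c)
        b = special.ndtr((hi - p.mu_c) / p.sigma_c)
        return float(b - a)

    # ------------------------------------------------------------------ #
    # continuous-OncotypeDX decision internals

    def zot_treat_interval(self, z_c, t: float, z_lo: float = -9.0,
                           z_hi: float = 9.0, n_scan: int = 241):
        """Interval of ``z_ot`` where ``benefit_cont(z_c, z_ot) > t``.

        The expected benefit rises with the OncotypeDX latent but can fold
        back below the threshold once the untreated risk saturates (an
        absolute risk reduction shrinks again as risk approaches one), so
        the treat set is an interval, not a half-line.  A dense scan
        brackets both edges, refined by vectorised bisection.  Returns
        ``(lo, hi)`` arrays; an empty set is encoded as ``(inf, inf)``.
        """
        z_c = np.atleast_1d(np.asarray(z_c, dtype=float))
        grid = np.linspace(z_lo, z_hi, n_scan)
        b = self.benefit_cont(z_c[:, None], grid[None, :]) > t
        any_above = b.any(axis=1)
        first = np.argmax(b, axis=1)
        last = n_scan - 1 - np.argmax(b[:, ::-1], axis=1)
        lo = np.full_like(z_c, np.inf)
        hi = np.full_like(z_c, np.inf)
        lo[any_above & (first == 0)] = -np.inf
        hi[any_above & (last == n_scan - 1)] = np.inf

        def _bisect(zc, a, bnd, rising):
            for _ in range(50):
                mid = 0.5 * (a + bnd)
                above = self.benefit_cont(zc, mid) > t
                take_hi = above if rising else ~above
                bnd = np.where(take_hi, mid, bnd)
                a = np.where(take_hi, a, mid)
            return 0.5 * (a + bnd)

        m = any_above & (first > 0)
        if m.any():
            lo[m] = _bisect(z_c[m], grid[first[m] - 1], grid[first[m]], True)
        m = any_above & (last < n_scan - 1)
        if m.any():
            hi[m] = _bisect(z_c[m], grid[last[m]], grid[last[m] + 1], False)
        return lo, hi

    def p_zot_between(self, z_c, z_lo, z_hi):
        """P(z_lo < z_ot <= z_hi | z_c)."""
        p = self.params
        m = p.rho_c_ot * np.asarray(z_c, dtype=float)
        z_lo = np.asarray(z_lo, dtype=float)
        z_hi = np.asarray(z_hi, dtype=float)
        with np.errstate(invalid="ignore"):
            p_above_lo = special.ndtr((m - z_lo) / p.s_ot_given_c)
            p_above_hi = special.ndtr((m - z_hi) / p.s_ot_given_c)
        p_above_lo = np.where(np.isneginf(z_lo), 1.0, p_above_lo)
        p_above_lo = np.where(np.isposinf(z_lo), 0.0, p_above_lo)
        p_above_hi = np.where(np.isneginf(z_hi), 1.0, p_above_hi)
        p_above_hi = np.where(np.isposinf(z_hi), 0.0, p_above_hi)
        return p_above_lo - p_above_hi

    def expect_benefit_zot_between(self, z_c, z_lo, z_hi):
        """E[benefit * 1{z_lo < z_ot <= z_hi} | z_c] (true benefit, mp mixed)."""
        p = self.params
        z_c = np.atleast_1d(np.asarray(z_c, dtype=float))
        z_lo = np.broadcast_to(np.asarray(z_lo, dtype=float), z_c.shape)
        z_hi = np.broadcast_to(np.asarray(z_hi, dtype=float), z_c.shape)
        m = p.rho_c_ot * z_c
        k = self._opts["n_inner"]
        with np.errstate(invalid="ignore"):
            a = special.ndtr((z_lo - m) / p.s_ot_given_c)
            b = special.ndtr((z_hi - m) / p.s_ot_given_c)
        a = np.where(np.isneginf(z_lo), 0.0, np.where(np.isposinf(z_lo), 1.0, a))
        b = np.where(np.isneginf(z_hi), 0.0, np.where(np.isposinf(z_hi), 1.0, b))
        mass = np.maximum(b - a, 0.0)
        z_ot = trunc_midq_nodes(m, p.s_ot_given_c, a, np.maximum(b, a), k)
        ben = self.benefit_cont(z_c[:, None], z_ot)
        return np.mean(ben, axis=1) * mass

    # ------------------------------------------------------------------ #
    # population moments

    def moments(self) -> dict:
        """Population moments of risks and test fractions (quadrature)."""
        if self._moments is not None:
            return self._moments
        p = self.params
        ghz, ghw = gauss_hermite(self._opts["n_gh"])
        z = p.mu_c + p.sigma_c * ghz
        mp = self.cond_given_mp(z)
        p1 = p.p_mp_high_given_zc(z)
        e_r0 = float(np.sum(((1 - p1) * mp["r0"][0] + p1 * mp["r0"][1]) * ghw))
        e_r1 = float(np.sum(((1 - p1) * mp["r1"][0] + p1 * mp["r1"][1]) * ghw))
        frac_ch_mp = self.zc_integral(p.p_mp_high_given_zc,
                                      lo=p.clinical_high_cutoff)
        self._moments = {
            "e_r0": e_r0,
            "e_r1": e_r1,
            "e_benefit": e_r0 - e_r1,
            "frac_clinical_high": p.frac_clinical_high,
            "frac_mp_high": p.frac_mp_high,
            "frac_ot_high": p.frac_ot_high,
            "frac_clinical_high_mp_high": frac_ch_mp,
        }
        return self._moments


# ---------------------------------------------------------------------- #
# public operations


def conditional_benefit(model: BenefitModel, info: InformationSet, z_c,
                        mp_high=None, ot_high=None, z_ot=None):
    """Expected absolute risk reduction given an information set.

    ``z_c`` is always observed; the genomic arguments must match ``info``.
    Tabulated curves (monotone cubic interpolation on the model grid) serve
    the one-dimensional lookups; the continuous-OncotypeDX case is
    evaluated in closed form.
    """
    info = InformationSet(info)
    z_c = np.asarray(z_c, dtype=float)
    if info is InformationSet.CLINICAL:
        return model.lookup("clin", z_c)
    if info is InformationSet.CLINICAL_MP:
        if mp_high is None:
            raise ValueError("clinical+mp requires mp_high")
        s = np.asarray(mp_high).astype(int)
        b0 = model.lookup(("mp", 0), z_c)
        b1 = model.lookup(("mp", 1), z_c)
        return np.where(s == 1, b1, b0)
    if info is InformationSet.CLINICAL_OT_BINARY:
        if ot_high is None:
            raise ValueError("clinical+ot_binary requires ot_high")
        h = np.asarray(ot_high).astype(int)
        b0 = model.lookup(("otbin", 0), z_c)
        b1 = model.lookup(("otbin", 1), z_c)
        return np.where(h == 1, b1, b0)
    if z_ot is None:
        raise ValueError("clinical+ot_continuous requires z_ot")
    return model.benefit_cont(z_c, np.asarray(z_ot, dtype=float))


def testing_window(model: BenefitModel, info: InformationSet,
                   threshold: float) -> TestingWindow:
    """Interval of clinical-only benefit where a test result could flip
    the treatment decision.

    For a binary test the window is where the two post-test benefit values
    straddle the threshold; for the continuous OncotypeDX it is where the
    post-test benefit over the central achievable band of the conditional
    score distribution straddles it.  Patients outside the window keep the
    clinical-only decision and are not tested.
    """
    info = InformationSet(info)
    t = float(threshold)
    if not (0.0 < t < 1.0):
        raise ValueError(f"threshold must be in (0,1), got {t}")
    if info is InformationSet.CLINICAL_MP:
        z_lo = model.crossing(("mp", 1), t)
        z_hi = model.crossing(("mp", 0), t)
    elif info is InformationSet.CLINICAL_OT_BINARY:
        z_lo = model.crossing(("otbin", 1), t)
        z_hi = model.crossing(("otbin", 0), t)
    elif info is InformationSet.CLINICAL_OT_CONTINUOUS:
        z_lo = model.crossing("cont_hi", t)
        z_hi = model.crossing("cont_lo", t)
    else:
        raise ValueError("testing_window requires a genomic information set")
    if not (z_lo < z_hi):
        # degenerate: the test can never change the decision
        return TestingWindow(info, t, lower=t, upper=t, fraction_tested=0.0,
                             z_lower=np.nan, z_upper=np.nan)
    frac = model.zc_prob(z_lo, z_hi)
    lower = 0.0 if np.isneginf(z_lo) else float(model.lookup("clin", z_lo))
    upper = (float(model.curve("clin").max()) if np.isposinf(z_hi)
             else float(model.lookup("clin", z_hi)))
    return TestingWindow(info, t, lower=lower, upper=upper,
                         fraction_tested=frac, z_lower=z_lo, z_upper=z_hi)


def analytic_moments(model: BenefitModel, threshold: float = 0.05) -> dict:
    """Deterministic evaluation of every calibration-target quantity.

    Combines the population risk moments with expected-mode outcomes of
    each decision strategy at ``threshold``, all per 1000 patients where
    the quantity is a count.
    """
    from . import strategies  # local import to avoid a module cycle

    m = dict(model.moments())
    out = {
        "events_untreated": 1000.0 * m["e_r0"],
        "events_treat_all": 1000.0 * m["e_r1"],
        "prevented_treat_all": 1000.0 * m["e_benefit"],
        "frac_clinical_high": m["frac_clinical_high"],
        "frac_mp_high": m["frac_mp_high"],
        "frac_ot_high": m["frac_ot_high"],
        "frac_clinical_high_mp_high": m["frac_clinical_high_mp_high"],
    }
    for key, strat in strategies.standard_strategies(threshold).items():
        o = strategies.expected_outcome(model, strat)
        out[f"{key}_treated"] = o.n_treated
        out[f"{key}_prevented"] = o.prevented_events
        out[f"{key}_events"] = o.expected_events
        out[f"{key}_nb"] = o.net_benefit
        out[f"{key}_tests"] = o.n_tests
    return out
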