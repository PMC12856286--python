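"""Conditional-benefit engine: quadrature accuracy, windows, invariants."""

import numpy as np
import pytest
from scipy import special

import dxtwin as dx
from dxtwin.benefit import CONT_OT_ACHIEVABLE, InformationSet
from dxtwin.risk import treatment_benefit


def test_low_quadrature_order_rejected(toy_params):
    with pytest.raises(dx.ConfigurationError):
        dx.BenefitModel(toy_params, profile="fast", n_quad=4)


def test_full_information_equals_true_benefit(mindact_model, mindact_cohort):
    sub = mindact_cohort.head(5000)
    b = mindact_model.benefit_full(sub["z_c"].to_numpy(),
                                   sub["mp_high"].to_numpy().astype(float),
                                   sub["z_ot"].to_numpy())
    truth = (sub["r0"] - sub["r1"]).to_numpy()
    # only the tabulated score transform separates the two paths
    assert np.max(np.abs(b - truth)) < 5e-5


def test_clinical_benefit_exact_when_genomics_uninformative():
    p = dx.DGPParams(beta_mp=0.0, beta_ot=0.0, beta_c=0.6, s0_10=0.9)
    model = dx.BenefitModel(p, profile="fast")
    z = np.linspace(-3, 3, 41)
    expected = treatment_benefit(p.beta_c * z, p.s0_10, p.hr_chemo)
    # direct quadrature integrates a constant: exact to float precision
    direct = model.cond_given_mp(z)["benefit"]
    assert np.max(np.abs(direct[0] - expected)) < 1e-12
    assert np.max(np.abs(direct[1] - expected)) < 1e-12
    # per-patient lookup only adds the tabulation-grid error
    got = dx.conditional_benefit(model, InformationSet.CLINICAL, z)
    assert np.max(np.abs(got - expected)) < 1e-5


@pytest.mark.parametrize("info", ["clinical", "clinical+mp",
                                  "clinical+ot_binary",
                                  "clinical+ot_continuous"])
def test_quadrature_matches_monte_carlo(mindact_model, mindact_params, info,
                                        rng):
    """Conditional expectations agree with a large conditional simulation."""
    p = mindact_params
    n = 1_000_000
    z_c = 0.4
    eps = rng.standard_normal((n, 2))
    z_mp = p.rho_c_mp * z_c + p.s_mp_given_c * eps[:, 0]
    z_ot = p.rho_c_ot * z_c + p.l32 * eps[:, 0] + p.l33 * eps[:, 1]
    mp = (z_mp > p.mp_latent_cutoff).astype(float)
    b_true = mindact_model.benefit_full(z_c, mp, z_ot)
    if info == "clinical":
        mc = b_true.mean()
        quad = dx.conditional_benefit(mindact_model, info, z_c)
    elif info == "clinical+mp":
        mc = b_true[mp == 1].mean()
        quad = dx.conditional_benefit(mindact_model, info, z_c, mp_high=1)
    elif info == "clinical+ot_binary":
        high = z_ot > p.ot_cut_z
        mc = b_true[high].mean()
        quad = dx.conditional_benefit(mindact_model, info, z_c, ot_high=1)
    else:
        z_fix = 0.8
        eps2 = rng.standard_normal(n)
        mean_mp = (p.rho_c_mp * z_c
                   + p.kappa_ot * (z_fix - p.rho_c_ot * z_c))
        mp2 = (mean_mp + p.s_mp_given_c_ot * eps2 > p.mp_latent_cutoff)
        mc = mindact_model.benefit_full(z_c, mp2.astype(float), z_fix).mean()
        quad = dx.conditional_benefit(mindact_model, info, z_c, z_ot=z_fix)
    assert float(quad) == pytest.approx(float(mc), abs=1e-3)


def test_grid_interpolation_error_contract(mindact_model, rng):
    """Per-patient curve lookup within 1e-5 of direct quadrature."""
    z = rng.uniform(-3.5, 3.5, size=40)
    direct = mindact_model.cond_given_mp(z)["benefit"]
    p1 = mindact_model.params.p_mp_high_given_zc(z)
    direct_clin = (1 - p1) * direct[0] + p1 * direct[1]
    assert np.max(np.abs(mindact_model.lookup("clin", z) - direct_clin)) < 1e-5
    for s in (0, 1):
        err = np.abs(mindact_model.lookup(("mp", s), z) - direct[s])
        assert np.max(err) < 1e-5


def test_benefit_increasing_in_clinical_score(mindact_model):
    """Estimated benefit rises with clinical risk until risk saturates
    (an absolute risk reduction shrinks again once the 10-year risk
    approaches one), so monotonicity is asserted below that fold."""
    z = np.linspace(-4, 4, 200)
    risk = mindact_model.lookup("r0_clin", z)
    pre_fold = risk[:-1] < 0.5
    for key in ("clin", ("mp", 0), ("mp", 1), ("otbin", 0), ("otbin", 1)):
        y = mindact_model.lookup(key, z)
        d = np.diff(y)
        # strictly increasing wherever benefit is nonzero and pre-fold
        assert np.all(d[pre_fold & (y[:-1] > 1e-8)] > 0), key


def test_benefit_increasing_in_ot_score(mindact_model):
    z_ot = np.linspace(-4, 4, 200)
    b = mindact_model.benefit_cont(np.zeros_like(z_ot), z_ot)
    assert np.all(np.diff(b) > 0)


def test_law_of_total_expectation(mindact_model, mindact_cohort):
    """Mean conditional benefit equals mean true benefit per info set."""
    truth = (mindact_cohort["r0"] - mindact_cohort["r1"]).mean()
    z = mindact_cohort["z_c"].to_numpy()
    ests = {
        "clinical": dx.conditional_benefit(mindact_model, "clinical", z),
        "clinical+mp": dx.conditional_benefit(
            mindact_model, "clinical+mp", z,
            mp_high=mindact_cohort["mp_high"].to_numpy()),
        "clinical+ot_binary": dx.conditional_benefit(
            mindact_model, "clinical+ot_binary", z,
            ot_high=mindact_cohort["ot_high"].to_numpy()),
        "clinical+ot_continuous": dx.conditional_benefit(
            mindact_model, "clinical+ot_continuous", z,
            z_ot=mindact_cohort["z_ot"].to_numpy()),
    }
    n = len(mindact_cohort)
    mc_se = 3 * (mindact_cohort["r0"] - mindact_cohort["r1"]).std() / np.sqrt(n)
    for info, est in ests.items():
        assert abs(est.mean() - truth) < mc_se + 1e-4, info


def test_information_ordering(mindact_model, mindact_cohort):
    """More information never hurts: MSE against true benefit shrinks."""
    truth = (mindact_cohort["r0"] - mindact_cohort["r1"]).to_numpy()
    z = mindact_cohort["z_c"].to_numpy()
    mse = {}
    mse["clinical"] = np.mean((dx.conditional_benefit(
        mindact_model, "clinical", z) - truth) ** 2)
    mse["otbin"] = np.mean((dx.conditional_benefit(
        mindact_model, "clinical+ot_binary", z,
        ot_high=mindact_cohort["ot_high"].to_numpy()) - truth) ** 2)
    mse["otcont"] = np.mean((dx.conditional_benefit(
        mindact_model, "clinical+ot_continuous", z,
        z_ot=mindact_cohort["z_ot"].to_numpy()) - truth) ** 2)
    assert mse["clinical"] >= mse["otbin"] >= mse["otcont"]


class TestTestingWindow:
    def test_uninformative_marker_gives_empty_window(self):
        p = dx.DGPParams(beta_mp=0.0, rho_mp_ot=0.0)
        model = dx.BenefitModel(p, profile="fast")
        win = dx.testing_window(model, "clinical+mp", 0.05)
        assert win.fraction_tested == 0.0

    def test_window_bounds_are_clinical_benefits(self, mindact_model):
        win = dx.testing_window(mindact_model, "clinical+mp", 0.05)
        assert 0.0 < win.lower < 0.05 < win.upper < 1.0
        assert win.fraction_tested == pytest.approx(
            mindact_model.zc_prob(win.z_lower, win.z_upper))

    def test_binary_window_nested_in_continuous(self, mindact_model):
        wb = dx.testing_window(mindact_model, "clinical+ot_binary", 0.05)
        wc = dx.testing_window(mindact_model, "clinical+ot_continuous", 0.05)
        assert wc.z_lower <= wb.z_lower and wb.z_upper <= wc.z_upper

    def test_threshold_widens_low_thresholds(self, mindact_model):
        """The window tracks the threshold: its bounds straddle t."""
        for t in (0.03, 0.05, 0.08):
            win = dx.testing_window(mindact_model, "clinical+mp", t)
            assert win.lower < t < win.upper

    def test_requires_genomic_info_set(self, mindact_model):
        with pytest.raises(ValueError):
            dx.testing_window(mindact_model, "clinical", 0.05)


def test_hr_one_collapses_benefit():
    p = dx.DGPParams(hr_chemo=1.0)
    model = dx.BenefitModel(p, profile="fast")
    z = np.linspace(-3, 3, 50)
    assert np.max(np.abs(dx.conditional_benefit(model, "clinical", z))) < 1e-14
    win = dx.testing_window(model, "clinical+mp", 0.05)
    assert win.fraction_tested == 0.0


def test_moments_match_simulation(mindact_model, mindact_cohort):
    """Quadrature moments within 3 Monte-Carlo SEs of the 100k cohort."""
    m = mindact_model.moments()
    n = len(mindact_cohort)
    checks = {
        "e_r0": mindact_cohort["r0"].mean(),
        "e_r1": mindact_cohort["r1"].mean(),
        "frac_mp_high": mindact_cohort["mp_high"].mean(),
        "frac_ot_high": mindact_cohort["ot_high"].mean(),
        "frac_clinical_high_mp_high": (
            mindact_cohort["clinical_high"] & mindact_cohort["mp_high"]).mean(),
    }
    for key, sim in checks.items():
        se = np.sqrt(max(sim * (1 - sim), 1e-6) / n)
        if key.startswith("e_"):
            se = mindact_cohort["r0"].std() / np.sqrt(n)
        assert abs(m[key] - sim) < 3 * se + 1e-4, key


def test_achievable_band_is_central():
    lo, hi = CONT_OT_ACHIEVABLE
    assert lo + hi == pytest.approx(1.0)
    assert special.ndtri(hi) > 2.0
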