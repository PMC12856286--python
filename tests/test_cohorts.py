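"""Twin-cohort generation: reproducibility, coupling, and score laws."""

import numpy as np
import pandas as pd
import pytest

import dxtwin as dx
from dxtwin.cohorts import (
    COHORT_COLUMNS,
    derive_scores,
    sample_latents,
    write_cohort,
    read_cohort,
)


def test_same_seed_is_bit_identical(toy_params, toy_model):
    cfg = dx.CohortConfig("mindact", n_patients=20_000, seed=7,
                          params=toy_params)
    a = dx.generate_cohort(cfg, model=toy_model)
    b = dx.generate_cohort(cfg, model=toy_model)
    pd.testing.assert_frame_equal(a, b)


def test_columns_and_bounds(mindact_cohort):
    assert list(mindact_cohort.columns) == COHORT_COLUMNS
    assert mindact_cohort["ot_score"].between(0, 100).all()
    assert ((mindact_cohort["ot_high"]) ==
            (mindact_cohort["ot_score"] >= 26)).all()
    assert mindact_cohort["r0"].between(0, 1).all()
    assert (mindact_cohort["r1"] <= mindact_cohort["r0"]).all()


def test_twin_coupling_monotone(mindact_cohort):
    """The treated twin never has an event the untreated twin avoids."""
    assert (mindact_cohort["y1"] <= mindact_cohort["y0"]).all()


def test_latent_correlations_match_configuration(toy_params):
    cfg = dx.CohortConfig("mindact", n_patients=200_000, seed=11,
                          params=toy_params)
    lat = sample_latents(cfg)
    corr = np.corrcoef(lat[["z_c", "z_mp", "z_ot"]].to_numpy().T)
    se = 3.0 / np.sqrt(len(lat))
    target = toy_params.corr_matrix
    assert np.all(np.abs(corr - target) < 3 * se + 0.004)


def test_independent_latents_when_uncorrelated():
    p = dx.DGPParams(rho_c_mp=0.0, rho_c_ot=0.0, rho_mp_ot=0.0)
    cfg = dx.CohortConfig("mindact", n_patients=100_000, seed=5, params=p)
    lat = sample_latents(cfg)
    corr = np.corrcoef(lat[["z_c", "z_mp", "z_ot"]].to_numpy().T)
    off = corr[~np.eye(3, dtype=bool)]
    assert np.all(np.abs(off) < 0.01)


def test_extreme_mp_cutoff_gives_no_high_results(toy_params, toy_model):
    p = toy_params.replace(mp_latent_cutoff=12.0)
    cfg = dx.CohortConfig("mindact", n_patients=5_000, seed=1, params=p)
    lat = sample_latents(cfg)
    scores = derive_scores(lat, p, model=toy_model)
    assert not scores["mp_high"].any()


def test_zero_betas_give_constant_risk(toy_model):
    p = dx.DGPParams(beta_c=0.0, beta_mp=0.0, beta_ot=0.0, s0_10=0.9)
    cfg = dx.CohortConfig("mindact", n_patients=2_000, seed=3, params=p)
    coh = dx.generate_cohort(cfg)
    assert np.allclose(coh["r0"], 0.1, atol=1e-12)


def test_hr_one_means_no_effect():
    p = dx.DGPParams(hr_chemo=1.0)
    cfg = dx.CohortConfig("mindact", n_patients=2_000, seed=3, params=p)
    coh = dx.generate_cohort(cfg)
    assert np.allclose(coh["r0"], coh["r1"], atol=1e-15)
    assert (coh["y0"] == coh["y1"]).all()


def test_realized_events_match_risks(mindact_cohort):
    """Binomial agreement of simulated events with assigned risks."""
    n = len(mindact_cohort)
    for y, r in (("y0", "r0"), ("y1", "r1")):
        rbar = mindact_cohort[r].mean()
        se = np.sqrt(rbar * (1 - rbar) / n)
        assert abs(mindact_cohort[y].mean() - rbar) < 3 * se


def test_clinical_high_fraction(mindact_cohort, mindact_params):
    n = len(mindact_cohort)
    frac = mindact_params.frac_clinical_high
    se = np.sqrt(frac * (1 - frac) / n)
    assert abs(mindact_cohort["clinical_high"].mean() - frac) < 3 * se


def test_clinical_risk_score_is_conditional_risk(mindact_cohort):
    """The observable clinical score tracks the untreated risk: its
    cohort mean matches mean(r0) (law of total expectation)."""
    assert mindact_cohort["clinical_risk_score"].mean() == pytest.approx(
        mindact_cohort["r0"].mean(), abs=3e-3)


class TestCrossCohortAdjust:
    def test_noop_when_already_at_target(self, mindact_params):
        low = 1.0 - mindact_params.frac_clinical_high
        assert dx.cross_cohort_adjust(mindact_params, low) == mindact_params

    def test_seventy_percent_low(self, mindact_params):
        adj = dx.cross_cohort_adjust(mindact_params, 0.70)
        assert adj.frac_clinical_high == pytest.approx(0.30, abs=1e-12)
        # only the clinical margin location moves
        assert adj.replace(mu_c=mindact_params.mu_c) == mindact_params

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3])
    def test_impossible_fraction(self, mindact_params, bad):
        with pytest.raises(dx.InvalidParameterError):
            dx.cross_cohort_adjust(mindact_params, bad)

    def test_genomic_scores_shift_through_correlation(self, mindact_params):
        """A lower-risk cohort has fewer MammaPrint/OncotypeDX highs."""
        adj = dx.cross_cohort_adjust(mindact_params, 0.70)
        assert adj.frac_mp_high < mindact_params.frac_mp_high
        assert adj.frac_ot_high < mindact_params.frac_ot_high


def test_cohort_io_round_trip(tmp_path, toy_params, toy_model):
    cfg = dx.CohortConfig("mindact", n_patients=500, seed=9, params=toy_params)
    coh = dx.generate_cohort(cfg, model=toy_model)
    path = tmp_path / "cohort.csv"
    write_cohort(coh, path)
    assert path.with_suffix(".json").exists()
    back = read_cohort(path)
    assert back.attrs["config"] == cfg
    pd.testing.assert_frame_equal(
        back.astype(coh.dtypes.to_dict()), coh.reset_index(drop=True),
        check_exact=False, rtol=1e-12)
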