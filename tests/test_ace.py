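"""Biometric design, ACE fits, comparisons, and the within/between
decomposition."""

import numpy as np
import pandas as pd
import pytest

from twinsle import (
    VarianceComponents,
    build_biometric_design,
    compare_aic,
    compare_decomposition,
    fit_ace,
    standardize,
    within_between_rr,
)
from twinsle.ace import AceFit
from twinsle.config import N_SLE_TOTAL, SimulationConfig, paper_like_config
from twinsle.simulate import latent_values, simulate_cohort

from conftest import scaled_groups


# ---------------------------------------------------------------------------
# biometric design
# ---------------------------------------------------------------------------

def test_membership_by_zygosity(tiny_config):
    cohort = simulate_cohort(tiny_config)
    design = build_biometric_design(cohort)
    m = design.membership
    mz = cohort["zygosity"] == "MZ"
    assert m.loc[mz, ["g_pair", "g_mz", "c_pair", "e_ind", "obs_resid"]].all().all()
    assert not m.loc[mz, "g_dz_within"].any()
    assert m.loc[~mz, ["g_pair", "g_dz_within", "c_pair", "e_ind", "obs_resid"]].all().all()
    assert not m.loc[~mz, "g_mz"].any()


def test_implied_genetic_variance_is_one(tiny_config):
    """Each row's genetic variance is 0.5 + 0.5 = 1 in sigma2_A units for
    both zygosities."""
    cohort = simulate_cohort(tiny_config)
    design = build_biometric_design(cohort)
    assert (design.implied_genetic_variance() == 1.0).all()
    cov = design.implied_genetic_covariance()
    assert (cov[cohort["zygosity"] == "MZ"] == 1.0).all()
    assert (cov[cohort["zygosity"] == "DZ"] == 0.5).all()


def test_single_zygosity_warns():
    config = SimulationConfig(n_pairs_by_group={"MZ-female": 5}, seed=1)
    cohort = simulate_cohort(config)
    with pytest.warns(UserWarning, match="single zygosity"):
        build_biometric_design(cohort)


def test_dz_implied_log_rate_covariance_monte_carlo():
    """The latent draws reproduce the closed-form within-pair covariance
    0.5*sigma2_A + sigma2_C on the log-rate scale."""
    config = SimulationConfig(
        n_pairs_by_group={"DZ-female": 20000},
        sigma2_a=0.36, sigma2_c=0.24, sigma2_e=0.17, seed=5,
    )
    lat = latent_values(config)
    stable = (lat["a"] + lat["c"] + lat["e"]).to_numpy().reshape(-1, 2)
    cov = np.cov(stable.T)[0, 1]
    assert cov == pytest.approx(0.5 * 0.36 + 0.24, abs=0.02)


# ---------------------------------------------------------------------------
# standardization / AIC / decomposition (closed-form arithmetic)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "vc,expected",
    [
        ((0.36, 0.24, 0.17), (47, 31, 22)),
        ((0.44, 0.14, 0.16), (59, 19, 22)),
        ((0.30, 0.14, 0.16), (50, 23, 27)),
        ((1.0, 0.0, 0.0), (100, 0, 0)),
    ],
)
def test_standardize_known_values(vc, expected):
    comps = VarianceComponents(*vc, sigma2_resid=0.5)
    assert standardize(comps).rounded() == expected
    pct = standardize(comps)
    assert pct.pct_a + pct.pct_c + pct.pct_e == pytest.approx(100.0)


def test_standardize_zero_total_fails():
    with pytest.raises(ValueError, match="zero"):
        standardize(VarianceComponents(0, 0, 0, 1.0))


def _fit_stub(aic, loglik, fingerprint="x", family="poisson",
              has_score=False, vc=None):
    return AceFit(
        label=f"stub-{aic}", family=family, include_c=True,
        fixed_effects=pd.Series(dtype=float),
        vc=vc or VarianceComponents(0.3, 0.2, 0.2, 0.5),
        loglik=loglik, aic=aic, n_params=2, n_obs=10,
        converged=True, boundary=False,
        data_fingerprint=fingerprint, has_score=has_score,
    )


def test_compare_aic_prefers_lower():
    comp = compare_aic(_fit_stub(24.0, -10.0), _fit_stub(26.0, -11.0))
    assert comp.preferred == "stub-24.0"
    assert comp.delta == pytest.approx(2.0)
    # AIC formula: -2*(-10) + 2*2 = 24
    assert -2 * (-10.0) + 2 * 2 == 24.0


def test_compare_aic_rejects_different_data():
    with pytest.raises(ValueError, match="same data"):
        compare_aic(_fit_stub(24, -10, "a"), _fit_stub(26, -11, "b"))


def test_decomposition_published_percentages():
    """Baseline (0.36, 0.24, 0.17) against residualized (0.30, 0.14,
    0.16): C falls 41.7%, A 16.7%, E 5.9%, and 22% of the stable variance
    is explained."""
    base = VarianceComponents(0.36, 0.24, 0.17, 0.59)
    resid = VarianceComponents(0.30, 0.14, 0.16, 0.57)
    comp = compare_decomposition(base, resid)
    assert comp.pct_decrease == {"A": 16.7, "C": 41.7, "E": 5.9}
    assert comp.total_pct_explained == 22
    assert comp.delta["C"] == pytest.approx(-0.10)
    assert comp.delta["A"] == pytest.approx(-0.06)
    assert comp.delta["E"] == pytest.approx(-0.01)


def test_decomposition_identical_fits_zero():
    vc = VarianceComponents(0.3, 0.2, 0.2, 0.5)
    comp = compare_decomposition(vc, vc)
    assert comp.pct_decrease == {"A": 0.0, "C": 0.0, "E": 0.0}
    assert comp.total_pct_explained == 0


def test_decomposition_zero_baseline_component_missing():
    base = VarianceComponents(0.3, 0.0, 0.2, 0.5)
    resid = VarianceComponents(0.25, 0.0, 0.18, 0.5)
    comp = compare_decomposition(base, resid)
    assert np.isnan(comp.pct_decrease["C"])


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def _gaussian_cohort(config, noise_var, seed):
    cohort = simulate_cohort(config)
    lat = latent_values(config)
    stable = pd.Series(
        (lat["a"] + lat["c"] + lat["e"]).to_numpy(),
        index=lat["pair_id"] + "_" + lat["member"].astype(str),
    )
    key = cohort["pair_id"] + "_" + cohort["twin_id"].str[-1]
    rng = np.random.default_rng(seed)
    cohort = cohort.copy()
    cohort["bpd_score"] = (
        stable.loc[key].to_numpy()
        + rng.normal(0, np.sqrt(noise_var), len(cohort))
    )
    return cohort


def test_gaussian_family_matches_moment_estimates():
    """On Gaussian data the ML variance components agree with the
    classical twin moment estimator (2(r_MZ - r_DZ) logic)."""
    config = SimulationConfig(
        n_pairs_by_group={"MZ-female": 2000, "DZ-female": 2000},
        sigma2_a=0.36, sigma2_c=0.24, sigma2_e=0.17, seed=21,
    )
    cohort = _gaussian_cohort(config, noise_var=0.59, seed=22)
    fit = fit_ace(cohort, family="gaussian", covariates=("wave",))

    # moment oracle on twin-level wave averages
    avg = cohort.groupby("twin_id").agg(
        score=("bpd_score", "mean"), pair=("pair_id", "first"),
        zyg=("zygosity", "first"),
    )
    wide = avg.pivot_table(index="pair", values="score",
                           aggfunc=list)["score"].apply(pd.Series)
    zyg = avg.groupby("pair")["zyg"].first()
    cov_mz = np.cov(wide[zyg == "MZ"].T)[0, 1]
    cov_dz = np.cov(wide[zyg == "DZ"].T)[0, 1]
    a_mom = 2 * (cov_mz - cov_dz)
    c_mom = 2 * cov_dz - cov_mz
    diff = cohort.groupby("twin_id")["bpd_score"].agg(
        lambda s: s.iloc[0] - s.iloc[1]
    )
    resid_mom = diff.var() / 2
    e_mom = wide.stack().var() - cov_mz - resid_mom / 2

    assert fit.vc.sigma2_a == pytest.approx(a_mom, abs=0.05)
    assert fit.vc.sigma2_c == pytest.approx(c_mom, abs=0.05)
    assert fit.vc.sigma2_e == pytest.approx(e_mom, abs=0.05)
    assert fit.vc.sigma2_resid == pytest.approx(resid_mom, abs=0.05)


def test_null_variance_recovery():
    """With sigma2_A = sigma2_C = 0 the fitted A and C stay below 0.05 in
    at least 80% of seeds."""
    hits_a, hits_c = 0, 0
    n_seeds = 20
    for seed in range(n_seeds):
        config = SimulationConfig(
            n_pairs_by_group=scaled_groups(600),
            sigma2_a=0.0, sigma2_c=0.0, sigma2_e=0.15, sigma2_resid=0.3,
            mu0=-0.3, seed=300 + seed,
        )
        cohort = simulate_cohort(config)
        fit = fit_ace(cohort, family="poisson", backend="laplace")
        hits_a += fit.vc.sigma2_a < 0.05
        hits_c += fit.vc.sigma2_c < 0.05
    assert hits_a >= 0.8 * n_seeds
    assert hits_c >= 0.8 * n_seeds


def test_ae_model_forces_c_to_zero(null_cohort):
    fit = fit_ace(null_cohort, family="poisson", include_c=False,
                  backend="laplace")
    assert fit.vc.sigma2_c == 0.0
    assert fit.n_params == 3 + 3  # intercept/sex/wave + three SDs


def test_aic_comparison_on_c_free_data():
    """When the generating C is zero the AE model usually wins on AIC."""
    prefer_ae = 0
    n_seeds = 10
    for seed in range(n_seeds):
        config = SimulationConfig(
            n_pairs_by_group=scaled_groups(500),
            sigma2_a=0.3, sigma2_c=0.0, sigma2_e=0.15, sigma2_resid=0.3,
            mu0=-0.3, seed=500 + seed,
        )
        cohort = simulate_cohort(config)
        ace = fit_ace(cohort, family="poisson", backend="laplace")
        ae = fit_ace(cohort, family="poisson", include_c=False,
                     backend="laplace")
        comp = compare_aic(ace, ae)
        # consistency of the AIC formula with one extra parameter
        if ace.loglik >= ae.loglik:
            assert ace.aic <= ae.aic + 2 + 1e-6
        prefer_ae += comp.preferred == ae.label
    assert prefer_ae > n_seeds / 2


def test_probit_and_poisson_standardizations_agree():
    """The liability-threshold and count decompositions of one cohort at
    full study size agree within 10 percentage points per component."""
    config = paper_like_config(seed=0).replace(
        gamma=np.zeros(N_SLE_TOTAL), w_a=np.zeros(N_SLE_TOTAL),
        w_c=np.zeros(N_SLE_TOTAL),
    )
    cohort = simulate_cohort(config)
    poisson = fit_ace(cohort, family="poisson").standardized()
    probit = fit_ace(cohort, family="probit").standardized()
    assert abs(poisson.pct_a - probit.pct_a) <= 10
    assert abs(poisson.pct_c - probit.pct_c) <= 10
    assert abs(poisson.pct_e - probit.pct_e) <= 10


def test_probit_residual_fixed_to_one(null_cohort):
    fit = fit_ace(null_cohort, family="probit")
    assert fit.vc.sigma2_resid == 1.0
    assert fit.thresholds is not None
    assert np.all(np.diff(fit.thresholds) > 0)


# ---------------------------------------------------------------------------
# within/between decomposition
# ---------------------------------------------------------------------------

def _exposure(cohort, col="sle_c_05"):
    return cohort[col].astype(float)


def test_constant_within_pair_exposure():
    """Exposure shared by co-twins has no within information; the between
    effect equals the whole-sample effect."""
    config = SimulationConfig(
        n_pairs_by_group=scaled_groups(400),
        sigma2_a=0, sigma2_c=1.0, sigma2_e=0, sigma2_resid=0,
        gamma=np.where(np.arange(N_SLE_TOTAL) == 4, np.log(2), 0.0),
        w_c=np.where(np.arange(N_SLE_TOTAL) == 4, 50.0, 0.0),
        sle_prevalence=np.full(N_SLE_TOTAL, 0.3),
        mu0=-0.3, seed=31,
    )
    cohort = simulate_cohort(config)
    expo = _exposure(cohort)
    shared = expo.groupby(cohort["pair_id"]).transform("mean")
    assert ((shared == 0) | (shared == 1)).mean() > 0.95
    keep = shared.isin([0.0, 1.0])
    cohort, expo = cohort[keep].copy(), expo[keep]
    table = within_between_rr(cohort, expo, dz_between=False).set_index(
        "effect"
    )
    assert np.isnan(table.loc["within_mz", "estimate"])
    assert np.isnan(table.loc["within_dz", "estimate"])
    assert table.loc["between", "estimate"] == pytest.approx(
        table.loc["whole_sample", "estimate"], abs=0.02
    )


def test_causal_exposure_within_equals_whole():
    """A purely causal exposure has equal whole-sample and within-pair
    RRs (no familial confounding)."""
    gamma = np.where(np.arange(N_SLE_TOTAL) == 4, np.log(2.0), 0.0)
    config = SimulationConfig(
        n_pairs_by_group={"MZ-female": 2500, "DZ-female": 2500},
        sigma2_a=0, sigma2_c=0, sigma2_e=0, sigma2_resid=0,
        gamma=gamma, sle_prevalence=np.full(N_SLE_TOTAL, 0.3),
        mu0=-0.3, n_criteria=50, seed=33,
    )
    cohort = simulate_cohort(config)
    table = within_between_rr(cohort, _exposure(cohort)).set_index("effect")
    whole = table.loc["whole_sample", "rr"]
    assert whole == pytest.approx(2.0, rel=0.1)
    assert table.loc["within_mz", "rr"] == pytest.approx(whole, rel=0.1)
    assert table.loc["within_dz", "rr"] == pytest.approx(whole, rel=0.1)


def test_confounded_exposure_nulls_within():
    """Under pure shared-environment confounding the whole-sample RR
    exceeds 1 while within-pair RRs stay at 1."""
    w_c = np.where(np.arange(N_SLE_TOTAL) == 4, 1.2, 0.0)
    config = SimulationConfig(
        n_pairs_by_group={"MZ-female": 2500, "DZ-female": 2500},
        sigma2_a=0.0, sigma2_c=0.5, sigma2_e=0.1, sigma2_resid=0.1,
        gamma=np.zeros(N_SLE_TOTAL), w_c=w_c,
        sle_prevalence=np.full(N_SLE_TOTAL, 0.3),
        mu0=-0.5, seed=35,
    )
    cohort = simulate_cohort(config)
    table = within_between_rr(cohort, _exposure(cohort)).set_index("effect")
    assert table.loc["whole_sample", "rr"] > 1.15
    assert table.loc["within_mz", "rr"] == pytest.approx(1.0, abs=0.1)
    assert table.loc["within_dz", "rr"] == pytest.approx(1.0, abs=0.1)


def test_within_between_probit_runs(null_cohort):
    from twinsle.descriptives import build_grouped_sle

    grouped = build_grouped_sle(null_cohort)
    expo = grouped["sle_child"] + grouped["sle_adult"]
    table = within_between_rr(null_cohort, expo, family="probit")
    assert set(table["effect"]) >= {"whole_sample", "within_mz", "within_dz"}
    assert np.isfinite(
        table.set_index("effect").loc["whole_sample", "estimate"]
    )
    assert "rr" not in table.columns or table["rr"].isna().all()


def test_exposure_without_variance_fails(null_cohort):
    with pytest.raises(ValueError, match="variance"):
        within_between_rr(null_cohort, np.zeros(len(null_cohort)))
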