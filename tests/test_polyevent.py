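"""Poisson elastic net: shrinkage limits, CV mechanics, and the risk
score."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from twinsle import ElasticNetConfig, compute_risk_score, fit_elastic_net_cv
from twinsle.config import elastic_net_log_rr, sle_column_names
from twinsle.io import integerize_scores
from twinsle.polyevent import (
    PolyeventModel,
    _fold_assignment,
    enet_poisson,
    penalty_value,
)


def _design(cohort):
    cols = sle_column_names()
    X = np.column_stack(
        [np.ones(len(cohort)), cohort[cols].to_numpy(dtype=float)]
    )
    penalized = np.array([False] + [True] * len(cols))
    y = integerize_scores(cohort["bpd_score"]).astype(float)
    return y, X, penalized


def test_full_shrinkage_at_large_lambda(paper_cohort):
    """A huge lambda zeroes every penalized coefficient and leaves the
    intercept at log(mean outcome)."""
    y, X, penalized = _design(paper_cohort)
    beta = enet_poisson(y, X, penalized, alpha=0.5, lam=1e6)
    assert np.all(beta[1:] == 0.0)
    assert beta[0] == pytest.approx(np.log(y.mean()), abs=1e-6)


def test_zero_lambda_matches_unpenalized_mle(paper_cohort):
    """At lambda = 0 the coordinate-descent solution equals the IRLS
    Poisson MLE (on covariates with identifiable coefficients)."""
    y, X, penalized = _design(paper_cohort)
    # exclude quasi-separated events (no positive outcome among the
    # exposed), whose unpenalized MLE diverges
    keep = (X.std(axis=0) > 0) & (((X > 0) & (y > 0)[:, None]).sum(0) >= 3)
    keep[0] = True
    Xk = X[:, keep]
    beta = enet_poisson(y, Xk, penalized[keep], alpha=0.5, lam=0.0,
                        max_iter=500)
    oracle = sm.GLM(y, Xk, family=sm.families.Poisson()).fit()
    np.testing.assert_allclose(beta, oracle.params, atol=1e-4)


def test_glmnet_agreement(paper_cohort):
    """Independent oracle: glmnet's Poisson elastic net at fixed
    (alpha, lambda) agrees with the coordinate-descent solver."""
    y, X, penalized = _design(paper_cohort)
    keep = X.std(axis=0) > 0
    keep[0] = True
    Xk, penk = X[:, keep], penalized[keep]
    alpha, lam = 0.5, 0.02
    beta = enet_poisson(y, Xk, penk, alpha=alpha, lam=lam, max_iter=500)

    np.savetxt("/tmp/enet_X.csv", Xk[:, 1:], delimiter=",")
    np.savetxt("/tmp/enet_y.csv", y, delimiter=",")
    rcode = textwrap.dedent(f"""
        suppressMessages(library(glmnet))
        X <- as.matrix(read.csv("/tmp/enet_X.csv", header=FALSE))
        y <- scan("/tmp/enet_y.csv", quiet=TRUE)
        fit <- glmnet(X, y, family="poisson", alpha={alpha},
                      lambda=c(0.1, {lam}), standardize=FALSE,
                      thresh=1e-12)
        co <- as.numeric(coef(fit, s={lam}, exact=TRUE, x=X, y=y))
        cat(co, sep="\\n")
    """)
    out = subprocess.run(
        ["Rscript", "-e", rcode], capture_output=True, text=True, check=True
    )
    ref = np.array([float(v) for v in out.stdout.split()])
    np.testing.assert_allclose(beta, ref, atol=2e-3)


def test_penalty_nonincreasing_in_lambda(paper_cohort):
    y, X, penalized = _design(paper_cohort)
    lambdas = np.geomspace(0.5, 1e-3, 12)
    values = []
    beta = None
    for lam in lambdas:
        beta = enet_poisson(y, X, penalized, 0.5, lam, beta0=beta)
        values.append(penalty_value(beta[penalized], 0.5))
    assert all(
        values[i] <= values[i + 1] + 1e-8 for i in range(len(values) - 1)
    )


def test_fold_assignment_keeps_waves_together(paper_cohort):
    config = ElasticNetConfig(fold_seed=3)
    folds = _fold_assignment(paper_cohort, config)
    per_twin = pd.Series(folds).groupby(
        paper_cohort["twin_id"].to_numpy()
    ).nunique()
    assert (per_twin == 1).all()
    folds2 = _fold_assignment(paper_cohort, config)
    np.testing.assert_array_equal(folds, folds2)
    config_pair = ElasticNetConfig(fold_seed=3, fold_unit="pair")
    per_pair = pd.Series(
        _fold_assignment(paper_cohort, config_pair)
    ).groupby(paper_cohort["pair_id"].to_numpy()).nunique()
    assert (per_pair == 1).all()


def test_cv_selection_and_refit(paper_cohort):
    config = ElasticNetConfig(
        alpha_grid=(1.0, 0.5), n_lambda=25, n_folds=5, fold_seed=0
    )
    model = fit_elastic_net_cv(paper_cohort, config)
    assert model.alpha in (1.0, 0.5)
    assert model.lambda_ > 0
    curve = model.cv_curve
    sel = curve[
        (curve["alpha"] == model.alpha)
        & (curve["lambda"] == model.lambda_)
    ]
    assert sel["cv_deviance"].iloc[0] == curve["cv_deviance"].min()
    assert 0 < model.n_selected <= 36
    rr = model.rr_table()
    zero_rows = rr[rr["coef"] == 0]
    assert (zero_rows["rr"] == "-").all()


def test_zero_pattern_invariant_to_row_duplication(paper_cohort):
    """The 1/n-scaled objective makes the solution invariant to
    duplicating every measure."""
    y, X, penalized = _design(paper_cohort)
    beta1 = enet_poisson(y, X, penalized, 0.5, 0.01)
    beta2 = enet_poisson(
        np.tile(y, 2), np.tile(X, (2, 1)), penalized, 0.5, 0.01
    )
    np.testing.assert_allclose(beta1, beta2, atol=1e-5)


def _model_from_coefs(coef: pd.Series) -> PolyeventModel:
    names = list(coef.index)
    return PolyeventModel(
        coef=coef,
        alpha=0.5,
        lambda_=0.02,
        cv_curve=pd.DataFrame(),
        feature_names=names,
        penalized_names=[n for n in names if n.startswith("sle_")],
    )


def test_constant_model_gives_unit_scores(paper_cohort):
    coef = pd.Series(
        0.0, index=["intercept"] + sle_column_names() + ["sex", "wave"]
    )
    model = _model_from_coefs(coef)
    result = compute_risk_score(model, paper_cohort)
    assert result.variance == 0.0
    assert result.min == result.max == 1.0


def test_score_ratio_is_product_of_rrs(paper_cohort):
    """A twin endorsing every selected event has a score equal to the
    product of the published RRs times the unexposed score."""
    log_rr = elastic_net_log_rr()
    coef = pd.Series(
        np.concatenate([[0.1], log_rr, [0.0, 0.0]]),
        index=["intercept"] + sle_column_names() + ["sex", "wave"],
    )
    model = _model_from_coefs(coef)
    cohort = paper_cohort.head(4).copy()
    cols = sle_column_names()
    cohort.loc[:, cols] = 0
    cohort.loc[cohort.index[0], cols] = (log_rr != 0).astype(int)
    cohort.loc[:, ["sex"]] = "female"
    cohort.loc[:, ["wave"]] = 1
    scores = compute_risk_score(model, cohort).scores
    expected_ratio = np.exp(log_rr[log_rr != 0].sum())
    assert scores.iloc[0] / scores.iloc[1] == pytest.approx(
        expected_ratio, rel=1e-10
    )


def test_perfect_prediction_correlation(paper_cohort):
    config = ElasticNetConfig(alpha_grid=(0.5,), n_lambda=10, n_folds=3)
    model = fit_elastic_net_cv(paper_cohort, config)
    result = compute_risk_score(model, paper_cohort)
    degenerate = paper_cohort.copy()
    degenerate["bpd_score"] = result.scores.round(6)
    again = compute_risk_score(model, degenerate)
    assert again.r_observed == pytest.approx(1.0, abs=1e-9)


def test_missing_sle_column_fails_with_name(paper_cohort):
    config = ElasticNetConfig(alpha_grid=(0.5,), n_lambda=5, n_folds=3)
    model = fit_elastic_net_cv(paper_cohort, config)
    broken = paper_cohort.drop(columns=["sle_c_07"])
    with pytest.raises(KeyError, match="sle_c_07"):
        compute_risk_score(model, broken)


def test_config_validation():
    with pytest.raises(ValueError):
        ElasticNetConfig(alpha_grid=(1.5,))
    with pytest.raises(ValueError):
        ElasticNetConfig(fold_unit="measure")
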