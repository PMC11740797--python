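"""Count regressions of the symptom score on life-event exposures.

Poisson and NB2 negative-binomial log-link models with pair-clustered
sandwich standard errors; estimates are reported as rate ratios (RRs) with
Wald 95% intervals on the log scale.  Covariates with zero variance (events
never endorsed) are dropped and reported as omitted with RR 1, matching the
convention of published exposure tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.discrete.discrete_model import NegativeBinomial

from .descriptives import build_grouped_sle
from .io import integerize_scores

logger = logging.getLogger(__name__)

_Z95 = stats.norm.ppf(0.975)


@dataclass
class ModelSpec:
    """Specification of a count regression.

    covariates may name SLE indicator columns, the derived grouped
    variables ``sle_child``/``sle_adult`` (built with ``group_mode``), and
    the demographic terms ``sex`` (male indicator) and ``wave`` (wave-2
    indicator).  ``cluster`` names the grouping column for the sandwich
    estimator; ``cov_type`` CR0 is the plain cluster sandwich, CR1 applies
    the small-sample degrees-of-freedom correction.
    """

    covariates: Sequence[str]
    family: str = "poisson"
    cluster: str = "pair_id"
    cov_type: str = "CR0"
    group_mode: str = "count"

    def __post_init__(self) -> None:
        if self.family not in {"poisson", "negbin"}:
            raise ValueError(f"unknown family {self.family!r}")
        if self.cov_type not in {"CR0", "CR1"}:
            raise ValueError(f"cov_type must be CR0 or CR1, got {self.cov_type!r}")
        if not self.covariates:
            raise ValueError("at least one covariate is required")


def design_matrix(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    extra: pd.DataFrame | None = None,
    group_mode: str = "count",
) -> pd.DataFrame:
    """Build the design frame (without intercept) for the named covariates."""
    grouped = None
    out = {}
    for name in covariates:
        if name == "sex":
            out[name] = (cohort["sex"] == "male").astype(float)
        elif name == "wave":
            out[name] = (cohort["wave"] == 2).astype(float)
        elif name in ("sle_child", "sle_adult"):
            if grouped is None:
                grouped = build_grouped_sle(cohort, mode=group_mode)
            out[name] = grouped[name].astype(float)
        elif name in cohort.columns:
            out[name] = cohort[name].astype(float)
        elif extra is not None and name in extra.columns:
            out[name] = extra[name].astype(float)
        else:
            raise KeyError(f"unknown covariate {name!r}")
    return pd.DataFrame(out, index=cohort.index)


def _coefficient_table(params, bse, pvalues, omitted) -> pd.DataFrame:
    rows = []
    for term in params.index:
        est, se, p = params[term], bse[term], pvalues[term]
        rows.append(
            {
                "term": term,
                "estimate": est,
                "se": se,
                "rr": np.exp(est),
                "ci_low": np.exp(est - _Z95 * se),
                "ci_high": np.exp(est + _Z95 * se),
                "p": p,
                "note": "",
            }
        )
    for term in omitted:
        rows.append(
            {
                "term": term,
                "estimate": 0.0,
                "se": np.nan,
                "rr": 1.0,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p": np.nan,
                "note": "omitted",
            }
        )
    return pd.DataFrame(rows)


def fit_count_model(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    extra: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit the specified count model with pair-clustered sandwich SEs.

    Returns a coefficient table (term, estimate, robust se, rr, 95% CI, p)
    with the log-likelihood, family and (for negbin) the dispersion alpha
    in ``DataFrame.attrs``.
    """
    y = integerize_scores(cohort["bpd_score"])
    X = design_matrix(cohort, spec.covariates, extra, spec.group_mode)

    omitted = [c for c in X.columns if X[c].nunique() <= 1]
    if omitted:
        logger.warning("dropping zero-variance covariates: %s", omitted)
        X = X.drop(columns=omitted)

    groups = cohort[spec.cluster]
    if groups.nunique() < 2:
        raise ValueError("need at least 2 clusters for the sandwich estimator")
    X = sm.add_constant(X, prepend=True)
    cov_kwds = {
        "groups": pd.factorize(groups)[0],
        "use_correction": spec.cov_type == "CR1",
    }

    if spec.family == "poisson":
        model = sm.GLM(y, X, family=sm.families.Poisson())
        res = model.fit(cov_type="cluster", cov_kwds=cov_kwds)
        params, bse, pvalues = res.params, res.bse, res.pvalues
        llf, alpha = res.llf, None
    else:
        model = NegativeBinomial(y, X, loglike_method="nb2")
        res = model.fit(
            cov_type="cluster", cov_kwds=cov_kwds, disp=0, maxiter=200
        )
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError("negative binomial fit did not converge")
        alpha = float(res.params["alpha"])
        params = res.params.drop("alpha")
        bse = res.bse.drop("alpha")
        pvalues = res.pvalues.drop("alpha")
        llf = res.llf

    bad = params[np.abs(params) > 15].index.tolist()
    if bad:
        raise RuntimeError(
            f"non-identified estimates (possible separation) for terms: {bad}"
        )

    table = _coefficient_table(params, bse, pvalues, omitted)
    table.attrs.update(
        {"loglik": float(llf), "family": spec.family, "dispersion": alpha,
         "n": int(len(y)), "cov_type": spec.cov_type}
    )
    return table


@dataclass
class OverdispersionTest:
    """Boundary likelihood-ratio test of NB2 dispersion against Poisson."""

    lr_stat: float
    p_value: float
    alpha: float
    reject: bool
    note: str = ""
    llf_poisson: float = field(default=np.nan)
    llf_negbin: float = field(default=np.nan)


def overdispersion_test(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    extra: pd.DataFrame | None = None,
    level: float = 0.05,
) -> OverdispersionTest:
    """Test for overdispersion via the NB-vs-Poisson likelihood ratio.

    The dispersion parameter sits on the boundary of its space under the
    null, so the statistic is referred to an equal mixture of chi2(0) and
    chi2(1): p = 0.5 * P(chi2_1 > LR).
    """
    if spec.family != "poisson":
        raise ValueError("overdispersion test starts from a Poisson spec")
    y = integerize_scores(cohort["bpd_score"])
    X = design_matrix(cohort, spec.covariates, extra, spec.group_mode)
    X = X.loc[:, X.nunique() > 1]
    X = sm.add_constant(X, prepend=True)

    res_p = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    if np.ptp(y) == 0:
        return OverdispersionTest(0.0, 1.0, 0.0, False, "constant outcome",
                                  res_p.llf, res_p.llf)
    try:
        res_nb = NegativeBinomial(y, X, loglike_method="nb2").fit(
            disp=0, maxiter=200
        )
        if not res_nb.mle_retvals.get("converged", True):
            raise RuntimeError("negbin non-convergence")
    except Exception as exc:  # pragma: no cover - backend-dependent
        logger.warning("negative binomial fit failed (%s); Poisson only", exc)
        return OverdispersionTest(
            np.nan, np.nan, np.nan, False, f"negbin failed: {exc}", res_p.llf
        )
    alpha_hat = float(res_nb.params["alpha"])
    # the null sits on the boundary alpha = 0; a negative fitted alpha
    # (underdispersion direction) counts as zero evidence
    lr = max(0.0, 2.0 * (res_nb.llf - res_p.llf)) if alpha_hat > 0 else 0.0
    p = 0.5 * stats.chi2.sf(lr, df=1)
    return OverdispersionTest(
        lr_stat=float(lr),
        p_value=float(p),
        alpha=alpha_hat,
        reject=bool(p < level),
        llf_poisson=float(res_p.llf),
        llf_negbin=float(res_nb.llf),
    )


def per_event_rr_table(
    cohort: pd.DataFrame,
    family: str = "poisson",
    adjust_for_other_sles: bool = True,
    cov_type: str = "CR0",
) -> pd.DataFrame:
    """RRs for all 36 SLE indicators (one joint mutually-adjusted model, or
    one model per event with only that event as covariate)."""
    from .config import sle_column_names

    cols = sle_column_names()
    if adjust_for_other_sles:
        spec = ModelSpec(covariates=cols, family=family, cov_type=cov_type)
        return fit_count_model(cohort, spec)
    tables = []
    for col in cols:
        spec = ModelSpec(covariates=[col], family=family, cov_type=cov_type)
        tab = fit_count_model(cohort, spec)
        tables.append(tab[tab["term"] == col])
    return pd.concat(tables, ignore_index=True)
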