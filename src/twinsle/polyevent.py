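"""Elastic-net penalized Poisson regression and the polyevent risk score.

The 36 life-event indicators enter a log-link Poisson model with the
elastic-net penalty

    (1/n) sum_i [mu_i - y_i * eta_i]  +  lambda * ( alpha * ||b||_1
                                         + (1 - alpha)/2 * ||b||_2^2 )

applied to the event coefficients only; intercept, sex and wave are
unpenalized.  The solver is penalized iteratively reweighted least squares
with cyclic coordinate descent and warm starts along a descending lambda
path (the glmnet strategy).  Binary covariates are left unstandardized so
coefficients exponentiate directly to per-event rate ratios.

The polyevent risk score of a measure is the model-predicted symptom
count, exp(linear predictor) — a weighted sum of the endorsed events on
the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import sle_column_names
from .count_regression import design_matrix
from .io import integerize_scores


@dataclass
class ElasticNetConfig:
    """Settings of the cross-validated elastic net."""

    alpha_grid: Sequence[float] = (1.0, 0.75, 0.5)
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    lambda_path: Sequence[float] | None = None
    n_folds: int = 10
    fold_seed: int = 0
    fold_unit: str = "twin"  # or "pair"
    unpenalized: Sequence[str] = ("sex", "wave")
    tol: float = 1e-8
    max_iter: int = 200

    def __post_init__(self) -> None:
        if any(not (0 <= a <= 1) for a in self.alpha_grid):
            raise ValueError("alpha values must lie in [0, 1]")
        if self.lambda_path is not None and any(
            l < 0 for l in self.lambda_path
        ):
            raise ValueError("lambda values must be nonnegative")
        if self.fold_unit not in {"twin", "pair"}:
            raise ValueError("fold_unit must be 'twin' or 'pair'")


def _soft_threshold(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def enet_poisson(
    y: np.ndarray,
    X: np.ndarray,
    penalized: np.ndarray,
    alpha: float,
    lam: float,
    beta0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> np.ndarray:
    """Solve one penalized Poisson problem by IRLS + coordinate descent.

    X must contain an explicit intercept column (unpenalized).  Returns the
    coefficient vector.
    """
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    eta = X @ beta
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu
        # working residual on the weight scale: r = w * (z - eta) = y - mu
        r = y - mu
        for _sweep in range(100):
            max_delta = 0.0
            for j in range(p):
                xj = X[:, j]
                wxj2 = (w * xj * xj).mean()
                if wxj2 <= 0 and not penalized[j]:
                    continue
                rho = (xj * r).mean() + wxj2 * beta[j]
                if penalized[j]:
                    new = _soft_threshold(rho, lam * alpha) / (
                        wxj2 + lam * (1 - alpha)
                    ) if (wxj2 + lam * (1 - alpha)) > 0 else 0.0
                else:
                    new = rho / wxj2 if wxj2 > 0 else beta[j]
                delta = new - beta[j]
                if delta != 0.0:
                    r -= delta * w * xj
                    eta += delta * xj
                    beta[j] = new
                    max_delta = max(max_delta, wxj2 * delta * delta)
            if max_delta < tol:
                break
        # outer (IRLS) convergence via exact KKT conditions:
        # unpenalized -> gradient ~ 0; penalized nonzero ->
        # grad_j + lam*(1-alpha)*b_j = -lam*alpha*sign(b_j);
        # penalized zero -> |grad_j| <= lam*alpha
        mu_new = np.exp(np.clip(eta, -30, 30))
        grad = -(X * (y - mu_new)[:, None]).mean(axis=0)
        viol = np.zeros(p)
        pen_grad = grad + lam * (1 - alpha) * beta * penalized
        nz = penalized & (beta != 0)
        viol[nz] = np.abs(pen_grad[nz] + lam * alpha * np.sign(beta[nz]))
        z0 = penalized & (beta == 0)
        viol[z0] = np.maximum(np.abs(grad[z0]) - lam * alpha, 0)
        viol[~penalized] = np.abs(grad[~penalized])
        if viol.max() < 1e-6:
            break
    return beta


def lambda_max(
    y: np.ndarray, X: np.ndarray, penalized: np.ndarray, alpha: float,
    tol: float = 1e-8,
) -> float:
    """Smallest lambda at which every penalized coefficient is zero."""
    beta = enet_poisson(y, X, penalized, alpha=1.0, lam=np.inf, tol=tol)
    # with lam = inf, enet_poisson keeps penalized coefs at 0 and fits the
    # unpenalized block; the score at that solution gives lambda_max
    mu = np.exp(np.clip(X @ beta, -30, 30))
    score = np.abs((X[:, penalized] * (y - mu)[:, None]).mean(axis=0))
    return float(score.max() / max(alpha, 1e-3))


def _default_lambda_path(
    y, X, penalized, alpha_grid, n_lambda, min_ratio
) -> np.ndarray:
    lmax = max(lambda_max(y, X, penalized, a) for a in alpha_grid if a > 0)
    lmax *= 1.0001
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Elementwise Poisson deviance contributions 2[y log(y/mu) - (y-mu)]."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return 2.0 * (term - (y - mu))


@dataclass
class PolyeventModel:
    """Fitted cross-validated elastic net over the 36 event indicators."""

    coef: pd.Series
    alpha: float
    lambda_: float
    cv_curve: pd.DataFrame
    feature_names: list[str]
    penalized_names: list[str]
    scale_factor: int = 1
    config: ElasticNetConfig = field(default_factory=ElasticNetConfig)

    @property
    def n_selected(self) -> int:
        return int((self.coef[self.penalized_names] != 0).sum())

    def rr_table(self) -> pd.DataFrame:
        """Per-event RRs with exact zeros rendered as an en dash."""
        from .config import N_SLE, SLE_LABELS

        rows = []
        for j in range(1, N_SLE + 1):
            for period, prefix in (
                ("childhood", "sle_c"),
                ("adulthood", "sle_a"),
            ):
                b = self.coef[f"{prefix}_{j:02d}"]
                rows.append(
                    {
                        "sle": j,
                        "label": SLE_LABELS[j - 1],
                        "period": period,
                        "coef": b,
                        "rr": "-" if b == 0 else f"{np.exp(b):.2f}",
                    }
                )
        return pd.DataFrame(rows)


def _fold_assignment(cohort: pd.DataFrame, config: ElasticNetConfig) -> np.ndarray:
    """Fold id per measure; both waves of a twin (or pair) share a fold."""
    unit = "twin_id" if config.fold_unit == "twin" else "pair_id"
    ids = cohort[unit].to_numpy()
    unique_ids = pd.unique(ids)
    rng = np.random.default_rng(config.fold_seed)
    perm = rng.permutation(len(unique_ids))
    fold_of = {
        uid: perm[i] % config.n_folds for i, uid in enumerate(unique_ids)
    }
    return np.array([fold_of[i] for i in ids])


def _design(cohort: pd.DataFrame, config: ElasticNetConfig):
    features = list(sle_column_names()) + [
        c for c in config.unpenalized if c not in sle_column_names()
    ]
    missing = [c for c in sle_column_names() if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort is missing SLE columns: {missing}")
    Xdf = design_matrix(cohort, features)
    names = ["intercept"] + features
    X = np.column_stack([np.ones(len(Xdf)), Xdf.to_numpy(dtype=float)])
    penalized = np.array([name in sle_column_names() for name in names])
    return X, names, penalized


def fit_elastic_net_cv(
    cohort: pd.DataFrame, config: ElasticNetConfig | None = None
) -> PolyeventModel:
    """Cross-validated elastic net: select (alpha, lambda) by mean
    out-of-fold Poisson deviance, then refit on all data at the selection."""
    config = config or ElasticNetConfig()
    y_int = integerize_scores(cohort["bpd_score"])
    scale = 2 if not np.allclose(cohort["bpd_score"], y_int) else 1
    y = y_int.astype(float)
    X, names, penalized = _design(cohort, config)
    if not penalized.any():
        raise ValueError("no penalized covariates in the design")
    keep = X.std(axis=0) > 0
    keep[0] = True
    if not keep[penalized].any():
        raise ValueError("all penalized covariates are constant")

    if config.lambda_path is not None:
        lambdas = np.sort(np.asarray(config.lambda_path, dtype=float))[::-1]
    else:
        lambdas = _default_lambda_path(
            y, X, penalized, config.alpha_grid,
            config.n_lambda, config.lambda_min_ratio,
        )

    folds = _fold_assignment(cohort, config)
    records = []
    dev = np.zeros((len(config.alpha_grid), len(lambdas), len(y)))
    for k in range(config.n_folds):
        train, test = folds != k, folds == k
        if not test.any():
            continue
        for ia, alpha in enumerate(config.alpha_grid):
            beta = None
            for il, lam in enumerate(lambdas):
                beta = enet_poisson(
                    y[train], X[train], penalized, alpha, lam,
                    beta0=beta, tol=config.tol, max_iter=config.max_iter,
                )
                mu = np.exp(np.clip(X[test] @ beta, -30, 30))
                dev[ia, il, test] = poisson_deviance(y[test], mu)
    mean_dev = dev.mean(axis=2)
    for ia, alpha in enumerate(config.alpha_grid):
        for il, lam in enumerate(lambdas):
            records.append(
                {"alpha": alpha, "lambda": lam, "cv_deviance": mean_dev[ia, il]}
            )
    cv_curve = pd.DataFrame(records)
    best = np.unravel_index(np.argmin(mean_dev), mean_dev.shape)
    alpha_sel = float(config.alpha_grid[best[0]])
    lam_sel = float(lambdas[best[1]])

    # refit on the full data along the path down to the selection
    beta = None
    for lam in lambdas[: best[1] + 1]:
        beta = enet_poisson(
            y, X, penalized, alpha_sel, lam,
            beta0=beta, tol=config.tol, max_iter=config.max_iter,
        )
    coef = pd.Series(beta, index=names)
    return PolyeventModel(
        coef=coef,
        alpha=alpha_sel,
        lambda_=lam_sel,
        cv_curve=cv_curve,
        feature_names=names,
        penalized_names=[n for n, p in zip(names, penalized) if p],
        scale_factor=scale,
        config=config,
    )


@dataclass
class RiskScoreResult:
    """Per-measure polyevent risk score with summary diagnostics."""

    scores: pd.Series
    min: float
    max: float
    mean: float
    median: float
    variance: float
    r_observed: float
    observed_wave: int

    def summary(self) -> dict:
        return {
            "min": self.min,
            "max": self.max,
            "mean": self.mean,
            "median": self.median,
            "variance": self.variance,
            "r_observed": self.r_observed,
            "observed_wave": self.observed_wave,
        }


def compute_risk_score(
    model: PolyeventModel,
    cohort: pd.DataFrame,
    observed_wave: int = 1,
) -> RiskScoreResult:
    """Predicted symptom count per measure and its correlation with the
    observed score at a single wave.

    The score is exp(linear predictor) on the original criteria scale
    (divided back by 2 when half-point scores were integerized by
    doubling).
    """
    features = model.feature_names[1:]
    missing = [
        c
        for c in features
        if c not in cohort.columns and c not in ("sex", "wave")
    ]
    if missing:
        raise KeyError(f"cohort is missing model columns: {missing}")
    Xdf = design_matrix(cohort, features)
    lp = model.coef["intercept"] + Xdf.to_numpy(dtype=float) @ model.coef[
        features
    ].to_numpy(dtype=float)
    scores = pd.Series(
        np.exp(lp) / model.scale_factor, index=cohort.index, name="risk_score"
    )
    at_wave = cohort["wave"] == observed_wave
    obs = cohort.loc[at_wave, "bpd_score"].to_numpy(dtype=float)
    pred = scores[at_wave].to_numpy()
    if len(obs) > 1 and np.std(obs) > 0 and np.std(pred) > 0:
        r = float(np.corrcoef(pred, obs)[0, 1])
    else:
        r = np.nan
    return RiskScoreResult(
        scores=scores,
        min=float(scores.min()),
        max=float(scores.max()),
        mean=float(scores.mean()),
        median=float(scores.median()),
        variance=float(scores.var(ddof=1)),
        r_observed=r,
        observed_wave=observed_wave,
    )


def penalty_value(model_or_coef, alpha: float, penalized_names=None) -> float:
    """Elastic-net penalty J(b) = alpha*||b||_1 + (1-alpha)/2*||b||_2^2."""
    if isinstance(model_or_coef, PolyeventModel):
        b = model_or_coef.coef[model_or_coef.penalized_names].to_numpy()
    else:
        b = np.asarray(model_or_coef, dtype=float)
        if penalized_names is not None:
            b = b[penalized_names]
    return float(
        alpha * np.abs(b).sum() + 0.5 * (1 - alpha) * (b**2).sum()
    )
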