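"""Biometric co-twin-control engine.

Fits generalized linear mixed models with fixed ACE random-effect
loadings to twin data:

* all pairs share a between-pair effect of variance 0.5*sigma2_A plus a
  shared-environment effect of variance sigma2_C;
* MZ pairs share an additional between-pair effect of 0.5*sigma2_A (they
  are fully identical by descent);
* DZ twins carry an individual 0.5*sigma2_A effect (segregation);
* every twin has a time-invariant nonshared effect of variance sigma2_E;
* Poisson fits add an observation-level residual effect of variance
  sigma2_R on the log rate (a lognormal-Poisson overdispersion term);
  the ordinal probit (liability-threshold) variant fixes the residual
  liability variance to 1.

Within a pair the correlated effects collapse to three independent
blocks -- one pair-level component (variance share*sigma2_A + sigma2_C,
share = 1 for MZ, 0.5 for DZ), two individual components (variance
sigma2_E + 0.5*sigma2_A for DZ, sigma2_E for MZ) and, for Poisson, one
component per observation -- so the marginal likelihood factorizes over
pairs.  It is evaluated by a Laplace approximation around the joint mode
of the pair's random effects (batched Newton across pairs) and maximized
over fixed effects and standard deviations with L-BFGS-B.  A Gaussian
identity family is included as an exactly-integrable debug family.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .count_regression import design_matrix
from .io import integerize_scores

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-8
_SD_MAX = 10.0

RANDOM_EFFECT_GROUPS = (
    "g_pair", "g_mz", "g_dz_within", "c_pair", "e_ind", "obs_resid"
)


# --------------------------------------------------------------------------
# value types
# --------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """Unstandardized A/C/E and residual variances (log-rate or liability
    scale)."""

    sigma2_a: float
    sigma2_c: float
    sigma2_e: float
    sigma2_resid: float

    def __post_init__(self) -> None:
        for name in ("sigma2_a", "sigma2_c", "sigma2_e", "sigma2_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total_ace(self) -> float:
        return self.sigma2_a + self.sigma2_c + self.sigma2_e

    @property
    def total(self) -> float:
        return self.total_ace + self.sigma2_resid

    def as_dict(self) -> dict:
        return {
            "sigma2_a": self.sigma2_a,
            "sigma2_c": self.sigma2_c,
            "sigma2_e": self.sigma2_e,
            "sigma2_resid": self.sigma2_resid,
        }


@dataclass
class StandardizedComponents:
    """A/C/E as percentages of the stable (A + C + E) variance."""

    pct_a: float
    pct_c: float
    pct_e: float

    def rounded(self) -> tuple[int, int, int]:
        return (
            int(round(self.pct_a)),
            int(round(self.pct_c)),
            int(round(self.pct_e)),
        )


def standardize(vc: VarianceComponents) -> StandardizedComponents:
    """Percentages of the A + C + E total (residual variance excluded)."""
    total = vc.total_ace
    if total <= 0:
        raise ValueError("A + C + E total is zero; standardization undefined")
    return StandardizedComponents(
        pct_a=100.0 * vc.sigma2_a / total,
        pct_c=100.0 * vc.sigma2_c / total,
        pct_e=100.0 * vc.sigma2_e / total,
    )


@dataclass
class AceFit:
    """A fitted biometric mixed model."""

    label: str
    family: str
    include_c: bool
    fixed_effects: pd.Series
    vc: VarianceComponents
    loglik: float
    aic: float
    n_params: int
    n_obs: int
    converged: bool
    boundary: bool
    backend: str = "laplace"
    thresholds: np.ndarray | None = None
    data_fingerprint: str = ""
    has_score: bool = False

    def standardized(self) -> StandardizedComponents:
        return standardize(self.vc)

    def summary(self) -> dict:
        std = self.standardized()
        return {
            "label": self.label,
            "family": self.family,
            "model": "ACE" if self.include_c else "AE",
            "fixed_effects": {k: float(v) for k, v in self.fixed_effects.items()},
            "variance_components": self.vc.as_dict(),
            "standardized_pct": {
                "A": std.pct_a, "C": std.pct_c, "E": std.pct_e
            },
            "loglik": self.loglik,
            "aic": self.aic,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "boundary": self.boundary,
            "backend": self.backend,
        }


# --------------------------------------------------------------------------
# biometric design
# --------------------------------------------------------------------------

@dataclass
class BiometricDesign:
    """Random-effect membership of every observation.

    ``membership`` has one boolean column per random-effect group; the
    implied per-individual genetic variance is sigma2_A for both
    zygosities (0.5 + 0.5 through g_pair + g_mz for MZ, g_pair +
    g_dz_within for DZ) and the implied within-pair genetic covariance is
    sigma2_A (MZ) or 0.5*sigma2_A (DZ).
    """

    membership: pd.DataFrame
    pair_id: pd.Series
    zygosity: pd.Series
    single_zygosity: bool

    def implied_genetic_variance(self) -> pd.Series:
        """Per-row genetic variance in units of sigma2_A (always 1)."""
        m = self.membership
        return (
            0.5 * m["g_pair"].astype(float)
            + 0.5 * m["g_mz"].astype(float)
            + 0.5 * m["g_dz_within"].astype(float)
        )

    def implied_genetic_covariance(self) -> pd.Series:
        """Within-pair genetic covariance in units of sigma2_A."""
        m = self.membership
        return 0.5 * m["g_pair"].astype(float) + 0.5 * m["g_mz"].astype(float)


def build_biometric_design(cohort: pd.DataFrame) -> BiometricDesign:
    """Construct the fixed-loading random-effect membership table."""
    zyg = cohort["zygosity"]
    kinds = set(zyg.unique())
    single = len(kinds) < 2
    if single and not cohort.empty:
        warnings.warn(
            "cohort contains a single zygosity; A and C are not separately "
            "identified (fit may proceed for simulation studies)",
            stacklevel=2,
        )
    membership = pd.DataFrame(
        {
            "g_pair": np.ones(len(cohort), dtype=bool),
            "g_mz": (zyg == "MZ").to_numpy(),
            "g_dz_within": (zyg == "DZ").to_numpy(),
            "c_pair": np.ones(len(cohort), dtype=bool),
            "e_ind": np.ones(len(cohort), dtype=bool),
            "obs_resid": np.ones(len(cohort), dtype=bool),
        },
        index=cohort.index,
    )
    return BiometricDesign(
        membership=membership,
        pair_id=cohort["pair_id"],
        zygosity=zyg,
        single_zygosity=single,
    )


# --------------------------------------------------------------------------
# Laplace machinery
# --------------------------------------------------------------------------

def _pack_pairs(cohort: pd.DataFrame, X: np.ndarray, y: np.ndarray):
    """Reshape long data into padded per-pair arrays.

    Returns (y_pad (P,4), X_pad (P,4,k), mask (P,4), ind (P,4) in {0,1},
    is_mz (P,)).
    """
    codes, uniques = pd.factorize(cohort["pair_id"], sort=True)
    P = len(uniques)
    order = np.lexsort(
        (cohort["wave"].to_numpy(), cohort["twin_id"].to_numpy(), codes)
    )
    codes_s = codes[order]
    counts = np.bincount(codes_s, minlength=P)
    m_max = int(counts.max())
    if m_max > 4:
        raise ValueError("more than 4 rows in a pair (waves beyond 2?)")
    m_max = max(m_max, 1)
    pos = np.concatenate([np.arange(c) for c in counts]) if len(codes_s) else np.empty(0, int)

    k = X.shape[1]
    y_pad = np.zeros((P, m_max))
    X_pad = np.zeros((P, m_max, k))
    mask = np.zeros((P, m_max), dtype=bool)
    ind = np.zeros((P, m_max), dtype=np.int64)

    y_pad[codes_s, pos] = y[order]
    X_pad[codes_s, pos, :] = X[order]
    mask[codes_s, pos] = True

    twin_sorted = cohort["twin_id"].to_numpy()[order]
    first_twin = {}
    for c, t, p_ in zip(codes_s, twin_sorted, pos):
        if c not in first_twin:
            first_twin[c] = t
        ind[c, p_] = 0 if t == first_twin[c] else 1

    zyg_per_pair = np.empty(P, dtype=object)
    zyg_sorted = cohort["zygosity"].to_numpy()[order]
    zyg_per_pair[codes_s] = zyg_sorted
    is_mz = zyg_per_pair == "MZ"
    return y_pad, X_pad, mask, ind, is_mz


class _LaplaceEngine:
    """Marginal likelihood of the biometric GLMM.

    The likelihood factorizes over pairs; each pair's random effects are
    integrated either by a Laplace approximation around their joint mode
    (batched Newton across pairs) or, on top of that, by importance
    sampling with the Laplace Gaussian as proposal and a fixed scrambled
    Sobol point set, which removes the Laplace bias of the
    observation-level Poisson residual while keeping the objective smooth
    and deterministic.
    """

    def __init__(
        self, cohort, X, y, family, include_c, thresholds_init=None,
    ):
        self.family = family
        self.include_c = include_c
        (self.y, self.X, self.mask, self.ind, self.is_mz) = _pack_pairs(
            cohort, X, y
        )
        self.P, self.m, self.k = self.X.shape[0], self.X.shape[1], self.X.shape[2]
        self.with_obs = family == "poisson"
        self.d = 3 + (self.m if self.with_obs else 0)
        # incidence of latent components per row
        A = np.zeros((self.P, self.m, self.d))
        rows = np.arange(self.m)
        A[:, rows, 0] = self.mask
        for r in rows:
            A[:, r, 1 + self.ind[:, r]] = self.mask[:, r]
        if self.with_obs:
            A[:, rows, 3 + rows] = self.mask
        self.A = A
        self.gshare_pair = np.where(self.is_mz, 1.0, 0.5)
        self.gshare_ind = np.where(self.is_mz, 0.0, 0.5)
        self._u_warm = np.zeros((self.P, self.d))
        self.n_thresh = 0 if thresholds_init is None else len(thresholds_init)
        if family == "poisson":
            self._lgamma = special.gammaln(self.y + 1.0) * self.mask
            # quadrature-table support for the observation-level integral
            self._table_grid = np.arange(-20.0, 8.0001, 0.02)
            counts = np.unique(self.y[self.mask]).astype(np.int64)
            self._distinct_counts = counts.astype(float)
            code_of = {int(k): i for i, k in enumerate(counts)}
            self._build_iw_layout()
            self._count_code = np.vectorize(
                lambda k: code_of.get(int(k), 0)
            )(self._y_iw).astype(np.int64)
        elif family == "probit":
            pass  # _build_iw_layout deferred until _ycode is attached

    # ---- per-family log-likelihood of eta (masked rows return 0) ----
    # eta may be (P, m) or (P, M, m); y/mask broadcast along the middle axis

    def _broadcast(self, arr, eta):
        return arr[:, None, :] if eta.ndim == 3 else arr

    def _row_loglik(self, eta, tau=None, deriv=True):
        y = self._broadcast(self.y, eta)
        if self.family == "poisson":
            mu = np.exp(np.clip(eta, -40, 40))
            l = y * eta - mu - self._broadcast(self._lgamma, eta)
            dl, d2l = (y - mu, -mu) if deriv else (None, None)
        elif self.family == "gaussian":
            sr2 = self._sigma2_r
            resid = y - eta
            l = -0.5 * np.log(2 * np.pi * sr2) - 0.5 * resid**2 / sr2
            if deriv:
                dl = resid / sr2
                d2l = np.full_like(eta, -1.0 / sr2)
            else:
                dl = d2l = None
        else:  # ordinal probit
            ycode = self._broadcast(self._ycode, eta)
            a = tau[ycode] - eta          # tau_k  (tau[0] = -inf)
            b = tau[ycode + 1] - eta      # tau_{k+1}
            L = stats.norm.cdf(b) - stats.norm.cdf(a)
            L = np.clip(L, 1e-12, None)
            l = np.log(L)
            if deriv:
                pa = np.where(np.isfinite(a), stats.norm.pdf(a), 0.0)
                pb = np.where(np.isfinite(b), stats.norm.pdf(b), 0.0)
                apa = np.where(np.isfinite(a), a * pa, 0.0)
                bpb = np.where(np.isfinite(b), b * pb, 0.0)
                dl = (pa - pb) / L
                d2l = (apa - bpb) / L - dl**2
                d2l = np.minimum(d2l, -1e-10)
            else:
                dl = d2l = None
        z = ~self._broadcast(self.mask, eta)
        l = np.where(z, 0.0, l)
        if deriv:
            dl = np.where(z, 0.0, dl)
            d2l = np.where(z, 0.0, d2l)
        return l, dl, d2l

    def _variances(self, s2a, s2c, s2e, s2r):
        v = np.empty((self.P, self.d))
        v[:, 0] = np.maximum(self.gshare_pair * s2a + s2c, _VAR_FLOOR)
        v_ind = np.maximum(self.gshare_ind * s2a + s2e, _VAR_FLOOR)
        v[:, 1] = v_ind
        v[:, 2] = v_ind
        if self.with_obs:
            v[:, 3:] = max(s2r, _VAR_FLOOR)
        return v

    def _joint(self, u, offset, v, tau):
        eta = offset + np.einsum("prd,pd->pr", self.A, u)
        l, dl, d2l = self._row_loglik(eta, tau)
        f = l.sum(axis=1) - 0.5 * (u**2 / v).sum(axis=1)
        return f, l, dl, d2l

    def nll(self, offset, s2a, s2c, s2e, s2r, tau=None):
        """Negative Laplace marginal log-likelihood."""
        self._sigma2_r = max(s2r, _VAR_FLOOR)
        v = self._variances(s2a, s2c, s2e, s2r)
        u = self._u_warm.copy()
        f, l, dl, d2l = self._joint(u, offset, v, tau)
        for _ in range(60):
            grad = np.einsum("prd,pr->pd", self.A, dl) - u / v
            gmax = np.abs(grad).max() if grad.size else 0.0
            if gmax < 1e-8:
                break
            W = -d2l
            H = np.einsum("prd,pr,pre->pde", self.A, W, self.A)
            H[:, np.arange(self.d), np.arange(self.d)] += 1.0 / v
            try:
                step = np.linalg.solve(H, grad[..., None])[..., 0]
            except np.linalg.LinAlgError:
                return 1e10
            if not np.all(np.isfinite(step)):
                return 1e10
            scale = np.ones(self.P)
            for _bt in range(25):
                u_new = u + scale[:, None] * step
                f_new, l, dl, d2l = self._joint(u_new, offset, v, tau)
                worse = ~(f_new >= f - 1e-12)  # catches NaN as worse
                if not worse.any():
                    break
                scale[worse] *= 0.5
            u, f = u_new, f_new
        else:
            logger.debug("inner Newton did not fully converge (gmax=%g)", gmax)
        # final Hessian at the mode
        W = -d2l
        H = np.einsum("prd,pr,pre->pde", self.A, W, self.A)
        H[:, np.arange(self.d), np.arange(self.d)] += 1.0 / v
        sign, logdet = np.linalg.slogdet(H)
        if np.any(sign <= 0):
            return 1e10
        self._u_warm = u
        self._mode_u, self._mode_H, self._mode_v = u, H, v
        ll = f - 0.5 * np.log(v).sum(axis=1) - 0.5 * logdet
        total = ll.sum()
        if not np.isfinite(total):
            return 1e10
        return -total

    # ---- nested adaptive Gauss-Hermite quadrature ----
    #
    # The random effects nest (pair -> twin -> observation) and, given the
    # pair effect, the two twins are conditionally independent, so the
    # pair marginal likelihood is a tower of one-dimensional integrals:
    #
    #   L_p = int phi(b_p; v_pair) prod_i int phi(b_i; v_ind)
    #             prod_w f(y_iw | offset + b_p + b_i) db_i db_p
    #
    # where f is the Poisson-lognormal row likelihood (observation-level
    # residual integrated by plain Gauss-Hermite, tabulated per distinct
    # count) or the ordinal-probit category probability.  The outer
    # integrals use Gauss-Hermite nodes centered and scaled with the
    # Laplace mode/curvature (adaptive quadrature), which the Newton
    # iteration above provides.

    def _build_iw_layout(self):
        """Scatter the padded (P, m) rows into a (P, 2, 2) twin-by-wave
        layout; returns index arrays used each objective evaluation."""
        # running count of rows per (pair, individual)
        w_idx = np.cumsum(
            np.stack(
                [self.mask & (self.ind == i) for i in (0, 1)], axis=1
            ),
            axis=2,
        )  # (P, 2, m)
        pos = np.zeros_like(self.ind)
        for i in (0, 1):
            sel = self.mask & (self.ind == i)
            pos[sel] = (w_idx[:, i, :][sel] - 1)
        self._iw_pos = pos
        y_iw = np.zeros((self.P, 2, 2))
        mask_iw = np.zeros((self.P, 2, 2), dtype=bool)
        pp, rr = np.nonzero(self.mask)
        y_iw[pp, self.ind[pp, rr], pos[pp, rr]] = self.y[pp, rr]
        mask_iw[pp, self.ind[pp, rr], pos[pp, rr]] = True
        self._y_iw, self._mask_iw = y_iw, mask_iw
        self._pp, self._rr = pp, rr
        if self.family == "probit":
            yc = np.zeros((self.P, 2, 2), dtype=np.int64)
            yc[pp, self.ind[pp, rr], pos[pp, rr]] = self._ycode[pp, rr]
            self._ycode_iw = yc

    def _offset_iw(self, offset):
        out = np.zeros((self.P, 2, 2))
        pp, rr = self._pp, self._rr
        out[pp, self.ind[pp, rr], self._iw_pos[pp, rr]] = offset[pp, rr]
        return out

    def _poisson_lognormal_tables(self, s2r, n_nodes=30):
        """log f_k(s) = log int Pois(k | e^(s+r)) N(r; 0, s2r) dr on a
        grid of stable log rates s, one table per distinct count k."""
        grid = self._table_grid
        z, w = np.polynomial.hermite.hermgauss(n_nodes)
        sd = np.sqrt(max(s2r, _VAR_FLOOR))
        shift = np.sqrt(2.0) * sd * z  # (Q,)
        ks = self._distinct_counts
        s = grid[None, :, None] + shift[None, None, :]  # (1, G, Q)
        k = ks[:, None, None]
        loglik = k * s - np.exp(np.clip(s, -700, 40)) - special.gammaln(
            k + 1.0
        )
        logw = np.log(w / np.sqrt(np.pi))[None, None, :]
        tab = special.logsumexp(loglik + logw, axis=2)  # (K, G)
        from scipy.interpolate import CubicSpline

        tables = [CubicSpline(grid, tab[i]) for i in range(len(ks))]
        self._table_cache = (float(s2r), tables)
        return tables

    def _row_logf_at(self, s, tables):
        """Spline-interpolated log row-likelihood at stable values s for
        the Poisson family; padded cells return 0.  Cubic interpolation
        keeps the objective twice continuously differentiable in the
        parameters (finite-difference gradients stay clean)."""
        out = np.zeros_like(s)
        grid = self._table_grid
        s = np.clip(s, grid[0], grid[-1])  # splines must not extrapolate
        kcode = self._count_code  # (P, 2, 2) index into tables
        for ik in range(len(self._distinct_counts)):
            sel = (kcode == ik) & self._mask_iw
            if not sel.any():
                continue
            # broadcast sel over the quadrature axes between ind and wave
            sel_b = np.broadcast_to(
                sel[:, :, None, None, :], s.shape
            )
            out[sel_b] = tables[ik](s[sel_b])
        return out

    def nll_agq(self, offset, s2a, s2c, s2e, s2r, tau=None, q_nodes=11):
        """Negative marginal log-likelihood by nested adaptive quadrature.

        Falls back to the Laplace value if the mode-finding fails.
        """
        base = self.nll(offset, s2a, s2c, s2e, s2r, tau)
        if base >= 1e10:
            return base
        if self.family == "gaussian":
            return base  # Laplace is exact
        u0, H, v = self._mode_u, self._mode_H, self._mode_v
        cov3 = np.linalg.inv(H)[:, :3, :3]
        mode3 = u0[:, :3]

        if not hasattr(self, "_y_iw"):
            self._build_iw_layout()
        off_iw = self._offset_iw(offset)

        z, w = np.polynomial.hermite.hermgauss(q_nodes)
        logw_adj = np.log(w) + z**2  # for adaptive reweighting

        sd_p = np.sqrt(np.maximum(cov3[:, 0, 0], 1e-12))  # (P,)
        b_p = mode3[:, 0:1] + np.sqrt(2.0) * sd_p[:, None] * z[None, :]
        # conditional centers/scales of the individual effects given b_p
        slope = cov3[:, 0, 1:3] / cov3[:, 0, 0][:, None]  # (P, 2)
        cond_var = np.maximum(
            np.stack([cov3[:, 1, 1], cov3[:, 2, 2]], axis=1)
            - slope**2 * cov3[:, 0, 0][:, None],
            1e-12,
        )
        sd_i = np.sqrt(cond_var)  # (P, 2)
        # b_i nodes: (P, 2, Qp, Qi)
        center = (
            mode3[:, 1:3][:, :, None]
            + slope[:, :, None] * (b_p - mode3[:, 0:1])[:, None, :]
        )
        b_i = center[..., None] + np.sqrt(2.0) * sd_i[:, :, None, None] * z

        # stable value per (pair, ind, qp, qi, wave)
        s = (
            off_iw[:, :, None, None, :]
            + b_p[:, None, :, None, None]
            + b_i[..., None]
        )
        if self.family == "poisson":
            cached = getattr(self, "_table_cache", None)
            if cached is not None and cached[0] == float(s2r):
                tables = cached[1]
            else:
                tables = self._poisson_lognormal_tables(s2r)
            logf = self._row_logf_at(s, tables)
        else:  # probit: exact ordinal likelihood at the stable value
            ycode = self._ycode_iw[:, :, None, None, :]
            a = tau[ycode] - s
            b = tau[ycode + 1] - s
            L = np.clip(stats.norm.cdf(b) - stats.norm.cdf(a), 1e-300, None)
            logf = np.where(
                self._mask_iw[:, :, None, None, :], np.log(L), 0.0
            )
        row_sum = logf.sum(axis=4)  # (P, 2, Qp, Qi)

        v_pair = v[:, 0]
        v_ind = v[:, 1]
        log_prior_i = -0.5 * np.log(2 * np.pi * v_ind)[
            :, None, None, None
        ] - 0.5 * b_i**2 / v_ind[:, None, None, None]
        inner = special.logsumexp(
            np.log(np.sqrt(2.0) * sd_i)[:, :, None, None]
            + logw_adj[None, None, None, :]
            + log_prior_i
            + row_sum,
            axis=3,
        )  # (P, 2, Qp)
        log_prior_p = (
            -0.5 * np.log(2 * np.pi * v_pair)[:, None]
            - 0.5 * b_p**2 / v_pair[:, None]
        )
        ll = special.logsumexp(
            np.log(np.sqrt(2.0) * sd_p)[:, None]
            + logw_adj[None, :]
            + log_prior_p
            + inner[:, 0, :]
            + inner[:, 1, :],
            axis=1,
        )
        total = ll.sum()
        if not np.isfinite(total):
            return base
        return -total


def _fingerprint(cohort: pd.DataFrame, y: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(y).tobytes())
    h.update("".join(map(str, cohort["pair_id"].tolist())).encode())
    return h.hexdigest()[:16]


def fit_ace(
    cohort: pd.DataFrame,
    family: str = "poisson",
    covariates: Sequence[str] = ("sex", "wave"),
    include_c: bool = True,
    score: pd.Series | np.ndarray | None = None,
    label: str | None = None,
    start: dict | None = None,
    maxiter: int = 400,
    backend: str = "agq",
    q_nodes: int = 9,
) -> AceFit:
    """Fit the ACE (or AE) biometric mixed model by marginal ML.

    family "poisson" models the integerized symptom count with a log link
    and an observation-level residual variance; "probit" fits the ordinal
    liability-threshold model (categories at every observed score level,
    residual liability fixed at 1); "gaussian" is an identity-link debug
    family with Gaussian observation error (exactly integrable).
    ``score``, when given, enters the linear predictor as one extra fixed
    covariate (the residualized model).

    Estimation is two-stage: a fast Laplace-approximate fit provides
    starting values (and quadrature centering), then the default "agq"
    backend maximizes the nested adaptive Gauss-Hermite marginal
    likelihood with ``q_nodes`` nodes per level, which removes the Laplace
    bias of low-count Poisson responses.  backend="laplace" skips the
    refinement.
    """
    if family not in {"poisson", "probit", "gaussian"}:
        raise ValueError(f"unknown family {family!r}")
    build_biometric_design(cohort)  # emits the single-zygosity warning

    extra = None
    covs = list(covariates)
    if score is not None:
        extra = pd.DataFrame(
            {"polyevent_score": np.asarray(score, dtype=float)},
            index=cohort.index,
        )
        covs = covs + ["polyevent_score"]
    Xdf = design_matrix(cohort, covs, extra=extra)

    if family == "probit":
        yraw = cohort["bpd_score"].to_numpy(dtype=float)
        levels = np.unique(yraw)
        ycode = np.searchsorted(levels, yraw)
        K = len(levels)
        if K < 2:
            raise ValueError("outcome is constant; probit model undefined")
        y = ycode.astype(float)
        names = list(Xdf.columns)
        X = Xdf.to_numpy(dtype=float)
    else:
        if family == "gaussian":
            y = cohort["bpd_score"].to_numpy(dtype=float)
        else:
            y = integerize_scores(cohort["bpd_score"]).astype(float)
        names = ["intercept"] + list(Xdf.columns)
        X = np.column_stack([np.ones(len(Xdf)), Xdf.to_numpy(dtype=float)])

    if backend not in {"agq", "laplace"}:
        raise ValueError(f"unknown backend {backend!r}")
    use_agq = backend == "agq" and family != "gaussian"
    engine = _LaplaceEngine(
        cohort, X, y, family, include_c,
        thresholds_init=np.zeros(K - 1) if family == "probit" else None,
    )
    if family == "probit":
        # outcome codes in the padded per-pair layout
        ycode_pad = np.zeros_like(engine.y, dtype=np.int64)
        ycode_pad[engine.mask] = engine.y[engine.mask].astype(np.int64)
        engine._ycode = ycode_pad

    k = X.shape[1]
    n_sd = (3 if include_c else 2) + (1 if family != "probit" else 0)

    # ---- starting values ----
    if start is None:
        start = {}
    if family == "poisson":
        mean_y = max(float(y.mean()), 1e-3)
        beta0 = np.zeros(k)
        beta0[0] = np.log(mean_y)
        sds0 = np.full(n_sd, 0.5)
    elif family == "gaussian":
        beta0 = np.zeros(k)
        beta0[0] = float(y.mean())
        sd_tot = float(np.std(y)) or 1.0
        sds0 = np.full(n_sd, sd_tot / 2)
    else:
        beta0 = np.zeros(k)
        sds0 = np.full(n_sd, 0.5)
    beta0 = start.get("beta", beta0)
    sds0 = start.get("sds", sds0)

    if family == "probit":
        counts = np.bincount(engine._ycode[engine.mask], minlength=K)
        cum = np.cumsum(counts)[:-1] / counts.sum()
        cum = np.clip(cum, 1e-4, 1 - 1e-4)
        tau0 = stats.norm.ppf(cum) * 1.4
        tinc0 = np.concatenate(
            [[tau0[0]], np.log(np.maximum(np.diff(tau0), 1e-3))]
        )
        theta0 = np.concatenate([beta0, sds0, tinc0])
    else:
        theta0 = np.concatenate([beta0, sds0])

    def unpack(theta):
        beta = theta[:k]
        sds = np.abs(theta[k : k + n_sd])
        i = 0
        s2a = sds[i] ** 2; i += 1
        s2c = sds[i] ** 2 if include_c else 0.0
        if include_c:
            i += 1
        s2e = sds[i] ** 2; i += 1
        if family == "probit":
            s2r = 1.0
            tpar = theta[k + n_sd :]
            tau_core = np.concatenate(
                [[tpar[0]], tpar[0] + np.cumsum(np.exp(tpar[1:]))]
            ) if len(tpar) > 1 else np.array([tpar[0]])
            tau = np.concatenate([[-np.inf], tau_core, [np.inf]])
        else:
            s2r = sds[i] ** 2
            tau = None
        return beta, s2a, s2c, s2e, s2r, tau

    def objective_laplace(theta):
        beta, s2a, s2c, s2e, s2r, tau = unpack(theta)
        offset = np.einsum("prk,k->pr", engine.X, beta)
        return engine.nll(offset, s2a, s2c, s2e, s2r, tau)

    def objective_agq(theta):
        beta, s2a, s2c, s2e, s2r, tau = unpack(theta)
        offset = np.einsum("prk,k->pr", engine.X, beta)
        return engine.nll_agq(offset, s2a, s2c, s2e, s2r, tau, q_nodes)

    bounds = (
        [(None, None)] * k
        + [(0.0, _SD_MAX)] * n_sd
        + [(None, None)] * (len(theta0) - k - n_sd)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            objective_laplace,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-6,
                "eps": 1e-5,
            },
        )
        if use_agq:
            res = optimize.minimize(
                objective_agq,
                res.x,
                method="L-BFGS-B",
                bounds=bounds,
                options={
                    "maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6,
                    "eps": 1e-5,
                },
            )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"ACE fit failed: non-finite likelihood ({res.message})")

    beta, s2a, s2c, s2e, s2r, tau = unpack(res.x)
    vc = VarianceComponents(
        sigma2_a=float(s2a),
        sigma2_c=float(s2c),
        sigma2_e=float(s2e),
        sigma2_resid=float(s2r),
    )
    n_params = len(theta0)
    loglik = -float(res.fun)
    boundary = bool(
        min(
            s2a,
            s2c if include_c else np.inf,
            s2e,
            s2r if family != "probit" else np.inf,
        )
        < 1e-4
    )
    if boundary:
        logger.info("variance component at boundary in %s fit", family)
    return AceFit(
        label=label or ("ACE" if include_c else "AE"),
        family=family,
        include_c=include_c,
        fixed_effects=pd.Series(beta, index=names),
        vc=vc,
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * n_params,
        n_params=n_params,
        n_obs=int(engine.mask.sum()),
        converged=bool(res.success),
        boundary=boundary,
        backend="agq" if use_agq else "laplace",
        thresholds=None if tau is None else tau[1:-1],
        data_fingerprint=_fingerprint(cohort, y),
        has_score=score is not None,
    )


# --------------------------------------------------------------------------
# comparisons
# --------------------------------------------------------------------------

@dataclass
class AicComparison:
    aic_first: float
    aic_second: float
    delta: float
    preferred: str


def compare_aic(fit_a: AceFit, fit_b: AceFit) -> AicComparison:
    """Compare two fits of the same data/family by AIC (lower wins)."""
    if fit_a.family != fit_b.family:
        raise ValueError("fits use different families")
    if fit_a.data_fingerprint != fit_b.data_fingerprint:
        raise ValueError("fits were not computed on the same data")
    delta = fit_b.aic - fit_a.aic
    preferred = fit_a.label if fit_a.aic <= fit_b.aic else fit_b.label
    return AicComparison(
        aic_first=fit_a.aic,
        aic_second=fit_b.aic,
        delta=float(abs(delta)),
        preferred=preferred,
    )


@dataclass
class DecompositionComparison:
    """Baseline vs score-residualized variance components."""

    baseline: VarianceComponents
    residualized: VarianceComponents
    delta: dict = field(default_factory=dict)
    pct_decrease: dict = field(default_factory=dict)
    total_pct_explained: float = np.nan

    def as_dict(self) -> dict:
        return {
            "baseline": self.baseline.as_dict(),
            "residualized": self.residualized.as_dict(),
            "delta": self.delta,
            "pct_decrease": self.pct_decrease,
            "total_pct_explained": self.total_pct_explained,
        }


def compare_decomposition(
    base: VarianceComponents | AceFit, resid: VarianceComponents | AceFit
) -> DecompositionComparison:
    """How much of each stable variance component the risk score explains.

    Per-component percent decreases are reported to one decimal; the total
    percent of stable (A + C + E) variance explained to the nearest
    integer.  Components that are zero at baseline have an undefined
    decrease, reported as NaN.
    """
    if isinstance(base, AceFit) and isinstance(resid, AceFit):
        if base.has_score or not resid.has_score:
            raise ValueError(
                "base fit must exclude and residualized fit include the score"
            )
        if base.family != resid.family:
            raise ValueError("fits use different families")
        base_vc, resid_vc = base.vc, resid.vc
    else:
        base_vc = base.vc if isinstance(base, AceFit) else base
        resid_vc = resid.vc if isinstance(resid, AceFit) else resid

    delta, pct = {}, {}
    for comp, b, r in (
        ("A", base_vc.sigma2_a, resid_vc.sigma2_a),
        ("C", base_vc.sigma2_c, resid_vc.sigma2_c),
        ("E", base_vc.sigma2_e, resid_vc.sigma2_e),
    ):
        delta[comp] = round(r - b, 10)
        # boundary estimates (~0) leave the percent decrease undefined
        pct[comp] = round(100.0 * (b - r) / b, 1) if b > 1e-6 else np.nan
    tb, tr = base_vc.total_ace, resid_vc.total_ace
    total = round(100.0 * (tb - tr) / tb) if tb > 0 else np.nan
    return DecompositionComparison(
        baseline=base_vc,
        residualized=resid_vc,
        delta=delta,
        pct_decrease=pct,
        total_pct_explained=float(total),
    )


# --------------------------------------------------------------------------
# within/between exposure decomposition
# --------------------------------------------------------------------------

def _cluster_sandwich(model, params, groups):
    """CR0 cluster-robust covariance from per-observation scores."""
    s = model.score_obs(params)
    H = model.hessian(params)
    Hinv = np.linalg.inv(-H)
    g = pd.factorize(groups)[0]
    n_g = g.max() + 1
    S = np.zeros((n_g, s.shape[1]))
    np.add.at(S, g, s)
    meat = S.T @ S
    return Hinv @ meat @ Hinv


def within_between_rr(
    cohort: pd.DataFrame,
    exposure: pd.Series | np.ndarray,
    family: str = "poisson",
    covariates: Sequence[str] = ("sex", "wave"),
    dz_between: bool = True,
) -> pd.DataFrame:
    """Whole-sample, within-MZ, within-DZ and additional between-DZ effects.

    The exposure is split into its pair mean (between effect) and the
    within-pair deviation, with deviation slopes estimated separately for
    MZ and DZ pairs (Begg--Parides decomposition).  Poisson effects are
    exponentiated to RRs; the ordinal probit liability model reports
    linear coefficients.  Strata without within-pair exposure variance get
    a missing within effect.
    """
    import statsmodels.api as sm
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    expo = pd.Series(np.asarray(exposure, dtype=float), index=cohort.index)
    pair_mean = expo.groupby(cohort["pair_id"]).transform("mean")
    dev = expo - pair_mean
    is_mz = (cohort["zygosity"] == "MZ").astype(float)
    is_dz = 1.0 - is_mz

    def _has_var(x):
        return float(np.std(x)) > 1e-12

    base = design_matrix(cohort, covariates)
    base = base.loc[:, [c for c in base.columns if _has_var(base[c])]]

    wb = base.copy()
    wb["between"] = pair_mean
    extra_between_dz = (
        dz_between
        and _has_var(pair_mean * is_dz)
        and not (
            (cohort["zygosity"] == "DZ").all()
            or (cohort["zygosity"] == "MZ").all()
        )
    )
    if extra_between_dz:
        wb["between_dz"] = pair_mean * is_dz
    within_ok = {}
    for name, stratum in (("within_mz", is_mz), ("within_dz", is_dz)):
        col = dev * stratum
        within_ok[name] = _has_var(col)
        if within_ok[name]:
            wb[name] = col

    whole = base.copy()
    whole["exposure"] = expo

    groups = pd.factorize(cohort["pair_id"])[0]
    rows = []

    def _fit(Xdf, wanted):
        if family == "poisson":
            y = integerize_scores(cohort["bpd_score"]).astype(float)
            X = sm.add_constant(Xdf, prepend=True)
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit(
                cov_type="cluster",
                cov_kwds={"groups": groups, "use_correction": False},
            )
            for w in wanted:
                est, se = float(res.params[w]), float(res.bse[w])
                rows.append(_record(w, est, se, rr=True))
        else:
            yraw = cohort["bpd_score"].to_numpy(dtype=float)
            levels = np.unique(yraw)
            ycat = pd.Categorical(yraw, categories=levels, ordered=True)
            mod = OrderedModel(ycat, Xdf, distr="probit")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = mod.fit(method="bfgs", disp=0, maxiter=500)
            cov = _cluster_sandwich(mod, res.params.to_numpy(), groups)
            names_all = list(res.params.index)
            for w in wanted:
                i = names_all.index(w)
                est = float(res.params.iloc[i])
                se = float(np.sqrt(cov[i, i]))
                rows.append(_record(w, est, se, rr=False))

    z = stats.norm.ppf(0.975)

    def _record(term, est, se, rr):
        name_map = {
            "exposure": "whole_sample",
            "within_dz": "within_dz",
            "within_mz": "within_mz",
            "between": "between",
            "between_dz": "between_dz_extra",
        }
        rec = {
            "effect": name_map[term],
            "estimate": est,
            "se": se,
            "ci_low": est - z * se,
            "ci_high": est + z * se,
        }
        if rr:
            rec.update(
                rr=float(np.exp(est)),
                rr_ci_low=float(np.exp(est - z * se)),
                rr_ci_high=float(np.exp(est + z * se)),
            )
        return rec

    if not _has_var(expo):
        raise ValueError("exposure has no variance")
    _fit(whole, ["exposure"])
    wanted = ["between"]
    if extra_between_dz:
        wanted.append("between_dz")
    wanted += [w for w in ("within_dz", "within_mz") if within_ok[w]]
    _fit(wb, wanted)
    for name, ok in within_ok.items():
        if not ok:
            rows.append(
                {
                    "effect": name,
                    "estimate": np.nan,
                    "se": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["family"] = family
    return out
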