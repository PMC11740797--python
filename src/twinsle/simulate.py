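"""Synthetic twin-cohort generator.

Simulates long-format twin data with the classical ACE structure on the
log-rate scale of a Poisson symptom count, and binary life-event exposures
drawn from a liability-threshold model that can load on the same genetic
and shared-environment components (gene--environment correlation and
family-environment selection).  The generator is the test substrate for
every downstream analysis stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import GROUPS, N_SLE_TOTAL, SimulationConfig, sle_column_names

COHORT_COLUMNS = (
    ["pair_id", "twin_id", "zygosity", "sex", "wave"]
    + sle_column_names()
    + ["bpd_score"]
)

_GROUP_ZYGOSITY = {
    "MZ-female": "MZ",
    "MZ-male": "MZ",
    "DZ-female": "DZ",
    "DZ-male": "DZ",
    "DZ-opposite-sex": "DZ",
}
_GROUP_SEXES = {
    "MZ-female": ("female", "female"),
    "MZ-male": ("male", "male"),
    "DZ-female": ("female", "female"),
    "DZ-male": ("male", "male"),
    "DZ-opposite-sex": ("female", "male"),
}


def _latent_components(
    config: SimulationConfig, zygosity: np.ndarray, rng: np.random.Generator
):
    """Per-twin additive-genetic, shared-C and nonshared-E draws.

    Returns arrays of shape (n_pairs, 2) for a and e, (n_pairs,) for c.
    MZ co-twins share the full genetic value; DZ co-twins correlate 0.5
    through a shared component plus an individual component of equal
    variance halves.
    """
    n_pairs = zygosity.shape[0]
    sd_a = np.sqrt(config.sigma2_a)
    a_common = rng.normal(0.0, sd_a, size=n_pairs)
    a_unique = rng.normal(0.0, sd_a, size=(n_pairs, 2))
    is_mz = (zygosity == "MZ")[:, None]
    a = np.where(
        is_mz,
        a_common[:, None],
        np.sqrt(0.5) * a_common[:, None] + np.sqrt(0.5) * a_unique,
    )
    c = rng.normal(0.0, np.sqrt(config.sigma2_c), size=n_pairs)
    e = rng.normal(0.0, np.sqrt(config.sigma2_e), size=(n_pairs, 2))
    return a, c, e


def _draw_exposures(
    config: SimulationConfig,
    a: np.ndarray,
    c: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binary exposures of shape (n_pairs, 2, 36) from the liability model.

    The threshold for event j is solved analytically from the normal CDF at
    the total liability variance w_a^2*sigma2_a + w_c^2*sigma2_c + 1, so the
    marginal prevalence equals the configured value exactly.
    """
    n_pairs = a.shape[0]
    eps = rng.standard_normal(size=(n_pairs, 2, N_SLE_TOTAL))
    liab = (
        config.w_a[None, None, :] * a[:, :, None]
        + config.w_c[None, None, :] * c[:, None, None]
        + eps
    )
    total_sd = np.sqrt(
        config.w_a**2 * config.sigma2_a + config.w_c**2 * config.sigma2_c + 1.0
    )
    threshold = norm.isf(config.sle_prevalence) * total_sd
    return (liab > threshold[None, None, :]).astype(np.int64)


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a long-format twin cohort (two waves per twin).

    Each twin contributes one row per wave; exposures are measured once per
    twin and repeated on both rows.  The symptom score is an integer Poisson
    draw on exp(mu0 + wave/sex effects + causal SLE effects + a + c + e +
    observation residual), truncated at ``n_criteria``.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    groups = [g for g in GROUPS if config.n_pairs_by_group.get(g, 0) > 0]
    zygosity = np.concatenate(
        [
            np.repeat(_GROUP_ZYGOSITY[g], config.n_pairs_by_group[g])
            for g in groups
        ]
    ) if groups else np.empty(0, dtype=object)
    sexes = np.array(
        [
            _GROUP_SEXES[g]
            for g in groups
            for _ in range(config.n_pairs_by_group[g])
        ],
        dtype=object,
    ).reshape(-1, 2)
    n_pairs = zygosity.shape[0]
    if n_pairs == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)

    a, c, e = _latent_components(config, zygosity, rng)
    exposures = _draw_exposures(config, a, c, rng)

    # Stable individual log-rate (time-invariant part).
    causal = exposures @ config.gamma  # (n_pairs, 2)
    male = (sexes == "male").astype(float)
    eta_ind = config.mu0 + config.beta_sex * male + causal + a + c[:, None] + e

    rows = []
    for wave in (1, 2):
        eta = eta_ind + config.beta_wave * (wave == 2)
        eta = eta + rng.normal(
            0.0, np.sqrt(config.sigma2_resid), size=eta.shape
        )
        if not np.all(np.isfinite(np.exp(eta))):
            raise FloatingPointError(
                "non-finite Poisson rate; check mu0/gamma/variances "
                f"(max eta = {np.max(eta):.3g})"
            )
        counts = rng.poisson(np.exp(eta))
        rows.append(np.minimum(counts, config.n_criteria))

    pair_id = np.array([f"p{i:05d}" for i in range(n_pairs)])
    records = {
        "pair_id": np.repeat(pair_id, 4),
        "twin_id": np.repeat(
            np.char.add(
                np.repeat(pair_id, 2), np.tile(["_1", "_2"], n_pairs)
            ),
            2,
        ),
        "zygosity": np.repeat(zygosity, 4),
        "sex": np.repeat(sexes.ravel(), 2),
        "wave": np.tile([1, 2], 2 * n_pairs),
    }
    sle_cols = sle_column_names()
    # exposures (n_pairs, 2, 36) -> per twin, repeated across the two waves
    exp_flat = np.repeat(exposures.reshape(-1, N_SLE_TOTAL), 2, axis=0)
    for j, col in enumerate(sle_cols):
        records[col] = exp_flat[:, j]
    score = np.empty((n_pairs, 2, 2), dtype=np.int64)
    score[:, :, 0] = rows[0]
    score[:, :, 1] = rows[1]
    records["bpd_score"] = score.reshape(-1)

    cohort = pd.DataFrame(records, columns=COHORT_COLUMNS)
    cohort["bpd_score"] = cohort["bpd_score"].astype(float)
    return cohort


def latent_values(config: SimulationConfig) -> pd.DataFrame:
    """Per-twin latent components (a, c, e) for the given configuration.

    Re-draws the exact latent stream used by :func:`simulate_cohort` (same
    seed, same order), for diagnostics and closed-form covariance checks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    groups = [g for g in GROUPS if config.n_pairs_by_group.get(g, 0) > 0]
    zygosity = np.concatenate(
        [
            np.repeat(_GROUP_ZYGOSITY[g], config.n_pairs_by_group[g])
            for g in groups
        ]
    )
    a, c, e = _latent_components(config, zygosity, rng)
    n_pairs = a.shape[0]
    return pd.DataFrame(
        {
            "pair_id": np.repeat([f"p{i:05d}" for i in range(n_pairs)], 2),
            "member": np.tile([1, 2], n_pairs),
            "zygosity": np.repeat(zygosity, 2),
            "a": a.ravel(),
            "c": np.repeat(c, 2),
            "e": e.ravel(),
        }
    )
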