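"""Simulation configuration and study constants.

The constants in this module encode the published descriptive tables of the
Norwegian twin-panel study of stressful life events (SLEs) and borderline
personality disorder (BPD) symptoms: exposure counts per event and period,
the elastic-net relative risks used as default effect sizes, and the
baseline ACE variance components.  They serve as the default conditions of
the synthetic cohort generator.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

#: The five zygosity-by-sex sampling groups.
GROUPS = ("MZ-female", "MZ-male", "DZ-female", "DZ-male", "DZ-opposite-sex")

#: Number of distinct stressful life events; each is coded separately for
#: childhood (up to age 18) and adulthood, giving 36 indicators.
N_SLE = 18
N_SLE_TOTAL = 2 * N_SLE

SLE_LABELS = (
    "Life-threatening illness",
    "Life-threatening accident",
    "Actively participated in war/combat",
    "Witnessed anyone be badly injured or killed",
    "Threatened with a weapon, held captive, or kidnapped",
    "Experienced fire, flooding, or natural disaster",
    "Rape",
    "Sexual abuse",
    "Otherwise physically attacked or assaulted",
    "Otherwise physically abused as a child",
    "Otherwise mistreated as a child",
    "Parental mental illness or alcohol problems as a child",
    "Parental divorce or separation as a child",
    "Having divorced or separated",
    "Long-term financial difficulties",
    "Unemployment for more than 6 months",
    "Major and lasting conflict with close person",
    "Other serious life event",
)

#: Exposure counts among measures with / without BPD symptoms, per event,
#: as (childhood_with, childhood_without, adulthood_with, adulthood_without).
SLE_EXPOSURE_COUNTS = (
    (40, 48, 54, 46),
    (44, 45, 82, 76),
    (0, 0, 23, 28),
    (40, 54, 107, 131),
    (26, 29, 110, 85),
    (46, 27, 60, 76),
    (55, 34, 51, 23),
    (162, 110, 32, 20),
    (120, 65, 169, 136),
    (90, 46, 0, 0),
    (79, 31, 0, 0),
    (298, 218, 6, 5),
    (362, 373, 28, 42),
    (5, 3, 404, 453),
    (10, 4, 118, 72),
    (12, 6, 134, 126),
    (27, 13, 148, 148),
    (79, 62, 154, 200),
)

#: Denominators of the two symptom strata (measures with / without symptoms).
N_MEASURES_WITH_SYMPTOMS = 2151
N_MEASURES_WITHOUT_SYMPTOMS = 2924
N_MEASURES_TOTAL = N_MEASURES_WITH_SYMPTOMS + N_MEASURES_WITHOUT_SYMPTOMS

#: Relative risks from the best-fitting elastic-net model, (childhood,
#: adulthood) per event; None marks a coefficient shrunk exactly to zero.
ELASTIC_NET_RR = (
    (None, 1.23),
    (None, 1.17),
    (None, None),
    (1.17, None),
    (0.73, 1.21),
    (1.19, None),
    (1.46, 1.59),
    (1.15, 1.08),
    (1.40, 1.56),
    (1.19, None),
    (1.88, None),
    (1.44, None),
    (1.15, 0.69),
    (None, 1.11),
    (1.24, 1.19),
    (None, 1.23),
    (1.12, 1.32),
    (1.33, 1.18),
)

#: Baseline ACE variance components on the log-rate scale (Poisson model):
#: additive genetic, shared environment, nonshared environment, and the
#: observation-level residual.
BASELINE_VARIANCES = {
    "sigma2_A": 0.36,
    "sigma2_C": 0.24,
    "sigma2_E": 0.17,
    "sigma2_resid": 0.59,
}

#: Complete twin pairs per group at wave 1 (twins counts halved).
PAIRS_BY_GROUP = {
    "MZ-female": 451,
    "MZ-male": 222,
    "DZ-female": 265,
    "DZ-male": 119,
    "DZ-opposite-sex": 343,
}

#: Floor applied to never-endorsed events so prevalences stay in (0, 1).
MIN_PREVALENCE = 5e-4


def sle_column_names() -> list[str]:
    """Column names of the 36 SLE indicators: childhood then adulthood."""
    return [f"sle_c_{j:02d}" for j in range(1, N_SLE + 1)] + [
        f"sle_a_{j:02d}" for j in range(1, N_SLE + 1)
    ]


def default_prevalences() -> np.ndarray:
    """Marginal exposure prevalences of the 36 indicators.

    Derived from the published exposure counts over all symptom measures;
    cells with zero endorsement are floored at :data:`MIN_PREVALENCE`.
    """
    child = [(c[0] + c[1]) / N_MEASURES_TOTAL for c in SLE_EXPOSURE_COUNTS]
    adult = [(c[2] + c[3]) / N_MEASURES_TOTAL for c in SLE_EXPOSURE_COUNTS]
    p = np.array(child + adult, dtype=float)
    return np.clip(p, MIN_PREVALENCE, 1.0 - MIN_PREVALENCE)


def elastic_net_log_rr() -> np.ndarray:
    """Published elastic-net coefficients on the log scale (0 where shrunk)."""
    child = [math.log(c[0]) if c[0] else 0.0 for c in ELASTIC_NET_RR]
    adult = [math.log(c[1]) if c[1] else 0.0 for c in ELASTIC_NET_RR]
    return np.array(child + adult, dtype=float)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic twin-cohort generator.

    The generative model draws, per pair, an additive-genetic component
    shared fully by MZ and half by DZ co-twins, a shared-environment
    component, an individual nonshared component, and an observation-level
    residual, all on the log-rate scale.  Exposure indicators arise from a
    liability-threshold model whose liability may load on the genetic
    (``w_a``, gene--environment correlation) and shared-environment
    (``w_c``, family selection) components; ``gamma`` holds the causal
    log-rate effects of each exposure on the symptom count.
    """

    n_pairs_by_group: dict[str, int] = field(
        default_factory=lambda: dict(PAIRS_BY_GROUP)
    )
    sigma2_a: float = BASELINE_VARIANCES["sigma2_A"]
    sigma2_c: float = BASELINE_VARIANCES["sigma2_C"]
    sigma2_e: float = BASELINE_VARIANCES["sigma2_E"]
    sigma2_resid: float = BASELINE_VARIANCES["sigma2_resid"]
    n_criteria: int = 9
    mu0: float = -1.05
    beta_wave: float = math.log(0.65)
    beta_sex: float = math.log(1.05)
    sle_prevalence: np.ndarray = field(default_factory=default_prevalences)
    w_a: np.ndarray = field(default_factory=lambda: np.zeros(N_SLE_TOTAL))
    w_c: np.ndarray = field(default_factory=lambda: np.zeros(N_SLE_TOTAL))
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(N_SLE_TOTAL))
    seed: int = 0

    def __post_init__(self) -> None:
        self.sle_prevalence = np.asarray(self.sle_prevalence, dtype=float)
        self.w_a = np.asarray(self.w_a, dtype=float)
        self.w_c = np.asarray(self.w_c, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.validate()

    def validate(self) -> None:
        problems = []
        for name in ("sigma2_a", "sigma2_c", "sigma2_e", "sigma2_resid"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be nonnegative")
        if self.n_criteria < 1:
            problems.append("n_criteria must be a positive integer")
        unknown = set(self.n_pairs_by_group) - set(GROUPS)
        if unknown:
            problems.append(f"unknown groups: {sorted(unknown)}")
        if any(v < 0 for v in self.n_pairs_by_group.values()):
            problems.append("pair counts must be nonnegative")
        for name in ("sle_prevalence", "w_a", "w_c", "gamma"):
            if getattr(self, name).shape != (N_SLE_TOTAL,):
                problems.append(f"{name} must have length {N_SLE_TOTAL}")
        if self.sle_prevalence.shape == (N_SLE_TOTAL,) and not np.all(
            (self.sle_prevalence > 0) & (self.sle_prevalence < 1)
        ):
            problems.append("sle_prevalence must lie strictly in (0, 1)")
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))

    @property
    def n_pairs(self) -> int:
        return sum(self.n_pairs_by_group.values())

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("sle_prevalence", "w_a", "w_c", "gamma"):
            d[k] = [float(x) for x in d[k]]
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


def paper_like_config(seed: int = 0) -> SimulationConfig:
    """Study-condition configuration of the synthetic cohort.

    Pair counts follow the wave-1 sample, exposure prevalences the published
    rates, and variance components the baseline ACE estimates.  Half of each
    published elastic-net log-RR is taken as the causal effect ``gamma``;
    the remainder of the SLE--symptom association is induced as familial
    confounding through shared-environment loadings (stronger for childhood
    events) and a weaker genetic loading.
    """
    log_rr = elastic_net_log_rr()
    w_c = np.where(
        np.arange(N_SLE_TOTAL) < N_SLE, 0.30, 0.15
    ) * (log_rr != 0)
    w_a = 0.15 * (log_rr != 0)
    return SimulationConfig(
        gamma=0.5 * log_rr,
        w_c=w_c,
        w_a=w_a,
        seed=seed,
    )
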