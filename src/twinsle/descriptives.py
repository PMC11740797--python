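"""Descriptive tables: sample counts, SLE prevalence by symptom status,
and the grouped childhood/adulthood event variables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import N_SLE, SLE_LABELS, sle_column_names


def sample_counts(cohort: pd.DataFrame) -> pd.DataFrame:
    """Participating twins per zygosity/sex group and wave."""
    if cohort.empty:
        return pd.DataFrame(columns=["group", "wave_1", "wave_2"])
    df = cohort.copy()
    is_os = (
        df.groupby("pair_id")["sex"].transform("nunique") > 1
    ) & (df["zygosity"] == "DZ")
    df["group"] = np.where(
        is_os, "DZ-opposite-sex", df["zygosity"] + "-" + df["sex"]
    )
    tab = (
        df.groupby(["group", "wave"])["twin_id"]
        .nunique()
        .unstack("wave", fill_value=0)
    )
    tab.columns = [f"wave_{w}" for w in tab.columns]
    return tab.reset_index()


def has_symptoms(cohort: pd.DataFrame) -> pd.Series:
    """Measure-level indicator of any BPD symptom (score above zero)."""
    return cohort["bpd_score"] > 0


def tabulate_prevalence(cohort: pd.DataFrame) -> pd.DataFrame:
    """Exposure counts and percentages split by presence of BPD symptoms.

    One record per (event, period) over all twin-wave measures; percentages
    are reported to two decimals of the stratum denominator.  The
    denominators are attached as ``DataFrame.attrs['n_with_symptoms']`` and
    ``attrs['n_without_symptoms']``.
    """
    cols = [
        "sle",
        "label",
        "period",
        "n_with_symptoms",
        "pct_with_symptoms",
        "n_without_symptoms",
        "pct_without_symptoms",
    ]
    if cohort.empty:
        out = pd.DataFrame(columns=cols)
        out.attrs["n_with_symptoms"] = 0
        out.attrs["n_without_symptoms"] = 0
        return out

    symptomatic = has_symptoms(cohort)
    n_with = int(symptomatic.sum())
    n_without = int((~symptomatic).sum())
    records = []
    for j in range(1, N_SLE + 1):
        for period, prefix in (("childhood", "sle_c"), ("adulthood", "sle_a")):
            col = f"{prefix}_{j:02d}"
            exposed = cohort[col] == 1
            cw = int((exposed & symptomatic).sum())
            co = int((exposed & ~symptomatic).sum())
            records.append(
                {
                    "sle": j,
                    "label": SLE_LABELS[j - 1],
                    "period": period,
                    "n_with_symptoms": cw,
                    "pct_with_symptoms": round(100 * cw / n_with, 2)
                    if n_with
                    else 0.0,
                    "n_without_symptoms": co,
                    "pct_without_symptoms": round(100 * co / n_without, 2)
                    if n_without
                    else 0.0,
                }
            )
    out = pd.DataFrame.from_records(records, columns=cols)
    out.attrs["n_with_symptoms"] = n_with
    out.attrs["n_without_symptoms"] = n_without
    return out


def build_grouped_sle(cohort: pd.DataFrame, mode: str = "count") -> pd.DataFrame:
    """Per-measure grouped SLE variables for childhood and adulthood.

    mode="count": number of distinct events endorsed in the period (0-18);
    mode="any": binary indicator of at least one event.
    """
    if mode not in {"count", "any"}:
        raise ValueError(f"mode must be 'count' or 'any', got {mode!r}")
    cols = sle_column_names()
    child = cohort[cols[:N_SLE]].sum(axis=1)
    adult = cohort[cols[N_SLE:]].sum(axis=1)
    if mode == "any":
        child = (child > 0).astype(np.int64)
        adult = (adult > 0).astype(np.int64)
    return pd.DataFrame(
        {"sle_child": child, "sle_adult": adult}, index=cohort.index
    )
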