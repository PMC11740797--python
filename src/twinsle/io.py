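"""Reading, writing and validating twin-cohort tables.

The on-disk dialect is TSV (UTF-8, "." decimal, no quoting); CSV is
accepted on read.  Validation enumerates every schema violation rather
than stopping at the first.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig, sle_column_names
from .simulate import COHORT_COLUMNS


class CohortSchemaError(ValueError):
    """Raised when a cohort table violates the schema; lists all problems."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid cohort table:\n  - " + "\n  - ".join(self.problems)
        )


def validate_cohort(cohort: pd.DataFrame) -> list[str]:
    """Return a list of schema violations (empty if the table is valid)."""
    problems: list[str] = []
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        problems.append(f"missing columns: {missing}")
        return problems
    if cohort.empty:
        return problems

    bad_zyg = set(cohort["zygosity"].unique()) - {"MZ", "DZ"}
    if bad_zyg:
        problems.append(f"zygosity values outside {{MZ, DZ}}: {sorted(bad_zyg)}")
    bad_sex = set(cohort["sex"].unique()) - {"female", "male"}
    if bad_sex:
        problems.append(f"sex values outside {{female, male}}: {sorted(bad_sex)}")
    bad_wave = set(cohort["wave"].unique()) - {1, 2}
    if bad_wave:
        problems.append(f"wave values outside {{1, 2}}: {sorted(bad_wave)}")

    for col in sle_column_names():
        vals = pd.unique(cohort[col])
        if not np.isin(vals, [0, 1]).all():
            problems.append(f"non-binary values in {col}")

    score = cohort["bpd_score"].to_numpy(dtype=float)
    if np.any(score < 0):
        problems.append("negative bpd_score values")
    if not np.allclose(score * 2, np.round(score * 2)):
        problems.append("bpd_score values not in half-unit increments")

    sizes = cohort.groupby("pair_id")["twin_id"].nunique()
    bad_pairs = sizes[sizes != 2]
    if not bad_pairs.empty:
        problems.append(
            "pairs without exactly 2 twins: "
            f"{list(bad_pairs.index[:10])}"
        )
    mz = cohort[cohort["zygosity"] == "MZ"]
    if not mz.empty:
        nsex = mz.groupby("pair_id")["sex"].nunique()
        mixed = nsex[nsex > 1]
        if not mixed.empty:
            problems.append(
                f"MZ pairs with mixed sex: {list(mixed.index[:10])}"
            )
    dup = cohort.duplicated(subset=["twin_id", "wave"])
    if dup.any():
        problems.append(
            "twins with more than one row per wave: "
            f"{sorted(cohort.loc[dup, 'twin_id'].unique()[:10])}"
        )
    per_twin = cohort.groupby("twin_id")[sle_column_names()].nunique()
    varying = per_twin[(per_twin > 1).any(axis=1)]
    if not varying.empty:
        problems.append(
            "SLE indicators differ across a twin's rows: "
            f"{list(varying.index[:10])}"
        )
    return problems


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as TSV with 0/1 indicator columns."""
    out = cohort.copy()
    for col in sle_column_names():
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path, validate: bool = True) -> pd.DataFrame:
    """Read a TSV/CSV cohort table, validating the schema.

    Raises :class:`CohortSchemaError` listing every violation found.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    cohort = pd.read_csv(path, sep=sep, comment="#")
    if validate:
        problems = validate_cohort(cohort)
        if problems:
            raise CohortSchemaError(problems)
    for col in sle_column_names():
        cohort[col] = cohort[col].astype(np.int64)
    cohort["wave"] = cohort["wave"].astype(np.int64)
    cohort["bpd_score"] = cohort["bpd_score"].astype(float)
    return cohort


def write_config_sidecar(config: SimulationConfig, cohort_path: str | Path) -> Path:
    """Echo the generating configuration (with seed) next to the cohort."""
    sidecar = Path(cohort_path).with_suffix(".config.json")
    sidecar.write_text(config.to_json(indent=2))
    return sidecar


def integerize_scores(score: pd.Series | np.ndarray) -> np.ndarray:
    """Integer symptom counts for count-model likelihoods.

    Instrument scores step in halves (0, 0.5, 1, 1.5 per criterion); when
    any half-point value is present the whole column is doubled, which
    leaves rate ratios untouched under a log link (the intercept shifts by
    log 2).  Integer-valued columns pass through unchanged.
    """
    arr = np.asarray(score, dtype=float)
    if np.allclose(arr, np.round(arr)):
        return np.round(arr).astype(np.int64)
    doubled = arr * 2
    if not np.allclose(doubled, np.round(doubled)):
        raise ValueError("scores are not on a half-unit grid")
    return np.round(doubled).astype(np.int64)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, comment="#")


def write_table(df: pd.DataFrame, path: str | Path, header_note: str | None = None) -> None:
    """Write a TSV result table, optionally with a provenance comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float))
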