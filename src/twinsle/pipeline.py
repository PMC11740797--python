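"""End-to-end orchestration of the synthetic-study analysis.

One configuration (YAML/JSON or dict) drives: simulate (or read) a
cohort -> descriptives -> count regressions -> elastic net + risk score
-> baseline and residualized ACE fits -> within/between RRs, writing TSV
and JSON outputs plus a run manifest with seeds and a config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ace import compare_aic, compare_decomposition, fit_ace, within_between_rr
from .config import SimulationConfig, paper_like_config
from .count_regression import ModelSpec, fit_count_model, overdispersion_test
from .descriptives import build_grouped_sle, sample_counts, tabulate_prevalence
from .io import (
    read_cohort,
    write_cohort,
    write_config_sidecar,
    write_json,
    write_table,
)
from .polyevent import ElasticNetConfig, compute_risk_score, fit_elastic_net_cv
from .simulate import simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    results_dir: str = "results"
    cohort_path: str | None = None  # read this cohort instead of simulating
    simulation: SimulationConfig | None = None
    elastic_net: ElasticNetConfig = field(default_factory=ElasticNetConfig)
    ace_families: tuple[str, ...] = ("poisson", "probit")
    group_mode: str = "count"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and d["simulation"] is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "elastic_net" in d and d["elastic_net"] is not None:
            d["elastic_net"] = ElasticNetConfig(**d["elastic_net"])
        if "ace_families" in d:
            d["ace_families"] = tuple(d["ace_families"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        )
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return {
            "results_dir": self.results_dir,
            "cohort_path": self.cohort_path,
            "simulation": None
            if self.simulation is None
            else self.simulation.to_dict(),
            "elastic_net": {
                "alpha_grid": list(self.elastic_net.alpha_grid),
                "n_lambda": self.elastic_net.n_lambda,
                "lambda_min_ratio": self.elastic_net.lambda_min_ratio,
                "n_folds": self.elastic_net.n_folds,
                "fold_seed": self.elastic_net.fold_seed,
                "fold_unit": self.elastic_net.fold_unit,
            },
            "ace_families": list(self.ace_families),
            "group_mode": self.group_mode,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        """Fingerprint of the analytic configuration (where outputs are
        written is not part of it)."""
        d = self.to_dict()
        d.pop("results_dir", None)
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict."""
    out = Path(config.results_dir)
    out.mkdir(parents=True, exist_ok=True)
    note = f"twinsle {__version__} config={config.config_hash()}"
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": [],
    }

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    # --- cohort ---
    stage("cohort")
    if config.cohort_path:
        cohort = read_cohort(config.cohort_path)
    else:
        sim = config.simulation or paper_like_config(seed=config.seed)
        cohort = simulate_cohort(sim)
        write_cohort(cohort, out / "cohort.tsv")
        write_config_sidecar(sim, out / "cohort.tsv")
    logger.info("cohort: %d rows, %d pairs", len(cohort),
                cohort["pair_id"].nunique())

    # --- descriptives ---
    stage("descriptives")
    write_table(sample_counts(cohort), out / "sample_counts.tsv", note)
    prev = tabulate_prevalence(cohort)
    write_table(prev, out / "sle_prevalence.tsv", note + f" | n_with={prev.attrs['n_with_symptoms']} n_without={prev.attrs['n_without_symptoms']}")

    # --- count regression ---
    stage("count_regression")
    spec = ModelSpec(
        covariates=["sle_child", "sle_adult", "sex", "wave"],
        family="poisson",
        group_mode=config.group_mode,
    )
    od = overdispersion_test(cohort, spec)
    manifest["overdispersion"] = {
        "lr_stat": od.lr_stat, "p_value": od.p_value, "reject": od.reject
    }
    family = "negbin" if od.reject else "poisson"
    grouped_tab = fit_count_model(
        cohort, ModelSpec(
            covariates=["sle_child", "sle_adult", "sex", "wave"],
            family=family, group_mode=config.group_mode,
        )
    )
    write_table(grouped_tab, out / "grouped_sle_rr.tsv", note)

    # --- elastic net / polyevent score ---
    stage("polyevent")
    model = fit_elastic_net_cv(cohort, config.elastic_net)
    score = compute_risk_score(model, cohort)
    write_table(model.rr_table(), out / "elastic_net_rr.tsv", note)
    write_table(model.cv_curve, out / "cv_curve.tsv", note)
    write_table(
        pd.DataFrame({"risk_score": score.scores}),
        out / "risk_score.tsv",
        note,
    )
    manifest["polyevent"] = {
        "alpha": model.alpha,
        "lambda": model.lambda_,
        "n_selected": model.n_selected,
        **score.summary(),
    }

    # --- co-twin ACE models ---
    stage("cotwin_ace")
    ace_results = {}
    for fam in config.ace_families:
        base = fit_ace(cohort, family=fam, label=f"{fam}-ACE-baseline")
        ae = fit_ace(
            cohort, family=fam, include_c=False, label=f"{fam}-AE-baseline"
        )
        resid = fit_ace(
            cohort,
            family=fam,
            score=score.scores,
            label=f"{fam}-ACE-residualized",
        )
        comp = compare_aic(base, ae)
        decomp = compare_decomposition(base, resid)
        ace_results[fam] = {
            "baseline": base.summary(),
            "ae": ae.summary(),
            "residualized": resid.summary(),
            "aic_comparison": {
                "ace": comp.aic_first,
                "ae": comp.aic_second,
                "delta": comp.delta,
                "preferred": comp.preferred,
            },
            "decomposition": decomp.as_dict(),
        }
        table5 = []
        for lbl, fit in (("baseline", base), ("residualized", resid)):
            std = fit.standardized()
            table5.append(
                {
                    "model": lbl,
                    "A": fit.vc.sigma2_a, "A_pct": round(std.pct_a),
                    "C": fit.vc.sigma2_c, "C_pct": round(std.pct_c),
                    "E": fit.vc.sigma2_e, "E_pct": round(std.pct_e),
                    "residual": fit.vc.sigma2_resid,
                    "total": fit.vc.total,
                    "aic": fit.aic,
                }
            )
        write_table(
            pd.DataFrame(table5), out / f"ace_components_{fam}.tsv", note
        )
    manifest["ace"] = ace_results

    # --- within/between RRs ---
    stage("within_between")
    grouped = build_grouped_sle(cohort, mode=config.group_mode)
    exposure = grouped["sle_child"] + grouped["sle_adult"]
    wb_frames = []
    for fam in config.ace_families:
        wb = within_between_rr(cohort, exposure, family=fam)
        wb.insert(0, "family", fam)
        wb_frames.append(wb)
    write_table(
        pd.concat(wb_frames, ignore_index=True),
        out / "within_between.tsv",
        note,
    )

    manifest_path = out / "manifest.json"
    write_json(manifest, manifest_path)
    logger.info("wrote %s", manifest_path)
    return manifest
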