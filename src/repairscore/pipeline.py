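"""End-to-end workflow: simulate or load cohorts, train the frozen risk
model, apply it, combine with mutation status, and emit a report bundle.

The report bundle written by :func:`run_pipeline` contains:

* ``model.json`` — the frozen risk model (panel, pathway cutpoints,
  retained pathways, merge map);
* ``panel.tsv`` — the selected probe sets with cutpoint, beta, HR,
  adjusted p per cohort and prognosis direction;
* ``pathway_cox.tsv`` — univariate and multivariate hazard ratios for all
  scored pathway flags;
* ``stratification_<cohort>.tsv`` — per-patient pathway scores, high/low
  flags, global group, points and final group;
* ``km_summary_<cohort>.tsv`` — per-group n, events, median OS (days, or
  "NR" when not reached) with CI, one-year OS with CI, log-rank p;
* ``run_log.txt`` — every parameter and seed of the run.

All randomness flows through the seed recorded in the log; a rerun with
the same configuration reproduces the bundle byte for byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .combined import classify_combined
from .estimators import CombinedRiskModel, DNARepairRiskModel
from .signature import DegenerateModelError, RiskModel, apply_frozen_model
from .simulate import default_study_configs, simulate_two_cohort_study
from .survival import SurvivalData, km_estimate, logrank_test, median_followup

logger = logging.getLogger("repairscore")

__all__ = ["run_pipeline", "train_model", "km_group_summary", "load_cohort"]


def load_cohort(expression_path, clinical_path, dialect="auto"):
    """Load and align an expression matrix with its clinical table."""
    expr = _io.read_expression(expression_path, dialect=dialect)
    clin = _io.read_clinical(clinical_path)
    shared = expr.index.intersection(clin.index)
    if len(shared) == 0:
        raise _io.ValidationError(
            "expression and clinical tables share no patient IDs"
        )
    if len(shared) < len(expr.index) or len(shared) < len(clin.index):
        logger.warning(
            "restricting to %d patients present in both tables", len(shared)
        )
    return expr.loc[shared], clin.loc[shared]


def _surv(clinical: pd.DataFrame, endpoint: str) -> SurvivalData:
    if endpoint not in ("os", "efs"):
        raise ValueError("endpoint must be 'os' or 'efs'")
    return SurvivalData.from_frame(clinical, f"{endpoint}_days", f"{endpoint}_event")


def train_model(
    expr_train,
    clin_train,
    expr_confirm,
    clin_confirm,
    gene_sets,
    alpha: float = 0.05,
    endpoint: str = "os",
) -> tuple[RiskModel, pd.DataFrame, DNARepairRiskModel]:
    """Fit the full frozen model (panel, pathway cutpoints, retention,
    merge map) on the training cohort, screening in both cohorts."""
    y_train = _surv(clin_train, endpoint)
    scorer = DNARepairRiskModel(gene_sets=gene_sets, alpha=alpha)
    scorer.fit(
        expr_train,
        y_train,
        X_confirm=expr_confirm,
        y_confirm=_surv(clin_confirm, endpoint),
    )
    strat = scorer.training_result_
    combiner = CombinedRiskModel(alpha=alpha)
    features = pd.DataFrame(
        {
            "global_group": strat.global_group,
            "npm1_mutated": clin_train["npm1_mutated"],
            "flt3_itd": clin_train["flt3_itd"],
        }
    )
    combiner.fit(features, y_train)
    model = RiskModel(
        panel=scorer.panel_,
        pathway_models=scorer.pathway_models_,
        retained_pathways=scorer.retained_pathways_,
        merge_map=combiner.merge_map_,
        alpha=alpha,
        endpoint=endpoint,
    )
    table = strat.to_frame()
    comb, _ = classify_combined(strat.global_group, clin_train, combiner.merge_map_)
    table = table.join(comb)
    return model, table, scorer


def apply_model(model: RiskModel, expr, clin) -> pd.DataFrame:
    """Frozen-model application to a cohort (no re-estimation)."""
    logger.info("frozen-model mode: applying stored cutpoints, no re-estimation")
    strat = apply_frozen_model(expr, model)
    table = strat.to_frame()
    if {"npm1_mutated", "flt3_itd"} <= set(clin.columns) and model.merge_map:
        comb, _ = classify_combined(strat.global_group, clin, model.merge_map)
        table = table.join(comb)
    return table


def km_group_summary(
    data: SurvivalData, groups: pd.Series, conf_level: float = 0.95
) -> pd.DataFrame:
    """Per-group KM summaries: n, events, median (CI), one-year survival (CI)."""
    rows = []
    groups = pd.Series(groups).reset_index(drop=True)
    for g in sorted(groups.dropna().unique()):
        mask = (groups == g).to_numpy()
        curve = km_estimate(data.subset(mask), conf_level=conf_level)
        lo, hi = curve.ci_at(365.0)
        rows.append(
            {
                "group": g,
                "n": int(mask.sum()),
                "events": curve.n_events,
                "median_days": _io.format_duration(curve.median),
                "median_ci_low": _io.format_duration(curve.median_ci[0]),
                "median_ci_high": _io.format_duration(curve.median_ci[1]),
                "one_year_survival_pct": round(100 * curve.survival_at(365.0), 1),
                "one_year_ci_low_pct": round(100 * lo, 1),
                "one_year_ci_high_pct": round(100 * hi, 1),
            }
        )
    out = pd.DataFrame(rows)
    if groups.dropna().nunique() >= 2:
        res = logrank_test(data, groups)
        out["logrank_p_overall"] = res.p_value
    return out


def _write_bundle(outdir: Path, model, tables, summaries, pathway_cox, log_lines):
    outdir.mkdir(parents=True, exist_ok=True)
    model.to_json(outdir / "model.json")
    model.panel.table.to_csv(outdir / "panel.tsv", sep="\t", index=False, float_format="%.6g")
    pathway_cox.to_csv(outdir / "pathway_cox.tsv", sep="\t", index=False, float_format="%.6g")
    for name, table in tables.items():
        table.to_csv(outdir / f"stratification_{name}.tsv", sep="\t", float_format="%.6g")
    for name, summ in summaries.items():
        summ.to_csv(outdir / f"km_summary_{name}.tsv", sep="\t", index=False, float_format="%.6g")
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")


def run_pipeline(config: dict, outdir) -> dict:
    """Run the configured workflow and write the report bundle.

    ``config`` keys: ``seed`` (int, default 0); either ``simulate`` (dict of
    SimulationConfig overrides, may be empty) or ``training`` /
    ``validation`` (dicts with ``expression`` and ``clinical`` paths) plus
    ``gene_sets`` (path); ``alpha`` (default 0.05); ``endpoint``
    ("os"/"efs", default "os").
    """
    outdir = Path(outdir)
    seed = int(config.get("seed", 0))
    alpha = float(config.get("alpha", 0.05))
    endpoint = str(config.get("endpoint", "os"))
    log = [
        "repairscore run",
        f"seed: {seed}",
        f"alpha: {alpha}",
        f"endpoint: {endpoint}",
    ]

    if "simulate" in config:
        overrides = dict(config.get("simulate") or {})
        study_keys = {
            k: overrides.pop(k)
            for k in ("n_training", "n_validation", "flt3_training", "flt3_validation")
            if k in overrides
        }
        cfg_tr, cfg_va = default_study_configs(seed=seed, **study_keys, **overrides)
        tr, va = simulate_two_cohort_study(cfg_tr, cfg_va)
        expr_tr, clin_tr = tr.expression, tr.clinical
        expr_va, clin_va = va.expression, va.clinical
        gene_sets = dict(zip(tr.gene_sets["probe_set"], tr.gene_sets["pathway"]))
        log.append(f"simulated study: {cfg_tr}")
    else:
        expr_tr, clin_tr = load_cohort(
            config["training"]["expression"], config["training"]["clinical"]
        )
        expr_va, clin_va = load_cohort(
            config["validation"]["expression"], config["validation"]["clinical"]
        )
        gene_sets = _io.read_gene_sets(config["gene_sets"])
        log.append(f"training files: {config['training']}")
        log.append(f"validation files: {config['validation']}")

    y_tr = _surv(clin_tr, endpoint)
    y_va = _surv(clin_va, endpoint)
    log.append(
        f"training cohort: n={len(clin_tr)}, events={y_tr.n_events}, "
        f"median follow-up={_io.format_duration(median_followup(y_tr))}"
    )
    log.append(f"validation cohort: n={len(clin_va)}, events={y_va.n_events}")

    model, table_tr, scorer = train_model(
        expr_tr, clin_tr, expr_va, clin_va, gene_sets, alpha=alpha, endpoint=endpoint
    )
    log.append(f"panel: {len(model.panel)} probe sets selected")
    log.append(f"retained pathways: {list(model.retained_pathways)}")
    log.append(f"merge map: {model.merge_map}")

    table_va = apply_model(model, expr_va, clin_va)
    log.append("validation scored in frozen-model mode (no re-estimation)")

    tables = {"training": table_tr, "validation": table_va}
    summaries = {}
    for name, (table, y) in {
        "training": (table_tr, y_tr),
        "validation": (table_va, y_va),
    }.items():
        summaries[f"{name}_global"] = km_group_summary(y, table["global_group"])
        if "final_group" in table:
            summaries[f"{name}_final"] = km_group_summary(y, table["final_group"])

    _write_bundle(outdir, model, tables, summaries, scorer.retention_.univariate, log)
    return {
        "model": model,
        "tables": tables,
        "summaries": summaries,
        "pathway_cox": scorer.retention_.univariate,
        "log": log,
    }
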