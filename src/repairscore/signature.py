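"""Construction and application of the DNA-repair prognostic signature.

The pipeline implemented here:

1. screen candidate probe sets for a survival-associated expression
   cutpoint (maxstat) in two independent cohorts, BH-adjusting within each
   cohort, and keep genes significant in BOTH (``select_prognostic_genes``);
2. freeze, from the training cohort, each kept gene's cutpoint and the Cox
   log hazard ratio (beta) of its dichotomized indicator;
3. per DNA-repair pathway, score each patient as the signed sum of betas,
   the sign set by whether the patient's expression is above (+1) or at or
   below (-1) the gene's cutpoint (``compute_pathway_score``);
4. dichotomize each continuous pathway score at its own maxstat cutpoint
   (``fit_pathway_cutpoints``) and keep the pathways that stay significant
   in a multivariate Cox model of the high/low flags (``retain_pathways``);
5. stratify patients into global risk groups I (no retained pathway high),
   III (all high) and II (otherwise) (``assign_global_group``);
6. apply the frozen model, with no re-estimation, to external cohorts
   (``apply_frozen_model``).

Expression is handled as a patients x probe-sets DataFrame of normalized
log-scale intensities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import maxstat as _maxstat
from .maxstat import NoValidCutpointError
from .survival import CoxFit, SurvivalData, as_survival, bh_adjust, cox_fit

__all__ = [
    "GenePanel",
    "PathwayScoreModel",
    "RiskModel",
    "StratificationResult",
    "RetentionResult",
    "DegenerateModelError",
    "select_prognostic_genes",
    "compute_pathway_score",
    "compute_pathway_scores",
    "fit_pathway_cutpoints",
    "retain_pathways",
    "assign_global_group",
    "apply_frozen_model",
    "load_reference_panel",
]

GLOBAL_GROUPS = ("I", "II", "III")


class DegenerateModelError(RuntimeError):
    """Raised when a fitted model is statistically empty (e.g. no genes kept)."""


@dataclass(frozen=True)
class GenePanel:
    """Frozen per-gene core of the signature.

    ``table`` has one row per (probe set, pathway) membership — a probe set
    annotated to two pathways contributes fully to both — with columns:
    probe_set, pathway, gene_symbol, cutpoint, beta, hazard_ratio,
    adjusted_p_train, adjusted_p_confirm, prognosis ("Bad" for hazard
    ratio > 1, "Good" otherwise).
    """

    table: pd.DataFrame

    COLUMNS = (
        "probe_set",
        "pathway",
        "gene_symbol",
        "cutpoint",
        "beta",
        "hazard_ratio",
        "adjusted_p_train",
        "adjusted_p_confirm",
        "prognosis",
    )

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"panel table lacks columns: {sorted(missing)}")
        bad = self.table[
            (self.table["beta"] > 0) != (self.table["prognosis"] == "Bad")
        ]
        if len(bad) and not bad["beta"].isna().all():
            raise ValueError(
                "prognosis direction inconsistent with beta sign for "
                f"{sorted(bad['probe_set'].unique())}"
            )

    @property
    def probe_sets(self) -> list[str]:
        return sorted(self.table["probe_set"].unique())

    @property
    def pathways(self) -> list[str]:
        return sorted(self.table["pathway"].unique())

    def members(self, pathway: str) -> pd.DataFrame:
        sub = self.table[self.table["pathway"] == pathway]
        if sub.empty:
            raise KeyError(f"no probe sets annotated to pathway {pathway!r}")
        return sub

    def __len__(self) -> int:
        return self.table["probe_set"].nunique()


@dataclass(frozen=True)
class PathwayScoreModel:
    """A pathway's frozen score threshold: high risk means score > cutpoint."""

    pathway: str
    members: tuple[str, ...]
    score_cutpoint: float

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("pathway score model needs at least one member gene")
        if not np.isfinite(self.score_cutpoint):
            raise ValueError("pathway score cutpoint must be finite")


@dataclass
class RetentionResult:
    """Outcome of the multivariate pathway-retention step."""

    retained: list[str]
    multivariate: CoxFit | None
    univariate: pd.DataFrame
    excluded_constant: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class RiskModel:
    """The complete frozen model, serializable to JSON without loss."""

    panel: GenePanel
    pathway_models: Mapping[str, PathwayScoreModel]
    retained_pathways: tuple[str, ...]
    merge_map: Mapping[int, str] | None = None
    alpha: float = 0.05
    endpoint: str = "os"

    def __post_init__(self) -> None:
        unknown = set(self.retained_pathways) - set(self.pathway_models)
        if unknown:
            raise ValueError(f"retained pathways not modelled: {sorted(unknown)}")

    def to_json(self, path=None) -> str:
        doc = {
            "format": "repairscore-risk-model",
            "version": 1,
            "alpha": self.alpha,
            "endpoint": self.endpoint,
            "panel": self.panel.table.to_dict(orient="records"),
            "pathway_models": {
                name: {"members": list(m.members), "score_cutpoint": m.score_cutpoint}
                for name, m in self.pathway_models.items()
            },
            "retained_pathways": list(self.retained_pathways),
            "merge_map": (
                None
                if self.merge_map is None
                else {str(k): v for k, v in self.merge_map.items()}
            ),
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RiskModel":
        if hasattr(source, "read"):
            doc = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        if doc.get("format") != "repairscore-risk-model":
            raise ValueError("not a repairscore risk-model document")
        panel = GenePanel(pd.DataFrame(doc["panel"], columns=list(GenePanel.COLUMNS)))
        models = {
            name: PathwayScoreModel(name, tuple(spec["members"]), spec["score_cutpoint"])
            for name, spec in doc["pathway_models"].items()
        }
        merge = doc.get("merge_map")
        return cls(
            panel=panel,
            pathway_models=models,
            retained_pathways=tuple(doc["retained_pathways"]),
            merge_map=None if merge is None else {int(k): v for k, v in merge.items()},
            alpha=doc.get("alpha", 0.05),
            endpoint=doc.get("endpoint", "os"),
        )


@dataclass(frozen=True)
class StratificationResult:
    """Per-patient output of applying a risk model to a cohort."""

    scores: pd.DataFrame  # patients x pathways, continuous
    flags: pd.DataFrame  # patients x pathways, bool (True = high risk)
    global_group: pd.Series  # "I" / "II" / "III"

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.add_suffix("_score").join(
            self.flags.add_suffix("_high").astype(int)
        )
        out["global_group"] = self.global_group
        return out


def _normalize_candidates(candidates) -> pd.DataFrame:
    """Candidate probe->pathway map as a (probe_set, pathway) frame."""
    rows: list[tuple[str, str]] = []
    if isinstance(candidates, Mapping):
        for probe, pw in candidates.items():
            for p in ([pw] if isinstance(pw, str) else list(pw)):
                rows.append((str(probe), str(p)))
    else:
        for probe, pw in candidates:
            rows.append((str(probe), str(pw)))
    if not rows:
        raise ValueError("candidate probe-set list is empty")
    frame = pd.DataFrame(rows, columns=["probe_set", "pathway"]).drop_duplicates()
    return frame


def select_prognostic_genes(
    expr_train: pd.DataFrame,
    surv_train: SurvivalData,
    expr_confirm: pd.DataFrame,
    surv_confirm: SurvivalData,
    candidates,
    alpha: float = 0.05,
    *,
    minprop: float = 0.10,
    maxprop: float = 0.90,
    pmethod: str = "approx",
    gene_symbols: Mapping[str, str] | None = None,
) -> GenePanel:
    """Two-cohort prognostic gene selection.

    Per cohort, every candidate probe set gets a maxstat selection-adjusted
    p-value which is BH-adjusted across all candidates within that cohort;
    a probe set enters the panel iff its adjusted p-value is below ``alpha``
    in BOTH cohorts.  Cutpoint and beta (Cox log-HR of the indicator
    [expression > cutpoint]) are frozen from the training cohort.

    Candidates missing from one expression matrix are skipped with a
    warning; a candidate absent from both matrices raises.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    cand = _normalize_candidates(candidates)
    surv_train = as_survival(surv_train)
    surv_confirm = as_survival(surv_confirm)
    probes = cand["probe_set"].unique()
    absent_both = [
        p for p in probes if p not in expr_train.columns and p not in expr_confirm.columns
    ]
    if absent_both:
        raise ValueError(
            f"candidates absent from both cohorts: {sorted(absent_both)[:10]}"
        )
    usable, skipped = [], []
    for p in probes:
        if p in expr_train.columns and p in expr_confirm.columns:
            usable.append(p)
        else:
            skipped.append(p)
    if skipped:
        warnings.warn(
            f"skipping {len(skipped)} candidate probe set(s) missing from one "
            f"cohort: {sorted(skipped)[:10]}",
            stacklevel=2,
        )

    def cohort_pvalues(expr: pd.DataFrame, surv: SurvivalData) -> pd.Series:
        scores = _maxstat.logrank_scores(surv)
        pvals = {}
        for probe in usable:
            x = expr[probe].to_numpy(float)
            try:
                res = _maxstat.maxstat_cutpoint(
                    x, surv, minprop=minprop, maxprop=maxprop,
                    pmethod=pmethod, scores=scores,
                )
                pvals[probe] = res.p_value
            except NoValidCutpointError:
                pvals[probe] = 1.0
        raw = pd.Series(pvals)
        return pd.Series(bh_adjust(raw.to_numpy()), index=raw.index)

    adj_train = cohort_pvalues(expr_train, surv_train)
    adj_confirm = cohort_pvalues(expr_confirm, surv_confirm)
    selected = [
        p for p in usable if adj_train[p] < alpha and adj_confirm[p] < alpha
    ]

    rows = []
    for probe in selected:
        x = expr_train[probe].to_numpy(float)
        res = _maxstat.maxstat_cutpoint(
            x, surv_train, minprop=minprop, maxprop=maxprop, pmethod="none"
        )
        indicator = (x > res.cutpoint).astype(float)
        fit = cox_fit(pd.DataFrame({probe: indicator}), surv_train)
        beta = float(fit.beta.iloc[0])
        hr = float(np.exp(beta))
        for pw in cand.loc[cand["probe_set"] == probe, "pathway"]:
            rows.append(
                {
                    "probe_set": probe,
                    "pathway": pw,
                    "gene_symbol": (gene_symbols or {}).get(probe, ""),
                    "cutpoint": res.cutpoint,
                    "beta": beta,
                    "hazard_ratio": hr,
                    "adjusted_p_train": float(adj_train[probe]),
                    "adjusted_p_confirm": float(adj_confirm[probe]),
                    "prognosis": "Bad" if hr > 1 else "Good",
                }
            )
    table = pd.DataFrame(rows, columns=list(GenePanel.COLUMNS))
    return GenePanel(table)


def _member_frame(panel: GenePanel, pathway: str) -> pd.DataFrame:
    return panel.members(pathway)[["probe_set", "cutpoint", "beta"]]


def compute_pathway_score(profile, panel: GenePanel, pathway: str):
    """Signed-beta risk score for one pathway.

    ``score = sum_i beta_i * s_i`` with ``s_i = +1`` when the patient's
    expression of member gene i is strictly above its cutpoint and
    ``s_i = -1`` when it is at or below the cutpoint.  ``profile`` may be a
    Series (one patient -> float) or a patients x probes DataFrame
    (-> Series per patient).
    """
    members = _member_frame(panel, pathway)
    if isinstance(profile, pd.Series):
        frame = profile.to_frame().T
        squeeze = True
    else:
        frame = profile
        squeeze = False
    missing = [p for p in members["probe_set"] if p not in frame.columns]
    if missing:
        raise KeyError(
            f"profile lacks probe set(s) required by pathway {pathway}: {missing}"
        )
    values = frame[members["probe_set"].tolist()].to_numpy(float)
    signs = np.where(values > members["cutpoint"].to_numpy(float), 1.0, -1.0)
    scores = signs @ members["beta"].to_numpy(float)
    if squeeze:
        return float(scores[0])
    return pd.Series(scores, index=frame.index, name=pathway)


def compute_pathway_scores(expr: pd.DataFrame, panel: GenePanel) -> pd.DataFrame:
    """All pathway scores for a cohort: patients x pathways DataFrame."""
    return pd.DataFrame(
        {pw: compute_pathway_score(expr, panel, pw) for pw in panel.pathways}
    )


def fit_pathway_cutpoints(
    scores: pd.DataFrame,
    data: SurvivalData,
    panel: GenePanel,
    *,
    minprop: float = 0.10,
    maxprop: float = 0.90,
) -> dict[str, PathwayScoreModel]:
    """Maxstat threshold on each continuous pathway score (training cohort).

    A pathway whose score is constant (or has no admissible split) is
    dropped with a warning rather than raising.
    """
    data = as_survival(data)
    models: dict[str, PathwayScoreModel] = {}
    for pw in scores.columns:
        try:
            res = _maxstat.maxstat_cutpoint(
                scores[pw].to_numpy(float), data,
                minprop=minprop, maxprop=maxprop, pmethod="none",
            )
        except NoValidCutpointError:
            warnings.warn(
                f"pathway {pw}: score admits no cutpoint (constant?); dropped",
                stacklevel=2,
            )
            continue
        members = tuple(panel.members(pw)["probe_set"]) if pw in panel.pathways else ()
        models[pw] = PathwayScoreModel(pw, members or (pw,), res.cutpoint)
    return models


def retain_pathways(
    flags: pd.DataFrame, data: SurvivalData, alpha: float = 0.05
) -> RetentionResult:
    """Multivariate Cox on the pathway high/low flags; keep Wald p < alpha.

    Pathways whose flag is constant are excluded before fitting and
    reported in the result.  Univariate hazard ratios are reported for all
    testable pathways.
    """
    data = as_survival(data)
    flags = flags.astype(bool)
    constant = [c for c in flags.columns if flags[c].nunique() <= 1]
    testable = [c for c in flags.columns if c not in constant]
    if not testable:
        return RetentionResult([], None, pd.DataFrame(), constant)
    uni_rows = []
    for pw in testable:
        fit = cox_fit(flags[[pw]].astype(float), data)
        uni_rows.append(
            {
                "pathway": pw,
                "univariate_hr": float(fit.hazard_ratio.iloc[0]),
                "univariate_p": float(fit.wald_p.iloc[0]),
            }
        )
    uni = pd.DataFrame(uni_rows).set_index("pathway")
    multi = cox_fit(flags[testable].astype(float), data)
    uni["multivariate_hr"] = multi.hazard_ratio
    uni["multivariate_p"] = multi.wald_p
    retained = [pw for pw in testable if multi.wald_p[pw] < alpha]
    return RetentionResult(retained, multi, uni.reset_index(), constant)


def assign_global_group(flags: pd.DataFrame) -> pd.Series:
    """Global risk group from the retained-pathway flags.

    Group I: no pathway high; group III: all pathways high; group II:
    anything in between.  With the two retained pathways of the reference
    model this is exactly the low/low, high/high, mixed partition.
    """
    if flags.shape[1] == 0:
        raise ValueError("no retained pathways: cannot assign global groups")
    n_high = flags.astype(bool).sum(axis=1)
    k = flags.shape[1]
    group = np.where(n_high == 0, "I", np.where(n_high == k, "III", "II"))
    return pd.Series(group, index=flags.index, name="global_group")


def apply_frozen_model(expr: pd.DataFrame, model: RiskModel) -> StratificationResult:
    """Score an expression cohort with a frozen model (no re-estimation)."""
    missing = [p for p in model.panel.probe_sets if p not in expr.columns]
    if missing:
        raise KeyError(f"cohort lacks panel probe set(s): {missing}")
    scores = compute_pathway_scores(expr, model.panel)
    scored = [pw for pw in scores.columns if pw in model.pathway_models]
    flags = pd.DataFrame(
        {
            pw: scores[pw] > model.pathway_models[pw].score_cutpoint
            for pw in scored
        }
    )
    retained_flags = flags[list(model.retained_pathways)]
    return StratificationResult(
        scores=scores,
        flags=flags,
        global_group=assign_global_group(retained_flags),
    )


def load_reference_panel() -> GenePanel:
    """The published 23-probe-set DNA-repair panel (annotation only).

    Betas are derived as log(hazard ratio); per-gene expression cutpoints
    were not published, so the reference panel cannot score patients — it
    documents pathway membership, effect direction and adjusted p-values.
    """
    from importlib.resources import files

    path = files("repairscore.data").joinpath("dna_repair_panel_23.tsv")
    raw = pd.read_csv(str(path), sep="\t")
    table = pd.DataFrame(
        {
            "probe_set": raw["probe_set"],
            "pathway": raw["pathway"],
            "gene_symbol": raw["gene_symbol"],
            "cutpoint": np.nan,
            "beta": np.log(raw["hazard_ratio"].astype(float)),
            "hazard_ratio": raw["hazard_ratio"].astype(float),
            "adjusted_p_train": raw["adjusted_p"].astype(float),
            "adjusted_p_confirm": np.nan,
            "prognosis": raw["prognosis"],
        }
    )
    return GenePanel(table)
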