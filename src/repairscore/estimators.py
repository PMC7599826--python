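"""scikit-learn-style estimators wrapping the signature pipeline.

All estimators follow the sklearn contract: hyperparameters in
``__init__``, data only in ``fit``, fitted attributes with a trailing
underscore, ``get_params``/``set_params`` inherited from ``BaseEstimator``.
Survival targets ``y`` may be a :class:`~repairscore.survival.SurvivalData`,
a ``(time, event)`` tuple, an (n, 2) array, or a scikit-survival structured
array.  Expression ``X`` is patients x probe sets (samples x features).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import combined as _combined
from . import maxstat as _maxstat
from . import signature as _signature
from .survival import as_survival

__all__ = ["MaxStatCutpoint", "DNARepairRiskModel", "CombinedRiskModel"]


class MaxStatCutpoint(TransformerMixin, BaseEstimator):
    """Dichotomize one continuous marker at its optimal survival cutpoint.

    ``fit(X, y)`` expects a single-column ``X`` (or 1-d array) and a
    survival target; ``transform`` returns the boolean high/low indicator
    at the fitted cutpoint.

    Attributes
    ----------
    cutpoint_ : float
        Threshold maximizing the standardized log-rank statistic.
    statistic_ : float
        The maximally selected standardized statistic.
    p_value_ : float
        Selection-adjusted p-value (per ``pmethod``).
    """

    def __init__(
        self,
        minprop: float = 0.10,
        maxprop: float = 0.90,
        pmethod: str = "approx",
        n_permutations: int = 1000,
        random_state=None,
    ):
        self.minprop = minprop
        self.maxprop = maxprop
        self.pmethod = pmethod
        self.n_permutations = n_permutations
        self.random_state = random_state

    @staticmethod
    def _column(X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2:
            if arr.shape[1] != 1:
                raise ValueError("MaxStatCutpoint handles a single marker column")
            arr = arr[:, 0]
        return arr

    def fit(self, X, y):
        res = _maxstat.maxstat_cutpoint(
            self._column(X),
            as_survival(y),
            minprop=self.minprop,
            maxprop=self.maxprop,
            pmethod=self.pmethod,
            n_permutations=self.n_permutations,
            random_state=self.random_state,
        )
        self.cutpoint_ = res.cutpoint
        self.statistic_ = res.max_statistic
        self.p_value_ = res.p_value
        self.n_low_ = res.n_low
        self.n_high_ = res.n_high
        self.candidate_grid_ = res.candidate_grid
        self.result_ = res
        return self

    def transform(self, X):
        check_is_fitted(self, "cutpoint_")
        return (self._column(X) > self.cutpoint_).reshape(-1, 1)


class DNARepairRiskModel(BaseEstimator):
    """The full gene-expression DNA-repair risk model as an estimator.

    ``fit(X, y, X_confirm=, y_confirm=)`` runs the training pipeline:
    two-cohort gene selection (the confirmation cohort is required for the
    dual-cohort screen), per-gene cutpoints and betas frozen from the
    training cohort, pathway scores, pathway-score cutpoints, and
    multivariate pathway retention.  ``transform(X)`` returns continuous
    pathway scores; ``predict(X)`` returns global risk groups I/II/III.

    Parameters
    ----------
    gene_sets : mapping or sequence
        Candidate probe set -> pathway(s) map (a probe set may belong to
        several pathways and then contributes to each pathway's score).
    alpha : float
        Significance threshold for both the BH-adjusted gene screen and
        the multivariate pathway retention.
    """

    def __init__(
        self,
        gene_sets=None,
        alpha: float = 0.05,
        minprop: float = 0.10,
        maxprop: float = 0.90,
        pmethod: str = "approx",
    ):
        self.gene_sets = gene_sets
        self.alpha = alpha
        self.minprop = minprop
        self.maxprop = maxprop
        self.pmethod = pmethod

    def fit(self, X, y, X_confirm=None, y_confirm=None):
        if self.gene_sets is None:
            raise ValueError("gene_sets (candidate probe->pathway map) is required")
        if X_confirm is None or y_confirm is None:
            raise ValueError(
                "the dual-cohort screen needs a confirmation cohort: "
                "pass X_confirm and y_confirm"
            )
        X = pd.DataFrame(X)
        X_confirm = pd.DataFrame(X_confirm)
        surv = as_survival(y)
        surv_confirm = as_survival(y_confirm)
        panel = _signature.select_prognostic_genes(
            X,
            surv,
            X_confirm,
            surv_confirm,
            self.gene_sets,
            alpha=self.alpha,
            minprop=self.minprop,
            maxprop=self.maxprop,
            pmethod=self.pmethod,
        )
        if len(panel) == 0:
            raise _signature.DegenerateModelError(
                "no probe set passed the dual-cohort screen at "
                f"alpha={self.alpha}"
            )
        scores = _signature.compute_pathway_scores(X, panel)
        pathway_models = _signature.fit_pathway_cutpoints(
            scores, surv, panel, minprop=self.minprop, maxprop=self.maxprop
        )
        flags = pd.DataFrame(
            {pw: scores[pw] > m.score_cutpoint for pw, m in pathway_models.items()}
        )
        retention = _signature.retain_pathways(flags, surv, alpha=self.alpha)
        retained = retention.retained
        if not retained:
            raise _signature.DegenerateModelError(
                "no pathway score retained in multivariate analysis"
            )
        self.panel_ = panel
        self.pathway_models_ = pathway_models
        self.retention_ = retention
        self.retained_pathways_ = tuple(retained)
        self.model_ = _signature.RiskModel(
            panel=panel,
            pathway_models=pathway_models,
            retained_pathways=tuple(retained),
            alpha=self.alpha,
        )
        self.training_result_ = _signature.apply_frozen_model(X, self.model_)
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "model_")
        return _signature.compute_pathway_scores(pd.DataFrame(X), self.panel_)

    def predict(self, X) -> pd.Series:
        check_is_fitted(self, "model_")
        return self.stratify(X).global_group

    def stratify(self, X) -> _signature.StratificationResult:
        """Frozen-model application: scores, flags and global groups."""
        check_is_fitted(self, "model_")
        return _signature.apply_frozen_model(pd.DataFrame(X), self.model_)


class CombinedRiskModel(BaseEstimator):
    """Combined DNA-repair + NPM1/FLT3-ITD point score with group merging.

    ``fit(X, y)`` expects ``X`` with columns ``global_group``,
    ``npm1_mutated`` and ``flt3_itd``; it computes total points (0-4) and
    learns the merge map by consecutive log-rank tests on ``y``.
    ``predict(X)`` applies the frozen map to new cohorts.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    @staticmethod
    def _totals(X: pd.DataFrame) -> pd.Series:
        needed = {"global_group", "npm1_mutated", "flt3_itd"}
        missing = needed - set(X.columns)
        if missing:
            raise ValueError(f"X lacks column(s): {sorted(missing)}")
        mut = _combined.mutation_points(X["npm1_mutated"], X["flt3_itd"])
        return _combined.combined_points(X["global_group"], mut)

    def fit(self, X, y):
        X = pd.DataFrame(X)
        totals = self._totals(X)
        result = _combined.merge_point_groups(totals, as_survival(y), alpha=self.alpha)
        self.merge_map_ = result.merge_map
        self.tests_ = result.tests
        self.labels_ = pd.Series(
            np.asarray(result.labels), index=X.index, name="final_group"
        )
        return self

    def predict(self, X) -> pd.Series:
        check_is_fitted(self, "merge_map_")
        X = pd.DataFrame(X)
        totals = self._totals(X)
        return _combined.apply_merge_map(totals, self.merge_map_)
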