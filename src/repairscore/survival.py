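"""Right-censored survival statistics shared by the whole package.

Thin, validated wrappers around lifelines/statsmodels: Kaplan-Meier
estimation with a log-log (complementary log) confidence band, the
Mantel-Cox log-rank test, Cox proportional-hazards fits (Efron tie
correction by default, Breslow available), and Benjamini-Hochberg
adjustment.  Durations are in days throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SurvivalData",
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "bh_adjust",
    "median_followup",
    "as_survival",
]


@dataclass(frozen=True)
class SurvivalData:
    """Per-patient right-censored endpoint: duration in days and event flag.

    ``event == 1`` means the event (death for OS; progression, relapse or
    death for EFS) was observed; ``event == 0`` means censored.
    """

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        object.__setattr__(self, "time", time)
        if time.ndim != 1 or event.ndim != 1 or len(time) != len(event):
            raise ValueError("time and event must be 1-d arrays of equal length")
        if not np.all(np.isfinite(time)):
            raise ValueError("survival times must be finite")
        if np.any(time < 0):
            raise ValueError("survival times must be non-negative")
        if not np.isin(event, [0, 1]).all():
            raise ValueError("event indicators must be 0 (censored) or 1 (event)")
        object.__setattr__(self, "event", event.astype(int))

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, mask) -> "SurvivalData":
        mask = np.asarray(mask)
        return SurvivalData(self.time[mask], self.event[mask])

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, time_col: str = "os_days", event_col: str = "os_event"
    ) -> "SurvivalData":
        return cls(frame[time_col].to_numpy(float), frame[event_col].to_numpy())


def as_survival(y) -> SurvivalData:
    """Coerce common survival containers to :class:`SurvivalData`.

    Accepts a SurvivalData, a ``(time, event)`` pair of arrays, an (n, 2)
    array with columns time/event, or a structured array with ``time`` and
    ``event`` fields (scikit-survival convention, field order agnostic).
    """
    if isinstance(y, SurvivalData):
        return y
    if isinstance(y, tuple) and len(y) == 2:
        return SurvivalData(np.asarray(y[0], float), np.asarray(y[1]))
    arr = np.asarray(y)
    if arr.dtype.names:
        names = arr.dtype.names
        tname = next(n for n in names if "time" in n.lower() or n.lower() in ("t", "days"))
        ename = next(n for n in names if n != tname)
        return SurvivalData(arr[tname].astype(float), arr[ename].astype(int))
    if arr.ndim == 2 and arr.shape[1] == 2:
        return SurvivalData(arr[:, 0], arr[:, 1])
    raise ValueError("cannot interpret input as survival data")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve with a pointwise confidence band.

    ``median`` is the smallest event time at which S(t) drops to 0.5 or
    below, or ``None`` when the curve never reaches 0.5 ("not reached").
    """

    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    conf_level: float
    median: float | None
    median_ci: tuple[float | None, float | None]
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """Step-function lookup S(t); S = 1 before the first observed time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def ci_at(self, t: float) -> tuple[float, float]:
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return (1.0, 1.0)
        return float(self.ci_lower[idx]), float(self.ci_upper[idx])


def _none_if_unreached(value: float) -> float | None:
    return None if not np.isfinite(value) else float(value)


def km_estimate(data: SurvivalData, conf_level: float = 0.95) -> KMCurve:
    """Kaplan-Meier estimate with Greenwood variance and log-log band."""
    data = as_survival(data)
    if data.n == 0:
        raise ValueError("cannot estimate a survival curve from no patients")
    if not 0 < conf_level < 1:
        raise ValueError("conf_level must be in (0, 1)")
    kmf = KaplanMeierFitter(alpha=1 - conf_level)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(data.time, data.event)
        sf = kmf.survival_function_
        ci = kmf.confidence_interval_survival_function_
        med_ci = median_survival_times(kmf.confidence_interval_)
    times = sf.index.to_numpy(float)
    keep = times > 0 if times.size and times[0] == 0 else np.ones_like(times, bool)
    lo = med_ci.iloc[0, 0]
    hi = med_ci.iloc[0, 1]
    return KMCurve(
        times=times[keep],
        survival=sf.iloc[:, 0].to_numpy(float)[keep],
        ci_lower=ci.iloc[:, 0].to_numpy(float)[keep],
        ci_upper=ci.iloc[:, 1].to_numpy(float)[keep],
        conf_level=conf_level,
        median=_none_if_unreached(kmf.median_survival_time_),
        median_ci=(_none_if_unreached(lo), _none_if_unreached(hi)),
        n=data.n,
        n_events=data.n_events,
    )


def median_followup(data: SurvivalData) -> float | None:
    """Median follow-up by reverse Kaplan-Meier (censoring-distribution median)."""
    data = as_survival(data)
    flipped = SurvivalData(data.time, 1 - data.event)
    return km_estimate(flipped).median


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float
    df: int
    observed: "pd.Series[float]"
    expected: "pd.Series[float]"


def _observed_expected(data: SurvivalData, labels: pd.Series) -> tuple[pd.Series, pd.Series]:
    levels = labels.cat.categories if hasattr(labels, "cat") else pd.unique(labels)
    observed = pd.Series(0.0, index=pd.Index(levels, name="group"))
    expected = observed.copy()
    for t in np.unique(data.time[data.event == 1]):
        at_risk = data.time >= t
        n_t = at_risk.sum()
        d_t = int(((data.time == t) & (data.event == 1)).sum())
        for g in levels:
            in_g = np.asarray(labels == g)
            observed[g] += int(((data.time == t) & (data.event == 1) & in_g).sum())
            expected[g] += d_t * (at_risk & in_g).sum() / n_t
    return observed, expected


def logrank_test(data: SurvivalData, group: Sequence) -> LogRankResult:
    """Mantel-Cox log-rank test between two or more patient groups."""
    data = as_survival(data)
    labels = pd.Series(group).reset_index(drop=True)
    if len(labels) != data.n:
        raise ValueError("group labels must align with the survival records")
    counts = labels.value_counts()
    levels = labels.cat.categories if hasattr(labels, "cat") else counts.index
    if len(levels) < 2:
        raise ValueError("log-rank test needs at least two groups")
    if any(counts.get(g, 0) == 0 for g in levels):
        empty = [g for g in levels if counts.get(g, 0) == 0]
        raise ValueError(f"log-rank test received empty group(s): {empty}")
    if data.n_events == 0:
        raise ValueError("log-rank test needs at least one observed event")
    res = multivariate_logrank_test(data.time, labels, data.event)
    observed, expected = _observed_expected(data, labels)
    chi2 = max(float(res.test_statistic), 0.0)
    return LogRankResult(
        chi_square=chi2,
        p_value=float(min(max(res.p_value, np.finfo(float).tiny), 1.0)),
        df=len(levels) - 1,
        observed=observed,
        expected=expected,
    )


@dataclass(frozen=True)
class CoxFit:
    """Cox proportional-hazards fit: beta is the log hazard ratio."""

    beta: "pd.Series[float]"
    se: "pd.Series[float]"
    hazard_ratio: "pd.Series[float]"
    wald_p: "pd.Series[float]"
    converged: bool
    ties: str
    n: int
    n_events: int
    log_likelihood: float = field(default=np.nan)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "hazard_ratio": self.hazard_ratio,
                "wald_p": self.wald_p,
            }
        )


def _as_design(covariates) -> pd.DataFrame:
    if isinstance(covariates, pd.DataFrame):
        return covariates.reset_index(drop=True).astype(float)
    if isinstance(covariates, pd.Series):
        return covariates.rename(covariates.name or "x").to_frame().reset_index(drop=True).astype(float)
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return pd.DataFrame(arr, columns=[f"x{i + 1}" for i in range(arr.shape[1])])


def cox_fit(covariates, data: SurvivalData, ties: str = "efron") -> CoxFit:
    """Fit a Cox proportional-hazards model by partial likelihood.

    ``ties`` selects the tie correction: "efron" (default, via lifelines)
    or "breslow" (via statsmodels PHReg).  Complete separation / monotone
    likelihood is reported through ``converged=False`` rather than raising.
    """
    data = as_survival(data)
    X = _as_design(covariates)
    if len(X) != data.n:
        raise ValueError("covariate rows must align with the survival records")
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise ValueError(f"covariate '{col}' is constant across patients")
    if X.shape[1] > 1:
        centered = X - X.mean()
        if np.linalg.matrix_rank(centered.to_numpy()) < X.shape[1]:
            raise ValueError("covariate matrix is rank deficient (collinear columns)")
    if data.n_events < X.shape[1]:
        raise ValueError(
            f"{data.n_events} events cannot support {X.shape[1]} covariates"
        )
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")

    if ties == "breslow":
        model = PHReg(data.time, X.to_numpy(), status=data.event, ties="breslow")
        res = model.fit()
        beta = pd.Series(res.params, index=X.columns)
        se = pd.Series(res.bse, index=X.columns)
        pvals = pd.Series(res.pvalues, index=X.columns)
        converged = bool(np.all(np.isfinite(res.params)))
        llf = float(model.loglike(res.params))
        return CoxFit(beta, se, np.exp(beta), pvals, converged, ties, data.n, data.n_events, llf)

    frame = X.copy()
    frame["__time"] = data.time
    frame["__event"] = data.event
    converged = True
    cph = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(frame, duration_col="__time", event_col="__event")
        except ConvergenceError:
            # monotone likelihood / separation: refit with a light ridge so the
            # caller still gets finite (flagged) coefficients
            converged = False
            cph = CoxPHFitter(penalizer=0.1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(frame, duration_col="__time", event_col="__event")
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        converged = False
    return CoxFit(
        beta=cph.params_.rename(None),
        se=cph.standard_errors_.rename(None),
        hazard_ratio=np.exp(cph.params_).rename(None),
        wald_p=cph.summary["p"].rename(None),
        converged=converged,
        ties=ties,
        n=data.n,
        n_events=data.n_events,
        log_likelihood=float(cph.log_likelihood_),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
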