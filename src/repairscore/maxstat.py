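"""Maximally selected rank statistics for right-censored survival endpoints.

For a continuous marker x (a probe-set expression value or a pathway risk
score) the optimal cutpoint is the threshold c maximizing the standardized
two-sample log-rank statistic between the groups x > c and x <= c, searched
over candidate thresholds inside a quantile window.  Because the statistic
is maximized over many correlated candidate splits, its p-value must be
adjusted for that selection; this module offers an analytic normal
approximation (an improved-Bonferroni bound in the Lausen-Schumacher /
Miller-Siegmund family) and a Monte-Carlo permutation alternative.

The per-split statistic is the linear log-rank score statistic: with
log-rank scores ``a_i = event_i - NelsonAalen(t_i)``, the split statistic
for the high group H = {i : x_i > c} is ``S = sum_{i in H} a_i``
standardized by its permutation mean and variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .survival import SurvivalData, as_survival

__all__ = [
    "NoValidCutpointError",
    "CutpointResult",
    "logrank_scores",
    "maxstat_cutpoint",
    "maxstat_pvalue",
]

PMETHODS = ("approx", "bonferroni", "permutation", "none")


class NoValidCutpointError(ValueError):
    """Raised when no candidate split exists inside the quantile window."""


@dataclass(frozen=True)
class CutpointResult:
    """Outcome of a maximally selected log-rank cutpoint search."""

    cutpoint: float
    max_statistic: float
    p_value: float
    n_low: int
    n_high: int
    candidate_grid: np.ndarray
    candidate_statistics: np.ndarray
    pmethod: str

    @property
    def n(self) -> int:
        return self.n_low + self.n_high


def logrank_scores(data: SurvivalData) -> np.ndarray:
    """Per-patient log-rank (Savage) scores ``a_i = d_i - NelsonAalen(t_i)``.

    The Nelson-Aalen cumulative hazard is evaluated at each patient's own
    time; the scores sum to zero exactly (up to float round-off).
    """
    data = as_survival(data)
    n = data.n
    order = np.argsort(data.time, kind="stable")
    t_sorted = data.time[order]
    e_sorted = data.event[order]
    # distinct times, events and risk-set sizes
    uniq, first_idx = np.unique(t_sorted, return_index=True)
    d = np.add.reduceat(e_sorted, first_idx)  # events at each distinct time
    n_at_risk = n - first_idx  # all with time >= t (sorted ascending)
    na_increments = d / n_at_risk
    cumhaz = np.cumsum(na_increments)
    # map each patient to the cumulative hazard at its own time
    pos = np.searchsorted(uniq, data.time)
    return data.event - cumhaz[pos]


def _candidate_splits(
    x_sorted: np.ndarray, n: int, minprop: float, maxprop: float
) -> np.ndarray:
    """Indices m such that the split (first m) vs (rest) is admissible.

    m counts patients with x <= candidate threshold; the threshold is the
    midpoint between x_sorted[m-1] and x_sorted[m].  Equal values can never
    be separated, and the low-group proportion must lie in [minprop, maxprop].
    """
    boundaries = np.nonzero(np.diff(x_sorted) > 0)[0] + 1  # admissible m values
    lo = max(1, int(np.ceil(minprop * n)))
    hi = min(n - 1, int(np.floor(maxprop * n)))
    return boundaries[(boundaries >= lo) & (boundaries <= hi)]


def _standardized_statistics(
    a_in_x_order: np.ndarray, splits: np.ndarray
) -> np.ndarray:
    """Standardized |S - E| / sqrt(V) for each split, vectorized.

    S is the score sum of the high group (x above the threshold); E and V
    are the mean and variance of S under the permutation null hypothesis.
    """
    n = len(a_in_x_order)
    total = a_in_x_order.sum()
    abar = total / n
    ssq = np.square(a_in_x_order - abar).sum()
    cum_low = np.cumsum(a_in_x_order)
    s_high = total - cum_low[splits - 1]
    m_high = n - splits
    e_high = m_high * abar
    var = splits * m_high / (n * (n - 1.0)) * ssq
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.abs(s_high - e_high) / np.sqrt(var)
    return np.where(var > 0, stat, 0.0)


def maxstat_cutpoint(
    x,
    data: SurvivalData,
    minprop: float = 0.10,
    maxprop: float = 0.90,
    pmethod: str = "approx",
    n_permutations: int = 1000,
    random_state=None,
    scores: np.ndarray | None = None,
) -> CutpointResult:
    """Optimal survival cutpoint for a continuous marker.

    Parameters
    ----------
    x : array-like
        One continuous value per patient (e.g. log-scale expression).
    data : SurvivalData
        Right-censored endpoint aligned with ``x``.
    minprop, maxprop : float
        Quantile window restricting candidate splits: the low group
        (x <= c) must contain between ``minprop*n`` and ``maxprop*n``
        patients.
    pmethod : str
        "approx" for the analytic improved-Bonferroni normal approximation,
        "permutation" for a Monte-Carlo p, "none" to skip the p-value.
    scores : ndarray, optional
        Precomputed log-rank scores (they depend only on the survival data,
        so multi-gene screens compute them once per cohort).
    """
    data = as_survival(data)
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) != data.n:
        raise ValueError("x must be one value per patient")
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    if data.n_events < 1:
        raise ValueError("cutpoint search needs at least one observed event")
    if not (0 < minprop < maxprop < 1):
        raise ValueError("need 0 < minprop < maxprop < 1")
    if pmethod not in PMETHODS:
        raise ValueError(f"unknown pmethod {pmethod!r}; supported: {PMETHODS}")

    n = data.n
    order = np.argsort(x, kind="stable")
    x_sorted = x[order]
    splits = _candidate_splits(x_sorted, n, minprop, maxprop)
    if splits.size == 0:
        raise NoValidCutpointError(
            "no admissible cutpoint: marker constant (or no two distinct "
            "values) inside the quantile window"
        )
    a = logrank_scores(data) if scores is None else np.asarray(scores, float)
    a_x = a[order]
    stat = _standardized_statistics(a_x, splits)
    best = int(np.argmax(stat))
    m = splits[best]
    cutpoint = 0.5 * (x_sorted[m - 1] + x_sorted[m])
    max_stat = float(stat[best])
    grid = 0.5 * (x_sorted[splits - 1] + x_sorted[splits])

    if pmethod == "none":
        p = float("nan")
    elif pmethod in ("approx", "bonferroni"):
        p = maxstat_pvalue(max_stat, splits / n, pmethod=pmethod)
    else:
        rng = np.random.default_rng(random_state)
        exceed = 0
        for _ in range(int(n_permutations)):
            perm = rng.permutation(a_x)
            if _standardized_statistics(perm, splits).max() >= max_stat:
                exceed += 1
        p = (1.0 + exceed) / (n_permutations + 1.0)

    return CutpointResult(
        cutpoint=float(cutpoint),
        max_statistic=max_stat,
        p_value=float(p),
        n_low=int(m),
        n_high=int(n - m),
        candidate_grid=grid,
        candidate_statistics=stat,
        pmethod=pmethod,
    )


def _split_correlation(props: np.ndarray) -> np.ndarray:
    """Asymptotic correlation matrix of the standardized split statistics.

    For two nested splits at low-group proportions p_i <= p_j the
    correlation is sqrt(p_i (1 - p_j) / (p_j (1 - p_i))).
    """
    pi, pj = props[:, None], props[None, :]
    lo, hi = np.minimum(pi, pj), np.maximum(pi, pj)
    return np.sqrt(lo * (1.0 - hi) / ((1.0 - lo) * hi))


# cache of simulated max-|T| distributions, keyed by the candidate grid
_GAUSS_MAX_CACHE: dict[tuple, np.ndarray] = {}
_GAUSS_DRAWS = 20_000
_GAUSS_SEED = 20201006  # fixed: the approximation is deterministic


def _gaussian_max_distribution(props: np.ndarray) -> np.ndarray:
    key = tuple(np.round(props, 12))
    cached = _GAUSS_MAX_CACHE.get(key)
    if cached is not None:
        return cached
    corr = _split_correlation(props)
    corr.flat[:: len(props) + 1] += 1e-10
    chol = np.linalg.cholesky(corr)
    rng = np.random.default_rng(_GAUSS_SEED)
    draws = rng.standard_normal((_GAUSS_DRAWS, len(props))) @ chol.T
    maxima = np.sort(np.abs(draws).max(axis=1))
    if len(_GAUSS_MAX_CACHE) > 128:
        _GAUSS_MAX_CACHE.clear()
    _GAUSS_MAX_CACHE[key] = maxima
    return maxima


def maxstat_pvalue(
    max_statistic: float,
    candidate_grid_proportions,
    pmethod: str = "approx",
) -> float:
    """Selection-adjusted p-value for a maximally selected log-rank statistic.

    ``candidate_grid_proportions`` are the low-group proportions m/n of the
    candidate splits actually examined.

    ``pmethod="approx"`` (default) uses the normal approximation: the split
    statistics converge jointly to a correlated Gaussian vector with a
    known correlation structure, and the distribution of its maximum
    absolute coordinate is evaluated by a fixed-seed (deterministic,
    cached) simulation of that limiting vector.  ``pmethod="bonferroni"``
    is the closed-form improved-Bonferroni upper bound computed from the
    bivariate margins of consecutive splits; it is conservative on dense
    grids.  Both are exactly 1 at statistic 0 and non-increasing.
    """
    if pmethod == "permutation":
        raise ValueError(
            "permutation p-values need the data; call maxstat_cutpoint with "
            "pmethod='permutation'"
        )
    if pmethod not in ("approx", "bonferroni"):
        raise ValueError(
            f"unknown pmethod {pmethod!r}; supported: ('approx', 'bonferroni', 'permutation')"
        )
    b = float(max_statistic)
    if b < 0:
        raise ValueError("max_statistic must be non-negative")
    props = np.unique(np.asarray(list(candidate_grid_proportions), dtype=float))
    if props.size == 0 or np.any(props <= 0) or np.any(props >= 1):
        raise ValueError("candidate proportions must lie strictly in (0, 1)")
    tail = 2.0 * stats.norm.sf(b)
    if props.size == 1:
        return float(min(1.0, tail))
    if pmethod == "bonferroni":
        if b == 0.0:
            return 1.0
        rho = _split_correlation(props).diagonal(1)

        def both_exceed(r: np.ndarray) -> np.ndarray:
            # P(X > b, Y > b) for standard bivariate normal, via Owen's T
            a = np.sqrt((1.0 - r) / (1.0 + r))
            return 1.0 - stats.norm.cdf(b) - 2.0 * special.owens_t(b, a)

        joint = 2.0 * (both_exceed(rho) + both_exceed(-rho))
        p = tail + float(np.sum(np.clip(tail - joint, 0.0, None)))
        return float(np.clip(p, tail, 1.0))
    maxima = _gaussian_max_distribution(props)
    n_ge = len(maxima) - np.searchsorted(maxima, b, side="left")
    return float((1.0 + n_ge) / (len(maxima) + 1.0))
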