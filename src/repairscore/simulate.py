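"""Synthetic CN-AML-like cohorts with planted cutpoint hazard effects.

The generator emulates the statistical structure the scoring pipeline
assumes: ~160-patient cohorts profiled for 175 candidate probe sets spread
over the six DNA-repair pathways, already-normalized Gaussian log-scale
expression, exponential survival in days whose hazard is multiplied by a
planted gene's hazard ratio whenever that gene's expression exceeds its
true cutpoint (a step effect, matching the dichotomizing method),
independent right censoring calibrated to a target censored fraction,
and binary NPM1 / FLT3-ITD status with configurable prevalences and
hazard effects.  Two-cohort studies share one gene universe and planted
truth but draw patients independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlantedGene",
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_two_cohort_study",
    "default_study_configs",
]

PATHWAYS = ("BER", "NER", "MMR", "HRR", "NHEJ", "FANC")

# default 175-gene universe across the six pathways
DEFAULT_PATHWAY_SIZES: Mapping[str, int] = {
    "BER": 30,
    "NER": 35,
    "MMR": 20,
    "HRR": 35,
    "NHEJ": 25,
    "FANC": 30,
}


@dataclass(frozen=True)
class PlantedGene:
    """A truly prognostic gene: hazard multiplied by ``hazard_ratio`` when
    expression exceeds the cutpoint planted at ``cutpoint_quantile`` of the
    gene's expression distribution."""

    probe: str
    pathway: str
    hazard_ratio: float
    cutpoint_quantile: float = 0.5

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratios must be positive")
        if not 0 < self.cutpoint_quantile < 1:
            raise ValueError("cutpoint quantile must be in (0, 1)")


def _default_planted() -> tuple[PlantedGene, ...]:
    """Ten prognostic genes in the two pathways the reference model retains,
    with hazard ratios in the range the published panel reports (0.5-2.5)."""
    hrr = [2.2, 2.0, 2.5, 1.8, 0.55]
    ner = [2.2, 1.9, 2.4, 1.7, 0.55]
    return tuple(
        [PlantedGene(f"HRR_{i + 1:03d}", "HRR", hr) for i, hr in enumerate(hrr)]
        + [PlantedGene(f"NER_{i + 1:03d}", "NER", hr) for i, hr in enumerate(ner)]
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated cohort.

    ``universe_seed`` fixes the gene universe (per-gene means, cutpoints)
    shared across the cohorts of a study; ``seed`` drives the
    patient-level draws.  ``censoring`` is the target censored fraction;
    the exponential censoring rate is solved from the realized hazards so
    the marginal censored fraction matches it.  Durations are in days.
    """

    n_patients: int = 162
    pathway_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PATHWAY_SIZES)
    )
    planted: Sequence[PlantedGene] = field(default_factory=_default_planted)
    baseline_rate: float = 1.7e-4  # per-day exponential hazard of a low-risk patient
    censoring: float = 0.25
    admin_horizon: float | None = 2500.0
    npm1_prevalence: float = 0.50
    flt3_prevalence: float = 0.48
    npm1_hr: float = 0.55
    flt3_hr: float = 2.0
    relapse_rate_scale: float = 1.6  # relapse hazard relative to death hazard (EFS)
    planted_coexpression: float = 0.5  # within-pathway co-expression of planted genes
    expression_mean_range: tuple[float, float] = (5.0, 11.0)
    expression_sd: float = 1.0
    cohort_label: str = "training"
    seed: int = 0
    universe_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least two patients")
        if not 0 <= self.censoring < 1:
            raise ValueError("target censored fraction must be in [0, 1)")
        for p in (self.npm1_prevalence, self.flt3_prevalence):
            if not 0 <= p <= 1:
                raise ValueError("mutation prevalences must be in [0, 1]")
        if self.baseline_rate <= 0 or self.npm1_hr <= 0 or self.flt3_hr <= 0:
            raise ValueError("rates and hazard ratios must be positive")
        if not 0 <= self.planted_coexpression < 1:
            raise ValueError("planted co-expression must be in [0, 1)")
        unknown = {g.pathway for g in self.planted} - set(self.pathway_sizes)
        if unknown:
            raise ValueError(f"planted genes reference unknown pathway(s): {sorted(unknown)}")

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    @property
    def effective_universe_seed(self) -> int:
        return self.seed if self.universe_seed is None else self.universe_seed


@dataclass(frozen=True)
class SimulatedCohort:
    """One simulated cohort plus the generative truth that produced it."""

    expression: pd.DataFrame  # patients x probe sets, log scale
    clinical: pd.DataFrame  # patient_id-indexed clinical table
    gene_sets: pd.DataFrame  # probe_set, pathway
    truth: dict
    config: SimulationConfig
    censoring_rate: float = 0.0  # solved exponential censoring rate (cohort-specific)

    @property
    def patient_ids(self) -> pd.Index:
        return self.expression.index


def _build_universe(config: SimulationConfig) -> pd.DataFrame:
    rng = np.random.default_rng(config.effective_universe_seed)
    rows = []
    for pw in PATHWAYS:
        size = config.pathway_sizes.get(pw, 0)
        for i in range(size):
            rows.append({"probe_set": f"{pw}_{i + 1:03d}", "pathway": pw})
    uni = pd.DataFrame(rows)
    lo, hi = config.expression_mean_range
    uni["mean"] = rng.uniform(lo, hi, len(uni))
    uni["sd"] = config.expression_sd
    planted = {g.probe: g for g in config.planted}
    missing = set(planted) - set(uni["probe_set"])
    if missing:
        raise ValueError(f"planted genes outside the gene universe: {sorted(missing)}")
    uni["hazard_ratio"] = [
        planted[p].hazard_ratio if p in planted else 1.0 for p in uni["probe_set"]
    ]
    from scipy.stats import norm

    uni["cutpoint"] = [
        mu + sd * norm.ppf(planted[probe].cutpoint_quantile)
        if probe in planted
        else np.nan
        for probe, mu, sd in zip(uni["probe_set"], uni["mean"], uni["sd"])
    ]
    return uni


def _censoring_rate(
    hazards: np.ndarray, target: float, horizon: float | None
) -> float:
    """Exponential censoring rate giving the target marginal censored fraction.

    With death hazard L, censor rate c and administrative horizon H the
    event probability is L/(L+c) * (1 - exp(-(L+c)H)); the rate is found by
    bisection on the mean over patients.  Returns 0 when even pure
    administrative censoring exceeds the target.
    """
    if target == 0 and horizon is None:
        return 0.0

    def censored_fraction(c: float) -> float:
        total = hazards + c
        if horizon is None:
            p_event = hazards / total
        else:
            p_event = hazards / total * (1.0 - np.exp(-total * horizon))
        return float(1.0 - p_event.mean())

    if censored_fraction(0.0) >= target:
        return 0.0
    lo, hi = 0.0, 1.0
    while censored_fraction(hi) < target:
        hi *= 2
        if hi > 1e6:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if censored_fraction(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw one cohort; identical config (incl. seed) gives identical output."""
    uni = _build_universe(config)
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    prefix = {"training": "TR", "validation": "VA"}.get(config.cohort_label, "PT")
    ids = pd.Index([f"{prefix}_{i + 1:04d}" for i in range(n)], name="patient_id")

    # planted genes of one pathway co-vary through a shared latent factor
    # (a deregulated-pathway "module"); risk genes load positively,
    # protective genes negatively.  Marginals stay N(mean, sd^2), so the
    # planted cutpoints remain marginal quantiles.
    z = rng.standard_normal((n, len(uni)))
    rho = config.planted_coexpression
    planted_mask = (uni["hazard_ratio"] != 1.0).to_numpy()
    if rho > 0 and planted_mask.any():
        for pw in uni.loc[planted_mask, "pathway"].unique():
            cols = (uni["pathway"] == pw).to_numpy() & planted_mask
            factor = rng.standard_normal(n)
            loading = np.sign(np.log(uni.loc[cols, "hazard_ratio"].to_numpy()))
            loading[loading == 0] = 1.0
            z[:, cols] = (
                np.sqrt(rho) * factor[:, None] * loading
                + np.sqrt(1.0 - rho) * z[:, cols]
            )
    expr = pd.DataFrame(
        uni["mean"].to_numpy() + uni["sd"].to_numpy() * z,
        index=ids,
        columns=uni["probe_set"],
    )
    npm1 = (rng.random(n) < config.npm1_prevalence).astype(int)
    flt3 = (rng.random(n) < config.flt3_prevalence).astype(int)

    log_mult = np.zeros(n)
    planted = uni[uni["hazard_ratio"] != 1.0]
    for row in planted.itertuples(index=False):
        high = expr[row.probe_set].to_numpy() > row.cutpoint
        log_mult += np.log(row.hazard_ratio) * high
    log_mult += np.log(config.npm1_hr) * npm1 + np.log(config.flt3_hr) * flt3
    death_hazard = config.baseline_rate * np.exp(log_mult)

    t_death = rng.exponential(1.0 / death_hazard)
    c_rate = _censoring_rate(death_hazard, config.censoring, config.admin_horizon)
    t_censor = (
        rng.exponential(1.0 / c_rate, n) if c_rate > 0 else np.full(n, np.inf)
    )
    if config.admin_horizon is not None:
        t_censor = np.minimum(t_censor, config.admin_horizon)
    os_days = np.minimum(t_death, t_censor)
    os_event = (t_death <= t_censor).astype(int)

    relapse_hazard = death_hazard * config.relapse_rate_scale
    t_relapse = rng.exponential(1.0 / relapse_hazard)
    t_efs = np.minimum(t_relapse, t_death)
    efs_days = np.minimum(t_efs, t_censor)
    efs_event = (t_efs <= t_censor).astype(int)

    clinical = pd.DataFrame(
        {
            "os_days": np.round(os_days, 1),
            "os_event": os_event,
            "efs_days": np.round(efs_days, 1),
            "efs_event": efs_event,
            "npm1_mutated": npm1,
            "flt3_itd": flt3,
            "cohort": config.cohort_label,
        },
        index=ids,
    )
    truth = {
        "planted": [
            {
                "probe_set": row.probe_set,
                "pathway": row.pathway,
                "hazard_ratio": float(row.hazard_ratio),
                "cutpoint": float(row.cutpoint),
            }
            for row in planted.itertuples(index=False)
        ],
        "prognostic_pathways": sorted({g.pathway for g in config.planted}),
        "baseline_rate": config.baseline_rate,
        "npm1_hr": config.npm1_hr,
        "flt3_hr": config.flt3_hr,
        "universe_seed": config.effective_universe_seed,
    }
    return SimulatedCohort(
        expression=expr,
        clinical=clinical,
        gene_sets=uni[["probe_set", "pathway"]].copy(),
        truth=truth,
        config=config,
        censoring_rate=c_rate,
    )


def default_study_configs(
    seed: int = 0,
    n_training: int = 162,
    n_validation: int = 78,
    flt3_training: float = 0.48,
    flt3_validation: float = 0.22,
    **overrides,
) -> tuple[SimulationConfig, SimulationConfig]:
    """Config pair mirroring the reference two-cohort design."""
    train = SimulationConfig(
        n_patients=n_training,
        flt3_prevalence=flt3_training,
        cohort_label="training",
        seed=seed,
        universe_seed=seed,
        **overrides,
    )
    valid = train.replace(
        n_patients=n_validation,
        flt3_prevalence=flt3_validation,
        cohort_label="validation",
        seed=seed + 104_729,  # independent patient draws, same universe
    )
    return train, valid


def simulate_two_cohort_study(
    config_train: SimulationConfig, config_valid: SimulationConfig
) -> tuple[SimulatedCohort, SimulatedCohort]:
    """Two independent cohorts sharing one gene universe and planted truth."""
    same_universe = (
        dict(config_train.pathway_sizes) == dict(config_valid.pathway_sizes)
        and tuple(config_train.planted) == tuple(config_valid.planted)
        and config_train.effective_universe_seed == config_valid.effective_universe_seed
    )
    if not same_universe:
        raise ValueError("cohort configs must share the gene universe and planted truth")
    return simulate_cohort(config_train), simulate_cohort(config_valid)
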