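import numpy as np
import pytest

from repairscore.survival import SurvivalData

try:
    from hypothesis import settings

    settings.register_profile("ci", max_examples=25, deadline=None, derandomize=True)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover - hypothesis is a test extra
    pass


@pytest.fixture
def rng():
    return np.random.default_rng(20201006)


@pytest.fixture
def toy_survival():
    """Six patients, alternating groups, two censored; tie-free."""
    data = SurvivalData(
        time=np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
        event=np.array([1, 1, 1, 1, 0, 0]),
    )
    groups = np.array(["A", "B", "A", "B", "A", "B"])
    return data, groups


def random_survival(rng, n, censor_frac=0.3, scale=100.0):
    """Exponential survival with independent exponential censoring."""
    t_event = rng.exponential(scale, n)
    if censor_frac > 0:
        c_scale = scale * (1 - censor_frac) / censor_frac
        t_cens = rng.exponential(c_scale, n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    if event.sum() == 0:  # guarantee at least one event
        event[np.argmin(time)] = 1
    return SurvivalData(time, event)


@pytest.fixture(scope="session")
def trained_study():
    """One planted two-cohort study with a fully trained model (shared by
    several suites to keep the run fast)."""
    import pandas as pd

    from repairscore.pipeline import train_model
    from repairscore.simulate import default_study_configs, simulate_two_cohort_study

    tr, va = simulate_two_cohort_study(
        *default_study_configs(seed=3, n_training=200, n_validation=200)
    )
    gene_sets = dict(zip(tr.gene_sets["probe_set"], tr.gene_sets["pathway"]))
    model, table_tr, scorer = train_model(
        tr.expression, tr.clinical, va.expression, va.clinical, gene_sets
    )
    return {
        "training": tr,
        "validation": va,
        "gene_sets": gene_sets,
        "model": model,
        "table_training": table_tr,
        "scorer": scorer,
    }
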