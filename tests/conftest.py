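import numpy as np
import pandas as pd
import pytest

import sbpvar as sv
from sbpvar import variability as vb


@pytest.fixture(scope="session")
def dense_cohort():
    """n=200 subjects with the full 9-reading schedule (slopes identifiable)."""
    cfg = sv.GeneratorConfig(n_subjects=200, retention_prob=1.0, seed=101)
    truths, longitudinal = sv.generate_cohort(cfg)
    return cfg, truths, longitudinal


@pytest.fixture(scope="session")
def dense_fit(dense_cohort):
    _, truths, longitudinal = dense_cohort
    mcmc = vb.MCMCConfig(iterations=700, burn_in=250, seed=7)
    return vb.fit_heteroscedastic_mixed_model(longitudinal, mcmc=mcmc)


@pytest.fixture(scope="session")
def sparse_cohort():
    """n=200 subjects with exactly 4 quarterly readings each."""
    cfg = sv.GeneratorConfig(
        n_subjects=200, visit_schedule=(0, 3, 6, 9), retention_prob=1.0, seed=202
    )
    truths, longitudinal = sv.generate_cohort(cfg)
    return cfg, truths, longitudinal


@pytest.fixture(scope="session")
def sparse_fit(sparse_cohort):
    _, truths, longitudinal = sparse_cohort
    mcmc = vb.MCMCConfig(iterations=700, burn_in=250, seed=8)
    return vb.fit_heteroscedastic_mixed_model(longitudinal, mcmc=mcmc)


@pytest.fixture(scope="session")
def survival_cohort():
    """Outcome-rich cohort with a positive true effect, no MCMC needed."""
    cfg = sv.GeneratorConfig(
        n_subjects=4000,
        seed=11,
        log_hr_per_5mmhg_sd=float(np.log(1.3)),
        baseline_hazard_rate=0.05,
    )
    truths, _ = sv.generate_cohort(cfg)
    truths = truths.copy()
    truths["time"] = truths["time_composite"]
    truths["event"] = truths["event_composite"]
    return cfg, truths
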