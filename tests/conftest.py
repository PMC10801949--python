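"""Shared fixtures: small hand-built cohorts and simulation helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from csbn.cohort_io import Cohort, VariableSpec


def make_survival_cohort(covariate_levels, rows, times, events):
    """Build a Cohort from explicit per-row categorical values.

    ``covariate_levels``: {name: levels tuple}; ``rows``: list of dicts.
    """
    schema = [
        VariableSpec("time", role="time"),
        VariableSpec("event", role="event"),
    ]
    for name, levels in covariate_levels.items():
        schema.append(VariableSpec(name, levels=tuple(str(l) for l in levels)))
    df = pd.DataFrame(rows)
    df.insert(0, "time", np.asarray(times, dtype=float))
    df.insert(1, "event", np.asarray(events, dtype=int))
    for name in covariate_levels:
        df[name] = df[name].map(lambda v: v if pd.isna(v) else str(v))
    return Cohort(schema, df)


def simulate_binary_cohort(n, betas, seed, baseline_hazard=0.1, censor_scale=15.0,
                           prevalence=0.5):
    """Exponential survival cohort with independent binary covariates."""
    rng = np.random.default_rng(seed)
    p = len(betas)
    X = (rng.random((n, p)) < prevalence).astype(int)
    lp = X @ np.asarray(betas, dtype=float)
    T = rng.exponential(1.0, n) / (baseline_hazard * np.exp(lp))
    C = rng.exponential(censor_scale, n)
    t = np.minimum(T, C)
    e = (T <= C).astype(int)
    names = [f"x{i}" for i in range(p)]
    rows = [{names[j]: str(X[i, j]) for j in range(p)} for i in range(n)]
    cohort = make_survival_cohort({nm: ("0", "1") for nm in names}, rows, t, e)
    return cohort, names, X


@pytest.fixture
def three_subject_cohort():
    """Single binary covariate, x = (1, 0, 1), all events at t = 1, 2, 3.

    The partial-likelihood score has the closed form
    1 - 2u/(2u+1) - u/(u+1) with u = exp(beta), whose root is u = 1/sqrt(2).
    """
    return make_survival_cohort(
        {"x": ("0", "1")},
        [{"x": "1"}, {"x": "0"}, {"x": "1"}],
        [1.0, 2.0, 3.0],
        [1, 1, 1],
    )
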