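"""Shared fixtures: small deterministic cohorts and one cached demo run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from brainage_eval.cohort import (
    CohortSpec,
    FeatureSetSpec,
    demo_spec,
    generate_cohort,
)
from brainage_eval.enet import HyperGrid
from brainage_eval.folds import make_fold_scheme


@pytest.fixture(scope="session")
def tiny_cohort():
    """150 participants, four small feature sets; used across modules."""
    spec = demo_spec(n_participants=150)
    return generate_cohort(spec, seed=11)


@pytest.fixture(scope="session")
def reduced_grid():
    return HyperGrid.reduced()


@pytest.fixture(scope="session")
def tiny_scheme(tiny_cohort):
    cohort, _, _ = tiny_cohort
    return make_fold_scheme(cohort.index.to_numpy(), seed=7)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline run on the demo cohort, shared read-only."""
    from brainage_eval.config import RunConfig
    from brainage_eval.pipeline import run_all

    out = tmp_path_factory.mktemp("demo_run")
    cfg = RunConfig(
        seed=3,
        cohort={"preset": "demo", "n_participants": 150},
        grid="reduced",
        n_components=10,
        importance=False,
        out_dir=str(out / "run"),
    )
    run_dir = run_all(cfg)
    return cfg, run_dir


def planted_signal_set(n=120, p=5, seed=0):
    """A feature set whose first column equals the target."""
    rng = np.random.default_rng(seed)
    y = rng.normal(50, 10, n)
    x = rng.standard_normal((n, p))
    x[:, 0] = y
    ids = pd.Index([f"P{i:05d}" for i in range(n)], name="participant_id")
    table = pd.DataFrame(x, index=ids, columns=[f"c{j}" for j in range(p)])
    cohort = pd.DataFrame(
        {
            "participant_id": ids,
            "age_years": y,
            "sex": rng.integers(0, 2, n),
            "fluid_cognition": rng.normal(100, 15, n),
        },
        index=ids,
    )
    return cohort, table
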