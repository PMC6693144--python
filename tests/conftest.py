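"""Shared fixtures for the agescreen test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from agescreen import (
    BetaMatrix,
    SampleSheet,
    SimulationConfig,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """The default simulated cohort (seed 0): used by many read-only tests."""
    return generate_cohort(SimulationConfig(seed=20260101))


@pytest.fixture(scope="session")
def adult_cohort():
    """Adult-only cohort where year-scale effects are exact (linear branch)."""
    cfg = SimulationConfig(seed=20260102, age_range=(20.0, 55.0),
                           case_age_range=(20.0, 55.0), n_probes=700,
                           n_admp_hyper=50, n_admp_hypo=50, n_disease_hypo=50,
                           n_disease_hyper=20)
    return generate_cohort(cfg)


def make_sheet(ages, sexes=None, batches=None, groups=None, prefix="S"):
    """Small hand-built sample sheet for arithmetic oracles."""
    n = len(ages)
    ids = [f"{prefix}{i:03d}" for i in range(n)]
    return SampleSheet(pd.DataFrame({
        "age": np.asarray(ages, dtype=float),
        "sex": (sexes if sexes is not None
                else [("female", "male")[i % 2] for i in range(n)]),
        "batch": batches if batches is not None else ["b1"] * n,
        "group": groups if groups is not None else ["control"] * n,
    }, index=pd.Index(ids, name="sample_id")))


def make_betas(values, probe_prefix="cg", sample_prefix="S"):
    arr = np.asarray(values, dtype=float)
    probes = [f"{probe_prefix}{i:06d}" for i in range(arr.shape[0])]
    samples = [f"{sample_prefix}{j:03d}" for j in range(arr.shape[1])]
    return BetaMatrix(pd.DataFrame(arr, index=probes, columns=samples))
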