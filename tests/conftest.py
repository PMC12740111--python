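"""Shared fixtures: small simulated cohorts and their matrices."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import methclock as mc

warnings.filterwarnings("ignore", message="dropping .* zero-variance")


def build_channel_matrix(cohort: mc.Cohort, mod: str = "a", min_cov: int = 10):
    filt = {sid: mc.filter_coverage(t, min_cov) for sid, t in cohort.tables.items()}
    return mc.build_matrix(filt, cohort.manifest, min_cov=min_cov).subset_channel(mod)


@pytest.fixture(scope="session")
def small_cohort() -> mc.Cohort:
    """One modest default-condition cohort (one channel, 500 sites)."""
    cfg = mc.SimulationConfig(seed=11, n_sites=500, mod_codes=("a",))
    return mc.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_cohort) -> mc.MethylationMatrix:
    return build_channel_matrix(small_cohort)


@pytest.fixture(scope="session")
def null_cohort() -> mc.Cohort:
    """Zero-signal cohort: no drifting sites, no entropy schedule."""
    cfg = mc.SimulationConfig(
        seed=7, n_sites=300, frac_clock_sites=0.0, frac_entropy_sites=0.0,
        mod_codes=("a",),
    )
    return mc.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_matrix(null_cohort) -> mc.MethylationMatrix:
    return build_channel_matrix(null_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
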