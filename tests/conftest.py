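"""Shared fixtures: small synthetic worlds generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from climdebt import WorldConfig, run_pipeline
from climdebt.synthetic import generate_landscape, generate_species_pool, sample_occurrences


def tiny_config(**overrides) -> WorldConfig:
    """A fast little world for unit tests (correctness, not recovery)."""
    base = dict(
        lon_min=-6.0, lon_max=6.0, lat_min=38.0, lat_max=50.0,
        resolution=1.0, sea_band=(-1.0, 1.0),
        window_lat_min=None, window_lat_max=None,
        n_species=40, effort_first_period=3000.0, effort_growth=1.5,
        seed=7,
    )
    base.update(overrides)
    return WorldConfig(**base)


@pytest.fixture(scope="session")
def tiny_world():
    cfg = tiny_config()
    landscape = generate_landscape(cfg)
    pool = generate_species_pool(cfg)
    records = sample_occurrences(landscape, pool)
    return cfg, landscape, pool, records


@pytest.fixture(scope="session")
def pipeline_result():
    """Full pipeline on a small world with heterogeneous warming.

    Session-scoped: several invariant tests (CTI bounds, turnover identity,
    thinning bound, trend consistency) read from it without refitting.
    """
    cfg = tiny_config(warming_rate=(0.0, 0.04), lam=1.0, n_species=60,
                      effort_first_period=4000.0, seed=11)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def recovery_result():
    """Default-geometry world (lambda = 1, heterogeneous warming), one seed.

    Used by parameter-recovery tests that need the buffered study design.
    """
    cfg = WorldConfig(warming_rate=(0.0, 0.04), lam=1.0, seed=3)
    return run_pipeline(cfg)
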