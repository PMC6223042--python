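"""Shared fixtures: small phantoms and reduced-size registration configs.

Expensive artefacts (generated phantom pairs, cohort runs) are session-scoped
so several test modules can share one computation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import cbcthm as c


def small_spec(seed: int = 3, **kw) -> c.PhantomSpec:
    """Compact pelvis phantom (96x96 in-plane) used for registration tests."""
    base = dict(shape=(48, 96, 96), spacing=(3.0, 1.42, 1.42), seed=seed)
    base.update(kw)
    return c.PhantomSpec(**base)


@pytest.fixture(scope="session")
def phantom_pair():
    """Deterministic small phantom study unit (pCT, CBCT, truth warp, ROIs)."""
    return c.generate_pair(small_spec(seed=3))


@pytest.fixture(scope="session")
def preprocessed_pair(phantom_pair):
    pct_pp, pct_mask = c.preprocess_volume(phantom_pair["pct"], threshold=-700.0)
    cbct_pp, cbct_mask = c.preprocess_volume(phantom_pair["cbct"], threshold=-600.0)
    return {
        "pct": pct_pp,
        "pct_mask": pct_mask,
        "cbct": cbct_pp,
        "cbct_mask": cbct_mask,
    }


@pytest.fixture()
def fast_config():
    """Cut-down registration config for smoke/determinism tests."""
    return c.RegistrationConfig(
        levels=2,
        smoothing_sigmas=(4.0, 2.0),
        downsample_factors=(4, 2),
        grid_schedule=(4.0, 2.0),
        step_schedule=(4.0, 2.0),
        iterations=48,
        samples_per_iteration=512,
        validation_samples=2048,
        seed=7,
    )


def fast_pipeline_config(seed: int = 11) -> c.PipelineConfig:
    reg = c.RegistrationConfig(
        levels=2,
        smoothing_sigmas=(4.0, 2.0),
        downsample_factors=(4, 2),
        grid_schedule=(4.0, 2.0),
        step_schedule=(4.0, 2.0),
        iterations=48,
        samples_per_iteration=512,
        validation_samples=2048,
    )
    return c.PipelineConfig(phantom=small_spec(), registration=reg, seed=seed)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
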