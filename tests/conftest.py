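"""Shared fixtures: simulated cohorts and their metric tables.

Cohort simulation and metric extraction are the expensive steps, so the
study-sized cohorts are built once per session and shared.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import mocapskill as m


@pytest.fixture(scope="session")
def run_config() -> m.RunConfig:
    return m.RunConfig()


@pytest.fixture(scope="session")
def default_cohort() -> m.Cohort:
    """Study-sized cohort (32 experts / 18 intermediates / 20 novices)."""
    return m.generate_cohort(m.SyntheticCohortConfig(seed=42))


@pytest.fixture(scope="session")
def default_features(default_cohort, run_config) -> m.FeatureMatrix:
    return m.compute_features(default_cohort, run_config)


@pytest.fixture(scope="session")
def ordering_features(run_config) -> m.FeatureMatrix:
    """Balanced 20/20/20 cohort for the effect-direction property."""
    cfg = m.SyntheticCohortConfig(
        n_experts=20, n_intermediates=20, n_novices=20, seed=7
    )
    return m.compute_features(m.generate_cohort(cfg), run_config)


@pytest.fixture(scope="session")
def null_features(run_config) -> m.FeatureMatrix:
    """Zero-effect cohort, balanced 24/23/23: no planted group differences."""
    cfg = m.SyntheticCohortConfig(
        n_experts=24, n_intermediates=23, n_novices=23, seed=99
    ).zero_effect()
    return m.compute_features(m.generate_cohort(cfg), run_config)


@pytest.fixture()
def noise_free_config() -> m.SyntheticCohortConfig:
    """Single-goal, noise-free simulator settings for degenerate-case checks."""
    return dataclasses.replace(
        m.SyntheticCohortConfig(seed=0),
        goals_per_trial=1,
        corrective_rate=(0.0, 0.0),
        tremor_rms_mm=(0.0, 0.0),
        depth_excursion_mm=(0.0, 0.0),
        spurious_grip_per_min=(0.0, 0.0),
        bimanual_jitter_s=(0.0, 0.0),
    )


@pytest.fixture()
def tiny_spec() -> m.ClassifierSpec:
    return m.ClassifierSpec(kind="svm", grid={"C": [1.0], "gamma": [0.1]})


def make_track(
    x, y=None, z=None, roll=None, pitch=None, yaw=None, grip=None,
    sample_rate=30.0, instrument_id="scissors", hand="right",
):
    """Build a valid InstrumentTrack from whichever channels a test cares
    about, zero-filling the rest."""
    x = np.asarray(x, dtype=float)
    n = x.size
    zeros = np.zeros(n)
    def pick(v):
        return zeros if v is None else np.asarray(v, dtype=float)
    return m.InstrumentTrack(
        instrument_id=instrument_id,
        hand=hand,
        t=np.arange(n) / sample_rate,
        x=x, y=pick(y), z=pick(z),
        roll=pick(roll), pitch=pick(pitch), yaw=pick(yaw), grip=pick(grip),
        sample_rate=sample_rate,
    )
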