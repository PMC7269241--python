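"""Shared fixtures: templates, small study configurations, and one
full-scale seeded study reused by the end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

from palzsim.config import StudyConfig
from palzsim.synthetic import SimStudyConfig, make_cohorts, make_template
from palzsim.study import prepare_scoring_inputs


@pytest.fixture(scope="session")
def small_template():
    """A compact phantom lattice, cheap enough for per-test use."""
    return make_template(grid_shape=(28, 32, 28), voxel_size_mm=(4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def default_template():
    """The default half-resolution lattice (46 x 55 x 46 at 4 mm)."""
    return make_template()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def tiny_config(seed: int = 7, **overrides) -> SimStudyConfig:
    base = dict(
        n_nc=8,
        n_ad=8,
        n_mci=8,
        n_mci_converters=4,
        n_error_maps_a=2,
        n_error_maps_b=3,
        n_reference=12,
        grid_shape=(28, 32, 28),
        seed=seed,
    )
    base.update(overrides)
    return SimStudyConfig(**base)


@pytest.fixture()
def tiny_sim_config():
    return tiny_config()


@pytest.fixture(scope="session")
def default_study():
    """The full seeded default study (203 subjects x 47 maps), run once.

    Returns ``(cohorts, smoothed_subjects, model, score_table)``; shared by
    the end-to-end and acceptance tests.
    """
    from palzsim.errorsim import run_cross_simulation

    config = StudyConfig(sim=SimStudyConfig(seed=20))
    cohorts = make_cohorts(config.sim)
    smoothed_subjects, model = prepare_scoring_inputs(cohorts, config)
    scores = run_cross_simulation(
        smoothed_subjects, cohorts.error_maps, model, cohorts.template, config.scoring
    )
    return cohorts, smoothed_subjects, model, scores
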