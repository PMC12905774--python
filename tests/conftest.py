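"""Shared fixtures: desk-scale synthetic cohorts and completed LOCO runs.

The LOCO runs are session-scoped because training the two classifiers per
fold is the expensive step; several test modules assert different properties
of the same runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from rsipipe.cohort import CohortConfig, SiteProfile, generate_cohort, synthesize_cohort_volumes
from rsipipe.loco import LocoConfig, run_loco_evaluation
from rsipipe.nn import TrainConfig

TINY_GRID = (12, 12, 8)
TINY_SPACING = (2.0, 2.0, 3.0)


def tiny_sites(noise_a: float = 0.02, noise_b: float = 0.03) -> tuple[SiteProfile, ...]:
    return (
        SiteProfile("siteA", 30, prevalence=0.45, bnbc_fraction=0.8, noise_sigma=noise_a),
        SiteProfile("siteB", 30, prevalence=0.35, bnbc_fraction=0.8, noise_sigma=noise_b),
    )


def tiny_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    kwargs = dict(
        sites=tiny_sites(),
        grid_shape=TINY_GRID,
        voxel_spacing=TINY_SPACING,
        lesion_radius_range=(4.0, 7.0),
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_cohort():
    """One noiseless-ish two-site cohort with volumes, shared across modules."""
    cfg = tiny_cohort_config(seed=7)
    truths, manifest = generate_cohort(cfg)
    studies = synthesize_cohort_volumes(truths, cfg)
    return cfg, truths, manifest, studies


def run_tiny_loco(seed: int):
    cfg = tiny_cohort_config(seed=seed)
    truths, manifest = generate_cohort(cfg)
    studies = synthesize_cohort_volumes(truths, cfg)
    lcfg = LocoConfig(
        train_config=TrainConfig(total_epochs=4, batch_size=8),
        crop_shape=TINY_GRID,
        always_train=None,
        n_boot=200,
        seed=seed,
    )
    return manifest, run_loco_evaluation(studies, manifest, lcfg)


@pytest.fixture(scope="session")
def loco_runs():
    """Complete LOCO evaluations for three seeds on two-site cohorts."""
    return {seed: run_tiny_loco(seed) for seed in (1, 2, 3)}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
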