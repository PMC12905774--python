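"""Shared configuration for the analysis drivers.

The study cohort is a desk-scale replica of the seven-center structure:
per-center sizes are the published counts scaled down (factor ~0.15, floor of
five patients) so the full leave-one-center-out rotation, including the
always-train smallest center, runs in minutes on one CPU. Prevalence and
BN-BC mix per center keep their published ratios.
"""

from pathlib import Path

from rsipipe.cohort import CohortConfig, SiteProfile, default_site_profiles
from rsipipe.loco import LocoConfig
from rsipipe.nn import TrainConfig
from rsipipe.rsi import RSIFitConfig

REPO = Path(__file__).resolve().parents[1]
RESULTS = REPO / "results"
SCRATCH = REPO / "scratch"
COHORT_DIR = SCRATCH / "cohort"

SCALE = 0.15
MIN_SITE = 5
GRID = (16, 16, 12)
SPACING = (2.0, 2.0, 3.0)
SEED = 20260927


def study_sites() -> tuple[SiteProfile, ...]:
    scaled = []
    for p in default_site_profiles():
        n = max(MIN_SITE, round(SCALE * p.n_patients))
        scaled.append(SiteProfile(
            site_id=p.site_id,
            n_patients=n,
            prevalence=p.prevalence,
            bnbc_fraction=p.bnbc_fraction,
            noise_sigma=0.02,
        ))
    return tuple(scaled)


def study_cohort_config(seed: int = SEED) -> CohortConfig:
    return CohortConfig(
        sites=study_sites(),
        grid_shape=GRID,
        voxel_spacing=SPACING,
        lesion_radius_range=(4.0, 8.0),
        seed=seed,
    )


def study_loco_config(seed: int = SEED) -> LocoConfig:
    return LocoConfig(
        fit_config=RSIFitConfig(),
        train_config=TrainConfig(total_epochs=6, batch_size=8),
        net_preset="tiny",
        crop_shape=GRID,
        always_train="smallest",
        n_boot=10000,
        seed=seed,
    )
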