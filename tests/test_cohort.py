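"""Synthetic cohort generator: sampling structure, forward model, disk layout."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import tiny_cohort_config, tiny_sites, TINY_GRID
from rsipipe.cohort import (
    CohortConfig,
    SiteProfile,
    default_site_profiles,
    generate_cohort,
    read_cohort,
    site_count_table,
    synthesize_cohort_volumes,
    synthesize_patient_volumes,
    write_cohort,
)
from rsipipe.errors import CohortIOError, ConfigurationError
from rsipipe.rsi import RSIFitConfig, compute_rsirs, fit_compartments


def test_manifest_deterministic():
    cfg = tiny_cohort_config(seed=5)
    _, m1 = generate_cohort(cfg)
    _, m2 = generate_cohort(cfg)
    assert m1.to_csv(index=False) == m2.to_csv(index=False)


def test_zero_prevalence_all_negative():
    cfg = tiny_cohort_config(seed=1, sites=(SiteProfile("z", 50, 0.0, 0.5),))
    _, manifest = generate_cohort(cfg)
    assert (manifest["cspca_label"] == 0).all()


def test_prevalence_matches_binomial_oracle():
    """At n=2000 and the cohort-wide 39% prevalence, the observed csPCa
    fraction lies within 3 binomial standard errors."""
    cfg = tiny_cohort_config(seed=2, sites=(SiteProfile("big", 2000, 0.39, 0.5),))
    _, manifest = generate_cohort(cfg)
    phat = manifest["cspca_label"].mean()
    se = np.sqrt(0.39 * 0.61 / 2000)
    assert abs(phat - 0.39) < 3 * se


def test_invalid_probability_vector_names_site():
    bad = SiteProfile("badsite", 10, 0.5, 0.5, pirads_given_pos=(0.5, 0.5, 0.5, 0, 0))
    with pytest.raises(ConfigurationError, match="badsite"):
        generate_cohort(tiny_cohort_config(sites=(bad,)))


def test_pirads_conditionals_chisquare():
    """Empirical label-conditional PI-RADS frequencies are consistent with the
    configured conditionals (chi-square goodness of fit, n=5000, alpha=0.01)."""
    site = SiteProfile("chi", 5000, 0.5, 0.5)
    _, manifest = generate_cohort(tiny_cohort_config(seed=3, sites=(site,)))
    for label, probs in ((1, site.pirads_given_pos), (0, site.pirads_given_neg)):
        sub = manifest[manifest["cspca_label"] == label]
        observed = np.array([(sub["pirads"] == k).sum() for k in range(1, 6)])
        expected = np.asarray(probs) * len(sub)
        _, p = stats.chisquare(observed, expected)
        assert p > 0.01


def test_default_profiles_match_published_center_counts():
    table = site_count_table(default_site_profiles())
    assert table["n_patients"].sum() == 1846
    assert table["n_cspca"].sum() == 721
    assert table["n_bnbc"].sum() == 876


def test_fraction_conservation_and_b0_signal(tiny_cohort):
    cfg, truths, _, studies = tiny_cohort
    noiseless_cfg = tiny_cohort_config(seed=9, sites=tiny_sites(0.0, 0.0))
    truths0, _ = generate_cohort(noiseless_cfg)
    rng = np.random.default_rng(0)
    study = synthesize_patient_volumes(truths0[0], noiseless_cfg, rng)
    frac = truths0[0].true_compartment_maps
    assert np.all(frac >= 0)
    assert np.allclose(frac.sum(axis=0), 1.0, atol=1e-6)
    # at b=0 every decay term is 1, so the signal is exactly S0
    assert np.allclose(study.dwi[0.0], 100.0, atol=1e-4)


def test_single_compartment_log_linear_decay():
    cfg = tiny_cohort_config(
        seed=4,
        sites=(SiteProfile("one", 3, 0.0, 0.5, noise_sigma=0.0),),
        background_fractions=(1.0, 0.0, 0.0, 0.0),
    )
    truths, _ = generate_cohort(cfg)
    study = synthesize_patient_volumes(
        truths[0], cfg, np.random.default_rng(1), background_variation=0.0
    )
    b = np.asarray(cfg.b_values)
    voxel = tuple(np.array(TINY_GRID) // 2)
    sig = np.array([study.dwi[float(bb)][voxel] for bb in b], dtype=float)
    slope = np.polyfit(b, np.log(sig), 1)[0]
    assert slope == pytest.approx(-cfg.compartment_adcs[0], rel=1e-4)


def test_lesion_elevates_restricted_fraction():
    cfg = tiny_cohort_config(seed=6, sites=(SiteProfile("l", 20, 1.0, 0.5, noise_sigma=0.0),))
    truths, _ = generate_cohort(cfg)
    rng = np.random.default_rng(2)
    for t in truths[:5]:
        synthesize_patient_volumes(t, cfg, rng)
        assert t.lesion_centers, "csPCa-positive patient must get a lesion"
        c1 = t.true_compartment_maps[0]
        background_c1_max = cfg.background_fractions[0] + 0.03  # base + variation bound
        assert c1.max() > background_c1_max


def test_lesion_impossible_raises():
    cfg = tiny_cohort_config(
        seed=6,
        grid_shape=(6, 6, 4),
        sites=(SiteProfile("l", 2, 1.0, 0.5),),
        lesion_radius_range=(40.0, 50.0),
    )
    truths, _ = generate_cohort(cfg)
    with pytest.raises(ConfigurationError, match="lesion"):
        synthesize_patient_volumes(truths[0], cfg, np.random.default_rng(0), max_lesion_attempts=5)


def test_biomarker_separates_labels_without_noise():
    """With zero noise and C1 contrast > 1, RSIrs_max is strictly larger for
    every csPCa-positive patient than for every negative patient."""
    cfg = tiny_cohort_config(seed=11, sites=tiny_sites(0.0, 0.0))
    truths, manifest = generate_cohort(cfg)
    studies = synthesize_cohort_volumes(truths, cfg)
    fit = RSIFitConfig(b_values=cfg.b_values, compartment_adcs=cfg.compartment_adcs)
    rs = {}
    for s in studies:
        maps = fit_compartments(s.dwi, fit, mask=s.prostate_mask)
        rs[s.patient_id] = compute_rsirs(maps.c1, s.t2w, s.prostate_mask).rsirs_max
    labels = manifest.set_index("patient_id")["cspca_label"]
    pos = [rs[p] for p in rs if labels[p] == 1]
    neg = [rs[p] for p in rs if labels[p] == 0]
    assert min(pos) > max(neg)


def test_cohort_roundtrip(tmp_path, tiny_cohort):
    cfg, _, manifest, studies = tiny_cohort
    sub = studies[:4]
    sub_manifest = manifest[manifest["patient_id"].isin([s.patient_id for s in sub])]
    out = write_cohort(sub, sub_manifest, tmp_path / "cohort")
    studies2, manifest2 = read_cohort(out)
    pd.testing.assert_frame_equal(sub_manifest.reset_index(drop=True), manifest2)
    by_id = {s.patient_id: s for s in studies2}
    for s in sub:
        r = by_id[s.patient_id]
        assert np.allclose(r.t2w, s.t2w.astype(np.float32))
        assert np.array_equal(r.prostate_mask, s.prostate_mask)
        assert set(r.dwi) == {float(b) for b in cfg.b_values}
        for b in s.dwi:
            assert np.allclose(r.dwi[b], s.dwi[b].astype(np.float32))
        # affine encodes the voxel spacing
        assert np.allclose(np.abs(np.diag(r.t2w_affine))[:3], cfg.voxel_spacing)


def test_read_missing_files_names_patients(tmp_path, tiny_cohort):
    cfg, _, manifest, studies = tiny_cohort
    sub = studies[:3]
    sub_manifest = manifest[manifest["patient_id"].isin([s.patient_id for s in sub])]
    out = write_cohort(sub, sub_manifest, tmp_path / "cohort")
    victim = sub[1].patient_id
    (out / f"{victim}_mask.nii.gz").unlink()
    with pytest.raises(CohortIOError, match=victim):
        read_cohort(out)
    with pytest.raises(CohortIOError, match="manifest"):
        read_cohort(tmp_path / "nowhere")


def test_config_validation_errors():
    with pytest.raises(ConfigurationError):
        tiny_cohort_config(b_values=(0.0, 500.0)).validate()
    with pytest.raises(ConfigurationError):
        tiny_cohort_config(compartment_adcs=(1e-3, 1e-3, 2e-3, 3e-3)).validate()
    with pytest.raises(ConfigurationError):
        tiny_cohort_config(background_fractions=(0.5, 0.5, 0.5, 0.5)).validate()
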