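"""Phantom generator: atlas geometry, cohort sampling, volume rendering, I/O."""

import numpy as np
import pandas as pd
import pytest

from taucl.synthetic import (
    COHORT_COLUMNS, RegionSpec, SyntheticConfig, g_high, g_low, generate_atlas,
    generate_dataset, read_cohort, render_volume, sample_cohort, write_dataset,
)


# ---------------------------------------------------------------- atlas

def test_atlas_single_region_covers_whole_mask(tiny_config):
    spec = [RegionSpec("everything", "effect_low", (0.5, 0.5, 0.5), 5.0)]
    atlas = generate_atlas(tiny_config, regions=spec)
    labs = np.unique(atlas.labels[atlas.brain_mask])
    assert labs.tolist() == [1]


def test_atlas_sphere_counts_match_bruteforce(tiny_config):
    centers = [(5.0, 6.0, 8.0), (11.0, 14.0, 8.0)]
    spec = [RegionSpec(f"s{i}", "null", c, 3.0, units="voxel")
            for i, c in enumerate(centers)]
    atlas = generate_atlas(tiny_config, regions=spec)
    # independent oracle: exhaustive voxel enumeration inside each sphere
    mask_spec = [RegionSpec("m", "null", (0.5, 0.5, 0.5), 5.0)]
    brain = generate_atlas(tiny_config, regions=mask_spec).brain_mask
    for lab, c in enumerate(centers, start=1):
        count = 0
        for i in range(16):
            for j in range(20):
                for k in range(16):
                    if brain[i, j, k] and \
                            (i - c[0])**2 + (j - c[1])**2 + (k - c[2])**2 <= 9.0:
                        count += 1
        assert int((atlas.labels == lab).sum()) == count


def test_atlas_deterministic(tiny_config):
    a, b = generate_atlas(tiny_config), generate_atlas(tiny_config)
    assert np.array_equal(a.labels, b.labels)
    assert a.roles == b.roles


def test_atlas_default_layout_has_all_roles(tiny_atlas):
    for role in ("reference", "effect_low", "effect_high_left",
                 "effect_high_right", "null", "hot"):
        assert tiny_atlas.role_mask(role).any(), role
    assert np.all(tiny_atlas.labels[~tiny_atlas.brain_mask] == 0)


def test_atlas_too_small_grid_rejected():
    with pytest.raises(ValueError, match="too small"):
        generate_atlas(SyntheticConfig(grid_shape=(8, 20, 16)))


def test_atlas_empty_region_names_culprit(tiny_config):
    spec = [RegionSpec("outside", "null", (1.5, 1.5, 1.5), 0.01)]
    with pytest.raises(ValueError, match="outside"):
        generate_atlas(tiny_config, regions=spec)


# --------------------------------------------------------------- cohort

def test_cohort_empty_is_valid_schema():
    table = sample_cohort(SyntheticConfig(n_subjects=0))
    assert len(table) == 0
    assert list(table.columns) == COHORT_COLUMNS


def test_cohort_uniform_abeta_fraction_matches_closed_form():
    # uniform on [-10, 140]: P(CL >= 25) = 115/150; Monte-Carlo at n=5000
    # must fall within 3 binomial SDs of the closed form
    cfg = SyntheticConfig(n_subjects=5000, cl_distribution="uniform", seed=3)
    table = sample_cohort(cfg)
    p = 115.0 / 150.0
    sd = np.sqrt(p * (1 - p) / 5000)
    assert abs((table["cl"] >= 25).mean() - p) < 3 * sd


def test_cohort_default_mixture_calibrated_to_abeta_rate():
    cfg = SyntheticConfig(n_subjects=5000, seed=3)
    table = sample_cohort(cfg)
    sd = np.sqrt(0.49 * 0.51 / 5000)
    assert abs((table["cl"] >= 25).mean() - 0.49) < 3 * sd
    assert table["cl"].between(cfg.cl_low, cfg.cl_high).all()


def test_cohort_deterministic_and_splits_partition(tiny_config):
    a, b = sample_cohort(tiny_config), sample_cohort(tiny_config)
    pd.testing.assert_frame_equal(a, b)
    assert a["id"].is_unique
    assert set(a["split"]) <= {"train", "validation", "test"}
    counts = a["split"].value_counts()
    assert counts.sum() == len(a)


def test_cohort_split_proportions_default():
    # 150 subjects at 109/12/13-of-134 proportions
    table = sample_cohort(SyntheticConfig(n_subjects=150, seed=0))
    counts = table["split"].value_counts()
    assert counts["test"] == round(13 / 134 * 150)
    assert counts["validation"] == round(12 / 134 * 150)
    assert counts["train"] == 150 - counts["test"] - counts["validation"]


# -------------------------------------------------------------- volumes

def _uniform_baseline_config(**kw):
    base = dict(grid_shape=(16, 20, 16), n_subjects=4, seed=2,
                region_baseline_contrast=0.0)
    base.update(kw)
    return SyntheticConfig(**base)


def test_render_no_signal_is_flat_baseline(tiny_config):
    cfg = _uniform_baseline_config(noise_sd=0.0, effect_low_region=0.0,
                                   effect_high_region=0.0, hot_region_offset=0.0)
    atlas = generate_atlas(cfg)
    vol = render_volume({"id": "s0", "cl": 50.0}, atlas, cfg)
    assert np.allclose(vol.data[atlas.brain_mask], cfg.baseline)
    assert np.all(vol.data[~atlas.brain_mask] == 0.0)


def test_render_effect_high_at_saturation_analytic():
    # noiseless: at CL far above the changepoint g_high -> 1, so the
    # effect_high regions sit exactly at baseline + amplitude
    cfg = _uniform_baseline_config(noise_sd=0.0, effect_low_region=0.0,
                                   effect_high_region=0.5)
    atlas = generate_atlas(cfg)
    cl = cfg.changepoint_cl + 40 * cfg.tau_high
    vol = render_volume({"id": "s0", "cl": cl}, atlas, cfg)
    high = atlas.role_mask("effect_high_left") | atlas.role_mask("effect_high_right")
    rest = atlas.brain_mask & ~high & ~atlas.role_mask("hot")
    assert np.allclose(vol.data[high], cfg.baseline + 0.5)
    assert np.allclose(vol.data[rest], cfg.baseline)


def test_render_out_of_mask_zero_for_every_subject(tiny_dataset):
    for vol in tiny_dataset["volumes"]:
        assert np.all(vol.data[~tiny_dataset["atlas"].brain_mask] == 0.0)


def test_render_deterministic_and_order_independent(tiny_config):
    atlas = generate_atlas(tiny_config)
    row = {"id": "sub-0007", "cl": 60.0}
    v1 = render_volume(row, atlas, tiny_config)
    v2 = render_volume(row, atlas, tiny_config)
    assert np.array_equal(v1.data, v2.data)


def test_render_grid_mismatch_fatal(tiny_config):
    atlas = generate_atlas(tiny_config)
    other = SyntheticConfig(grid_shape=(20, 20, 20))
    with pytest.raises(ValueError, match="grid"):
        render_volume({"id": "x", "cl": 0.0}, atlas, other)


def test_planted_crossover_of_regional_slopes():
    """Analytic invariant: d/dCL of the planted regional intensity is larger
    for the low-CL region far below the changepoint and larger for the
    high-CL region far above it."""
    cfg = SyntheticConfig()
    h = 1e-4

    def slope(g, cl):
        return (float(g(cl + h, cfg)) - float(g(cl - h, cfg))) / (2 * h)

    lo_cl, hi_cl = cfg.changepoint_cl - 30, cfg.changepoint_cl + 30
    assert cfg.effect_low_region * slope(g_low, lo_cl) > \
        cfg.effect_high_region * slope(g_high, lo_cl)
    assert cfg.effect_high_region * slope(g_high, hi_cl) > \
        cfg.effect_low_region * slope(g_low, hi_cl)


def test_null_regions_uncorrelated_with_cl():
    cfg = SyntheticConfig(grid_shape=(16, 20, 16), n_subjects=120, seed=9)
    cohort, atlas, volumes = generate_dataset(cfg)
    null = atlas.role_mask("null")
    means = np.array([v.data[null].mean() for v in volumes])
    r = np.corrcoef(cohort["cl"], means)[0, 1]
    assert abs(r) < 3.0 / np.sqrt(len(cohort))


# ------------------------------------------------------------------ I/O

def test_write_dataset_roundtrip(tmp_path, tiny_dataset):
    cohort = tiny_dataset["cohort"].iloc[:5].reset_index(drop=True)
    volumes = tiny_dataset["volumes"][:5]
    manifest = write_dataset(cohort, volumes, tiny_dataset["atlas"], tmp_path,
                             config=tiny_dataset["config"])
    assert len(manifest["images"]) == len(cohort) + 1  # + atlas
    from taucl.volume import Volume
    back = Volume.load(tmp_path / f"{cohort['id'][0]}_suv.nii.gz")
    assert np.allclose(back.data, volumes[0].data, atol=1e-6)  # float32 on disk
    re = read_cohort(tmp_path / "cohort.tsv")
    pd.testing.assert_frame_equal(
        re.drop(columns="fold"), cohort.drop(columns="fold"),
        check_exact=False, rtol=1e-12)


def test_write_dataset_count_mismatch(tmp_path, tiny_dataset):
    with pytest.raises(ValueError, match="volumes"):
        write_dataset(tiny_dataset["cohort"], tiny_dataset["volumes"][:2],
                      tiny_dataset["atlas"], tmp_path)
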