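"""Phantom generator: determinism, density, truth consistency, controls."""

import numpy as np
import pandas as pd
import pytest

from imic.io import INTENSITY_MAX, MARKER_CHANNELS
from imic.phantom import (
    DEFAULT_LINEAGE_FRACTIONS,
    PhantomConfig,
    PlacementError,
    canonical_profiles,
    generate_isotype_control,
    generate_phantom,
    generate_single_stain,
)


def test_canonical_profiles_cover_all_marker_triples():
    profiles = canonical_profiles()
    assert len(profiles) == 8
    assert {p.expresses for p in profiles.values()} == {
        (a, b, c) for a in (False, True) for b in (False, True) for c in (False, True)
    }


def test_zero_density_yields_background_only():
    cfg = PhantomConfig(
        width_px=256, height_px=256, cell_density_per_mm2=0.0, seed=3
    )
    stack, truth, _ = generate_phantom(cfg)
    assert len(truth) == 0
    assert truth.label_image.max() == 0
    for c in MARKER_CHANNELS:
        assert stack.channel(c).mean() == pytest.approx(
            cfg.background_level[c], abs=3 * cfg.noise_sd[c]
        )


def test_same_seed_is_bit_identical(small_config):
    a_stack, a_truth, _ = generate_phantom(small_config)
    b_stack, b_truth, _ = generate_phantom(small_config)
    for c in a_stack.channels:
        np.testing.assert_array_equal(a_stack.channel(c), b_stack.channel(c))
    pd.testing.assert_frame_equal(a_truth.table, b_truth.table)
    np.testing.assert_array_equal(a_truth.label_image, b_truth.label_image)


def test_cell_count_follows_poisson_placement(default_phantom, default_config):
    # 1 mm^2 at the default density: count within 3*sqrt(lambda) of lambda
    _, truth, _ = default_phantom
    lam = default_config.cell_density_per_mm2 * default_config.area_mm2
    assert abs(len(truth) - lam) <= 3 * np.sqrt(lam)


def test_truth_lineage_fractions_match_config(default_phantom):
    _, truth, _ = default_phantom
    for region, sub in truth.table.groupby("region"):
        n = len(sub)
        obs = sub["lineage"].value_counts()
        for name, frac in DEFAULT_LINEAGE_FRACTIONS.items():
            sd = np.sqrt(n * frac * (1 - frac))
            assert abs(obs.get(name, 0) - n * frac) <= 3 * sd, (region, name)


def test_nucleus_area_median_converges(default_phantom, default_config):
    _, truth, _ = default_phantom
    assert len(truth) >= 2000
    med = truth.table["nucleus_area_um2"].median()
    assert med == pytest.approx(default_config.nucleus_area_um2_median, rel=0.05)


def test_truth_ids_map_to_connected_nuclei(small_phantom):
    import scipy.ndimage as ndi

    _, truth, _ = small_phantom
    lab = truth.label_image
    ids = truth.table["cell_id"].to_numpy()
    present, counts = np.unique(lab[lab > 0], return_counts=True)
    assert set(ids) == set(present)
    # each truth nucleus is a single connected component
    objects = ndi.find_objects(lab)
    for i in np.random.default_rng(0).choice(ids, size=25, replace=False):
        sl = objects[i - 1]
        comp, n = ndi.label(lab[sl] == i)
        assert n == 1


def test_region_matches_band_of_centroid(small_phantom, small_config):
    _, truth, _ = small_phantom
    band = int(round(small_config.epithelium_fraction * small_config.height_px))
    rows = truth.table["centroid_row"].to_numpy()
    expect = np.where(rows < band, "epithelium", "lamina_propria")
    assert (truth.table["region"].to_numpy() == expect).all()


def test_pixels_stay_in_14bit_range(small_phantom):
    stack, _, _ = small_phantom
    for c, arr in stack.channels.items():
        assert arr.dtype == np.uint16
        assert arr.min() >= 0 and arr.max() <= INTENSITY_MAX


def test_impossible_density_raises_with_achievable_value():
    cfg = PhantomConfig(
        width_px=200, height_px=200, cell_density_per_mm2=60000, seed=0
    )
    with pytest.raises(PlacementError, match="achievable density"):
        generate_phantom(cfg)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="sum"):
        PhantomConfig(
            lineage_fractions={
                "epithelium": {"triple_negative": 0.5},
                "lamina_propria": {"triple_negative": 1.0},
            }
        )
    with pytest.raises(ValueError, match="diagonal"):
        PhantomConfig(spillover=np.full((3, 3), 0.5))
    with pytest.raises(ValueError, match="off-diagonal"):
        PhantomConfig(spillover=np.eye(3) + 1.5 * (1 - np.eye(3)))


class TestIsotypeControl:
    def test_marker_channels_are_background_and_noise_only(self, small_config):
        stack = generate_isotype_control(small_config)
        for c in MARKER_CHANNELS:
            assert stack.channel(c).mean() == pytest.approx(
                small_config.background_level[c], abs=3 * small_config.noise_sd[c]
            )

    def test_dapi_identical_to_phantom(self, small_config, small_phantom):
        phantom_stack, _, _ = small_phantom
        iso = generate_isotype_control(small_config)
        np.testing.assert_array_equal(
            iso.channel("dapi"), phantom_stack.channel("dapi")
        )

    def test_seed_determinism(self, small_config):
        a = generate_isotype_control(small_config)
        b = generate_isotype_control(small_config)
        for c in a.channels:
            np.testing.assert_array_equal(a.channel(c), b.channel(c))


class TestSingleStain:
    def test_invalid_channel_rejected(self, small_config):
        with pytest.raises(ValueError, match="channel"):
            generate_single_stain(small_config, "dapi")

    def test_identity_spillover_matches_isotype_off_target(self):
        cfg = PhantomConfig(
            width_px=512, height_px=512, spillover=np.eye(3), seed=5
        )
        ss, _ = generate_single_stain(cfg, "af488")
        iso = generate_isotype_control(cfg)
        for c in ("efluor570", "af594"):
            np.testing.assert_array_equal(ss.channel(c), iso.channel(c))

    def test_off_target_specific_component_is_spillover_fraction(self):
        # noise-free construction: off-target = background + 0.005 * source
        spill = np.eye(3) + 0.005 * (1 - np.eye(3))
        cfg = PhantomConfig(
            width_px=512,
            height_px=512,
            spillover=spill,
            noise_sd={"dapi": 0.0, "af488": 0.0, "efluor570": 0.0, "af594": 0.0},
            seed=5,
        )
        ss, _ = generate_single_stain(cfg, "af488")
        src = ss.channel("af488").astype(float) - cfg.background_level["af488"]
        for c in ("efluor570", "af594"):
            off = ss.channel(c).astype(float) - cfg.background_level[c]
            np.testing.assert_allclose(off, 0.005 * src, atol=1.0)
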