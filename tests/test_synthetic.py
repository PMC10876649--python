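"""Synthetic tissue generator: placement, rendering, study bundles."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from tilecyte.datatypes import LINING, SUBLINING, NucleusSet, RegionMask
from tilecyte.errors import PlacementInfeasibleError, UnknownCellTypeError
from tilecyte.synthetic import (
    COMPARATOR_COMPOSITION,
    FROZEN_SHOULDER_COMPOSITION,
    assign_true_types,
    comparator_config,
    frozen_shoulder_config,
    make_region_mask,
    place_nuclei,
    render_multiplex,
    simulate_sample,
    simulate_study,
)


def _all_roi(h, w, pixel_size=1.0):
    return RegionMask(np.full((h, w), SUBLINING, dtype=np.int8), pixel_size)


class TestPlaceNuclei:
    def test_zero_nuclei_gives_empty_set(self):
        assert len(place_nuclei(_all_roi(16, 16), 0, 5, seed=0)) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_hard_core_distance_holds_exactly(self, seed):
        nuclei = place_nuclei(_all_roi(64, 64), 60, min_spacing=5, seed=seed)
        assert len(nuclei) == 60
        assert pdist(nuclei.centroids).min() >= 5
        px = nuclei.pixels()
        assert _all_roi(64, 64).roi[px[:, 0], px[:, 1]].all()

    def test_reproducible_per_seed_and_distinct_across_seeds(self):
        mask = _all_roi(256, 256)
        a1 = place_nuclei(mask, 500, 6, seed=10)
        a2 = place_nuclei(mask, 500, 6, seed=10)
        b = place_nuclei(mask, 500, 6, seed=11)
        np.testing.assert_array_equal(a1.centroids, a2.centroids)
        assert not np.array_equal(a1.centroids, b.centroids)

    def test_infeasible_placement_reports_achieved_count(self):
        with pytest.raises(PlacementInfeasibleError) as err:
            place_nuclei(_all_roi(8, 8), 50, min_spacing=6, seed=0)
        assert 0 < err.value.achieved < 50
        assert "placement infeasible" in str(err.value)


class TestRenderMultiplex:
    def test_background_only_when_no_nuclei(self):
        cfg = comparator_config(
            image_height=16, image_width=16, lining_depth=4, n_nuclei=0
        )
        cfg.noise_sd = {c: 0.0 for c in cfg.channel_names}
        mask = make_region_mask(cfg)
        nuclei = NucleusSet.empty()
        truth = assign_true_types(nuclei, mask, cfg, seed=0)
        img = render_multiplex(nuclei, truth, mask, cfg, seed=0)
        assert (img.channel("DAPI").values == 0).all()
        for name in img.marker_names:
            assert (img.channel(name).values == cfg.background_level[name]).all()

    def test_single_nucleus_fills_roi_with_its_marker(self):
        cfg = comparator_config(
            image_height=16, image_width=16, lining_depth=4, n_nuclei=1
        )
        cfg.noise_sd = {c: 0.0 for c in cfg.channel_names}
        mask = make_region_mask(cfg)
        nuclei = NucleusSet(np.array([[8.0, 8.0]]))
        truth = assign_true_types(nuclei, mask, cfg, seed=0)
        truth["true_type"] = "CD31"
        img = render_multiplex(nuclei, truth, mask, cfg, seed=0)
        cd31 = img.channel("CD31").values
        expected = cfg.background_level["CD31"] + cfg.signal_mean["CD31"]["CD31"]
        assert (cd31 == expected).all()
        for other in ("CD68", "DKK3"):
            assert (
                img.channel(other).values == cfg.background_level[other]
            ).all()

    def test_channel_means_match_analytic_expectation(self):
        cfg = comparator_config(
            image_height=128, image_width=128, lining_depth=16, n_nuclei=100
        )
        cfg.noise_sd = {"DAPI": 0.0, **{c: 2.0 for c in cfg.marker_names}}
        b = simulate_sample(cfg, seed=5)
        # analytic mean per marker: background + tile-area-weighted signal
        from tilecyte.tessellate import voronoi_label

        tiles = voronoi_label(b.nuclei, b.region_mask)
        tile_area = tiles.tile_areas()
        n_px = b.region_mask.roi_area_px
        type_of = b.truth.set_index("id")["true_type"]
        for name in cfg.marker_names:
            signal = sum(
                tile_area[nid - 1] * cfg.signal_mean[type_of.loc[nid]][name]
                for nid in b.nuclei.ids
            )
            analytic = cfg.background_level[name] + signal / n_px
            se = cfg.noise_sd[name] / np.sqrt(n_px)
            observed = b.image.channel(name).values[b.region_mask.roi].mean()
            assert abs(observed - analytic) <= 3 * se

    def test_unknown_cell_type_rejected(self):
        cfg = comparator_config(
            image_height=16, image_width=16, lining_depth=4, n_nuclei=1
        )
        mask = make_region_mask(cfg)
        nuclei = NucleusSet(np.array([[8.0, 8.0]]))
        truth = assign_true_types(nuclei, mask, cfg, seed=0)
        truth["true_type"] = "NOT_A_TYPE"
        with pytest.raises(UnknownCellTypeError):
            render_multiplex(nuclei, truth, mask, cfg, seed=0)


class TestStudySimulation:
    def test_bundles_bit_identical_for_same_seed(self):
        kw = dict(image_height=64, image_width=64, lining_depth=8, n_nuclei=30,
                  min_spacing=6)
        runs = [
            simulate_study(
                comparator_config(**kw), frozen_shoulder_config(**kw), 2, seed=3
            )
            for _ in range(2)
        ]
        for b1, b2 in zip(*runs):
            np.testing.assert_array_equal(b1.image.channels, b2.image.channels)
            np.testing.assert_array_equal(b1.nuclei.centroids, b2.nuclei.centroids)
            assert b1.truth.equals(b2.truth)

    def test_sample_dkk3_fraction_within_binomial_bound(self):
        # 99% two-sided binomial interval for p=0.67 at n=1000
        cfg = comparator_config()
        b = simulate_sample(cfg, seed=21)
        frac = (b.truth["true_type"] == "DKK3").mean()
        p = COMPARATOR_COMPOSITION["DKK3"]
        half = 2.576 * np.sqrt(p * (1 - p) / len(b.truth))
        assert abs(frac - p) <= half

    def test_group_separation_in_truth_tables(self):
        kw = dict(image_height=128, image_width=128, lining_depth=16, n_nuclei=150)
        bundles = simulate_study(
            comparator_config(**kw), frozen_shoulder_config(**kw), 5, seed=9
        )
        means = {}
        for group in ("comparator", "frozen_shoulder"):
            fracs = [
                (b.truth["true_type"] == "DKK3").mean()
                for b in bundles
                if b.group == group
            ]
            means[group] = np.mean(fracs)
        assert means["comparator"] > means["frozen_shoulder"]

    def test_composition_calibrated_over_many_samples(self):
        # mean truth-label proportions within 2 pp of the configured overall
        cfg = comparator_config()
        rng = np.random.default_rng(123)
        fracs = []
        for _ in range(20):
            mask = make_region_mask(cfg)
            nuclei = place_nuclei(
                mask, cfg.n_nuclei, cfg.min_spacing, int(rng.integers(2**31))
            )
            truth = assign_true_types(nuclei, mask, cfg, int(rng.integers(2**31)))
            fracs.append(
                [
                    (truth["true_type"] == t).mean()
                    for t in ("DKK3", "CD68", "CD31")
                ]
            )
        mean = np.mean(fracs, axis=0)
        target = [COMPARATOR_COMPOSITION[t] for t in ("DKK3", "CD68", "CD31")]
        assert (np.abs(mean - target) <= 0.02).all()

    def test_lining_cd68_enrichment_in_truth(self):
        bundles = simulate_study(n_samples_per_group=2, seed=4)
        for b in bundles:
            by_region = b.truth.groupby("region")["true_type"].value_counts(
                normalize=True
            )
            assert by_region["lining"]["CD68"] > by_region["sub-lining"]["CD68"]
            assert by_region["sub-lining"]["CD31"] > by_region["lining"]["CD31"]

    def test_region_split_means_recover_overall_target(self):
        for overall, cfg in (
            (COMPARATOR_COMPOSITION, comparator_config()),
            (FROZEN_SHOULDER_COMPOSITION, frozen_shoulder_config()),
        ):
            f = cfg.lining_fraction
            for t, target in overall.items():
                mixed = (
                    f * cfg.composition_by_region["lining"][t]
                    + (1 - f) * cfg.composition_by_region["sub-lining"][t]
                )
                assert mixed == pytest.approx(target, abs=1e-12)
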