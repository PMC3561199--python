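"""Generator: determinism, ground-truth self-consistency, target realization,
and the geometric contrast between pure-PP clusters and round islets."""

import numpy as np
import pandas as pd
import pytest

import isletquant as iq
from isletquant.synthetic import TYPE_CODES


def small(**kw):
    defaults = dict(image_size=(256, 256))
    defaults.update(kw)
    return defaults


class TestDeterminismAndValidation:
    def test_same_config_bit_identical(self):
        cfg_a = iq.pp_poor_config(**small())
        cfg_b = iq.pp_poor_config(**small())
        sa, ta = iq.generate_section(cfg_a)
        sb, tb = iq.generate_section(cfg_b)
        for name in iq.CHANNELS:
            assert np.array_equal(sa.channels[name], sb.channels[name])
        assert np.array_equal(ta.label_map, tb.label_map)
        pd.testing.assert_frame_equal(ta.object_table, tb.object_table)

    def test_different_seed_differs(self):
        cfg_a = iq.pp_poor_config(**small())
        cfg_b = iq.pp_poor_config(**small())
        cfg_b.seed = 99
        _, ta = iq.generate_section(cfg_a)
        _, tb = iq.generate_section(cfg_b)
        assert not np.array_equal(ta.label_map, tb.label_map)

    @pytest.mark.parametrize(
        "mutate",
        [
            lambda c: setattr(c, "image_size", (32, 512)),
            lambda c: setattr(c, "pixel_size", 0.0),
            lambda c: c.composition_small.update({"beta": 0.9}),  # sum != 1
            lambda c: setattr(c, "singlet_fraction", 1.5),
        ],
    )
    def test_invalid_config_rejected(self, mutate):
        cfg = iq.pp_poor_config()
        mutate(cfg)
        with pytest.raises(ValueError):
            iq.generate_section(cfg)


class TestGroundTruthConsistency:
    def test_area_fractions_self_consistent(self, rich_section):
        _, truth = rich_section
        assert truth.recompute_area_fractions() == truth.true_area_fractions

    def test_every_label_has_one_row(self, rich_section):
        _, truth = rich_section
        labels = set(np.unique(truth.label_map)) - {0}
        assert labels == set(truth.object_table.object_id)
        assert truth.object_table.object_id.is_unique

    def test_object_pixel_counts_match_label_map(self, poor_section):
        _, truth = poor_section
        for _, row in truth.object_table.iterrows():
            assert (truth.label_map == row.object_id).sum() == row.area_px

    def test_composition_fractions_sum_to_one(self, rich_section):
        _, truth = rich_section
        comp = truth.object_table[[f"comp_{t}" for t in iq.CELL_TYPES]].sum(axis=1)
        assert np.allclose(comp, 1.0, atol=1e-9)


class TestTargetRealization:
    def test_rich_preset_pp_within_10pct_of_target(self, rich_section):
        """Oracle: direct pixel counting on the label/type maps."""
        _, truth = rich_section
        pp_px = int((truth.type_map == TYPE_CODES["pp"]).sum())
        realized = 100.0 * pp_px / truth.type_map.size
        assert realized == pytest.approx(truth.true_area_fractions["pp_rich"]["pp"])
        assert abs(realized - 1.2) / 1.2 < 0.10

    def test_zero_pp_target_gives_empty_pp_channel(self):
        cfg = iq.pp_poor_config(**small())
        cfg.target_area_fractions["pp_poor"] = {
            "beta": 0.5, "alpha": 0.2, "delta": 0.1, "pp": 0.0,
        }
        # no islet composition can carry PP either
        cfg.composition_small = {"beta": 0.85, "alpha": 0.1, "delta": 0.05, "pp": 0.0}
        cfg.composition_large = {"beta": 0.6, "alpha": 0.3, "delta": 0.1, "pp": 0.0}
        _, truth = iq.generate_section(cfg)
        assert (truth.type_map == TYPE_CODES["pp"]).sum() == 0
        assert truth.true_area_fractions["pp_poor"]["pp"] == 0.0

    def test_zero_density_all_singlets(self):
        cfg = iq.pp_poor_config(**small())
        cfg.islet_count_density = 0.0
        cfg.singlet_fraction = 1.0
        _, truth = iq.generate_section(cfg)
        assert len(truth.object_table) > 0
        assert (truth.object_table.kind == "singlet").all()
        cell_area = np.pi * (cfg.cell_radius_mean / cfg.pixel_size) ** 2
        assert (truth.object_table.area_px < 3 * cell_area).all()

    def test_unsatisfiable_target_raises_named_error(self):
        cfg = iq.pp_poor_config(image_size=(64, 64))
        cfg.target_area_fractions["pp_poor"] = {
            "beta": 40.0, "alpha": 0.0, "delta": 0.0, "pp": 0.0,
        }
        cfg.islet_count_density = 0.0
        with pytest.raises(iq.UnsatisfiableTargetError, match="beta"):
            iq.generate_section(cfg)


class TestRichZoneGeometry:
    def test_pp_clusters_less_circular_than_islets(self):
        """Irregular pure-PP clusters vs round islets, on truth geometry."""
        circ = {"pp_cluster": [], "islet": []}
        for seed in (1, 2, 3):
            cfg = iq.pp_rich_config()
            cfg.seed = seed
            _, truth = iq.generate_section(cfg)
            for _, row in truth.object_table.iterrows():
                if row.kind not in circ:
                    continue
                mask = truth.label_map == row.object_id
                circ[row.kind].append(iq.shape_metrics(mask).circularity)
        assert circ["pp_cluster"] and circ["islet"]
        assert np.mean(circ["pp_cluster"]) < np.mean(circ["islet"])

    def test_pure_pp_clusters_only_in_rich_zone(self, rich_section, poor_section):
        _, rich_truth = rich_section
        _, poor_truth = poor_section
        assert (rich_truth.object_table.pure_pp_cluster).any()
        assert not (poor_truth.object_table.pure_pp_cluster).any()

    def test_polygon_zone_separates_regions(self):
        cfg = iq.GeneratorConfig(
            image_size=(256, 256),
            pp_rich_zone=[(0, 0), (0, 255), (255, 255), (255, 0)],
            seed=3,
        )
        cfg.pp_rich_zone = [(0, 0), (0, 127), (255, 127), (255, 0)]
        _, truth = iq.generate_section(cfg)
        tab = truth.object_table
        assert set(tab.region) == {"pp_rich", "pp_poor"}
        for _, row in tab.iterrows():
            in_zone = truth.region_mask[int(row.centroid_row), int(row.centroid_col)]
            assert (row.region == "pp_rich") == bool(in_zone)


class TestBlockSeries:
    def test_labels_flip_at_stated_block(self):
        cfgs = iq.series_configs(10, 4, seed=0, image_size=(128, 128))
        sections = iq.generate_block_series(cfgs)
        regions = [
            "pp_rich" if truth.region_mask.all() else "pp_poor"
            for _, truth in sections
        ]
        assert regions == ["pp_rich"] * 4 + ["pp_poor"] * 6

    def test_identical_configs_identical_sections(self):
        cfg = iq.pp_poor_config(**small())
        sections = iq.generate_block_series([cfg, cfg])
        (sa, _), (sb, _) = sections
        for name in iq.CHANNELS:
            assert np.array_equal(sa.channels[name], sb.channels[name])

    def test_empty_or_single_block_rejected(self):
        with pytest.raises(ValueError):
            iq.generate_block_series([])
        with pytest.raises(ValueError):
            iq.generate_block_series([iq.pp_poor_config()])

    def test_true_pp_step_recoverable_within_one_block(self):
        """Oracle: exhaustive change-point scan on the true PP fractions."""
        cfgs = iq.series_configs(12, 5, seed=2, image_size=(256, 256))
        sections = iq.generate_block_series(cfgs)
        true_pp = []
        for _, truth in sections:
            region = "pp_rich" if truth.region_mask.all() else "pp_poor"
            true_pp.append(truth.true_area_fractions[region]["pp"])
        assert iq.detect_boundary(true_pp) in (4, 5, 6)


class TestTiles:
    def test_grid_shape_and_tags(self, poor_section):
        stack, _ = poor_section
        grid = iq.render_tiles(stack, 192, 16)
        assert (grid.n_rows, grid.n_cols) == (3, 3)
        assert len(grid.tiles) == 9
        assert {t.grid_pos for t in grid.tiles} == {(r, c) for r in range(3) for c in range(3)}

    def test_overlap_strips_are_copies(self, poor_section):
        stack, _ = poor_section
        grid = iq.render_tiles(stack, 192, 16)
        for t in grid.tiles:
            r0, c0 = t.origin
            th, tw = t.shape
            for name, arr in t.channels.items():
                assert np.array_equal(arr, stack.channels[name][r0 : r0 + th, c0 : c0 + tw])

    def test_tile_larger_than_image_gives_single_tile(self, poor_section):
        stack, _ = poor_section
        grid = iq.render_tiles(stack, 4096, 0)
        assert len(grid.tiles) == 1
        assert grid.tiles[0].shape == stack.shape

    def test_invalid_tile_parameters(self, poor_section):
        stack, _ = poor_section
        with pytest.raises(ValueError):
            iq.render_tiles(stack, 16, 16)
        with pytest.raises(ValueError):
            iq.render_tiles(stack, 64, -1)
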