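"""Aggregation to segments and blocks, and the density filters."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point

from greenview.aggregate import (
    Block,
    BufferScheme,
    aggregate_segments,
    assign_sites_to_blocks,
    delineate_blocks,
    filter_units,
)
from greenview.network import StreetSegment


class TestAggregateSegments:
    def test_closed_form_mean_and_population_sd(self):
        sites = pd.DataFrame({"segment_id": ["a", "a"], "gvi": [0.1, 0.3]})
        out = aggregate_segments(sites, {"a": 1000.0})
        row = out.iloc[0]
        assert row["mean_gvi"] == pytest.approx(0.2)
        assert row["std_gvi"] == pytest.approx(0.1)  # population sd, not n-1

    def test_single_site_zero_sd(self):
        out = aggregate_segments(
            pd.DataFrame({"segment_id": ["a"], "gvi": [0.4]}), {"a": 500.0}
        )
        assert out.iloc[0]["std_gvi"] == 0.0

    def test_sites_per_km(self):
        sites = pd.DataFrame({"segment_id": ["a"] * 13, "gvi": [0.2] * 13})
        out = aggregate_segments(sites, {"a": 1000.0})
        assert out.iloc[0]["sites_per_km"] == pytest.approx(13.0)


class TestDelineateBlocks:
    def test_square_loop_closed_form_area(self):
        loop = StreetSegment(
            "loop", LineString([(0, 0), (200, 0), (200, 200), (0, 200), (0, 0)]), 3
        )
        blocks = delineate_blocks([loop], BufferScheme({3: 5.0}))
        assert len(blocks) == 1
        assert blocks[0].area_ha == pytest.approx(3.61, abs=1e-6)  # (190 m)^2

    def test_grid_interior_block_count(self, grid_3x3):
        blocks = delineate_blocks(grid_3x3, BufferScheme({3: 5.0}))
        assert len(blocks) == 4
        for b in blocks:
            assert b.area_ha == pytest.approx(3.61, abs=1e-6)

    def test_block_ids_deterministic(self, grid_3x3):
        a = delineate_blocks(grid_3x3, BufferScheme({3: 5.0}))
        b = delineate_blocks(list(reversed(grid_3x3)), BufferScheme({3: 5.0}))
        assert [blk.block_id for blk in a] == [blk.block_id for blk in b]
        assert [blk.polygon.bounds for blk in a] == [blk.polygon.bounds for blk in b]

    def test_overwide_buffer_leaves_no_blocks(self):
        tiny = StreetSegment(
            "loop", LineString([(0, 0), (50, 0), (50, 50), (0, 50), (0, 0)]), 3
        )
        with pytest.warns(UserWarning, match="no blocks"):
            assert delineate_blocks([tiny], BufferScheme({3: 30.0})) == []

    def test_empty_network_warns(self):
        with pytest.warns(UserWarning, match="empty street network"):
            assert delineate_blocks([], BufferScheme({3: 5.0})) == []

    def test_buffer_widths_validated(self):
        with pytest.raises(ValueError):
            BufferScheme({3: 1.0})
        with pytest.raises(ValueError):
            BufferScheme({3: 31.0})

    def test_linear_scheme_spans_range(self):
        s = BufferScheme.linear([1, 2, 3, 4])
        assert s.width_for(1) == pytest.approx(30.0)  # widest for highways
        assert s.width_for(4) == pytest.approx(2.0)  # narrowest for lanes


class TestAssignSites:
    @pytest.fixture()
    def two_blocks(self, grid_3x3):
        blocks = delineate_blocks(grid_3x3, BufferScheme({3: 5.0}))
        return blocks[:2]  # B0000 at lower-left, B0001 at lower-right

    def test_nearest_assignment_oracle(self, two_blocks):
        sites = pd.DataFrame(
            {
                "x": [50.0, 60.0, 80.0, 90.0, 310.0, 350.0],
                "y": [100.0, 100.0, 100.0, 100.0, 100.0, 100.0],
                "gvi": [0.2, 0.2, 0.4, 0.4, 0.6, 0.8],
            }
        )
        blocks, assign = assign_sites_to_blocks(sites, two_blocks)
        # exhaustive nearest-distance oracle
        for i, row in sites.iterrows():
            d = [b.polygon.distance(Point(row.x, row.y)) for b in blocks]
            assert assign[i] == blocks[int(np.argmin(d))].block_id
        by_id = {b.block_id: b for b in blocks}
        assert by_id["B0000"].mean_gvi == pytest.approx(0.3)
        assert by_id["B0001"].mean_gvi == pytest.approx(0.7)

    def test_equidistant_tie_goes_to_lower_id(self, two_blocks):
        # x = 200 is the symmetry axis between the two lower blocks
        sites = pd.DataFrame({"x": [200.0], "y": [100.0], "gvi": [0.5]})
        _, assign = assign_sites_to_blocks(sites, two_blocks)
        assert assign[0] == "B0000"

    def test_single_block_takes_global_mean(self, grid_3x3, rng):
        blocks = delineate_blocks(grid_3x3, BufferScheme({3: 5.0}))[:1]
        sites = pd.DataFrame(
            {
                "x": rng.uniform(0, 400, 30),
                "y": rng.uniform(0, 400, 30),
                "gvi": rng.uniform(0, 1, 30),
            }
        )
        blocks, _ = assign_sites_to_blocks(sites, blocks)
        assert blocks[0].n_sites == 30
        assert blocks[0].mean_gvi == pytest.approx(sites["gvi"].mean())

    def test_partition_and_weighted_mean_conservation(self, grid_3x3, rng):
        """Site counts partition; count-weighted block mean = global mean."""
        blocks_all = delineate_blocks(grid_3x3, BufferScheme({3: 5.0}))
        for _ in range(10):
            n = int(rng.integers(5, 40))
            sites = pd.DataFrame(
                {
                    "x": rng.uniform(-50, 450, n),
                    "y": rng.uniform(-50, 450, n),
                    "gvi": rng.uniform(0, 1, n),
                }
            )
            blocks, _ = assign_sites_to_blocks(sites, blocks_all)
            assert sum(b.n_sites for b in blocks) == n
            weighted = sum(b.n_sites * b.mean_gvi for b in blocks if b.n_sites)
            assert weighted / n == pytest.approx(sites["gvi"].mean(), abs=1e-9)

    def test_scale_equivariance(self, grid_3x3, rng):
        k = 3.0
        scaled = [
            StreetSegment(
                s.id,
                LineString([(x * k, y * k) for x, y in s.geometry.coords]),
                s.road_class,
            )
            for s in grid_3x3
        ]
        b1 = delineate_blocks(grid_3x3, BufferScheme({3: 5.0}))
        b2 = delineate_blocks(scaled, BufferScheme({3: 5.0 * k}))
        assert len(b1) == len(b2)
        for a, b in zip(b1, b2):
            assert b.area_ha == pytest.approx(a.area_ha * k**2, rel=1e-9)


class TestFilterUnits:
    def _block(self, bid, area_ha, n_sites):
        from shapely.geometry import box

        side = np.sqrt(area_ha * 1e4)
        b = Block(bid, box(0, 0, side, side), area_ha)
        b.n_sites = n_sites
        b.sites_per_ha = n_sites / area_ha
        b.mean_gvi = 0.3
        return b

    def test_hand_computed_keep_drop_table(self):
        seg_stats = pd.DataFrame(
            {
                "segment_id": ["keep1", "drop1", "edge13", "keep2"],
                "n_sites": [3, 1, 13, 40],
                "mean_gvi": [0.3] * 4,
                "std_gvi": [0.0] * 4,
                "length_m": [148.0, 1000.0, 1000.0, 2000.0],
                "sites_per_km": [3 / 0.148, 1.0, 13.0, 20.0],
            }
        )
        blocks = [
            self._block("Bkeep", 2.0, 5),   # 2 ha, 2.5/ha -> kept
            self._block("Bsmall", 0.5, 50),  # under 1 ha -> dropped
            self._block("Bedge", 2.0, 2),   # exactly 1.0/ha -> dropped (strict)
            self._block("Bsparse", 4.0, 3),  # 0.75/ha -> dropped
        ]
        kept_seg, kept_blocks = filter_units(seg_stats, blocks)
        assert set(kept_seg["segment_id"]) == {"keep1", "keep2"}  # 13.0 is strict
        assert [b.block_id for b in kept_blocks] == ["Bkeep"]

    def test_boundary_segment_at_exactly_13_dropped(self):
        seg_stats = pd.DataFrame(
            {
                "segment_id": ["s"],
                "n_sites": [13],
                "mean_gvi": [0.3],
                "std_gvi": [0.0],
                "length_m": [1000.0],
                "sites_per_km": [13.0],
            }
        )
        kept, _ = filter_units(seg_stats, [])
        assert kept.empty
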