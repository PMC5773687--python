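import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from shapely.geometry import Polygon, box

import sdmrisk as sr
from sdmrisk.errors import GridMismatchError


def binary_map(grid, mask, species="sp", scenario_id="future"):
    return sr.BinaryRangeMap(
        layer=sr.RasterLayer(grid, "bin", np.asarray(mask, dtype=float)),
        threshold=0.5,
        species=species,
        scenario_id=scenario_id,
    )


# published range-change accounts for three invasive woody oil species
# (current km^2, then loss/gain km^2 under a low and a high emission scenario)
PUBLISHED_ROWS = [
    ("Jatropha curcas", 1_269_140, 368, 192_280, 15),
    ("Jatropha curcas", 1_269_140, 276, 278_116, 22),
    ("Aleurites moluccana", 340_768, 5_704, 117_392, 33),
    ("Aleurites moluccana", 340_768, 3_772, 175_812, 50),
    ("Ricinus communis", 1_680_620, 73_784, 393_024, 19),
    ("Ricinus communis", 1_680_620, 89_240, 561_384, 28),
]


class TestNetChangePercent:
    @pytest.mark.parametrize(
        "species,current,loss,gain,expected",
        PUBLISHED_ROWS,
        ids=[f"{r[0].split()[0]}_{r[4]}" for r in PUBLISHED_ROWS],
    )
    def test_reproduces_published_net_changes(self, species, current, loss,
                                              gain, expected):
        assert sr.net_change_percent(current, loss, gain) == expected

    def test_rounding_is_half_away_from_zero(self):
        assert sr.net_change_percent(100, 0, 15.5) == 16
        assert sr.net_change_percent(100, 15.5, 0) == -16
        assert sr.net_change_percent(100, 0, 15.4) == 15

    def test_zero_current_area_is_rejected(self):
        with pytest.raises(ValueError):
            sr.net_change_percent(0, 0, 10)


class TestSummarizeRangeChange:
    def test_identical_maps_show_no_change(self, small_grid):
        rng = np.random.default_rng(0)
        mask = rng.random(small_grid.shape) < 0.5
        cur = binary_map(small_grid, mask, scenario_id="current")
        fut = binary_map(small_grid, mask)
        rc = sr.summarize_range_change(cur, fut)
        assert rc.loss_km2 == 0 and rc.gain_km2 == 0 and rc.net_pct == 0
        assert rc.current_km2 == rc.future_km2 == rc.stable_km2

    def test_areas_match_brute_force_per_cell_tally(self):
        grid = sr.Grid.from_origin(100.0, 20.0, 0.5, 20, 20)
        rng = np.random.default_rng(3)
        cur_mask = rng.random(grid.shape) < 0.5
        fut_mask = rng.random(grid.shape) < 0.5
        rc = sr.summarize_range_change(
            binary_map(grid, cur_mask, scenario_id="current"),
            binary_map(grid, fut_mask),
        )
        loss = stable = gain = 0.0
        for r in range(grid.n_rows):
            a = sr.cell_area(grid, r)
            for c in range(grid.n_cols):
                if cur_mask[r, c] and not fut_mask[r, c]:
                    loss += a
                elif cur_mask[r, c] and fut_mask[r, c]:
                    stable += a
                elif fut_mask[r, c]:
                    gain += a
        assert rc.loss_km2 == pytest.approx(loss, rel=1e-12)
        assert rc.stable_km2 == pytest.approx(stable, rel=1e-12)
        assert rc.gain_km2 == pytest.approx(gain, rel=1e-12)

    @given(st.integers(0, 500))
    def test_mask_bookkeeping_conservation_laws(self, seed):
        grid = sr.Grid.from_origin(0.0, 0.0, 1.0, 8, 8)
        rng = np.random.default_rng(seed)
        cur_mask = rng.random(grid.shape) < rng.uniform(0.2, 0.8)
        fut_mask = rng.random(grid.shape) < rng.uniform(0.2, 0.8)
        if not cur_mask.any():
            cur_mask[0, 0] = True
        rc = sr.summarize_range_change(
            binary_map(grid, cur_mask, scenario_id="current"),
            binary_map(grid, fut_mask),
        )
        assert rc.loss_km2 + rc.stable_km2 == rc.current_km2
        assert rc.stable_km2 + rc.gain_km2 == rc.future_km2
        np.testing.assert_array_equal(rc.loss_mask | rc.stable_mask, cur_mask)
        np.testing.assert_array_equal(rc.stable_mask | rc.gain_mask, fut_mask)

    def test_grid_mismatch_is_an_error(self, small_grid):
        other = sr.Grid.from_origin(0.0, 0.0, 1.0, 6, 6)
        with pytest.raises(GridMismatchError):
            sr.summarize_range_change(
                binary_map(small_grid, np.ones(small_grid.shape),
                           scenario_id="current"),
                binary_map(other, np.ones(other.shape)),
            )

    def test_raising_threshold_never_grows_the_current_range(
        self, demo, demo_training
    ):
        ts = demo_training["training_sets"]
        records = sr.evaluate_all(ts, ["GLM", "SRE"], n_splits=2, seed=0)
        ens = sr.build_ensemble(records, ts, retention_tss_min=0.7)
        sm = sr.project(ens, demo["stacks"]["current"])
        areas = []
        for t in (0.2, 0.4, 0.6, 0.8):
            bm = sr.binarize(sm, t)
            areas.append(sr.mask_area_km2(bm.mask, sm.layer.grid))
        assert all(b <= a for a, b in zip(areas, areas[1:]))


def ray_casting_contains(poly_coords, x, y):
    """Independent even-odd ray-casting point-in-polygon test."""
    inside = False
    n = len(poly_coords)
    for i in range(n):
        x1, y1 = poly_coords[i]
        x2, y2 = poly_coords[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


class TestRasterizePA:
    def test_rectangle_covering_four_cell_centers(self, small_grid):
        # centers of cells (rows 0..1, cols 0..1) are at lon 100.5/101.5,
        # lat 25.5/24.5
        rect = box(100.1, 24.1, 101.9, 25.9)
        mask = sr.rasterize_protected_area(rect, small_grid)
        assert mask.sum() == 4
        assert mask[0, 0] and mask[0, 1] and mask[1, 0] and mask[1, 1]

    def test_agreement_with_ray_casting_oracle(self, small_grid):
        rng = np.random.default_rng(5)
        coords = [
            (100.5, 20.5), (105.5, 21.5), (104.5, 25.0), (101.5, 25.5),
        ]
        poly = Polygon(coords)
        mask = sr.rasterize_protected_area(poly, small_grid)
        lon = small_grid.lon_centers()
        lat = small_grid.lat_centers()
        for _ in range(1000):
            r = int(rng.integers(0, 6)); c = int(rng.integers(0, 6))
            assert mask[r, c] == ray_casting_contains(coords, lon[c], lat[r])

    def test_degenerate_polygon_gives_empty_mask_with_warning(self, small_grid):
        degenerate = Polygon([(100, 20), (101, 21), (100, 20)])
        with pytest.warns(UserWarning, match="degenerate"):
            mask = sr.rasterize_protected_area(degenerate, small_grid)
        assert not mask.any()

    def test_polygon_outside_extent_warns_empty(self, small_grid):
        outside = box(0, 0, 1, 1)
        with pytest.warns(UserWarning, match="no cell center"):
            mask = sr.rasterize_protected_area(outside, small_grid)
        assert not mask.any()


class TestPAThreat:
    def make_maps(self, grid, cur_cells, fut_cells):
        cur = np.zeros(grid.shape); fut = np.zeros(grid.shape)
        for rc in cur_cells:
            cur[rc] = 1
        for rc in fut_cells:
            fut[rc] = 1
        return (binary_map(grid, cur, scenario_id="current"),
                binary_map(grid, fut))

    def test_current_overlap_excludes_threat_regardless_of_future(self, small_grid):
        pa = sr.ProtectedAreaSet([
            sr.ProtectedArea("a", "A", box(100.1, 24.1, 101.9, 25.9))
        ])
        cur, fut = self.make_maps(small_grid, [(0, 0)], [(0, 0), (0, 1), (1, 1)])
        threats = sr.assess_pa_threat(cur, fut, pa)
        assert threats[0].threatened is False

    def test_new_future_overlap_flags_threat_with_summed_area(self, small_grid):
        pa = sr.ProtectedAreaSet([
            sr.ProtectedArea("a", "A", box(100.1, 24.1, 101.9, 25.9),
                             protected_species=["x"], protected_ecosystem="eco")
        ])
        fut_cells = [(0, 0), (0, 1), (1, 1)]
        cur, fut = self.make_maps(small_grid, [(5, 5)], fut_cells)
        threats = sr.assess_pa_threat(cur, fut, pa)
        t = threats[0]
        assert t.threatened is True
        expected = sum(sr.cell_area(small_grid, r) for r, _ in fut_cells)
        assert t.overlap_km2 == pytest.approx(expected, rel=1e-12)

    def test_flags_match_brute_force_overlay_on_simulated_reserves(self, demo):
        grid = demo["stacks"]["current"].grid
        pas = sr.simulate_protected_areas(grid, n=10, seed=21)
        rng = np.random.default_rng(22)
        cur_mask = rng.random(grid.shape) < 0.15
        fut_mask = rng.random(grid.shape) < 0.3
        cur = binary_map(grid, cur_mask, scenario_id="current")
        fut = binary_map(grid, fut_mask)
        threats = sr.assess_pa_threat(cur, fut, pas)
        lon = grid.lon_centers()
        lat = grid.lat_centers()
        any_threat = False
        for t, pa in zip(threats, pas.areas):
            # reserves are axis-aligned rectangles, so the brute-force
            # overlay reduces to coordinate comparisons per cell center
            x0, y0, x1, y1 = pa.geometry.bounds
            cur_hit = fut_hit = False
            for r in range(grid.n_rows):
                for c in range(grid.n_cols):
                    if x0 < lon[c] < x1 and y0 < lat[r] < y1:
                        cur_hit |= bool(cur_mask[r, c])
                        fut_hit |= bool(fut_mask[r, c])
            assert t.threatened == ((not cur_hit) and fut_hit)
            any_threat |= t.threatened
        assert any_threat  # the instance exercises the inclusion clause


class TestRiskReport:
    def threat(self, area_id, species="sp", scenario="f", threatened=True,
               plants=(), eco="", overlap=10.0):
        return sr.PAThreat(
            area_id=area_id, area_name=area_id.upper(), species=species,
            scenario_id=scenario, threatened=threatened, overlap_km2=overlap,
            affected_species=list(plants), affected_ecosystem=eco,
        )

    def change(self, species="sp", scenario="f"):
        return sr.RangeChange(
            species=species, scenario_id=scenario, current_km2=100.0,
            loss_km2=10.0, stable_km2=90.0, gain_km2=30.0, future_km2=120.0,
            net_pct=20,
        )

    def test_shared_protected_species_deduplicate(self):
        report = sr.build_risk_report(
            [
                self.threat("a", plants=["Ginkgo biloba"], eco="forest-1"),
                self.threat("b", plants=["Ginkgo biloba"], eco="forest-2"),
            ],
            [self.change()],
        )
        row = report.summary_table().iloc[0]
        assert row["n_reserves"] == 2
        assert row["n_affected_plant_species"] == 1
        assert row["n_affected_ecosystems"] == 2
        assert row["total_area_km2"] == 20.0

    def test_no_threats_gives_zero_counts(self):
        report = sr.build_risk_report(
            [self.threat("a", threatened=False, plants=["x"])], [self.change()]
        )
        row = report.summary_table().iloc[0]
        assert row["n_reserves"] == 0
        assert row["n_affected_plant_species"] == 0
        assert row["total_area_km2"] == 0.0

    def test_counts_match_set_union_oracle(self):
        rng = np.random.default_rng(30)
        vocab_sp = [f"plant_{i}" for i in range(6)]
        vocab_eco = [f"eco_{i}" for i in range(4)]
        threats = []
        for i in range(25):
            plants = list(
                rng.choice(vocab_sp, size=int(rng.integers(0, 4)), replace=False)
            )
            threats.append(
                self.threat(
                    f"pa{i}", threatened=bool(rng.random() < 0.6), plants=plants,
                    eco=str(rng.choice(vocab_eco)), overlap=float(rng.integers(1, 9)),
                )
            )
        report = sr.build_risk_report(threats, [self.change()])
        row = report.summary_table().iloc[0]
        active = [t for t in threats if t.threatened]
        plants_union = set().union(*[set(t.affected_species) for t in active])
        assert row["n_reserves"] == len(active)
        assert row["n_affected_plant_species"] == len(plants_union)
        assert row["n_affected_ecosystems"] == len(
            {t.affected_ecosystem for t in active if t.affected_ecosystem}
        )
        assert row["total_area_km2"] == pytest.approx(
            sum(t.overlap_km2 for t in active)
        )

    def test_csv_outputs_have_documented_columns(self, tmp_path):
        report = sr.build_risk_report(
            [self.threat("a", plants=["p"], eco="e")], [self.change()]
        )
        report.write(tmp_path)
        import pandas as pd

        rc = pd.read_csv(tmp_path / "rangechange.csv")
        assert list(rc.columns) == [
            "species", "scenario", "current_km2", "loss_km2", "stable_km2",
            "gain_km2", "net_pct",
        ]
        risk = pd.read_csv(tmp_path / "risk.csv")
        assert list(risk.columns) == [
            "species", "scenario", "n_reserves", "n_affected_plant_species",
            "n_affected_ecosystems", "total_area_km2",
        ]
        threats = pd.read_csv(tmp_path / "pa_threats.csv")
        assert "area_id" in threats.columns and len(threats) == 1
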