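"""Lattice geometry, contiguity weights, file round-trips, cohort summaries."""

import json

import numpy as np
import pandas as pd
import pytest

import disparity as dp
from disparity.data_model import CohortTable, CountPanel
from disparity.errors import SchemaError, ValidationError


@pytest.fixture(scope="module")
def lattice3():
    return dp.generate_lattice(dp.SimulationConfig(n_rows=3, n_cols=3, seed=5))


class TestQueenContiguity:
    def test_corner_and_center_cardinalities(self, lattice3):
        card = {rid: len(nb) for rid, nb in lattice3.neighbors.items()}
        assert card["R001001"] == 8          # center cell
        for corner in ("R000000", "R000002", "R002000", "R002002"):
            assert card[corner] == 3

    def test_s0_hand_count_3x3(self, lattice3):
        # 4 corners x 3 + 4 edges x 5 + 1 center x 8 = 40 queen adjacencies
        w = dp.build_queen_weights(lattice3)
        assert w.S0 == 40

    @pytest.mark.parametrize("rows,cols", [(3, 4), (5, 5), (4, 7)])
    def test_s0_closed_form(self, rows, cols):
        lat = dp.generate_lattice(dp.SimulationConfig(n_rows=rows, n_cols=cols, seed=1))
        w = dp.build_queen_weights(lat)
        interior = (rows - 2) * (cols - 2)
        edge = 2 * (rows - 2) + 2 * (cols - 2)
        assert w.S0 == 8 * interior + 5 * edge + 3 * 4

    def test_symmetry_and_row_standardization(self, lattice3):
        w = dp.build_queen_weights(lattice3)
        M = w.to_sparse()
        assert (M != M.T).nnz == 0
        ws = w.row_standardize()
        sums = np.asarray(ws.to_sparse().sum(axis=1)).ravel()
        np.testing.assert_allclose(sums, 1.0)

    def test_disjoint_polygons_are_islands(self):
        from shapely.geometry import Polygon
        polys = [Polygon([(0, 0), (1, 0), (1, 1), (0, 1)]),
                 Polygon([(5, 5), (6, 5), (6, 6), (5, 6)])]
        nbrs = dp.data_model.queen_neighbors(["a", "b"], polys)
        assert nbrs == {"a": set(), "b": set()}


class TestGeoJsonRoundTrip:
    def test_lossless(self, lattice3, tmp_path):
        path = tmp_path / "regions.geojson"
        dp.write_regions(lattice3, path)
        back = dp.read_regions(path)
        assert back.region_ids == lattice3.region_ids
        assert back.neighbors == lattice3.neighbors
        np.testing.assert_array_equal(back.populations, lattice3.populations)
        assert back.admin_blocks == lattice3.admin_blocks

    def test_feature_contract(self, lattice3, tmp_path):
        path = tmp_path / "regions.geojson"
        dp.write_regions(lattice3, path)
        gj = json.loads(path.read_text())
        assert gj["type"] == "FeatureCollection"
        assert all("region_id" in f["properties"] for f in gj["features"])

    def test_missing_property_named(self, tmp_path):
        bad = {"type": "FeatureCollection", "features": [{
            "type": "Feature",
            "geometry": {"type": "Polygon",
                         "coordinates": [[[0, 0], [1, 0], [1, 1], [0, 0]]]},
            "properties": {"population": 10},
        }]}
        path = tmp_path / "bad.geojson"
        path.write_text(json.dumps(bad))
        with pytest.raises(SchemaError, match="region_id"):
            dp.read_regions(path)


class TestCountPanel:
    def test_fixture_csv_round_trip(self, small_study, tmp_path):
        lattice, _, panel = small_study
        path = tmp_path / "counts.csv"
        dp.write_counts(panel, path)
        back = dp.read_counts(path, lattice)
        pd.testing.assert_frame_equal(
            back.data.reset_index(drop=True), panel.data.reset_index(drop=True),
            check_dtype=False)
        assert back.complete(lattice)

    def test_negative_count_rejected(self):
        df = pd.DataFrame({"region_id": ["a"], "year": [2013],
                           "indicator": ["death"], "count": [-1],
                           "population": [10]})
        with pytest.raises(ValidationError, match="negative count"):
            CountPanel(df)

    def test_duplicate_cell_rejected(self):
        df = pd.DataFrame({"region_id": ["a", "a"], "year": [2013, 2013],
                           "indicator": ["death", "death"], "count": [1, 2],
                           "population": [10, 10]})
        with pytest.raises(ValidationError, match="duplicate"):
            CountPanel(df)

    def test_unknown_region_rejected(self, small_study, tmp_path):
        lattice, _, panel = small_study
        df = panel.data.copy()
        df.loc[0, "region_id"] = "NOWHERE"
        path = tmp_path / "counts.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="NOWHERE"):
            dp.read_counts(path, lattice)

    def test_aggregation_sums_counts_and_populations(self):
        df = pd.DataFrame({
            "region_id": ["m1", "m2", "m3"], "year": 2013,
            "indicator": "death", "count": [1, 2, 3],
            "population": [100, 200, 300]})
        out = dp.aggregate_to_regions(CountPanel(df),
                                      {"m1": "A", "m2": "A", "m3": "B"})
        rec = out.data.set_index("region_id")
        assert rec.loc["A", "count"] == 3 and rec.loc["A", "population"] == 300
        assert rec.loc["B", "count"] == 3


class TestGal:
    def test_round_trip_with_island(self, tmp_path):
        nbrs = {"a": {"b"}, "b": {"a"}, "c": set()}
        w = dp.WeightsMatrix.from_neighbors(["a", "b", "c"], nbrs)
        path = tmp_path / "w.gal"
        dp.write_gal(w, path)
        back = dp.read_gal(path)
        assert back.ids == w.ids
        for i in range(3):
            np.testing.assert_array_equal(back.neighbor_idx[i], w.neighbor_idx[i])

    def test_header_mismatch_rejected(self, tmp_path):
        path = tmp_path / "w.gal"
        path.write_text("5\na 1\nb\nb 1\na\n")
        with pytest.raises(SchemaError, match="header"):
            dp.read_gal(path)


class TestCohortSummary:
    def test_worked_examples(self):
        """Known shares of the national RTC cohort reproduce to 2 decimals."""
        summary = dp.summarize_cohort(dp.load_rtc_cohort())
        idx = summary.set_index(["indicator", "partition", "stratum"])["share"]
        assert idx[("diagnosis", "site", "larynx")] == 29.91
        assert idx[("treatment", "site", "larynx")] == 31.16
        assert idx[("death", "sex", "male")] == 62.78
        assert idx[("death", "site", "lung_bronchus")] == 84.88

    def test_exhaustive_partition_sums_to_100(self):
        summary = dp.summarize_cohort(dp.load_rtc_cohort())
        sex = summary[summary["partition"] == "sex"]
        for _, grp in sex.groupby("indicator"):
            assert abs(grp["share"].sum() - 100.0) <= 0.02

    def test_single_stratum_is_100(self):
        table = CohortTable(
            pd.DataFrame({"indicator": ["x"], "partition": ["sex"],
                          "stratum": ["all"], "count": [7]}),
            {"x": 7})
        assert dp.summarize_cohort(table)["share"].iloc[0] == 100.00

    def test_zero_total_rejected(self):
        table = CohortTable(
            pd.DataFrame({"indicator": ["x"], "partition": ["sex"],
                          "stratum": ["all"], "count": [0]}),
            {"x": 0})
        with pytest.raises(ValidationError, match="zero total"):
            dp.summarize_cohort(table)

    def test_inconsistent_exhaustive_strata_rejected(self):
        with pytest.raises(ValidationError, match="sum to"):
            CohortTable(
                pd.DataFrame({"indicator": ["x", "x"],
                              "partition": ["sex", "sex"],
                              "stratum": ["m", "f"], "count": [3, 3]}),
                {"x": 7})
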