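"""Domain types, table round-trips, polygons, and rasters."""

import json

import numpy as np
import pytest

import ddxburden as d
from ddxburden.model import ValidationError, SchemaError


class TestDomainTypes:
    def test_ddx_is_congener_sum(self):
        conc = {c: float(i + 1) for i, c in enumerate(d.CONGENERS)}
        s = d.Slice(z_top=0, z_bottom=2, conc=conc, total_solids=0.4)
        assert s.analyte("ddx") == pytest.approx(sum(conc.values()), rel=1e-12)
        assert s.analyte("ddt") == pytest.approx(conc["ddt_24"] + conc["ddt_44"])

    def test_overlapping_slices_rejected(self):
        mk = lambda a, b: d.Slice(z_top=a, z_bottom=b, conc={}, total_solids=0.4)
        with pytest.raises(ValidationError, match="overlap"):
            d.DepthProfile([mk(0, 2), mk(2, 4), mk(2, 4)])

    def test_profile_sorted_and_gaps_allowed(self):
        mk = lambda a, b: d.Slice(z_top=a, z_bottom=b, conc={}, total_solids=0.4)
        p = d.DepthProfile([mk(6, 8), mk(0, 2)])
        assert [s.z_top for s in p] == [0, 6]

    @pytest.mark.parametrize("bad", [
        dict(z_top=-1, z_bottom=2),
        dict(z_top=2, z_bottom=2),
        dict(z_top=0, z_bottom=2, conc={"ddt_44": -5.0}),
        dict(z_top=0, z_bottom=2, total_solids=1.5),
    ])
    def test_slice_invariants(self, bad):
        kw = dict(z_top=0.0, z_bottom=2.0, conc={}, total_solids=0.4)
        kw.update(bad)
        with pytest.raises(ValidationError):
            d.Slice(**kw)

    def test_station_invariants(self):
        prof = d.DepthProfile([d.Slice(0, 2, {}, 0.4)])
        with pytest.raises(ValidationError, match="1955"):
            d.Station(id="X", x=0, y=0, water_depth=10, sampling_year=1950,
                      profile=prof)

    def test_burden_total_identity(self):
        est = d.BurdenEstimate.from_mean(36.6, 8.14e8, sigma=0, method="point")
        assert est.total == 36.6 * 8.14e8 * 1e-9


class TestStationTables:
    def test_round_trip_preserves_everything(self, tmp_path, small_basin):
        stations, _, _ = small_basin
        p1, p2, p3 = (tmp_path / f for f in
                      ("stations.csv", "slices.csv", "minicores.csv"))
        d.write_stations(stations, p1, p2, p3)
        back = d.read_stations(p1, p2, p3)
        assert len(back) == len(stations)
        for a, b in zip(stations, back):
            assert a.id == b.id
            assert a.x == b.x and a.y == b.y
            assert a.sampling_year == b.sampling_year
            assert len(a.profile) == len(b.profile)
            for sa, sb in zip(a.profile, b.profile):
                assert sa.z_top == sb.z_top and sa.z_bottom == sb.z_bottom
                for c in d.CONGENERS:
                    assert sa.conc[c] == sb.conc[c]
                assert sa.total_solids == sb.total_solids
            assert len(a.minicores) == len(b.minicores)
            for ma, mb in zip(a.minicores, b.minicores):
                assert (ma.replicate, ma.interval) == (mb.replicate, mb.interval)
                for c in d.CONGENERS:
                    assert ma.content[c] == mb.content[c]

    def test_slices_sorted_on_read(self, tmp_path):
        (tmp_path / "st.csv").write_text(
            "id,x_m,y_m,water_depth_m,sampling_year\nA,0,0,800,2023\n")
        cong = ",".join(f"{c}_ug_kg" for c in d.CONGENERS)
        rows = ["A,6,8," + ",".join("2" * 6) + ",0.4",
                "A,0,2," + ",".join("1" * 6) + ",0.4"]
        (tmp_path / "sl.csv").write_text(
            f"station_id,z_top_cm,z_bottom_cm,{cong},total_solids_frac\n"
            + "\n".join(rows) + "\n")
        (sta,) = d.read_stations(tmp_path / "st.csv", tmp_path / "sl.csv")
        assert [s.z_top for s in sta.profile] == [0.0, 6.0]

    def test_missing_column_is_schema_error(self, tmp_path):
        (tmp_path / "st.csv").write_text("id,x_m,y_m\nA,0,0\n")
        (tmp_path / "sl.csv").write_text("station_id\nA\n")
        with pytest.raises(SchemaError, match="water_depth_m"):
            d.read_stations(tmp_path / "st.csv", tmp_path / "sl.csv")

    def test_supplied_ddx_checked_not_trusted(self, tmp_path, caplog):
        (tmp_path / "st.csv").write_text(
            "id,x_m,y_m,water_depth_m,sampling_year\nA,0,0,800,2023\n")
        cong = ",".join(f"{c}_ug_kg" for c in d.CONGENERS)
        (tmp_path / "sl.csv").write_text(
            f"station_id,z_top_cm,z_bottom_cm,{cong},ddx_ug_kg,total_solids_frac\n"
            "A,0,2,1,1,1,1,1,1,999,0.4\n")
        with caplog.at_level("WARNING", logger="ddxburden"):
            (sta,) = d.read_stations(tmp_path / "st.csv", tmp_path / "sl.csv")
        assert sta.profile.slices[0].analyte("ddx") == pytest.approx(6.0)
        assert any("ddx" in r.message for r in caplog.records)

    def test_negative_concentration_rejected(self, tmp_path):
        (tmp_path / "st.csv").write_text(
            "id,x_m,y_m,water_depth_m,sampling_year\nA,0,0,800,2023\n")
        cong = ",".join(f"{c}_ug_kg" for c in d.CONGENERS)
        (tmp_path / "sl.csv").write_text(
            f"station_id,z_top_cm,z_bottom_cm,{cong},total_solids_frac\n"
            "A,0,2,1,1,-1,1,1,1,0.4\n")
        with pytest.raises(ValidationError, match="station A"):
            d.read_stations(tmp_path / "st.csv", tmp_path / "sl.csv")


class TestPolygons:
    def test_rect_area_by_shoelace(self, tmp_path):
        ring = [[0, 0], [40700, 0], [40700, 20000], [0, 20000], [0, 0]]
        gj = {"type": "Feature", "properties": {},
              "geometry": {"type": "Polygon", "coordinates": [ring]}}
        p = tmp_path / "a.geojson"
        p.write_text(json.dumps(gj))
        area = d.read_polygon(p)
        assert area.area == pytest.approx(8.14e8)  # 814 km^2

    def test_unit_square_with_hole(self, tmp_path):
        outer = [[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]]
        hole = [[0.25, 0.25], [0.25, 0.75], [0.75, 0.75], [0.75, 0.25],
                [0.25, 0.25]]
        p = tmp_path / "a.geojson"
        p.write_text(json.dumps({"type": "Polygon",
                                 "coordinates": [outer, hole]}))
        assert d.read_polygon(p).area == pytest.approx(0.75)

    def test_bowtie_rejected(self, tmp_path):
        ring = [[0, 0], [1, 1], [1, 0], [0, 1], [0, 0]]
        p = tmp_path / "a.geojson"
        p.write_text(json.dumps({"type": "Polygon", "coordinates": [ring]}))
        with pytest.raises(ValidationError, match="simple|invalid"):
            d.read_polygon(p)

    def test_local_projection_scale(self):
        # half a degree of latitude is ~55.6 km; longitude shrinks by cos(lat)
        x, y = d.local_projection(-118.0, 34.0, lon0=-118.5, lat0=33.5)
        assert y == pytest.approx(55597.5, rel=1e-3)
        assert x / y == pytest.approx(np.cos(np.radians(33.5)), rel=1e-3)


class TestRasters:
    def test_round_trip_bit_identical(self, tmp_path):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 100, (5, 7))
        vals[2, 3] = np.nan
        s = d.Surface(x_ll=1.5, y_ll=-2.25, cellsize=250.0, values=vals)
        p = tmp_path / "g.asc"
        d.write_surface(s, p)
        b = d.read_surface(p)
        assert b.x_ll == s.x_ll and b.y_ll == s.y_ll
        assert b.cellsize == s.cellsize
        ok = ~np.isnan(vals)
        assert np.array_equal(b.values[ok], vals[ok])
        assert np.isnan(b.values[2, 3])

    def test_masked_cell_written_as_nodata(self, tmp_path):
        s = d.Surface(0, 0, 1.0, np.array([[1.0, np.nan], [3.0, 4.0]]))
        p = tmp_path / "g.asc"
        d.write_surface(s, p)
        assert "-9999" in p.read_text()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            d.Surface(0, 0, 1.0, np.empty((0, 0)))
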