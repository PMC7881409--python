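"""I/O, fixture integrity and adjacency invariants."""

import json

import pytest

import spatrisk as sp
from spatrisk.data import DataFormatError, ValidationError, slugify


def _write(tmp_path, text, name="counts.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestCountsCsv:
    def test_parses_numbers_exactly_as_printed(self, tmp_path):
        p = _write(
            tmp_path,
            "area,sex,observed,expected\nE- Azerbaijan,female,376,32.96\n",
        )
        ds = sp.read_counts_csv(p)
        (r,) = ds.records
        assert r.area_id == "east_azerbaijan"
        assert r.observed == 376
        assert r.expected == 32.96

    def test_header_only_gives_empty_dataset(self, tmp_path, caplog):
        p = _write(tmp_path, "area,sex,observed,expected\n")
        with caplog.at_level("WARNING"):
            ds = sp.read_counts_csv(p)
        assert ds.records == []
        assert any("empty" in m for m in caplog.messages)

    @pytest.mark.parametrize(
        "row,err",
        [
            ("A,male,10,0", ValidationError),
            ("A,male,-3,5.0", ValidationError),
            ("A,male,ten,5.0", DataFormatError),
        ],
    )
    def test_bad_rows_are_rejected_with_location(self, tmp_path, row, err):
        p = _write(tmp_path, f"area,sex,observed,expected\n{row}\n")
        with pytest.raises(err, match="line 2"):
            sp.read_counts_csv(p)

    def test_missing_mandatory_column_named_in_error(self, tmp_path):
        p = _write(tmp_path, "area,sex,observed\nA,male,3\n")
        with pytest.raises(DataFormatError, match="expected"):
            sp.read_counts_csv(p)

    def test_round_trip_preserves_decimal_strings(self, tmp_path, table1):
        out = tmp_path / "again.csv"
        sp.write_counts_csv(table1, out)
        ds2 = sp.read_counts_csv(out)
        for a, b in zip(table1.records, ds2.records):
            assert (a.area_id, a.sex, a.observed, a.expected) == (
                b.area_id,
                b.sex,
                b.observed,
                b.expected,
            )

    def test_duplicate_area_within_sex_rejected(self, tmp_path):
        p = _write(
            tmp_path,
            "area,sex,observed,expected\nA,male,1,2.0\nA,male,2,3.0\n",
        )
        with pytest.raises(ValidationError, match="duplicate"):
            sp.read_counts_csv(p)


class TestTable1Fixture:
    def test_sixty_records_over_thirty_areas(self, table1):
        assert len(table1.records) == 60
        assert len({r.area_id for r in table1.records}) == 30

    def test_observed_totals_match_published_marginals(self, table1):
        male = sum(r.observed for r in table1.records if r.sex == "male")
        female = sum(r.observed for r in table1.records if r.sex == "female")
        assert male == 12155
        assert female == 9388
        assert male + female == 21543

    def test_anomalous_rows_kept_verbatim(self, table1):
        # transcription fidelity: values are not "corrected" even where odd
        wa = {r.sex: r for r in table1.records if r.area_id == "west_azerbaijan"}
        assert wa["female"].expected == 330.51
        assert wa["male"].expected == 63.80


class TestIranAdjacency:
    def test_structure_invariants(self, iran_adj):
        assert iran_adj.n_areas == 30
        assert iran_adj.connected
        g = iran_adj.graph()
        assert all(not g.has_edge(a, a) for a in iran_adj.areas)
        assert all(d >= 1 for d in iran_adj.neighbour_counts().values())

    def test_edge_count_matches_independent_parse(self, iran_adj):
        from importlib import resources

        raw = (
            resources.files("spatrisk.datasets") / "iran_adjacency.txt"
        ).read_text()
        pairs = {
            frozenset(line.split())
            for line in raw.splitlines()
            if line.strip() and not line.startswith("#")
        }
        assert iran_adj.n_edges == len(pairs)

    def test_areas_match_count_fixture(self, table1, iran_adj):
        assert set(iran_adj.areas) == {r.area_id for r in table1.records}


class TestReadAdjacency:
    def test_edge_list_small(self, tmp_path):
        p = _write(tmp_path, "A\tB\nB\tC\n", "adj.txt")
        adj = sp.read_adjacency(p)
        assert adj.n_areas == 3 and adj.n_edges == 2
        assert adj.neighbour_counts() == {"a": 1, "b": 2, "c": 1}

    def test_self_loop_rejected(self, tmp_path):
        p = _write(tmp_path, "A\tA\n", "adj.txt")
        with pytest.raises(ValidationError, match="self-loop"):
            sp.read_adjacency(p)

    def test_unknown_area_rejected_when_dataset_known(self, tmp_path):
        p = _write(tmp_path, "A\tB\n", "adj.txt")
        with pytest.raises(ValidationError, match="unknown"):
            sp.read_adjacency(p, areas=["a", "c"])

    def test_geojson_grid_gives_rook_adjacency(self, tmp_path):
        # 2x2 grid of unit squares: rook adjacency has exactly 4 edges
        def square(x, y):
            return [[[x, y], [x + 1, y], [x + 1, y + 1], [x, y + 1], [x, y]]]

        feats = [
            {
                "type": "Feature",
                "properties": {"area": f"s{x}{y}"},
                "geometry": {"type": "Polygon", "coordinates": square(x, y)},
            }
            for x in range(2)
            for y in range(2)
        ]
        p = tmp_path / "grid.geojson"
        p.write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
        adj = sp.read_adjacency(p)
        # independent brute-force shared-boundary check with shapely
        from shapely.geometry import box

        geoms = {f"s{x}{y}": box(x, y, x + 1, y + 1) for x in range(2) for y in range(2)}
        names = sorted(geoms)
        expect = {
            frozenset((a, b))
            for i, a in enumerate(names)
            for b in names[i + 1 :]
            if geoms[a].boundary.intersection(geoms[b].boundary).length > 0
        }
        assert adj.edges == expect
        assert adj.n_edges == 4


def test_slugify_normalizes_published_variants():
    assert slugify("E- Azerbaijan") == "east_azerbaijan"
    assert slugify("S-Khorasan") == "south_khorasan"
    assert slugify("Sistan and Baluchestan") == "sistan"
    assert slugify("Tehran ") == "tehran"


def test_dataset_adjacency_area_mismatch_rejected(chain3):
    bad_adj = sp.AdjacencyStructure.from_pairs(["A", "B", "D"], [("A", "B")])
    with pytest.raises(ValidationError, match="mismatch"):
        sp.StudyDataset(records=chain3.records, adjacency=bad_adj)
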