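"""Record model, tabular I/O, geocoding, deduplication and pruning."""

import copy

import pytest
from hypothesis import given, settings, strategies as st

from marineqc import (
    Flag,
    Gazetteer,
    OccurrenceRecord,
    RecordSet,
    dedup_records,
    geocode_records,
    prune_records,
    read_records,
    write_records,
)
from marineqc.dwc_core import duplicate_key


def _csv(tmp_path, text, name="records.csv"):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


HEADER = "id,name,decimalLongitude,decimalLatitude,year,month,day,sourceType"


class TestReadRecords:
    def test_well_formed_rows(self, tmp_path):
        p = _csv(tmp_path, HEADER + "\n"
                 "a,Zostera marina,-8.0,37.0,2001,5,4,literature\n"
                 "b,Zostera marina,-8.1,37.1,2002,,,herbaria\n"
                 "c,Fucus vesiculosus,-8.2,37.2,,,,repositories\n")
        rs = read_records(p)
        assert len(rs) == 3
        assert rs.provenance == [f"read {p.name}: 3 kept, 0 dropped"]
        assert rs.records[0].decimalLongitude == -8.0
        assert rs.records[1].month is None

    def test_out_of_range_latitude_dropped(self, tmp_path):
        p = _csv(tmp_path, HEADER + "\na,X,0.0,91.0,,,,literature\nb,X,0.0,45.0,,,,literature\n")
        rs = read_records(p)
        assert len(rs) == 1
        assert "1 dropped" in rs.provenance[0]

    @pytest.mark.parametrize("row", [
        "a,X,181.0,0.0,,,,literature",       # longitude out of range
        "a,X,0.0,0.0,2001,13,1,literature",   # month out of range
        "a,X,0.0,0.0,2001,5,32,literature",   # day out of range
        "a,X,0.0,0.0,,5,4,literature",        # month without year
        "a,X,0.0,0.0,2001,,4,literature",     # day without month
        "a,X,0.0,0.0,123,,,literature",       # not a 4-digit year
        "a,X,abc,0.0,,,,literature",          # unparseable number
        "a,X,0.0,0.0,,,,citizen-science",     # unknown source type
    ])
    def test_invariant_violations_dropped(self, tmp_path, row):
        rs = read_records(_csv(tmp_path, HEADER + "\n" + row + "\n"))
        assert len(rs) == 0

    def test_missing_file_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_records(tmp_path / "absent.csv")

    def test_missing_name_columns_fatal(self, tmp_path):
        p = _csv(tmp_path, "id,decimalLongitude\n1,0.0\n")
        with pytest.raises(ValueError, match="schema"):
            read_records(p)

    def test_flag_parsing_tristate(self, tmp_path):
        p = _csv(tmp_path,
                 "id,name,flagMachineOnLand\n"
                 "a,X,-1\n"
                 "b,X,\n")
        rs = read_records(p)
        assert rs.records[0].flag_on_land is Flag.FLAGGED
        assert rs.records[1].flag_on_land is Flag.CLEAR
        # columns absent from the header stay unevaluated
        assert rs.records[0].flag_unsuitable_light is Flag.UNEVALUATED

    def test_unicode_minus_flag(self, tmp_path):
        p = _csv(tmp_path, "id,name,flagMachineOnLand\na,X,−1\n")
        assert read_records(p).records[0].flag_on_land is Flag.FLAGGED

    def test_unknown_columns_passthrough(self, tmp_path):
        p = _csv(tmp_path, "id,name,basisOfRecord\na,X,PreservedSpecimen\n")
        rs = read_records(p)
        assert rs.records[0].extras == {"basisOfRecord": "PreservedSpecimen"}

    def test_tsv_dialect(self, tmp_path):
        p = _csv(tmp_path, "id\tname\tdecimalLongitude\na\tX\t-8.5\n", name="r.tsv")
        rs = read_records(p, delimiter="\t")
        assert rs.records[0].decimalLongitude == -8.5


class TestWriteRecords:
    def test_round_trip_identity(self, tmp_path, labelled_records):
        rs, _ = labelled_records
        path = write_records(rs, tmp_path / "out.csv")
        back = read_records(path)
        assert back.records == rs.records

    def test_round_trip_with_flags(self, tmp_path):
        recs = [
            OccurrenceRecord(id="a", name="X", flag_on_land=Flag.FLAGGED,
                             flag_unsuitable_light=Flag.CLEAR,
                             flag_outside_distribution=Flag.CLEAR),
            OccurrenceRecord(id="b", name="X", flag_on_land=Flag.CLEAR,
                             flag_unsuitable_light=Flag.CLEAR,
                             flag_outside_distribution=Flag.FLAGGED),
        ]
        path = write_records(RecordSet(records=recs), tmp_path / "f.csv")
        text = path.read_text()
        assert "flagMachineOnLand" in text
        back = read_records(path)
        assert back.records == recs

    def test_flagged_serializes_minus_one(self, tmp_path):
        rec = OccurrenceRecord(id="a", name="X", flag_on_land=Flag.FLAGGED,
                               flag_unsuitable_light=Flag.CLEAR,
                               flag_outside_distribution=Flag.CLEAR)
        path = write_records(RecordSet(records=[rec]), tmp_path / "f.csv")
        header, row = path.read_text().strip().split("\n")
        col = header.split(",").index("flagMachineOnLand")
        assert row.split(",")[col] == "-1"

    def test_pruned_writes_only_clear_records(self, tmp_path):
        def rec(i, land=Flag.CLEAR, light=Flag.CLEAR):
            return OccurrenceRecord(id=str(i), name="X", flag_on_land=land,
                                    flag_unsuitable_light=light,
                                    flag_outside_distribution=Flag.CLEAR)

        rs = RecordSet(records=[rec(1), rec(2, land=Flag.FLAGGED), rec(3),
                                rec(4, light=Flag.FLAGGED), rec(5)])
        path = write_records(rs, tmp_path / "p.csv", pruned=True)
        assert len(read_records(path)) == 3


class TestGeocode:
    @pytest.fixture()
    def gaz(self):
        return Gazetteer(entries={"faro, portugal": (-7.93, 37.02, 5000.0)})

    def test_record_with_coordinates_unchanged(self, gaz):
        r = OccurrenceRecord(id="a", name="X", decimalLongitude=1.0,
                             decimalLatitude=2.0, locality="Faro, Portugal")
        before = copy.deepcopy(r)
        rs = geocode_records(RecordSet(records=[r]), gaz)
        assert rs.records[0] == before

    def test_locality_lookup_fills_coordinates(self, gaz):
        r = OccurrenceRecord(id="a", name="X", locality="  Faro,   Portugal ")
        rs = geocode_records(RecordSet(records=[r]), gaz)
        assert rs.records[0].decimalLongitude == -7.93
        assert rs.records[0].coordinateUncertaintyInMeters == 5000.0
        assert "geocoded" in rs.records[0].recordNotes

    def test_locality_plus_country_fallback(self, gaz):
        r = OccurrenceRecord(id="a", name="X", locality="Faro", country="Portugal")
        rs = geocode_records(RecordSet(records=[r]), gaz)
        assert rs.records[0].has_coordinates()

    def test_unmatched_record_removed_with_count(self, gaz):
        r = OccurrenceRecord(id="a", name="X", locality="Atlantis")
        rs = geocode_records(RecordSet(records=[r]), gaz)
        assert len(rs) == 0
        assert "1 removed" in rs.provenance[-1]

    def test_empty_gazetteer_allowed(self):
        r = OccurrenceRecord(id="a", name="X", decimalLongitude=0.0, decimalLatitude=0.0)
        assert len(geocode_records(RecordSet(records=[r]), Gazetteer())) == 1

    def test_gazetteer_csv_round_trip(self, tmp_path, gaz):
        path = gaz.to_csv(tmp_path / "gaz.csv")
        assert Gazetteer.from_csv(path).entries == gaz.entries


def _rec(i, **kw):
    base = dict(id=str(i), name="X", acceptedAphiaID=100, decimalLongitude=1.5,
                decimalLatitude=2.5, verbatimDepth=10.0, year=2001, month=2, day=3)
    base.update(kw)
    return OccurrenceRecord(**base)


class TestDedup:
    def test_exact_duplicate_removed(self):
        rs = dedup_records(RecordSet(records=[_rec(1), _rec(2)]))
        assert [r.id for r in rs] == ["1"]  # keep-first

    def test_differing_day_both_kept(self):
        rs = dedup_records(RecordSet(records=[_rec(1), _rec(2, day=4)]))
        assert len(rs) == 2

    def test_missing_compares_equal_to_missing(self):
        rs = dedup_records(RecordSet(records=[
            _rec(1, verbatimDepth=None, day=None),
            _rec(2, verbatimDepth=None, day=None),
        ]))
        assert len(rs) == 1

    def test_depth_key_falls_back_to_min_max(self):
        a = _rec(1, verbatimDepth=None, minimumDepthInMeters=5.0, maximumDepthInMeters=8.0)
        b = _rec(2, verbatimDepth=None, minimumDepthInMeters=5.0, maximumDepthInMeters=9.0)
        assert len(dedup_records(RecordSet(records=[a, b]))) == 2

    def test_trailing_zero_insensitive(self):
        # "1.50" and "1.5" parse to the same coordinate value
        assert duplicate_key(_rec(1, decimalLongitude=float("1.50"))) == \
            duplicate_key(_rec(2, decimalLongitude=float("1.5")))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(
        st.integers(100, 103), st.sampled_from([1.0, 2.0]), st.sampled_from([3.0, 4.0]),
        st.sampled_from([2000, 2001]),
    ), max_size=20))
    def test_dedup_idempotent_and_shrinking(self, rows):
        recs = [
            OccurrenceRecord(id=str(i), name="X", acceptedAphiaID=a,
                             decimalLongitude=lon, decimalLatitude=lat, year=y)
            for i, (a, lon, lat, y) in enumerate(rows)
        ]
        once = dedup_records(RecordSet(records=recs))
        twice = dedup_records(once)
        assert twice.records == once.records
        assert len(once) <= len(recs)
        assert all(r in recs for r in once.records)


class TestPrune:
    def test_union_semantics(self):
        def rec(i, **flags):
            kw = dict(flag_on_land=Flag.CLEAR, flag_unsuitable_light=Flag.CLEAR,
                      flag_outside_distribution=Flag.CLEAR)
            kw.update(flags)
            return OccurrenceRecord(id=str(i), name="X", **kw)

        rs = RecordSet(records=[
            rec(1),
            rec(2, flag_on_land=Flag.FLAGGED, flag_unsuitable_light=Flag.FLAGGED),
            rec(3),
            rec(4, flag_outside_distribution=Flag.FLAGGED),
            rec(5),
        ])
        pruned = prune_records(rs)
        assert [r.id for r in pruned] == ["1", "3", "5"]
        n_flagged = sum(1 for r in rs if r.is_flagged())
        assert len(pruned) + n_flagged == len(rs)

    def test_no_flags_set_is_identity(self):
        recs = [OccurrenceRecord(id=str(i), name="X", flag_on_land=Flag.CLEAR,
                                 flag_unsuitable_light=Flag.CLEAR,
                                 flag_outside_distribution=Flag.CLEAR)
                for i in range(4)]
        assert prune_records(RecordSet(records=recs)).records == recs

    def test_unevaluated_flag_fatal(self):
        rs = RecordSet(records=[OccurrenceRecord(id="a", name="X")])
        with pytest.raises(ValueError, match="unevaluated"):
            prune_records(rs)


def test_duplicate_ids_rejected():
    with pytest.raises(ValueError, match="duplicate record ids"):
        RecordSet(records=[OccurrenceRecord(id="a"), OccurrenceRecord(id="a")])


def test_provenance_counts_reconcile(world, world_cfg):
    from marineqc import generate_records, run_pipeline
    rs, _ = generate_records(world, 400, seed=3, cfg=world_cfg)
    out = run_pipeline(rs, world, prune=True)
    assert out.removed_total() == len(rs) - len(out)
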