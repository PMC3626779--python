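"""Measurement ingestion, filtering rules, and genus aggregation."""

import math

import pytest

from icmolar.molar_data import (
    ExclusionRule,
    GenusMeta,
    MeasurementError,
    MolarMeasurement,
    SpecimenAreas,
    aggregate_genus,
    compute_specimen_areas,
    filter_specimens,
    read_genus_records,
    read_measurement_table,
    read_metadata_table,
    specimen_ratios,
    write_genus_records,
)

HEADER = "specimen_id,genus,tooth,length,width,source"


class TestReadMeasurementTable:
    def test_parses_one_record_per_row(self, write_csv):
        path = write_csv(
            "m.csv",
            HEADER,
            [
                ("S1", "Canis", "m1", 2.0, 1.5, "literature"),
                ("S1", "Canis", "m2", 2.2, 1.4, "literature"),
                ("S1", "Canis", "m3", 1.1, 0.9, "literature"),
            ],
        )
        records = read_measurement_table(path)
        assert len(records) == 3
        assert records[0] == MolarMeasurement("S1", "Canis", "m1", 2.0, 1.5, "literature")

    def test_unknown_tooth_label_rejected(self, write_csv):
        path = write_csv("m.csv", HEADER, [("S1", "Canis", "m4", 2.0, 1.5, "x")])
        with pytest.raises(MeasurementError, match="m4"):
            read_measurement_table(path)

    def test_blank_dimension_becomes_missing(self, write_csv):
        path = write_csv("m.csv", HEADER, [("S1", "Canis", "m1", "", 1.5, "x")])
        (rec,) = read_measurement_table(path)
        assert rec.length is None and rec.width == 1.5

    @pytest.mark.parametrize("bad", ["0", "-1.2", "nan"])
    def test_non_positive_length_names_the_row(self, write_csv, bad):
        path = write_csv("m.csv", HEADER, [("S1", "Canis", "m1", bad, 1.5, "x")])
        with pytest.raises(MeasurementError, match=r"m\.csv:2"):
            read_measurement_table(path)

    def test_duplicate_specimen_tooth_rejected(self, write_csv):
        path = write_csv(
            "m.csv",
            HEADER,
            [("S1", "Canis", "m1", 2.0, 1.5, "x"), ("S1", "Canis", "m1", 2.1, 1.5, "x")],
        )
        with pytest.raises(MeasurementError, match="duplicate"):
            read_measurement_table(path)

    def test_missing_columns_rejected(self, write_csv):
        path = write_csv("m.csv", "specimen_id,genus", [("S1", "Canis")])
        with pytest.raises(MeasurementError, match="missing required columns"):
            read_measurement_table(path)


class TestMetadataTable:
    def test_reads_flags(self, write_csv):
        path = write_csv(
            "meta.csv",
            "genus,group,diet,isolated_only,molar_count",
            [("Canis", "Carnivora", "carnivorous", "false", 3)],
        )
        meta = read_metadata_table(path)
        assert meta["Canis"] == GenusMeta("Carnivora", "carnivorous", False, 3)

    def test_unknown_diet_rejected(self, write_csv):
        path = write_csv(
            "meta.csv", "genus,group,diet", [("Canis", "Carnivora", "nectarivorous")]
        )
        with pytest.raises(MeasurementError, match="nectarivorous"):
            read_metadata_table(path)


class TestSpecimenAreas:
    def test_area_is_length_times_width(self):
        areas = compute_specimen_areas(
            [
                MolarMeasurement("S1", "Canis", "m1", 2.0, 1.5),
                MolarMeasurement("S1", "Canis", "m2", 2.0, 1.0),
                MolarMeasurement("S1", "Canis", "m3", 2.0, 1.0),
            ]
        )
        assert areas[0].a1 == 3.0 and areas[0].a2 == 2.0 and areas[0].a3 == 2.0

    def test_missing_dimension_gives_missing_area_not_length_proxy(self):
        (areas,) = compute_specimen_areas(
            [MolarMeasurement("S1", "Canis", "m3", 2.0, None)]
        )
        assert areas.a3 is None
        assert "m3" in areas.recorded


class TestFilterSpecimens:
    META = {"Canis": GenusMeta("Carnivora", "carnivorous")}

    def _areas(self, a1, a2, a3, recorded=("m1", "m2", "m3")):
        return SpecimenAreas("S1", "Canis", a1, a2, a3, frozenset(recorded))

    def test_two_adjacent_molars_suffice(self):
        kept, excluded = filter_specimens([self._areas(3.0, 3.1, None)], self.META)
        assert len(kept) == 1 and not excluded

    def test_m1_m3_only_is_not_adjacent(self):
        kept, excluded = filter_specimens([self._areas(3.0, None, 2.9)], self.META)
        assert not kept
        assert excluded[0].rule is ExclusionRule.MISSING_LENGTH_OR_WIDTH

    def test_m1_m3_with_m2_never_recorded(self):
        kept, excluded = filter_specimens(
            [self._areas(3.0, None, 2.9, recorded=("m1", "m3"))], self.META
        )
        assert excluded[0].rule is ExclusionRule.FEWER_THAN_TWO_ADJACENT

    def test_isolated_only_genus_fully_excluded(self):
        meta = {"Canis": GenusMeta("Carnivora", "carnivorous", isolated_only=True)}
        specimens = [
            SpecimenAreas(f"S{i}", "Canis", 3.0, 3.0, 3.0, frozenset()) for i in range(5)
        ]
        kept, excluded = filter_specimens(specimens, meta)
        assert not kept and len(excluded) == 5
        assert all(e.rule is ExclusionRule.ISOLATED_MOLARS_ONLY for e in excluded)

    def test_short_tooth_row_excluded(self):
        meta = {"Canis": GenusMeta("Carnivora", "carnivorous", molar_count=2)}
        kept, excluded = filter_specimens([self._areas(3.0, 3.0, None)], meta)
        assert not kept
        assert excluded[0].rule is ExclusionRule.FEWER_THAN_THREE_MOLAR_POSITIONS

    def test_unknown_genus_strict_vs_assume(self):
        with pytest.raises(MeasurementError, match="Canis"):
            filter_specimens([self._areas(3.0, 3.0, 3.0)], {})
        kept, _ = filter_specimens(
            [self._areas(3.0, 3.0, 3.0)], {}, missing_metadata="assume"
        )
        assert len(kept) == 1

    def test_kept_plus_excluded_partition_input(self):
        specimens = [
            self._areas(3.0, 3.0, 3.0),
            SpecimenAreas("S2", "Canis", 3.0, None, 2.0, frozenset({"m1", "m3"})),
        ]
        kept, excluded = filter_specimens(specimens, self.META)
        assert len(kept) + len(excluded) == len(specimens)


class TestRatios:
    def test_equal_areas(self):
        r = specimen_ratios(SpecimenAreas("S1", "g", 3.0, 3.0, 3.0))
        assert (r.r21, r.r31, r.m2_share) == (1.0, 1.0, 1.0 / 3.0)

    def test_hand_arithmetic(self):
        r = specimen_ratios(SpecimenAreas("S1", "g", 2.0, 3.0, 4.0))
        assert (r.r21, r.r31, r.r32) == (1.5, 2.0, 4.0 / 3.0)
        assert r.m2_share == pytest.approx(3.0 / 9.0)

    def test_missing_propagates(self):
        r = specimen_ratios(SpecimenAreas("S1", "g", 2.0, 3.0, None))
        assert r.r21 == 1.5 and r.r31 is None and r.m2_share is None

    def test_ratio_chain_identity(self):
        r = specimen_ratios(SpecimenAreas("S1", "g", 2.3, 3.7, 5.1))
        assert r.r31 == pytest.approx(r.r21 * r.r32, rel=1e-12)


class TestAggregateGenus:
    META = {"Canis": ("Carnivora", "carnivorous")}

    def test_mean_of_specimen_ratios(self):
        ratios = [
            specimen_ratios(SpecimenAreas("S1", "Canis", 1.0, 1.0, 1.0)),
            specimen_ratios(SpecimenAreas("S2", "Canis", 1.0, 1.2, 1.2)),
        ]
        (rec,) = aggregate_genus(ratios, self.META)
        assert rec.x == pytest.approx(1.1)
        assert rec.n_specimens == 2

    def test_genus_with_only_r21_keeps_x_but_not_y(self):
        ratios = [specimen_ratios(SpecimenAreas("S1", "Canis", 2.0, 3.0, None))]
        (rec,) = aggregate_genus(ratios, self.META)
        assert rec.x == 1.5 and rec.y is None and rec.m2_share_mean is None

    def test_single_specimen_identity(self):
        ratios = [specimen_ratios(SpecimenAreas("S1", "Canis", 2.0, 3.0, 4.0))]
        (rec,) = aggregate_genus(ratios, self.META)
        assert (rec.x, rec.y) == (1.5, 2.0)

    def test_missing_metadata_lists_genus(self):
        ratios = [specimen_ratios(SpecimenAreas("S1", "Canis", 2.0, 3.0, 4.0))]
        with pytest.raises(MeasurementError, match="Canis"):
            aggregate_genus(ratios, {})

    def test_mean_of_ratios_not_ratio_of_means(self):
        # Two specimens whose ratio-of-mean-areas differs from mean-of-ratios.
        ratios = [
            specimen_ratios(SpecimenAreas("S1", "Canis", 1.0, 2.0, 2.0)),
            specimen_ratios(SpecimenAreas("S2", "Canis", 4.0, 4.0, 4.0)),
        ]
        (rec,) = aggregate_genus(ratios, self.META)
        assert rec.x == pytest.approx(1.5)  # (2.0 + 1.0) / 2
        assert rec.x != pytest.approx(6.0 / 5.0)  # ratio of mean areas


def test_genus_records_round_trip(tmp_path):
    ratios = [
        specimen_ratios(SpecimenAreas("S1", "Canis", 2.0, 3.0, 4.0)),
        specimen_ratios(SpecimenAreas("S2", "Vulpes", 1.7, math.pi, None)),
    ]
    meta = {"Canis": ("Carnivora", "carnivorous"), "Vulpes": ("Carnivora", "carnivorous")}
    records = aggregate_genus(ratios, meta)
    path = tmp_path / "records.tsv"
    write_genus_records(records, path)
    assert read_genus_records(path) == records
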