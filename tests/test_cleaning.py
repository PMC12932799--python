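"""Tests of the six-rule occurrence filter against planted ground truth."""

import dataclasses

import pytest

import richgap as rg
from richgap.cleaning import (
    ABSENCE,
    BAD_BASIS,
    BAD_LICENSE,
    COUNTRY_MISMATCH,
    INVALID_BINOMIAL,
    OFF_CHECKLIST,
    CleaningConfig,
    MalformedRecordError,
    FilterReport,
    checklist_pairs,
    flag_record,
    read_occurrences,
    write_occurrences,
)


def make_record(**overrides):
    base = dict(
        scientific_name="Apis mellifera",
        decimal_latitude=10.0,
        decimal_longitude=5.0,
        country_code="FR",
        basis_of_record="PRESERVED_SPECIMEN",
        occurrence_status="present",
        license="CC0",
        year=2000,
        species_key="Apis mellifera",
    )
    base.update(overrides)
    return rg.OccurrenceRecord(**base)


CHECKLIST = {("Apis mellifera", "FR"), ("Apis mellifera", "DE")}


def resolver_fr(lat, lon):
    return "FR"


class TestFlagRecord:
    def test_clean_record_passes(self):
        assert flag_record(make_record(), CHECKLIST, resolver_fr) == set()

    def test_absence(self):
        rec = make_record(occurrence_status="absent")
        assert flag_record(rec, CHECKLIST, resolver_fr) == {ABSENCE}

    def test_uninomial_is_invalid(self):
        rec = make_record(scientific_name="Apis", species_key=None)
        assert flag_record(rec, CHECKLIST, resolver_fr) == {INVALID_BINOMIAL}

    def test_infraspecific_markers_are_stripped(self):
        rec = make_record(scientific_name="Apis mellifera subsp. ligustica")
        assert flag_record(rec, CHECKLIST, resolver_fr) == set()

    def test_mismatch_plus_off_checklist(self):
        rec = make_record(
            country_code="DE",
            scientific_name="Bombus terrestris",
            species_key="Bombus terrestris",
        )
        flags = flag_record(rec, CHECKLIST, resolver_fr)
        assert flags == {COUNTRY_MISMATCH, OFF_CHECKLIST}

    def test_mismatch_needs_both_coordinates_and_country(self):
        rec = make_record(country_code="DE", decimal_latitude=None,
                          scientific_name="Apis mellifera")
        assert COUNTRY_MISMATCH not in flag_record(rec, CHECKLIST, resolver_fr)

    def test_bad_basis_and_license(self):
        rec = make_record(basis_of_record="FOSSIL_SPECIMEN", license="proprietary")
        assert flag_record(rec, CHECKLIST, resolver_fr) == {BAD_BASIS, BAD_LICENSE}

    def test_missing_fields_do_not_flag(self):
        rec = make_record(
            basis_of_record=None, license=None, occurrence_status=None,
            decimal_latitude=None, decimal_longitude=None,
        )
        assert flag_record(rec, CHECKLIST, resolver_fr) == set()

    def test_malformed_latitude_raises(self):
        with pytest.raises(MalformedRecordError):
            flag_record(make_record(decimal_latitude=91.0), CHECKLIST, resolver_fr)


class TestCleanDataset:
    def test_all_clean_retains_everything(self, community, checklist_and_zero):
        checklist, zero = checklist_and_zero
        records, _ = rg.sample_occurrences(
            community, 300, rg.ContaminationSpec(), seed=1, exclude_species=zero
        )
        resolver = rg.band_resolver(community.regions)
        retained, report = rg.clean_dataset(records, checklist, resolver)
        assert len(retained) == 300
        assert report.removed == 0

    def test_planted_defects_filtered_exactly(
        self, community, checklist_and_zero, dirty_occurrences
    ):
        checklist, _ = checklist_and_zero
        records, truths = dirty_occurrences
        resolver = rg.band_resolver(community.regions)
        retained, report = rg.clean_dataset(records, checklist, resolver)
        expected_clean = [r for r, t in zip(records, truths) if not t]
        assert retained == expected_clean  # order preserved, exact set
        for rule in rg.cleaning.RULES:
            planted = sum(1 for t in truths if rule in t)
            assert report.rule_counts[rule] == planted

    def test_per_record_flags_match_planted_labels(
        self, community, checklist_and_zero, dirty_occurrences
    ):
        checklist, _ = checklist_and_zero
        pairs = checklist_pairs(checklist)
        resolver = rg.band_resolver(community.regions)
        records, truths = dirty_occurrences
        for record, truth in zip(records, truths):
            assert flag_record(record, pairs, resolver) == truth

    def test_idempotence(self, community, checklist_and_zero, dirty_occurrences):
        checklist, _ = checklist_and_zero
        resolver = rg.band_resolver(community.regions)
        records, _ = dirty_occurrences
        once, _ = rg.clean_dataset(records, checklist, resolver)
        twice, report = rg.clean_dataset(once, checklist, resolver)
        assert twice == once
        assert report.removed == 0

    def test_union_semantics_single_removal_double_tally(self):
        rec = make_record(occurrence_status="absent", license="proprietary")
        retained, report = rg.clean_dataset([rec], CHECKLIST, resolver_fr)
        assert retained == []
        assert report.removed == 1
        assert report.rule_counts[ABSENCE] == 1
        assert report.rule_counts[BAD_LICENSE] == 1

    def test_monotonicity_adding_a_record(self):
        clean = make_record()
        dirty = make_record(occurrence_status="absent")
        base, _ = rg.clean_dataset([clean], CHECKLIST, resolver_fr)
        extended, _ = rg.clean_dataset([clean, dirty], CHECKLIST, resolver_fr)
        assert set(map(id, base)) <= set(map(id, extended))

    def test_disabling_a_rule_retains_its_exclusive_flags(self):
        only_absent = make_record(occurrence_status="absent")
        config = CleaningConfig(enabled=frozenset(set(rg.cleaning.RULES) - {ABSENCE}))
        retained, _ = rg.clean_dataset([only_absent], CHECKLIST, resolver_fr, config)
        assert retained == [only_absent]

    def test_malformed_records_reported(self):
        bad = make_record(decimal_latitude=200.0)
        retained, report = rg.clean_dataset([bad, make_record()], CHECKLIST, resolver_fr)
        assert len(retained) == 1
        assert report.malformed == 1
        assert report.removed == 1

    def test_empty_input_is_zeroed_report(self):
        retained, report = rg.clean_dataset([], CHECKLIST, resolver_fr)
        assert retained == []
        assert report == FilterReport(input=0)


class TestReportAndIO:
    def test_summary_reconciles_and_roundtrips(self):
        report = FilterReport(input=100, retained=93, removed=7)
        summary = rg.summarize_flags(report)
        assert summary["removed"] == 7
        assert "7 removed" in summary["message"]
        assert FilterReport.from_json(report.to_json()) == report

    def test_zeroed_report_message(self):
        assert "0 removed" in rg.summarize_flags(FilterReport())["message"]

    def test_csv_roundtrip_lossless(self, tmp_path, dirty_occurrences):
        records, _ = dirty_occurrences
        path = tmp_path / "occ.csv"
        write_occurrences(records, path)
        back = read_occurrences(path)
        for a, b in zip(records, back):
            da, db = dataclasses.asdict(a), dataclasses.asdict(b)
            for key in da:
                if isinstance(da[key], float):
                    assert db[key] == pytest.approx(da[key])
                else:
                    assert db[key] == da[key]
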