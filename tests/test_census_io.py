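"""Census I/O: packed distribution strings, the printed per-state code
conversions, register merging, and reader row accounting."""

import pytest
from hypothesis import given, settings, strategies as st

from afa.census_io import (
    DELETE,
    REGIONS,
    RegionStatusMap,
    builtin_ruleset,
    convert_record,
    format_distribution,
    lint_rules,
    load_register,
    parse_distribution,
    read_state_census,
)
from afa.errors import InputError, ParseError, SchemaError, VocabularyError
from afa.status_vocab import InvasionStatus

S = InvasionStatus


class TestParseDistribution:
    def test_empty_string_gives_empty_map(self):
        assert parse_distribution("") == RegionStatusMap()

    def test_bare_region_token_means_native(self):
        rsm = parse_distribution("NSW, Vic (naturalised)")
        assert rsm.entries == {"NSW": S.NATIVE, "VIC": S.NATURALISED}

    def test_combined_phrase_is_condensed(self):
        rsm = parse_distribution("Qld (native and naturalised)")
        assert rsm.entries == {"QLD": S.NATIVE_COLONISING}

    def test_territories_accept_full_vocabulary(self):
        rsm = parse_distribution("LHI (doubtfully naturalised), NI")
        assert rsm.entries == {
            "LHI": S.DOUBTFULLY_NATURALISED,
            "NI": S.NATIVE,
        }

    def test_duplicate_region_condensed(self):
        rsm = parse_distribution("Tas, Tas (naturalised)")
        assert rsm.entries == {"TAS": S.NATIVE_COLONISING}

    def test_unknown_region_reported_not_dropped(self):
        rsm = parse_distribution("NSW, Atlantis (naturalised)")
        assert rsm.entries == {"NSW": S.NATIVE}
        assert rsm.unknown_regions == ["Atlantis"]

    def test_unbalanced_parenthetical_raises_with_offset(self):
        with pytest.raises(ParseError) as exc:
            parse_distribution("NSW, Vic (naturalised")
        assert exc.value.offset is not None

    def test_unknown_status_phrase_raises(self):
        with pytest.raises(VocabularyError, match="rampant"):
            parse_distribution("Vic (rampant)")

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        entries=st.dictionaries(
            st.sampled_from(REGIONS), st.sampled_from(list(S)), max_size=8
        )
    )
    def test_round_trip_identity(self, entries):
        rsm = RegionStatusMap(entries=entries)
        assert parse_distribution(format_distribution(rsm)) == rsm


# Every printed code mapping of the eight state censuses.
PRINTED_CONVERSIONS = [
    ("ACT", {"ORIGIN": ""}, S.NATIVE),
    ("ACT", {"ORIGIN": "Exotic [Aust]"}, S.INTRODUCED),
    ("ACT", {"ORIGIN": "Exotic [EA]"}, S.INTRODUCED),
    ("ACT", {"ORIGIN": "Indigenous/Exotic [Aust]"}, S.NATIVE_COLONISING),
    (
        "ACT",
        {"ORIGIN": "Exotic [Aust]", "NATURALISED STATUS": "Doubtfully"},
        S.DOUBTFULLY_NATURALISED,
    ),
    (
        "ACT",
        {"ORIGIN": "Exotic [Aust]", "NATURALISED STATUS": "Formerly"},
        S.FORMERLY_NATURALISED,
    ),
    ("NT", {"Introduced Status": "Native to NT"}, S.NATIVE),
    ("NT", {"Introduced Status": "Introduced to NT"}, S.INTRODUCED),
    ("NT", {"Introduced Status": "Status uncertain in NT"}, S.UNCERTAIN_ORIGIN),
    (
        "NT",
        {"Introduced Status": "Formerly introduced to NT extinct"},
        S.FORMERLY_INTRODUCED,
    ),
    ("NSW", {"natural/introduced": "N"}, S.NATIVE),
    ("NSW", {"natural/introduced": "N/I"}, S.NATIVE_COLONISING),
    ("NSW", {"natural/introduced": "I"}, S.INTRODUCED),
    ("QLD", {"Origin_Status": "Native to QLD"}, S.NATIVE),
    (
        "QLD",
        {"Origin_Status": "Native and naturalised in QLD"},
        S.NATIVE_COLONISING,
    ),
    ("QLD", {"Origin_Status": "Naturalised in QLD"}, S.NATURALISED),
    (
        "QLD",
        {"Origin_Status": "Doubtfully naturalised in QLD"},
        S.DOUBTFULLY_NATURALISED,
    ),
    (
        "QLD",
        {"Origin_Status": "Formerly naturalised in QLD"},
        S.FORMERLY_NATURALISED,
    ),
    ("SA", {"INTRODUCED": ""}, S.NATIVE),
    ("SA", {"INTRODUCED": "*"}, S.INTRODUCED),
    ("SA", {"NPW ACT STATUS COMMENT": "EX"}, S.PRESUMED_EXTINCT),
    (
        "SA",
        {"INTRODUCED": "*", "NPW ACT STATUS COMMENT": "Presumed Extinct"},
        S.PRESUMED_EXTINCT,
    ),
    ("TAS", {"INTRO": ""}, S.NATIVE),
    ("TAS", {"INTRO": "i"}, S.NATURALISED),
    ("TAS", {"INTRO": "?i"}, S.DOUBTFULLY_NATURALISED),
    ("TAS", {"INTRO": "", "EXTINCT": "x"}, S.PRESUMED_EXTINCT),
    ("TAS", {"INTRO": "i", "EXTINCT": "x"}, S.FORMERLY_INTRODUCED),
    ("VIC", {"establishment_means": "native"}, S.NATIVE),
    (
        "VIC",
        {"establishment_means": "native", "has_introduced_occurrences": "1"},
        S.NATIVE_COLONISING,
    ),
    ("VIC", {"establishment_means": "introduced"}, S.INTRODUCED),
    ("VIC", {"establishment_means": "uncertain"}, S.UNCERTAIN_ORIGIN),
    (
        "VIC",
        {"establishment_means": "introduced", "degree_of_establishment": "Casual"},
        S.INTRODUCED,
    ),
    (
        "VIC",
        {
            "establishment_means": "introduced",
            "degree_of_establishment": "Established",
        },
        S.NATURALISED,
    ),
    (
        "VIC",
        {
            "establishment_means": "introduced",
            "degree_of_establishment": "Reproducing",
        },
        S.NATURALISED,
    ),
    (
        "VIC",
        {"occurrenceStatus": "extinct", "establishment_means": "native"},
        S.PRESUMED_EXTINCT,
    ),
    (
        "VIC",
        {"occurrenceStatus": "extinct", "establishment_means": "uncertain"},
        S.PRESUMED_EXTINCT,
    ),
    (
        "VIC",
        {"occurrenceStatus": "extinct", "establishment_means": "introduced"},
        S.FORMERLY_INTRODUCED,
    ),
    ("WA", {"NATURALISED_STATUS": "N"}, S.NATIVE),
    ("WA", {"NATURALISED_STATUS": "M"}, S.NATIVE_COLONISING),
    ("WA", {"NATURALISED_STATUS": "A"}, S.NATURALISED),
    (
        "WA",
        {"NATURALISED_STATUS": "N", "IS_CURRENT": "N"},
        S.PRESUMED_EXTINCT,
    ),
    (
        "WA",
        {"NATURALISED_STATUS": "M", "IS_CURRENT": "N"},
        S.PRESUMED_EXTINCT,
    ),
    (
        "WA",
        {"NATURALISED_STATUS": "A", "IS_CURRENT": "N"},
        S.FORMERLY_INTRODUCED,
    ),
]


class TestConvertRecord:
    @pytest.mark.parametrize("state,row,expected", PRINTED_CONVERSIONS)
    def test_printed_code_mappings(self, state, row, expected):
        assert convert_record(row, builtin_ruleset(state)) is expected

    def test_vic_excluded_row_deleted(self):
        assert convert_record(
            {"occurrenceStatus": "excluded"}, builtin_ruleset("VIC")
        ) is DELETE

    def test_sa_extinct_detection_case_rules(self):
        rules = builtin_ruleset("SA")
        # the word is case-insensitive, the bare code case-sensitive
        assert convert_record(
            {"NPW ACT STATUS COMMENT": "EXTINCT"}, rules
        ) is S.PRESUMED_EXTINCT
        assert convert_record(
            {"NPW ACT STATUS COMMENT": "rare"}, rules
        ) is S.NATIVE

    def test_first_match_wins_is_deterministic(self):
        rules = builtin_ruleset("TAS")
        row = {"INTRO": "i", "EXTINCT": "x"}
        assert convert_record(row, rules) is S.FORMERLY_INTRODUCED

    def test_lint_reports_ordered_fallback_overlaps(self):
        # the TAS extinct rules deliberately overlap the plain INTRO rules
        pairs = lint_rules(builtin_ruleset("TAS"))
        assert (1, 2) in pairs  # x+i overlaps with plain i


class TestReaders:
    def test_row_conservation_with_deletions(self, tmp_path):
        path = tmp_path / "vic.csv"
        path.write_text(
            "scientific_name,occurrenceStatus,establishment_means,"
            "has_introduced_occurrences,degree_of_establishment\n"
            "Poa annua,present,introduced,,Established\n"
            "Poa excluda,excluded,,,\n"
            ",present,native,,\n"
        )
        records, report = read_state_census(path, builtin_ruleset("VIC"))
        assert report["rows_in"] == 3
        assert (
            report["rows_in"]
            == report["rows_out"] + report["rows_deleted"] + report["rows_errored"]
        )
        assert len(records) == 1 and records[0][1] is S.NATURALISED

    def test_missing_required_column_names_census_and_column(self, tmp_path):
        path = tmp_path / "tas.csv"
        path.write_text("scientific_name,INTRO\nPoa annua,i\n")
        with pytest.raises(SchemaError, match="EXTINCT"):
            read_state_census(path, builtin_ruleset("TAS"))


def _register_file(tmp_path, name, rows):
    path = tmp_path / name
    lines = ["taxonID,scientificName,kingdom,establishmentMeans,isInvasive"]
    lines += [",".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestLoadRegister:
    def test_kingdom_filter_and_invasive_relabel(self, tmp_path):
        files = [
            _register_file(
                tmp_path,
                "a.csv",
                [("1", "Poa annua L.", "Plantae", "introduced", "")],
            ),
            _register_file(
                tmp_path,
                "b.csv",
                [("2", "Ulex europaeus L.", "Plantae", "introduced", "invasive")],
            ),
            _register_file(
                tmp_path,
                "c.csv",
                [("3", "Vulpes vulpes", "Animalia", "introduced", "invasive")],
            ),
        ]
        records = load_register(files)
        assert len(records) == 2
        by_name = {r.canonical_name: r for r in records}
        assert by_name["Poa annua"].converted_status is S.INTRODUCED
        assert by_name["Ulex europaeus"].converted_status is S.HARMFUL_INVASIVE

    def test_duplicate_keeps_status_furthest_along_continuum(self, tmp_path):
        files = [
            _register_file(
                tmp_path,
                "a.csv",
                [("1", "Ulex europaeus L.", "Plantae", "introduced", "")],
            ),
            _register_file(
                tmp_path,
                "b.csv",
                [("2", "Ulex europaeus L.", "Plantae", "introduced", "invasive")],
            ),
        ]
        (record,) = load_register(files)
        assert record.converted_status is S.HARMFUL_INVASIVE

    def test_zero_files_rejected(self):
        with pytest.raises(InputError):
            load_register([])
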