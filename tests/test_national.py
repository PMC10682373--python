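"""National integration, register cross-referencing and assembly.

``oracle_national`` implements the six-tier precedence literally and the
implementation is checked against it exhaustively over all state mappings
of up to three states.
"""

import itertools
import random

import pytest

from afa.census_io import RegionStatusMap, RegisterRecord
from afa.errors import InputError
from afa.harmonizer import StateRecord, harmonize_state
from afa.national import assemble_afa, crossref_register, integrate_national
from afa.status_vocab import InvasionStatus, continuum_rank
from afa.taxonomy import TaxonName, build_index, resolve

S = InvasionStatus

ALIEN_ORDER = ["formerly_introduced", "formerly_naturalised",
               "doubtfully_introduced", "introduced", "doubtfully_naturalised",
               "naturalised", "harmful_invasive"]
PRESENT_ALIEN = ["doubtfully_introduced", "introduced",
                 "doubtfully_naturalised", "naturalised", "harmful_invasive"]


def oracle_national(values: list[str]) -> str:
    """Literal six-tier precedence."""
    values = [v for v in values if v not in ("absent", "deleted")]
    if "native" in values:
        return "native"
    if "native_colonising" in values:
        return "native_colonising"
    if "native_potentially_colonising" in values:
        return "native_potentially_colonising"
    if "uncertain_origin" in values:
        return "uncertain_origin"
    aliens = [v for v in values if v in PRESENT_ALIEN]
    if aliens:
        return max(aliens, key=ALIEN_ORDER.index)
    if "formerly_naturalised" in values:
        return "formerly_naturalised"
    if "formerly_introduced" in values:
        return "formerly_introduced"
    return "presumed_extinct"


ALL = [s.value for s in S]


class TestIntegrateNational:
    def test_matches_oracle_on_all_mappings_up_to_three_states(self):
        states = ["NSW", "QLD", "SA"]
        for size in (1, 2, 3):
            for combo in itertools.combinations_with_replacement(ALL, size):
                mapping = dict(zip(states, combo))
                got = integrate_national(
                    {k: S(v) for k, v in mapping.items()}
                )
                assert got.value == oracle_national(list(combo)), mapping

    @pytest.mark.parametrize(
        "mapping,expected",
        [
            ({"NSW": S.NATIVE, "VIC": S.NATURALISED}, S.NATIVE),
            ({"QLD": S.INTRODUCED, "SA": S.NATURALISED}, S.NATURALISED),
            (
                {"NT": S.NATIVE_COLONISING, "WA": S.HARMFUL_INVASIVE},
                S.NATIVE_COLONISING,
            ),
            ({"TAS": S.PRESUMED_EXTINCT}, S.PRESUMED_EXTINCT),
            (
                {"SA": S.FORMERLY_NATURALISED, "WA": S.FORMERLY_INTRODUCED},
                S.FORMERLY_NATURALISED,
            ),
        ],
    )
    def test_precedence_examples(self, mapping, expected):
        assert integrate_national(mapping) is expected

    def test_permutation_and_duplication_invariance(self):
        rng = random.Random(13)
        states = ["ACT", "NSW", "NT", "QLD", "SA", "TAS", "VIC", "WA"]
        for _ in range(100):
            n = rng.randint(1, 8)
            chosen = rng.sample(states, n)
            statuses = [S(rng.choice(ALL)) for _ in range(n)]
            mapping = dict(zip(chosen, statuses))
            base = integrate_national(mapping)
            shuffled = list(mapping.items())
            rng.shuffle(shuffled)
            assert integrate_national(dict(shuffled)) is base
            # duplicating one state's entry under a spare code changes nothing
            spare = [s for s in states if s not in mapping]
            if spare:
                dup = dict(mapping)
                dup[spare[0]] = statuses[0]
                assert integrate_national(dup) is base

    def test_empty_mapping_rejected(self):
        with pytest.raises(InputError):
            integrate_national({})

    def test_fold_mode_merges_potentially_colonising(self):
        mapping = {"NSW": S.NATIVE_POTENTIALLY_COLONISING}
        assert integrate_national(mapping) is S.NATIVE_POTENTIALLY_COLONISING
        assert integrate_national(mapping, mode="fold") is S.NATIVE_COLONISING


class TestCrossrefRegister:
    @pytest.mark.parametrize(
        "national,register,expected",
        [
            (S.NATURALISED, S.HARMFUL_INVASIVE, (S.HARMFUL_INVASIVE, "promoted")),
            (S.NATIVE, S.HARMFUL_INVASIVE, (S.NATIVE, "register_conflict")),
            (S.NATIVE, S.INTRODUCED, (S.NATIVE, "register_conflict")),
            (S.INTRODUCED, None, (S.INTRODUCED, "register_absent")),
            (S.INTRODUCED, S.INTRODUCED, (S.INTRODUCED, "agree")),
            (
                S.UNCERTAIN_ORIGIN,
                S.HARMFUL_INVASIVE,
                (S.UNCERTAIN_ORIGIN, "register_conflict"),
            ),
        ],
    )
    def test_policy(self, national, register, expected):
        assert crossref_register(national, register) == expected

    def test_promotion_monotonic_over_all_pairs(self):
        for national in S:
            for register in list(S) + [None]:
                afa, _ = crossref_register(national, register)
                if national.origin_family == afa.origin_family:
                    assert continuum_rank(afa) >= continuum_rank(national)
                else:  # cross-family can only happen via promotion
                    assert afa is S.HARMFUL_INVASIVE


def _world():
    taxa = [
        TaxonName(scientific_name="Poa multistate L.", taxon_id="t1"),
        TaxonName(scientific_name="Poa insularis Benth.", taxon_id="t2"),
        TaxonName(scientific_name="Poa invasora L.", taxon_id="t3"),
    ]
    index = build_index(taxa)
    region_maps = {
        "t1": RegionStatusMap(entries={"NSW": S.NATIVE, "VIC": S.NATURALISED}),
        "t2": RegionStatusMap(entries={"NI": S.NATURALISED}),
        "t3": RegionStatusMap(entries={"VIC": S.NATURALISED}),
    }
    return taxa, index, region_maps


def _harmonized(index, region_maps):
    state_records = {}
    for state, census in {
        "NSW": [("Poa multistate", S.NATIVE)],
        "VIC": [
            ("Poa multistate", S.NATURALISED),
            ("Poa invasora", S.NATURALISED),
            ("Poa soloensis", S.INTRODUCED),  # census-only, not in reference
        ],
    }.items():
        state_records[state], _ = harmonize_state(
            census, index, region_maps, state
        )
    return state_records


class TestAssembleAfa:
    def test_assembly_conservation_and_territory_passthrough(self):
        taxa, index, region_maps = _world()
        state_records = _harmonized(index, region_maps)
        records, report = assemble_afa(state_records, index, region_maps)
        by_id = {r.name.taxon_id: r for r in records}
        # exactly one record per accepted taxon with >= 1 region entry
        assert sorted(by_id) == ["t1", "t2", "t3"]
        t1 = by_id["t1"]
        assert t1.state_statuses == {"NSW": S.NATIVE, "VIC": S.NATURALISED}
        assert t1.national_status is S.NATIVE
        # territory-only taxon: status passes through and feeds integration
        t2 = by_id["t2"]
        assert t2.territory_statuses == {"NI": S.NATURALISED}
        assert t2.national_from_territories
        assert t2.national_status is S.NATURALISED
        # census-only taxon never reaches the national dataset
        assert all(
            r.name.canonical_name != "Poa soloensis" for r in records
        )

    def test_register_promotion_and_unmatched_report(self):
        taxa, index, region_maps = _world()
        state_records = _harmonized(index, region_maps)
        register = [
            RegisterRecord(
                scientific_name="Poa invasora L.",
                canonical_name="Poa invasora",
                kingdom="Plantae",
                raw_status="invasive",
                converted_status=S.HARMFUL_INVASIVE,
            ),
            RegisterRecord(
                scientific_name="Ignotum cryptum L.",
                canonical_name="Ignotum cryptum",
                kingdom="Plantae",
                raw_status="introduced",
                converted_status=S.INTRODUCED,
            ),
        ]
        records, report = assemble_afa(
            state_records, index, region_maps, register
        )
        by_id = {r.name.taxon_id: r for r in records}
        t3 = by_id["t3"]
        assert t3.afa_status is S.HARMFUL_INVASIVE
        assert t3.register_comparison == "promoted"
        assert t3.dwc.degree_of_establishment == "invasive"
        # native-family national status is never overridden by the register
        assert by_id["t1"].afa_status is S.NATIVE
        assert [r.scientific_name for r in report.register_unmatched] == [
            "Ignotum cryptum L."
        ]

    def test_territory_toggle_excludes_territory_only_taxa(self):
        taxa, index, region_maps = _world()
        state_records = _harmonized(index, region_maps)
        records, _ = assemble_afa(
            state_records,
            index,
            region_maps,
            include_territories_in_national=False,
        )
        assert sorted(r.name.taxon_id for r in records) == ["t1", "t3"]
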