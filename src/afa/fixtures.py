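"""Synthetic census generator with known ground truth.

Emits a complete, internally consistent set of input files — reference
census, per-state censuses in each state's native code dialect, and a
three-file introduced-species register — together with the expected
harmonized output for every taxon.  The ground truth is computed by
straight-line re-implementations of the resolution rules (literal if-chains
in this module), not by the pipeline under test, so end-to-end equality is
a meaningful check.

Taxon names are synthesized from a syllable grammar with plausible
authorship strings; statistical realism of any particular flora is a
non-goal.  The per-state censuses only use statuses their code dialect can
express, which mirrors real censuses (a presence/origin flag pair cannot
encode, say, "doubtfully naturalised" in every state).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

from .census_io import STATES, TERRITORIES
from .errors import InputError
from .status_vocab import InvasionStatus

_S = InvasionStatus

__all__ = ["FixtureSpec", "FixtureResult", "generate"]


# -- fixed generator conditions (not part of FixtureSpec) -------------------
P_REF_ONLY = 0.10  # reference state entry with no census row
P_CENSUS_ONLY_STATE = 0.05  # census row for a state the reference omits
P_TERRITORY = 0.05  # external-territory entry per territory
P_SCIENTIFIC_NAME = 0.30  # census cites the full name instead of canonical
P_INFRASPECIFIC = 0.10
P_REGISTER_INTRODUCED = 0.30  # non-invasive register record for an alien taxon
CENSUS_ONLY_TAXA_FRAC = 0.05  # extra taxa present only in state censuses


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset."""

    n_taxa: int = 200
    states: tuple[str, ...] = STATES
    p_presence: float = 0.4
    rate_synonym: float = 0.10
    rate_misapplied: float = 0.03
    rate_pro_parte: float = 0.02
    rate_status_mismatch: float = 0.05
    rate_combined_status: float = 0.003
    rate_register_invasive: float = 0.10
    seed: int = 0

    def __post_init__(self):
        self.states = tuple(s.upper() for s in self.states)
        for s in self.states:
            if s not in STATES:
                raise InputError(f"unknown state code {s!r}")
        if self.n_taxa < 1:
            raise InputError("n_taxa must be >= 1")
        for name in (
            "p_presence",
            "rate_synonym",
            "rate_misapplied",
            "rate_pro_parte",
            "rate_status_mismatch",
            "rate_combined_status",
            "rate_register_invasive",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be within [0, 1], got {v}")


@dataclass
class FixtureResult:
    """Paths and in-memory ground truth for one generated dataset."""

    outdir: Path
    reference_path: Path
    state_paths: dict[str, Path]
    register_paths: list[Path]
    truth_path: Path
    tally_path: Path
    truth: list[dict] = field(default_factory=list)
    tally: dict[str, dict[str, int]] = field(default_factory=dict)


# -- status dialects --------------------------------------------------------

# statuses each state's raw codes can express, and the encoders themselves
_EXPRESSIBLE: dict[str, tuple[InvasionStatus, ...]] = {
    "ACT": (_S.NATIVE, _S.INTRODUCED, _S.NATIVE_COLONISING,
            _S.DOUBTFULLY_NATURALISED, _S.FORMERLY_NATURALISED),
    "NT": (_S.NATIVE, _S.INTRODUCED, _S.UNCERTAIN_ORIGIN,
           _S.FORMERLY_INTRODUCED),
    "NSW": (_S.NATIVE, _S.NATIVE_COLONISING, _S.INTRODUCED),
    "QLD": (_S.NATIVE, _S.NATIVE_COLONISING, _S.NATURALISED,
            _S.DOUBTFULLY_NATURALISED, _S.FORMERLY_NATURALISED),
    "SA": (_S.NATIVE, _S.INTRODUCED, _S.PRESUMED_EXTINCT),
    "TAS": (_S.NATIVE, _S.NATURALISED, _S.DOUBTFULLY_NATURALISED,
            _S.PRESUMED_EXTINCT, _S.FORMERLY_INTRODUCED),
    "VIC": (_S.NATIVE, _S.NATIVE_COLONISING, _S.INTRODUCED, _S.NATURALISED,
            _S.UNCERTAIN_ORIGIN, _S.PRESUMED_EXTINCT, _S.FORMERLY_INTRODUCED),
    "WA": (_S.NATIVE, _S.NATIVE_COLONISING, _S.NATURALISED,
           _S.PRESUMED_EXTINCT, _S.FORMERLY_INTRODUCED),
}

_STATE_COLUMNS: dict[str, tuple[str, ...]] = {
    "ACT": ("ORIGIN", "NATURALISED STATUS"),
    "NT": ("Introduced Status",),
    "NSW": ("natural/introduced",),
    "QLD": ("Origin_Status",),
    "SA": ("INTRODUCED", "NPW ACT STATUS COMMENT"),
    "TAS": ("INTRO", "EXTINCT"),
    "VIC": ("occurrenceStatus", "establishment_means",
            "has_introduced_occurrences", "degree_of_establishment"),
    "WA": ("NATURALISED_STATUS", "IS_CURRENT"),
}

_ENCODERS: dict[str, dict[InvasionStatus, tuple[str, ...]]] = {
    "ACT": {
        _S.NATIVE: ("", ""),
        _S.INTRODUCED: ("Exotic [Aust]", ""),
        _S.NATIVE_COLONISING: ("Indigenous/Exotic [Aust]", ""),
        _S.DOUBTFULLY_NATURALISED: ("Exotic [Aust]", "Doubtfully"),
        _S.FORMERLY_NATURALISED: ("Exotic [EA]", "Formerly"),
    },
    "NT": {
        _S.NATIVE: ("Native to NT",),
        _S.INTRODUCED: ("Introduced to NT",),
        _S.UNCERTAIN_ORIGIN: ("Status uncertain in NT",),
        _S.FORMERLY_INTRODUCED: ("Formerly introduced to NT extinct",),
    },
    "NSW": {
        _S.NATIVE: ("N",),
        _S.NATIVE_COLONISING: ("N/I",),
        _S.INTRODUCED: ("I",),
    },
    "QLD": {
        _S.NATIVE: ("Native to QLD",),
        _S.NATIVE_COLONISING: ("Native and naturalised in QLD",),
        _S.NATURALISED: ("Naturalised in QLD",),
        _S.DOUBTFULLY_NATURALISED: ("Doubtfully naturalised in QLD",),
        _S.FORMERLY_NATURALISED: ("Formerly naturalised in QLD",),
    },
    "SA": {
        _S.NATIVE: ("", ""),
        _S.INTRODUCED: ("*", ""),
        _S.PRESUMED_EXTINCT: ("", "EX"),
    },
    "TAS": {
        _S.NATIVE: ("", ""),
        _S.NATURALISED: ("i", ""),
        _S.DOUBTFULLY_NATURALISED: ("?i", ""),
        _S.PRESUMED_EXTINCT: ("", "x"),
        _S.FORMERLY_INTRODUCED: ("i", "x"),
    },
    "VIC": {
        _S.NATIVE: ("present", "native", "", ""),
        _S.NATIVE_COLONISING: ("present", "native", "1", ""),
        _S.INTRODUCED: ("present", "introduced", "", "Casual"),
        _S.NATURALISED: ("present", "introduced", "", "Established"),
        _S.UNCERTAIN_ORIGIN: ("present", "uncertain", "", ""),
        _S.PRESUMED_EXTINCT: ("extinct", "native", "", ""),
        _S.FORMERLY_INTRODUCED: ("extinct", "introduced", "", ""),
    },
    "WA": {
        _S.NATIVE: ("N", "Y"),
        _S.NATIVE_COLONISING: ("M", "Y"),
        _S.NATURALISED: ("A", "Y"),
        _S.PRESUMED_EXTINCT: ("N", "N"),
        _S.FORMERLY_INTRODUCED: ("A", "N"),
    },
}

# combined within-state phrases the reference census can carry, with the
# condensed status each one means (straight-line table, kept local)
_COMBINED_PHRASES = (
    ("native and naturalised", _S.NATIVE_COLONISING),
    ("native and doubtfully naturalised", _S.NATIVE_POTENTIALLY_COLONISING),
    ("native and uncertain origin", _S.NATIVE_POTENTIALLY_COLONISING),
    ("native and naturalised and uncertain origin", _S.NATIVE_COLONISING),
)

_TERRITORY_POOL = (_S.NATIVE, _S.NATURALISED, _S.INTRODUCED)

_REGION_SPELLING = {
    "ACT": "ACT", "NSW": "NSW", "NT": "NT", "QLD": "Qld", "SA": "SA",
    "TAS": "Tas", "VIC": "Vic", "WA": "WA", "AR": "AR", "CaI": "CaI",
    "ChI": "ChI", "CoI": "CoI", "CSI": "CSI", "HI": "HI", "LHI": "LHI",
    "MDI": "MDI", "NI": "NI",
}


# -- independent ground-truth rules (literal transcriptions) ----------------

_TRUTH_ALIEN_ORDER = [
    "formerly_introduced", "formerly_naturalised", "doubtfully_introduced",
    "introduced", "doubtfully_naturalised", "naturalised", "harmful_invasive",
]
_TRUTH_NATIVE = {"native", "native_potentially_colonising", "native_colonising",
                 "presumed_extinct"}
_TRUTH_NATIVE_ORDER = ["presumed_extinct", "native",
                       "native_potentially_colonising", "native_colonising"]
_TRUTH_ABSENT = {"formerly_naturalised", "formerly_introduced",
                 "presumed_extinct", "absent", "deleted"}


def _truth_unify(a: str | None, b: str | None) -> str | None:
    """Literal transcription of the two-source resolution rule."""
    if b is None:
        return a
    if a is None:
        return b
    if a == b:
        return a
    in_native_a, in_native_b = a in _TRUTH_NATIVE, b in _TRUTH_NATIVE
    in_alien_a = a in _TRUTH_ALIEN_ORDER
    in_alien_b = b in _TRUTH_ALIEN_ORDER
    if in_native_a and in_native_b:
        return max(a, b, key=_TRUTH_NATIVE_ORDER.index)
    if in_alien_a and in_alien_b:
        return max(a, b, key=_TRUTH_ALIEN_ORDER.index)
    if a == "presumed_extinct" and b not in _TRUTH_ABSENT:
        return b
    if b == "presumed_extinct" and a not in _TRUTH_ABSENT:
        return a
    if a in _TRUTH_ABSENT and b in _TRUTH_ABSENT:
        return a if in_alien_a else b
    if a == "uncertain_origin" or b == "uncertain_origin":
        other = b if a == "uncertain_origin" else a
        if other in _TRUTH_ALIEN_ORDER:
            return other
        if other == "native":
            return "native_potentially_colonising"
        return other
    native = a if in_native_a else b
    alien = b if in_native_a else a
    if _TRUTH_ALIEN_ORDER.index(alien) >= _TRUTH_ALIEN_ORDER.index("naturalised"):
        derived = "native_colonising"
    else:
        derived = "native_potentially_colonising"
    return max(native, derived, key=_TRUTH_NATIVE_ORDER.index)


def _truth_national(statuses: list[str]) -> str:
    """Literal transcription of the six-tier national precedence."""
    statuses = [s for s in statuses if s not in ("absent", "deleted")]
    if "native" in statuses:
        return "native"
    if "native_colonising" in statuses:
        return "native_colonising"
    if "native_potentially_colonising" in statuses:
        return "native_potentially_colonising"
    if "uncertain_origin" in statuses:
        return "uncertain_origin"
    present_alien = [
        s for s in statuses
        if s in _TRUTH_ALIEN_ORDER and s not in _TRUTH_ABSENT
    ]
    if present_alien:
        return max(present_alien, key=_TRUTH_ALIEN_ORDER.index)
    if "formerly_naturalised" in statuses:
        return "formerly_naturalised"
    if "formerly_introduced" in statuses:
        return "formerly_introduced"
    return "presumed_extinct"


def _truth_crossref(national: str, register: str | None) -> tuple[str, str]:
    if register is None:
        return national, "register_absent"
    if register == national:
        return national, "agree"
    if national in _TRUTH_ALIEN_ORDER and register == "harmful_invasive":
        return "harmful_invasive", "promoted"
    return national, "register_conflict"


# -- name synthesis ---------------------------------------------------------

_SYL = ("ba", "ce", "di", "fo", "gu", "ha", "ke", "li", "mo", "nu",
        "pa", "re", "si", "to", "vu", "wa", "xe", "zi", "lor", "mun")
_EPITHET_SUFFIX = ("ensis", "ifolia", "oides", "atum", "alis", "ana")
_AUTHORS = ("L.", "Link", "Benth.", "F.Muell.", "(Labill.) R.Br.", "Hook.f.",
            "(L.) DC.", "R.Br. ex Benth.", "Mill.", "Labill.",
            "A.Cunn. ex DC.", "(Benth.) Maiden")


class _NameFactory:
    def __init__(self, rng):
        self.rng = rng
        self.seen: set[str] = set()

    def _word(self, n_syl: int) -> str:
        return "".join(self.rng.choice(_SYL) for _ in range(n_syl))

    def canonical(self, infraspecific: bool = False) -> tuple[str, str]:
        """Return (canonical_name, rank)."""
        for _ in range(1000):
            genus = self._word(self.rng.randint(2, 3)).capitalize()
            epithet = self._word(self.rng.randint(2, 3))
            if self.rng.random() < 0.5:
                epithet += self.rng.choice(_EPITHET_SUFFIX)
            name = f"{genus} {epithet}"
            rank = "species"
            if infraspecific:
                marker = self.rng.choice(("subsp.", "var."))
                name = f"{name} {marker} {self._word(2)}"
                rank = "subspecies" if marker == "subsp." else "variety"
            if name.lower() not in self.seen:
                self.seen.add(name.lower())
                return name, rank
        raise InputError("name space exhausted; lower n_taxa")

    def authorship(self) -> str:
        return self.rng.choice(_AUTHORS)


# -- generator --------------------------------------------------------------


@dataclass
class _Taxon:
    taxon_id: str
    canonical: str
    authorship: str
    rank: str
    census_name: str  # name the state censuses cite (synonym/pro-parte/...)
    resolvable: bool  # False for the ambiguous pro-parte citation
    in_reference: bool
    ref_entries: dict[str, tuple[str, str]] = field(default_factory=dict)
    # state -> (distribution cell phrase or "", condensed truth status)
    territory_entries: dict[str, str] = field(default_factory=dict)
    census_rows: dict[str, str] = field(default_factory=dict)  # state -> status

    @property
    def scientific(self) -> str:
        return f"{self.canonical} {self.authorship}".strip()


def generate(spec: FixtureSpec, outdir: str | Path) -> FixtureResult:
    """Generate one synthetic dataset plus its ground truth under outdir."""
    import random

    rng = random.Random(spec.seed)
    outdir = Path(outdir)
    (outdir / "states").mkdir(parents=True, exist_ok=True)
    (outdir / "register").mkdir(exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    names = _NameFactory(rng)
    taxa: list[_Taxon] = []
    for i in range(spec.n_taxa):
        canonical, rank = names.canonical(rng.random() < P_INFRASPECIFIC)
        taxa.append(
            _Taxon(
                taxon_id=f"apc-{i:05d}",
                canonical=canonical,
                authorship=names.authorship(),
                rank=rank,
                census_name=canonical,
                resolvable=True,
                in_reference=True,
            )
        )

    # presence, reference statuses, census statuses
    for taxon in taxa:
        for state in spec.states:
            if rng.random() >= spec.p_presence:
                # census-only state entry (taxon is in the reference, but its
                # distribution string omits this state)
                if rng.random() < P_CENSUS_ONLY_STATE:
                    taxon.census_rows[state] = rng.choice(
                        _EXPRESSIBLE[state]
                    ).value
                continue
            if rng.random() < spec.rate_combined_status:
                phrase, condensed = _COMBINED_PHRASES[
                    rng.randrange(len(_COMBINED_PHRASES))
                ]
                taxon.ref_entries[state] = (phrase, condensed.value)
            else:
                status = rng.choice(_EXPRESSIBLE[state])
                phrase = "" if status is _S.NATIVE else status.phrase
                taxon.ref_entries[state] = (phrase, status.value)
            if rng.random() < P_REF_ONLY:
                continue  # reference-only: no census row
            ref_status = taxon.ref_entries[state][1]
            expressible = [s.value for s in _EXPRESSIBLE[state]]
            if ref_status in expressible and (
                rng.random() >= spec.rate_status_mismatch
            ):
                taxon.census_rows[state] = ref_status
            else:
                pool = [s for s in expressible if s != ref_status]
                taxon.census_rows[state] = rng.choice(pool)
        for territory in TERRITORIES:
            if rng.random() < P_TERRITORY:
                taxon.territory_entries[territory] = rng.choice(
                    _TERRITORY_POOL
                ).value
        if not taxon.ref_entries and not taxon.territory_entries and (
            not taxon.census_rows
        ):
            # keep every taxon observable somewhere (same mismatch logic as
            # sampled entries, native on the reference side)
            state = sorted(spec.states)[0] if spec.states else None
            if state is not None:
                taxon.ref_entries[state] = ("", _S.NATIVE.value)
                if rng.random() >= spec.rate_status_mismatch:
                    taxon.census_rows[state] = _S.NATIVE.value
                else:
                    pool = [
                        s.value for s in _EXPRESSIBLE[state]
                        if s is not _S.NATIVE
                    ]
                    taxon.census_rows[state] = rng.choice(pool)

    # extra rows in the reference: synonyms, misapplications, pro-parte
    extra_reference_rows: list[dict] = []
    serial = spec.n_taxa
    for taxon in taxa:
        r = rng.random()
        if r < spec.rate_synonym:
            status = "synonym"
        elif r < spec.rate_synonym + spec.rate_misapplied:
            status = "misapplied"
        else:
            continue
        alt, _ = names.canonical()
        extra_reference_rows.append(
            {
                "taxon_id": f"apc-{serial:05d}",
                "canonical": alt,
                "authorship": names.authorship(),
                "rank": "species",
                "taxon_status": status,
                "accepted_id": taxon.taxon_id,
            }
        )
        taxon.census_name = alt
        serial += 1
    if spec.rate_pro_parte > 0 and spec.n_taxa >= 3:
        # always both pro-parte cases: one unique, one ambiguous
        unique_target, ambig_a, ambig_b = taxa[0], taxa[1], taxa[2]
        pp_name, _ = names.canonical()
        extra_reference_rows.append(
            {
                "taxon_id": f"apc-{serial:05d}",
                "canonical": pp_name,
                "authorship": names.authorship(),
                "rank": "species",
                "taxon_status": "pro_parte",
                "accepted_id": unique_target.taxon_id,
            }
        )
        unique_target.census_name = pp_name
        serial += 1
        ambig_name, _ = names.canonical()
        for target, status in (
            (ambig_a, "pro_parte"),
            (ambig_b, "pro_parte_misapplied"),
        ):
            extra_reference_rows.append(
                {
                    "taxon_id": f"apc-{serial:05d}",
                    "canonical": ambig_name,
                    "authorship": names.authorship(),
                    "rank": "species",
                    "taxon_status": status,
                    "accepted_id": target.taxon_id,
                }
            )
            serial += 1
        ambig_a.census_name = ambig_name
        ambig_a.resolvable = False

    # taxa present only in state censuses (never in the reference)
    n_extra = round(spec.n_taxa * CENSUS_ONLY_TAXA_FRAC)
    for i in range(n_extra):
        canonical, rank = names.canonical()
        taxon = _Taxon(
            taxon_id=f"extra-{i:05d}",
            canonical=canonical,
            authorship=names.authorship(),
            rank=rank,
            census_name=canonical,
            resolvable=False,
            in_reference=False,
        )
        if spec.states:
            for state in rng.sample(
                sorted(spec.states), k=min(2, len(spec.states))
            ):
                taxon.census_rows[state] = rng.choice(_EXPRESSIBLE[state]).value
        taxa.append(taxon)

    # ---- write the reference census --------------------------------------
    ref_rows = []
    for taxon in taxa:
        if not taxon.in_reference:
            continue
        parts = []
        for state in STATES:
            if state in taxon.ref_entries:
                phrase = taxon.ref_entries[state][0]
                tok = _REGION_SPELLING[state]
                parts.append(f"{tok} ({phrase})" if phrase else tok)
        for territory in TERRITORIES:
            if territory in taxon.territory_entries:
                status = taxon.territory_entries[territory]
                tok = _REGION_SPELLING[territory]
                if status == "native":
                    parts.append(tok)
                else:
                    parts.append(f"{tok} ({status.replace('_', ' ')})")
        ref_rows.append(
            {
                "taxon_id": taxon.taxon_id,
                "scientific_name": taxon.scientific,
                "canonical_name": taxon.canonical,
                "authorship": taxon.authorship,
                "rank": taxon.rank,
                "taxon_status": "accepted",
                "accepted_id": "",
                "distribution": ", ".join(parts),
            }
        )
    for row in extra_reference_rows:
        ref_rows.append(
            {
                "taxon_id": row["taxon_id"],
                "scientific_name": f"{row['canonical']} {row['authorship']}",
                "canonical_name": row["canonical"],
                "authorship": row["authorship"],
                "rank": row["rank"],
                "taxon_status": row["taxon_status"],
                "accepted_id": row["accepted_id"],
                "distribution": "",
            }
        )
    reference_path = outdir / "reference.csv"
    pd.DataFrame(ref_rows).to_csv(reference_path, index=False, lineterminator="\n")

    # ---- write the state censuses -----------------------------------------
    state_paths: dict[str, Path] = {}
    for state in sorted(spec.states):
        rows = []
        for taxon in taxa:
            if state not in taxon.census_rows:
                continue
            status = InvasionStatus(taxon.census_rows[state])
            codes = _ENCODERS[state][status]
            name = taxon.census_name
            if rng.random() < P_SCIENTIFIC_NAME and taxon.census_name == (
                taxon.canonical
            ):
                name = taxon.scientific
            row = {"scientific_name": name}
            row.update(dict(zip(_STATE_COLUMNS[state], codes)))
            rows.append(row)
        rows.sort(key=lambda r: r["scientific_name"])
        path = outdir / "states" / f"{state}.csv"
        pd.DataFrame(
            rows, columns=("scientific_name",) + _STATE_COLUMNS[state]
        ).to_csv(path, index=False, lineterminator="\n")
        state_paths[state] = path

    # ---- ground truth ------------------------------------------------------
    truth_rows: list[dict] = []
    tally: dict[str, dict[str, int]] = {
        state: {
            "agree": 0, "status_mismatch": 0, "census_only": 0,
            "reference_only": 0, "name_unresolved": 0,
        }
        for state in sorted(spec.states)
    }
    register_candidates: list[tuple[_Taxon, str]] = []
    for taxon in taxa:
        unified: dict[str, str] = {}
        for state in sorted(spec.states):
            ref_status = (
                taxon.ref_entries[state][1]
                if (taxon.in_reference and state in taxon.ref_entries)
                else None
            )
            census_status = taxon.census_rows.get(state)
            if census_status is not None and not taxon.resolvable:
                tally[state]["name_unresolved"] += 1
                census_status = None  # an unresolved citation carries nothing
            if census_status is None and ref_status is None:
                continue
            if census_status is None:
                tally[state]["reference_only"] += 1
                unified[state] = ref_status
            elif ref_status is None:
                tally[state]["census_only"] += 1
                unified[state] = census_status
            else:
                if census_status == ref_status:
                    tally[state]["agree"] += 1
                else:
                    tally[state]["status_mismatch"] += 1
                unified[state] = _truth_unify(census_status, ref_status)
        if not taxon.in_reference:
            continue  # never reaches the national dataset
        territory_statuses = dict(sorted(taxon.territory_entries.items()))
        if not unified and not territory_statuses:
            continue
        if unified:
            national = _truth_national(list(unified.values()))
            from_territories = False
        else:
            national = _truth_national(list(territory_statuses.values()))
            from_territories = True
        register_status: str | None = None
        if national in _TRUTH_ALIEN_ORDER:
            if rng.random() < spec.rate_register_invasive:
                register_status = "harmful_invasive"
            elif rng.random() < P_REGISTER_INTRODUCED:
                register_status = "introduced"
        if register_status is not None:
            register_candidates.append((taxon, register_status))
        afa_status, register_comparison = _truth_crossref(
            national, register_status
        )
        row = {
            "taxon_id": taxon.taxon_id,
            "canonical_name": taxon.canonical,
            "national_status": national,
            "register_status": register_status or "",
            "register_comparison": register_comparison,
            "afa_status": afa_status,
            "national_from_territories": from_territories,
        }
        for state in sorted(spec.states):
            row[f"unified_{state}"] = unified.get(state, "")
        truth_rows.append(row)

    truth_path = outdir / "truth" / "afa_truth.csv"
    pd.DataFrame(truth_rows).to_csv(truth_path, index=False, lineterminator="\n")
    tally_path = outdir / "truth" / "state_tally.csv"
    tally_df = pd.DataFrame(
        [{"state": s, **counts} for s, counts in sorted(tally.items())]
    )
    tally_df.to_csv(tally_path, index=False, lineterminator="\n")

    # ---- write the register (three files, GRIIS-shaped) --------------------
    register_files: list[list[dict]] = [[], [], []]
    for i, (taxon, status) in enumerate(register_candidates):
        entry = {
            "taxonID": f"reg-{i:05d}",
            "scientificName": taxon.scientific,
            "kingdom": "Plantae",
            "establishmentMeans": "introduced",
            "isInvasive": "invasive" if status == "harmful_invasive" else "",
        }
        register_files[i % 3].append(entry)
        if status == "harmful_invasive" and rng.random() < 0.2:
            # duplicate listing with the weaker status in another file;
            # deduplication must keep the stronger one
            register_files[(i + 1) % 3].append(
                {**entry, "taxonID": f"reg-{i:05d}b", "isInvasive": ""}
            )
    # records the register carries but the reference cannot match
    register_files[0].append(
        {
            "taxonID": "reg-x0001",
            "scientificName": "Ignotum nullius L.",
            "kingdom": "Plantae",
            "establishmentMeans": "introduced",
            "isInvasive": "",
        }
    )
    register_files[1].append(
        {
            "taxonID": "reg-x0002",
            "scientificName": "Vulpes vulpes (Linnaeus, 1758)",
            "kingdom": "Animalia",
            "establishmentMeans": "introduced",
            "isInvasive": "invasive",
        }
    )
    register_paths = []
    for i, rows in enumerate(register_files, start=1):
        path = outdir / "register" / f"griis_{i}.csv"
        pd.DataFrame(
            rows,
            columns=(
                "taxonID", "scientificName", "kingdom",
                "establishmentMeans", "isInvasive",
            ),
        ).to_csv(path, index=False, lineterminator="\n")
        register_paths.append(path)

    manifest = {"spec": asdict(spec), "format": 1}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    return FixtureResult(
        outdir=outdir,
        reference_path=reference_path,
        state_paths=state_paths,
        register_paths=register_paths,
        truth_path=truth_path,
        tally_path=tally_path,
        truth=truth_rows,
        tally=tally,
    )
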