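"""Canonical-name handling and resolution against the reference taxonomy.

The reference census carries accepted names, synonyms, misapplications and
pro-parte names.  Jurisdictional censuses cite taxa by scientific or
canonical name, so every census name must be resolved to the accepted
reference taxon before statuses can be compared.  Matching is exact (no
fuzzy matching), case-insensitive on canonical names because census
capitalisation varies, with hybrid signs normalised to one glyph.

A pro-parte (or pro-parte misapplied) name can point at several accepted
taxa at once.  If exactly one accepted taxon is reachable the record is
kept (``pro_parte_unique``); with two or more it is impossible to tell
which taxon the census meant (``pro_parte_ambiguous``) and the record is
excluded from unified outputs, surviving only in the mismatch report.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .errors import InputError

log = logging.getLogger(__name__)

__all__ = [
    "TaxonName",
    "NameResolution",
    "NameIndex",
    "canonicalize",
    "build_index",
    "resolve",
    "load_backbone_map",
]

ACCEPTED = "accepted"
SYNONYM = "synonym"
MISAPPLIED = "misapplied"
PRO_PARTE = "pro_parte"
PRO_PARTE_MISAPPLIED = "pro_parte_misapplied"
EXCLUDED = "excluded"

TAXON_STATUSES = (
    ACCEPTED,
    SYNONYM,
    MISAPPLIED,
    PRO_PARTE,
    PRO_PARTE_MISAPPLIED,
    EXCLUDED,
)

# Infraspecific rank markers kept in the canonical name.  "f." doubles as an
# author abbreviation (e.g. Hook.f.); it counts as a rank marker only when
# followed by a lowercase epithet.
_RANK_MARKERS = {"subsp.", "ssp.", "var.", "subvar.", "f.", "forma", "nothosubsp."}
_EPITHET_RE = re.compile(r"^[a-z][a-z\-]*$")


@dataclass(frozen=True)
class TaxonName:
    """One name row of a census (reference or jurisdictional)."""

    scientific_name: str
    canonical_name: str = ""
    authorship: str = ""
    rank: str = "species"
    taxon_status: str = ACCEPTED
    accepted_id: str = ""
    taxon_id: str = ""

    def __post_init__(self):
        if not self.scientific_name.strip():
            raise InputError("TaxonName: empty scientific name")
        if not self.canonical_name:
            canonical, authorship = canonicalize(self.scientific_name)
            object.__setattr__(self, "canonical_name", canonical)
            if not self.authorship:
                object.__setattr__(self, "authorship", authorship)
        if self.taxon_status == ACCEPTED and self.accepted_id == self.taxon_id:
            object.__setattr__(self, "accepted_id", "")


@dataclass(frozen=True)
class NameResolution:
    """Outcome of resolving one census name against the reference."""

    query: TaxonName
    outcome: str  # accepted_direct | via_synonym | via_misapplication |
    #               pro_parte_unique | pro_parte_ambiguous | excluded | unmatched
    accepted: TaxonName | None = None
    candidates: tuple[TaxonName, ...] = ()

    def __post_init__(self):
        if self.outcome == "pro_parte_ambiguous":
            assert self.accepted is None and len(self.candidates) >= 2
        if self.outcome in {
            "accepted_direct",
            "via_synonym",
            "via_misapplication",
            "pro_parte_unique",
        }:
            assert self.accepted is not None


def canonicalize(scientific_name: str) -> tuple[str, str]:
    """Split a scientific name into (canonical name, authorship).

    The canonical name keeps infraspecific rank markers and hybrid signs;
    authorship (capitalised author tokens, parenthesised basionym authors,
    "ex", "&") is stripped off.  Idempotent on its own canonical output.
    """
    name = " ".join(scientific_name.split())
    if not name:
        raise InputError("canonicalize: empty name")
    tokens = name.split(" ")
    canonical: list[str] = []
    i = 0
    # genus (possibly preceded by a hybrid sign)
    if tokens and tokens[0] == "×":
        canonical.append(tokens[0])
        i = 1
    if i < len(tokens):
        canonical.append(tokens[i])
        i += 1
    while i < len(tokens):
        tok = tokens[i]
        if tok == "×":
            canonical.append(tok)
            i += 1
            continue
        if tok in _RANK_MARKERS:
            nxt = tokens[i + 1] if i + 1 < len(tokens) else ""
            if _EPITHET_RE.match(nxt):
                canonical.append(tok)
                canonical.append(nxt)
                i += 2
                continue
            break  # marker-shaped author abbreviation: authorship starts
        if _EPITHET_RE.match(tok):
            canonical.append(tok)
            i += 1
            continue
        break  # capitalised / parenthesised / dotted token: authorship
    authorship = " ".join(tokens[i:])
    return " ".join(canonical), authorship


def _key(name: str) -> str:
    """Lookup key: case-folded, hybrid sign unified, whitespace collapsed."""
    return " ".join(name.replace("×", "x").lower().split())


@dataclass
class NameIndex:
    """Exact-match lookup over the reference census."""

    by_id: dict[str, TaxonName] = field(default_factory=dict)
    by_canonical: dict[str, list[TaxonName]] = field(default_factory=dict)
    by_scientific: dict[str, list[TaxonName]] = field(default_factory=dict)

    def accepted_for(self, row: TaxonName) -> TaxonName | None:
        """Follow a row's accepted-name link (identity for accepted rows)."""
        if row.taxon_status == ACCEPTED:
            return row
        if row.accepted_id and row.accepted_id in self.by_id:
            target = self.by_id[row.accepted_id]
            if target.taxon_status == ACCEPTED:
                return target
        return None


def build_index(reference: list[TaxonName]) -> NameIndex:
    """Build the exact-match name index over the reference census.

    Duplicate accepted canonical names are indexed as multi-candidate
    entries; they surface as ambiguity at resolve time rather than as an
    indexing error.
    """
    index = NameIndex()
    for row in reference:
        if row.taxon_id:
            index.by_id[row.taxon_id] = row
        index.by_canonical.setdefault(_key(row.canonical_name), []).append(row)
        index.by_scientific.setdefault(_key(row.scientific_name), []).append(row)
    return index


def resolve(query: "TaxonName | str", index: NameIndex) -> NameResolution:
    """Resolve one census name to its accepted reference taxon.

    Total over queries: every failure mode is an outcome, never an
    exception.  An accepted direct match wins over a textual collision with
    a synonym of a different taxon (the collision is logged).
    """
    if isinstance(query, str):
        query = TaxonName(scientific_name=query)
    rows = index.by_scientific.get(_key(query.scientific_name), [])
    if not rows:
        # the cited string may itself be a canonical name (censuses often
        # omit authorship, and capitalisation varies)
        rows = index.by_canonical.get(_key(query.scientific_name), [])
    if not rows:
        rows = index.by_canonical.get(_key(query.canonical_name), [])
    if not rows:
        return NameResolution(query=query, outcome="unmatched")

    accepted_rows = [r for r in rows if r.taxon_status == ACCEPTED]
    if len(accepted_rows) == 1:
        if len(rows) > 1:
            log.info(
                "name %r matches an accepted name and %d other rows; "
                "direct match wins",
                query.canonical_name,
                len(rows) - 1,
            )
        return NameResolution(
            query=query, outcome="accepted_direct", accepted=accepted_rows[0]
        )
    if len(accepted_rows) >= 2:
        return NameResolution(
            query=query,
            outcome="pro_parte_ambiguous",
            candidates=tuple(sorted(accepted_rows, key=lambda t: t.taxon_id)),
        )

    targets: dict[str, TaxonName] = {}
    statuses: set[str] = set()
    for row in rows:
        statuses.add(row.taxon_status)
        target = index.accepted_for(row)
        if target is not None:
            targets[target.taxon_id] = target
    if not targets:
        if EXCLUDED in statuses:
            return NameResolution(query=query, outcome="excluded")
        return NameResolution(query=query, outcome="unmatched")
    if len(targets) >= 2:
        return NameResolution(
            query=query,
            outcome="pro_parte_ambiguous",
            candidates=tuple(
                sorted(targets.values(), key=lambda t: t.taxon_id)
            ),
        )
    (target,) = targets.values()
    if statuses & {PRO_PARTE, PRO_PARTE_MISAPPLIED}:
        outcome = "pro_parte_unique"
    elif SYNONYM in statuses:
        outcome = "via_synonym"
    else:
        outcome = "via_misapplication"
    return NameResolution(query=query, outcome=outcome, accepted=target)


def load_backbone_map(path) -> dict[str, dict[str, str]]:
    """Load an offline mapping of reference taxon ids to external backbone
    identifiers (GBIF / WFO style).

    Pure pass-through: the file is a CSV whose first column is the
    reference ``taxon_id`` and whose remaining columns are carried along
    verbatim (e.g. ``gbif_id``, ``wfo_id``).  No live lookups are made.
    """
    import csv as _csv
    from pathlib import Path as _Path

    mapping: dict[str, dict[str, str]] = {}
    with _Path(path).open(newline="", encoding="utf-8") as fh:
        reader = _csv.DictReader(fh)
        if not reader.fieldnames or "taxon_id" not in reader.fieldnames:
            raise InputError(f"{path}: backbone map needs a taxon_id column")
        for row in reader:
            taxon_id = row.pop("taxon_id")
            if taxon_id:
                mapping[taxon_id] = dict(row)
    return mapping
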