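"""State-level cross-referencing and precautionary status unification.

For each state, every retained jurisdictional census row is compared with
the reference census entry for the same taxon and state.  When the two
sources disagree, the status that has advanced the furthest along the
introduction-naturalisation-invasion continuum prevails — the precautionary
choice for management.  Taxa listed only in one source keep the status of
the source that lists them; names that cannot be resolved to exactly one
accepted taxon are carried as ``name_unresolved`` and excluded from the
unified outputs.

Cross-family resolution (the continuum orders statuses only within the
native and alien families) extends the condensation rules: a native taxon
that another source reports at or beyond naturalised becomes
``native_colonising``; below naturalised, ``native_potentially_colonising``;
``uncertain_origin`` yields to any alien status and pairs with native as
potentially colonising; ``presumed_extinct`` yields to any present status.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from .census_io import RegionStatusMap
from .status_vocab import (
    InvasionStatus,
    OriginFamily,
    condense_combined,
    continuum_rank,
)
from .taxonomy import NameIndex, NameResolution, TaxonName, canonicalize, resolve

log = logging.getLogger(__name__)

__all__ = ["StateRecord", "compare", "unify", "harmonize_state"]

COMPARISONS = (
    "agree",
    "status_mismatch",
    "census_only",
    "reference_only",
    "name_unresolved",
)

_S = InvasionStatus
_NO_INFO = frozenset({_S.ABSENT, _S.DELETED})


@dataclass(frozen=True)
class StateRecord:
    """One harmonized row of a per-state dataset."""

    state: str
    name: TaxonName
    resolution: NameResolution | None
    census_status: InvasionStatus | None
    reference_status: InvasionStatus | None
    comparison: str
    unified_status: InvasionStatus | None
    flags: tuple[str, ...] = ()

    @property
    def accepted(self) -> TaxonName | None:
        if self.resolution is not None and self.resolution.accepted is not None:
            return self.resolution.accepted
        if self.comparison == "reference_only":
            return self.name
        return None


def compare(
    census_status: InvasionStatus, reference_status: InvasionStatus | None
) -> str:
    """Classify one census-vs-reference status pair."""
    if reference_status is None:
        return "census_only"
    if census_status == reference_status:
        return "agree"
    return "status_mismatch"


def unify(
    census_status: InvasionStatus, reference_status: InvasionStatus | None
) -> InvasionStatus:
    """Resolve two statuses for one taxon and state into one.

    Commutative and idempotent; within a family the continuum maximum wins,
    across families the extended condensation rules apply.
    """
    a, b = census_status, reference_status
    if b is None:
        return a
    if a is None:
        return b
    if a == b:
        return a
    if a in _NO_INFO and b in _NO_INFO:
        return max(a, b, key=continuum_rank)
    if b in _NO_INFO:
        return a
    if a in _NO_INFO:
        return b

    fam_a, fam_b = a.origin_family, b.origin_family
    if fam_a == fam_b:
        return max(a, b, key=continuum_rank)

    # presumed_extinct yields to any present status (presence over absence;
    # the survivor is flagged for review by harmonize_state)
    if a is _S.PRESUMED_EXTINCT and b.present:
        return b
    if b is _S.PRESUMED_EXTINCT and a.present:
        return a
    if not a.present and not b.present:
        # cross-family loss records: the alien history (formerly_*) was the
        # furthest along the continuum before loss
        return a if a.origin_family is OriginFamily.ALIEN else b

    # uncertain origin yields to the alien claim, pairs with native-family
    # as potentially colonising
    if _S.UNCERTAIN_ORIGIN in (a, b):
        other = b if a is _S.UNCERTAIN_ORIGIN else a
        if other.origin_family is OriginFamily.ALIEN:
            return other
        return max(
            other, _S.NATIVE_POTENTIALLY_COLONISING, key=continuum_rank
        )

    # native family vs alien family
    native = a if fam_a is OriginFamily.NATIVE else b
    alien = b if fam_a is OriginFamily.NATIVE else a
    if continuum_rank(alien) >= continuum_rank(_S.NATURALISED):
        derived = _S.NATIVE_COLONISING
    else:
        derived = _S.NATIVE_POTENTIALLY_COLONISING
    return max(native, derived, key=continuum_rank)


def harmonize_state(
    census_records: Iterable[tuple[str, InvasionStatus]],
    index: NameIndex,
    region_maps: Mapping[str, RegionStatusMap],
    state: str,
) -> tuple[list[StateRecord], dict]:
    """Cross-reference one state's census with the reference census.

    ``census_records`` are ``(scientific_name, converted_status)`` pairs
    (extra tuple elements are ignored, so the reader output can be passed
    directly).  Returns one :class:`StateRecord` per retained census name
    plus one ``reference_only`` record per reference taxon listed for the
    state but absent from the census, and a mismatch report tallying each
    comparison outcome.
    """
    # condense duplicate census rows for the same name
    grouped: dict[str, tuple[str, list[InvasionStatus]]] = {}
    for rec in census_records:
        name, status = rec[0], rec[1]
        key = canonicalize(name)[0].lower()
        if key in grouped:
            grouped[key][1].append(status)
        else:
            grouped[key] = (name, [status])

    records: list[StateRecord] = []
    tally: Counter = Counter()
    matched_taxa: set[str] = set()
    duplicates = 0
    for key, (name, statuses) in grouped.items():
        if len(statuses) > 1:
            duplicates += len(statuses) - 1
            log.warning(
                "census %s: %d duplicate rows for %r condensed", state,
                len(statuses), name,
            )
        census_status = condense_combined(statuses)
        query = TaxonName(scientific_name=name)
        resolution = resolve(query, index)
        flags: tuple[str, ...] = ()
        if resolution.outcome in {"unmatched", "pro_parte_ambiguous"}:
            comparison = "name_unresolved"
            reference_status = None
            unified = None
        else:
            if resolution.outcome == "excluded":
                # excluded from the reference: semantically not listed there
                accepted_id = None
                flags = ("reference_excluded",)
            else:
                accepted_id = resolution.accepted.taxon_id
                matched_taxa.add(accepted_id)
            reference_status = None
            if accepted_id is not None and accepted_id in region_maps:
                reference_status = region_maps[accepted_id].entries.get(state)
            comparison = compare(census_status, reference_status)
            unified = unify(census_status, reference_status)
            if _S.PRESUMED_EXTINCT in (census_status, reference_status) and (
                unified is not _S.PRESUMED_EXTINCT
            ):
                flags = flags + ("extinction_conflict",)
        tally[comparison] += 1
        records.append(
            StateRecord(
                state=state,
                name=query,
                resolution=resolution,
                census_status=census_status,
                reference_status=reference_status,
                comparison=comparison,
                unified_status=unified,
                flags=flags,
            )
        )

    # reference taxa listed for this state but absent from the census
    for taxon_id in sorted(region_maps):
        if taxon_id in matched_taxa:
            continue
        rsm = region_maps[taxon_id]
        ref_status = rsm.entries.get(state)
        if ref_status is None:
            continue
        taxon = index.by_id.get(taxon_id)
        if taxon is None:
            continue
        tally["reference_only"] += 1
        records.append(
            StateRecord(
                state=state,
                name=taxon,
                resolution=None,
                census_status=None,
                reference_status=ref_status,
                comparison="reference_only",
                unified_status=ref_status,
            )
        )

    report = {
        "state": state,
        "comparisons": {c: tally.get(c, 0) for c in COMPARISONS},
        "census_names": len(grouped),
        "duplicates_condensed": duplicates,
        "records": len(records),
    }
    return records, report
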