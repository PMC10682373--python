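"""National integration and register cross-referencing.

The unified per-state statuses of each accepted taxon are folded into one
national status by a six-tier precedence: nativeness anywhere outranks any
alien status ("native to at least one state regardless of being introduced
or naturalised into other states"), then native colonising, then native
potentially colonising, then uncertain origin; otherwise the present alien
status furthest along the continuum prevails; a taxon present nowhere is
recorded by what it lost (formerly naturalised > formerly introduced >
presumed extinct).

The national status is then cross-referenced with the introduced-species
register: an alien taxon the register flags as invasive on impact is
promoted to ``harmful_invasive``; any other register disagreement leaves
the integrated national status in place and is reported as a conflict.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .census_io import RegionStatusMap, RegisterRecord
from .errors import InputError
from .harmonizer import StateRecord
from .status_vocab import (
    DarwinCorePair,
    InvasionStatus,
    OriginFamily,
    continuum_rank,
    to_darwin_core,
)
from .taxonomy import NameIndex, TaxonName, resolve

log = logging.getLogger(__name__)

__all__ = [
    "AfaRecord",
    "integrate_national",
    "crossref_register",
    "assemble_afa",
]

_S = InvasionStatus
_PRESENT_ALIEN = (
    _S.DOUBTFULLY_INTRODUCED,
    _S.INTRODUCED,
    _S.DOUBTFULLY_NATURALISED,
    _S.NATURALISED,
    _S.HARMFUL_INVASIVE,
)

REGISTER_COMPARISONS = ("agree", "promoted", "register_conflict", "register_absent")


@dataclass(frozen=True)
class AfaRecord:
    """One accepted taxon of the unified national dataset."""

    name: TaxonName
    state_statuses: Mapping[str, InvasionStatus]
    territory_statuses: Mapping[str, InvasionStatus]
    national_status: InvasionStatus
    register_status: InvasionStatus | None
    register_comparison: str
    afa_status: InvasionStatus
    dwc: DarwinCorePair
    national_from_territories: bool = False
    flags: tuple[str, ...] = ()


def integrate_national(
    state_statuses: Mapping[str, InvasionStatus], mode: str = "distinct"
) -> InvasionStatus:
    """Fold per-state unified statuses into one national status.

    ``mode="distinct"`` keeps native_potentially_colonising as its own
    national tier; ``mode="fold"`` merges it into native_colonising (the
    alternative reading of the integration rule).
    """
    statuses = [s for s in state_statuses.values() if s is not None]
    if not statuses:
        raise InputError("integrate_national: no state statuses")
    statuses = [s for s in statuses if s not in (_S.ABSENT, _S.DELETED)]
    present = set(statuses)
    if _S.NATIVE in present:
        return _S.NATIVE
    if mode == "fold":
        if present & {_S.NATIVE_COLONISING, _S.NATIVE_POTENTIALLY_COLONISING}:
            return _S.NATIVE_COLONISING
    else:
        if _S.NATIVE_COLONISING in present:
            return _S.NATIVE_COLONISING
        if _S.NATIVE_POTENTIALLY_COLONISING in present:
            return _S.NATIVE_POTENTIALLY_COLONISING
    if _S.UNCERTAIN_ORIGIN in present:
        return _S.UNCERTAIN_ORIGIN
    aliens = [s for s in present if s in _PRESENT_ALIEN]
    if aliens:
        return max(aliens, key=continuum_rank)
    if _S.FORMERLY_NATURALISED in present:
        return _S.FORMERLY_NATURALISED
    if _S.FORMERLY_INTRODUCED in present:
        return _S.FORMERLY_INTRODUCED
    return _S.PRESUMED_EXTINCT


def crossref_register(
    national_status: InvasionStatus, register_status: InvasionStatus | None
) -> tuple[InvasionStatus, str]:
    """Cross-reference the national status with the register status.

    Never moves a status backwards along the continuum: either the national
    status stands, or an alien taxon is promoted to harmful_invasive.
    """
    if register_status is None:
        return national_status, "register_absent"
    if register_status == national_status:
        return national_status, "agree"
    if (
        national_status.origin_family is OriginFamily.ALIEN
        and register_status is _S.HARMFUL_INVASIVE
    ):
        return _S.HARMFUL_INVASIVE, "promoted"
    return national_status, "register_conflict"


@dataclass
class AssemblyReport:
    """Side products of national assembly."""

    register_unmatched: list[RegisterRecord] = field(default_factory=list)
    register_comparisons: Counter = field(default_factory=Counter)
    territory_only: int = 0
    n_records: int = 0


def assemble_afa(
    state_records: Mapping[str, Iterable[StateRecord]],
    index: NameIndex,
    region_maps: Mapping[str, RegionStatusMap],
    register_records: Iterable[RegisterRecord] = (),
    dwc_table=None,
    include_territories_in_national: bool = True,
    potentially_colonising_national_mode: str = "distinct",
) -> tuple[list[AfaRecord], AssemblyReport]:
    """Assemble one national record per accepted reference taxon.

    Census-only taxa absent from the reference never reach the national
    dataset; they survive only in their state dataset.  External-territory
    statuses pass through from the reference and feed the national
    integration only when a taxon has no state entry at all (so
    territory-endemic aliens are not lost), flagged on the record.
    Register taxa that match no accepted reference name are reported, never
    added.
    """
    report = AssemblyReport()

    # per-taxon unified state statuses, from all harmonized state datasets
    per_taxon: dict[str, dict[str, InvasionStatus]] = {}
    for state, records in state_records.items():
        for rec in records:
            if rec.unified_status is None:
                continue
            accepted = rec.accepted
            if accepted is None or not accepted.taxon_id:
                continue
            if accepted.taxon_id not in index.by_id:
                continue
            per_taxon.setdefault(accepted.taxon_id, {})[state] = rec.unified_status

    # register statuses keyed by accepted taxon id
    register_by_taxon: dict[str, InvasionStatus] = {}
    for reg in register_records:
        resolution = resolve(
            TaxonName(
                scientific_name=reg.scientific_name,
                canonical_name=reg.canonical_name,
            ),
            index,
        )
        if resolution.accepted is None:
            report.register_unmatched.append(reg)
            continue
        tid = resolution.accepted.taxon_id
        prior = register_by_taxon.get(tid)
        if prior is None or continuum_rank(reg.converted_status) > continuum_rank(
            prior
        ):
            register_by_taxon[tid] = reg.converted_status

    records: list[AfaRecord] = []
    for taxon_id in sorted(region_maps):
        taxon = index.by_id.get(taxon_id)
        if taxon is None or taxon.taxon_status != "accepted":
            continue
        states = per_taxon.get(taxon_id, {})
        territories = region_maps[taxon_id].territories()
        if not states and not territories:
            continue
        from_territories = False
        if states:
            national = integrate_national(
                states, mode=potentially_colonising_national_mode
            )
        else:
            report.territory_only += 1
            if not include_territories_in_national:
                continue
            from_territories = True
            national = integrate_national(
                territories, mode=potentially_colonising_national_mode
            )
        register_status = register_by_taxon.get(taxon_id)
        afa_status, register_comparison = crossref_register(
            national, register_status
        )
        report.register_comparisons[register_comparison] += 1
        records.append(
            AfaRecord(
                name=taxon,
                state_statuses=dict(sorted(states.items())),
                territory_statuses=dict(sorted(territories.items())),
                national_status=national,
                register_status=register_status,
                register_comparison=register_comparison,
                afa_status=afa_status,
                dwc=to_darwin_core(afa_status, dwc_table),
                national_from_territories=from_territories,
            )
        )
    report.n_records = len(records)
    return records, report
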