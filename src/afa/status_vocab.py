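"""Unified invasion-status vocabulary and the continuum ordering.

The vocabulary combines presence, origin and introduction status in a single
token, following the introduction-naturalisation-invasion continuum: casual
aliens (``introduced``) may become ``naturalised`` (self-sustaining
populations) and a fraction of those become ``harmful_invasive`` (recorded
negative impact).  Native taxa that are also (potentially) naturalised
elsewhere within their home jurisdiction are ``native_colonising``
(``native_potentially_colonising``).  Absence codes (``formerly_*``,
``presumed_extinct``, ``absent``, ``deleted``) carry ``present = False``.

:func:`continuum_rank` provides the within-family total order used by the
precautionary resolution rules ("the status that has advanced the furthest
along the continuum prevails"); cross-family resolution lives in
:mod:`afa.harmonizer`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources

import yaml

from .errors import InputError, VocabularyError

__all__ = [
    "InvasionStatus",
    "OriginFamily",
    "DarwinCorePair",
    "continuum_rank",
    "condense_combined",
    "to_darwin_core",
    "load_dwc_table",
    "coerce_status",
]


class OriginFamily(str, enum.Enum):
    NATIVE = "native"
    ALIEN = "alien"
    UNCERTAIN = "uncertain"
    NONE = "none"


class InvasionStatus(str, enum.Enum):
    """One token of the unified vocabulary.

    The member order is not the continuum order; use :func:`continuum_rank`.
    """

    NATIVE = "native"
    NATIVE_POTENTIALLY_COLONISING = "native_potentially_colonising"
    NATIVE_COLONISING = "native_colonising"
    UNCERTAIN_ORIGIN = "uncertain_origin"
    DOUBTFULLY_INTRODUCED = "doubtfully_introduced"
    INTRODUCED = "introduced"
    DOUBTFULLY_NATURALISED = "doubtfully_naturalised"
    NATURALISED = "naturalised"
    HARMFUL_INVASIVE = "harmful_invasive"
    FORMERLY_NATURALISED = "formerly_naturalised"
    FORMERLY_INTRODUCED = "formerly_introduced"
    PRESUMED_EXTINCT = "presumed_extinct"
    ABSENT = "absent"
    DELETED = "deleted"

    @property
    def origin_family(self) -> OriginFamily:
        return _FAMILY[self]

    @property
    def present(self) -> bool:
        return self not in _ABSENT_CODES

    @property
    def phrase(self) -> str:
        """Human-readable rendering, e.g. ``native colonising``."""
        return self.value.replace("_", " ")


_ABSENT_CODES = frozenset(
    {
        InvasionStatus.FORMERLY_NATURALISED,
        InvasionStatus.FORMERLY_INTRODUCED,
        InvasionStatus.PRESUMED_EXTINCT,
        InvasionStatus.ABSENT,
        InvasionStatus.DELETED,
    }
)

_FAMILY = {
    InvasionStatus.NATIVE: OriginFamily.NATIVE,
    InvasionStatus.NATIVE_POTENTIALLY_COLONISING: OriginFamily.NATIVE,
    InvasionStatus.NATIVE_COLONISING: OriginFamily.NATIVE,
    # a presumed-extinct taxon was native to the jurisdiction before loss
    InvasionStatus.PRESUMED_EXTINCT: OriginFamily.NATIVE,
    InvasionStatus.UNCERTAIN_ORIGIN: OriginFamily.UNCERTAIN,
    InvasionStatus.DOUBTFULLY_INTRODUCED: OriginFamily.ALIEN,
    InvasionStatus.INTRODUCED: OriginFamily.ALIEN,
    InvasionStatus.DOUBTFULLY_NATURALISED: OriginFamily.ALIEN,
    InvasionStatus.NATURALISED: OriginFamily.ALIEN,
    InvasionStatus.HARMFUL_INVASIVE: OriginFamily.ALIEN,
    InvasionStatus.FORMERLY_NATURALISED: OriginFamily.ALIEN,
    InvasionStatus.FORMERLY_INTRODUCED: OriginFamily.ALIEN,
    InvasionStatus.ABSENT: OriginFamily.NONE,
    InvasionStatus.DELETED: OriginFamily.NONE,
}

# Total-order key.  Within the alien family the absence codes sit below the
# present codes; doubtfully_introduced < introduced and
# doubtfully_naturalised < naturalised (doubt weakens the claim one notch).
_RANK = {
    InvasionStatus.DELETED: 0,
    InvasionStatus.ABSENT: 1,
    InvasionStatus.PRESUMED_EXTINCT: 10,
    InvasionStatus.NATIVE: 11,
    InvasionStatus.NATIVE_POTENTIALLY_COLONISING: 12,
    InvasionStatus.NATIVE_COLONISING: 13,
    InvasionStatus.UNCERTAIN_ORIGIN: 20,
    InvasionStatus.FORMERLY_INTRODUCED: 30,
    InvasionStatus.FORMERLY_NATURALISED: 31,
    InvasionStatus.DOUBTFULLY_INTRODUCED: 32,
    InvasionStatus.INTRODUCED: 33,
    InvasionStatus.DOUBTFULLY_NATURALISED: 34,
    InvasionStatus.NATURALISED: 35,
    InvasionStatus.HARMFUL_INVASIVE: 36,
}


def coerce_status(token: "InvasionStatus | str", context: str = "") -> InvasionStatus:
    """Turn a token (snake_case or spaced phrase) into an InvasionStatus.

    Raises :class:`VocabularyError` naming the token if it is not a member.
    """
    if isinstance(token, InvasionStatus):
        return token
    key = str(token).strip().lower().replace(" ", "_")
    try:
        return InvasionStatus(key)
    except ValueError:
        raise VocabularyError(str(token), context) from None


def continuum_rank(status: "InvasionStatus | str") -> int:
    """Ordinal position along the continuum (within-family total order)."""
    return _RANK[coerce_status(status)]


def condense_combined(parts) -> InvasionStatus:
    """Condense the statuses found within one state entry into one status.

    A reference-census state entry can carry several statuses at once
    ("native and naturalised"); one status per species and state is required
    downstream.  Printed condensations: native+naturalised (and
    native+naturalised+uncertain origin) -> native_colonising;
    native+doubtfully_naturalised and native+uncertain origin ->
    native_potentially_colonising.  The general rule extrapolates them:
    a native-family part with an alien part at or beyond naturalised ->
    native_colonising; native-family with anything weaker ->
    native_potentially_colonising; all-alien -> continuum maximum.
    """
    parts = [coerce_status(p, "condense_combined") for p in parts]
    if not parts:
        raise InputError("condense_combined: empty status list")
    if len(parts) == 1:
        return parts[0]

    present = [p for p in parts if p.present] or parts
    natives = [p for p in present if p.origin_family is OriginFamily.NATIVE]
    aliens = [p for p in present if p.origin_family is OriginFamily.ALIEN]

    if natives and (aliens or any(p is InvasionStatus.UNCERTAIN_ORIGIN for p in present)):
        if aliens and max(continuum_rank(a) for a in aliens) >= continuum_rank(
            InvasionStatus.NATURALISED
        ):
            derived = InvasionStatus.NATIVE_COLONISING
        else:
            derived = InvasionStatus.NATIVE_POTENTIALLY_COLONISING
        return max(natives + [derived], key=continuum_rank)
    if natives:
        return max(natives, key=continuum_rank)
    if aliens:
        return max(aliens, key=continuum_rank)
    return max(present, key=continuum_rank)


@dataclass(frozen=True)
class DarwinCorePair:
    """Darwin Core ``establishmentMeans`` / ``degreeOfEstablishment`` pair.

    A degree of establishment is only meaningful for taxa that were moved by
    people, so a non-empty degree requires establishment_means in
    {introduced, uncertain}.
    """

    establishment_means: str = ""
    degree_of_establishment: str = ""

    _MEANS = frozenset({"native", "introduced", "uncertain", ""})
    _DEGREE = frozenset({"casual", "established", "invasive", ""})

    def __post_init__(self):
        if self.establishment_means not in self._MEANS:
            raise VocabularyError(self.establishment_means, "establishmentMeans")
        if self.degree_of_establishment not in self._DEGREE:
            raise VocabularyError(
                self.degree_of_establishment, "degreeOfEstablishment"
            )
        if self.degree_of_establishment and self.establishment_means not in (
            "introduced",
            "uncertain",
        ):
            raise InputError(
                "degreeOfEstablishment requires establishmentMeans "
                f"introduced/uncertain, got {self.establishment_means!r}"
            )


_dwc_cache: dict[InvasionStatus, DarwinCorePair] | None = None


def load_dwc_table(path=None) -> dict[InvasionStatus, DarwinCorePair]:
    """Load the status -> Darwin Core mapping (shipped default or override).

    The file is a flat YAML mapping ``status: [means, degree]``; it must be
    total over the vocabulary.
    """
    if path is None:
        text = (
            resources.files("afa.config").joinpath("darwin_core.yaml").read_text()
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    table = {}
    for key, pair in raw.items():
        means, degree = (pair + [""])[:2] if isinstance(pair, list) else (pair, "")
        table[coerce_status(key, "darwin core table")] = DarwinCorePair(
            means or "", degree or ""
        )
    missing = set(InvasionStatus) - set(table)
    if missing:
        raise InputError(
            "darwin core table not total; missing: "
            + ", ".join(sorted(s.value for s in missing))
        )
    return table


def to_darwin_core(
    status: "InvasionStatus | str",
    table: dict[InvasionStatus, DarwinCorePair] | None = None,
) -> DarwinCorePair:
    """Map a vocabulary member to its Darwin Core pair (total)."""
    global _dwc_cache
    if table is None:
        if _dwc_cache is None:
            _dwc_cache = load_dwc_table()
        table = _dwc_cache
    return table[coerce_status(status, "to_darwin_core")]
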