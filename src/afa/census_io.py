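"""Readers and converters for the three source shapes.

Three kinds of table feed the pipeline:

* the reference national census (accepted taxonomy plus a packed
  per-taxon ``Distribution`` string such as ``"NSW, Vic (naturalised)"``),
* one jurisdictional census per state, each with its own raw status-code
  columns, standardised here through declarative first-match-wins
  conversion rules shipped as YAML configs, and
* an introduced-species register split across up to three files
  (GRIIS-style), merged, restricted to plants and relabelled so that
  impact-based "invasive" records become ``harmful_invasive``.

All tabular I/O is CSV; files are read as UTF-8 with a latin-1 fallback
because herbarium exports vary.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import ConfigError, InputError, ParseError, SchemaError, VocabularyError
from .status_vocab import (
    InvasionStatus,
    coerce_status,
    condense_combined,
    continuum_rank,
)

log = logging.getLogger(__name__)

__all__ = [
    "STATES",
    "TERRITORIES",
    "REGIONS",
    "RegionStatusMap",
    "ConversionRuleSet",
    "RegisterRecord",
    "DELETE",
    "load_dialect",
    "parse_distribution",
    "format_distribution",
    "load_ruleset",
    "builtin_ruleset",
    "lint_rules",
    "convert_record",
    "read_table",
    "read_reference",
    "read_state_census",
    "load_register",
]

STATES = ("ACT", "NSW", "NT", "QLD", "SA", "TAS", "VIC", "WA")
TERRITORIES = ("AR", "CaI", "ChI", "CoI", "CSI", "HI", "LHI", "MDI", "NI")
REGIONS = STATES + TERRITORIES
_REGION_ORDER = {code: i for i, code in enumerate(REGIONS)}


class _Delete:
    """Sentinel returned by convert_record for rows the rules delete."""

    def __repr__(self) -> str:  # pragma: no cover
        return "DELETE"


DELETE = _Delete()


@dataclass
class RegionStatusMap:
    """Per-region invasion status for one taxon.

    ``unknown_regions`` collects region tokens that did not match the
    dialect; they are reported, never silently dropped.
    """

    entries: dict[str, InvasionStatus] = field(default_factory=dict)
    unknown_regions: list[str] = field(default_factory=list)

    def states(self) -> dict[str, InvasionStatus]:
        return {r: s for r, s in self.entries.items() if r in STATES}

    def territories(self) -> dict[str, InvasionStatus]:
        return {r: s for r, s in self.entries.items() if r in TERRITORIES}

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionStatusMap) and self.entries == other.entries


# ---------------------------------------------------------------------------
# packed distribution strings
# ---------------------------------------------------------------------------


def load_dialect(path: str | Path | None = None) -> dict:
    """Load the distribution-string dialect (region spellings, separator)."""
    if path is None:
        text = (
            resources.files("afa.config")
            .joinpath("reference_dialect.yaml")
            .read_text()
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    dialect = yaml.safe_load(text)
    if "region_spellings" not in dialect:
        raise ConfigError("dialect config lacks region_spellings")
    return dialect


_default_dialect: dict | None = None


def _dialect(dialect: dict | None) -> dict:
    global _default_dialect
    if dialect is not None:
        return dialect
    if _default_dialect is None:
        _default_dialect = load_dialect()
    return _default_dialect


def _split_packed(text: str) -> list[tuple[str, int]]:
    """Split on top-level commas, tracking offsets; validate parentheses."""
    items, depth, start = [], 0, 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ParseError("unbalanced ')'", offset=i)
        elif ch == "," and depth == 0:
            items.append((text[start:i], start))
            start = i + 1
    if depth != 0:
        raise ParseError("unbalanced '('", offset=len(text))
    items.append((text[start:], start))
    return [(s, off) for s, off in items if s.strip()]


def parse_distribution(text: str, dialect: dict | None = None) -> RegionStatusMap:
    """Parse a packed distribution string into a per-region status map.

    A bare region token means the taxon is native there; a parenthesised
    phrase carries the status.  Phrases joined with "and" are combined
    statuses and are condensed to a single status per region (e.g.
    ``"Qld (native and naturalised)"`` -> QLD native_colonising).  A region
    appearing more than once is likewise condensed.
    """
    dialect = _dialect(dialect)
    spellings = dialect["region_spellings"]
    result = RegionStatusMap()
    collected: dict[str, list[InvasionStatus]] = {}
    if not text or not text.strip():
        return result
    for item, offset in _split_packed(text):
        item = item.strip()
        if "(" in item:
            head, _, rest = item.partition("(")
            if not rest.endswith(")"):
                raise ParseError("malformed parenthetical", offset=offset)
            token = head.strip()
            phrase = rest[:-1].strip()
            parts = [p.strip() for p in phrase.split(" and ")]
            statuses = [
                coerce_status(p, f"distribution phrase {phrase!r}") for p in parts
            ]
        else:
            token = item
            statuses = [InvasionStatus.NATIVE]
        region = spellings.get(token)
        if region is None:
            log.warning("unknown region token %r in distribution string", token)
            result.unknown_regions.append(token)
            continue
        collected.setdefault(region, []).extend(statuses)
    for region in sorted(collected, key=_REGION_ORDER.get):
        result.entries[region] = condense_combined(collected[region])
    return result


def format_distribution(rsm: RegionStatusMap, dialect: dict | None = None) -> str:
    """Inverse of :func:`parse_distribution` (canonical region order)."""
    dialect = _dialect(dialect)
    reverse = {code: tok for tok, code in dialect["region_spellings"].items()}
    sep = dialect.get("separator", ", ")
    parts = []
    for region in sorted(rsm.entries, key=_REGION_ORDER.get):
        status = rsm.entries[region]
        token = reverse[region]
        if status is InvasionStatus.NATIVE:
            parts.append(token)
        else:
            parts.append(f"{token} ({status.phrase})")
    return sep.join(parts)


# ---------------------------------------------------------------------------
# conversion rule sets (jurisdictional censuses and register)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Matcher:
    kind: str  # equals | iequals | blank | any_of | contains
    value: object = None
    case_sensitive: bool = True

    def matches(self, cell: str) -> bool:
        cell = cell.strip()
        if self.kind == "equals":
            return cell == self.value
        if self.kind == "iequals":
            return cell.lower() == str(self.value).lower()
        if self.kind == "blank":
            return (cell == "") == bool(self.value)
        if self.kind == "any_of":
            return cell in self.value
        if self.kind == "contains":
            if self.case_sensitive:
                return str(self.value) in cell
            return str(self.value).lower() in cell.lower()
        raise ConfigError(f"unknown matcher kind {self.kind!r}")


@dataclass(frozen=True)
class _Rule:
    when: tuple[tuple[str, _Matcher], ...]
    status: InvasionStatus | None  # None => delete action

    def fires(self, row: Mapping[str, str]) -> bool:
        return all(
            matcher.matches(str(row.get(col, "") or ""))
            for col, matcher in self.when
        )


@dataclass(frozen=True)
class ConversionRuleSet:
    """Ordered first-match-wins status-conversion rules for one census."""

    census_id: str
    name_column: str
    rules: tuple[_Rule, ...]
    default: InvasionStatus

    @property
    def required_columns(self) -> tuple[str, ...]:
        cols: list[str] = []
        for rule in self.rules:
            for col, _ in rule.when:
                if col not in cols:
                    cols.append(col)
        return tuple(cols)


def _parse_matcher(spec: Mapping) -> _Matcher:
    spec = dict(spec)
    case_sensitive = bool(spec.pop("case_sensitive", True))
    if len(spec) != 1:
        raise ConfigError(f"matcher must have exactly one operator: {spec!r}")
    (kind, value), = spec.items()
    if kind not in {"equals", "iequals", "blank", "any_of", "contains"}:
        raise ConfigError(f"unknown matcher operator {kind!r}")
    if kind == "any_of":
        value = tuple(str(v) for v in value)
    return _Matcher(kind, value, case_sensitive)


def _parse_ruleset(raw: Mapping, source: str) -> ConversionRuleSet:
    try:
        census_id = str(raw["census_id"])
        rules_raw = raw["rules"]
        default = coerce_status(raw["default"], f"{source}: default")
    except KeyError as exc:
        raise ConfigError(f"{source}: missing key {exc}") from None
    rules = []
    for i, entry in enumerate(rules_raw):
        when = tuple(
            (str(col), _parse_matcher(m)) for col, m in entry["when"].items()
        )
        if entry.get("action") == "delete":
            status = None
        elif "status" in entry:
            status = coerce_status(entry["status"], f"{source}: rule {i}")
        else:
            raise ConfigError(f"{source}: rule {i} has neither status nor action")
        rules.append(_Rule(when, status))
    return ConversionRuleSet(
        census_id=census_id,
        name_column=str(raw.get("name_column", "scientific_name")),
        rules=tuple(rules),
        default=default,
    )


def load_ruleset(path: str | Path) -> ConversionRuleSet:
    """Load a conversion rule set from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return _parse_ruleset(raw, str(path))


def builtin_ruleset(state: str) -> ConversionRuleSet:
    """Load one of the shipped per-state rule sets (by region code)."""
    state = state.upper()
    if state not in STATES:
        raise InputError(f"unknown state code {state!r}")
    text = (
        resources.files("afa.config.states")
        .joinpath(f"{state.lower()}.yaml")
        .read_text()
    )
    return _parse_ruleset(yaml.safe_load(text), f"builtin:{state}")


def _matchers_compatible(a: _Matcher, b: _Matcher) -> bool:
    """Whether one cell value could satisfy both matchers."""
    if a.kind == "contains" or b.kind == "contains":
        if a.kind == b.kind == "contains":
            return True
        other = b if a.kind == "contains" else a
        cont = a if a.kind == "contains" else b
        if other.kind == "blank":
            return not other.value  # contains needs a non-empty cell
        candidates = (
            other.value if other.kind == "any_of" else (str(other.value),)
        )
        needle = str(cont.value) if cont.case_sensitive else str(cont.value).lower()
        return any(
            needle in (c if cont.case_sensitive else c.lower()) for c in candidates
        )
    values_a = _matcher_values(a)
    values_b = _matcher_values(b)
    if values_a is None or values_b is None:
        return True
    return bool(values_a & values_b)


def _matcher_values(m: _Matcher) -> set[str] | None:
    if m.kind == "equals":
        return {str(m.value)}
    if m.kind == "any_of":
        return set(m.value)
    if m.kind == "blank":
        return {""} if m.value else None
    return None  # iequals: approximate as open


def lint_rules(ruleset: ConversionRuleSet) -> list[tuple[int, int]]:
    """Report pairs of rules whose conditions can fire on the same row.

    Overlap is expected in first-match-wins rule sets (later rules are
    fallbacks); the lint exists so a curator editing a config can see which
    orderings carry meaning.
    """
    pairs = []
    for i in range(len(ruleset.rules)):
        for j in range(i + 1, len(ruleset.rules)):
            a, b = ruleset.rules[i], ruleset.rules[j]
            cols_a, cols_b = dict(a.when), dict(b.when)
            shared = set(cols_a) & set(cols_b)
            if all(
                _matchers_compatible(cols_a[c], cols_b[c]) for c in shared
            ):
                pairs.append((i, j))
    return pairs


def convert_record(
    raw_row: Mapping[str, str], rules: ConversionRuleSet
) -> "InvasionStatus | _Delete":
    """Standardise one raw census row to the unified vocabulary.

    First matching rule wins; ``DELETE`` is returned for rows the census
    marks as excluded.  Columns absent from the row are treated as blank
    (table-level column presence is validated by the readers).
    """
    for rule in rules.rules:
        if rule.fires(raw_row):
            return DELETE if rule.status is None else rule.status
    return rules.default


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV as strings (no NA coercion), UTF-8 with latin-1 fallback."""
    raw = Path(path).read_bytes()
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError:
        log.warning("%s is not valid UTF-8; falling back to latin-1", path)
        text = raw.decode("latin-1")
    return pd.read_csv(io.StringIO(text), dtype=str, keep_default_na=False)


REFERENCE_COLUMNS = (
    "taxon_id",
    "scientific_name",
    "canonical_name",
    "authorship",
    "rank",
    "taxon_status",
    "accepted_id",
    "distribution",
)


def read_reference(path: str | Path, dialect: dict | None = None):
    """Read the reference census.

    Returns ``(taxa, region_maps, report)`` where ``taxa`` is a list of
    :class:`afa.taxonomy.TaxonName`, ``region_maps`` maps taxon_id of each
    accepted taxon to its parsed :class:`RegionStatusMap`, and ``report``
    carries row accounting (rows_in = rows_out + rows_errored).
    """
    from .taxonomy import TaxonName  # local import to avoid a cycle

    df = read_table(path)
    for col in REFERENCE_COLUMNS:
        if col not in df.columns:
            raise SchemaError("reference", col)
    taxa: list[TaxonName] = []
    region_maps: dict[str, RegionStatusMap] = {}
    errored: list[tuple[int, str]] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            taxon = TaxonName(
                taxon_id=row.taxon_id,
                scientific_name=row.scientific_name,
                canonical_name=row.canonical_name,
                authorship=row.authorship,
                rank=row.rank,
                taxon_status=row.taxon_status,
                accepted_id=row.accepted_id,
            )
            if taxon.taxon_status == "accepted":
                region_maps[taxon.taxon_id] = parse_distribution(
                    row.distribution, dialect
                )
            taxa.append(taxon)
        except (ParseError, VocabularyError, InputError) as exc:
            errored.append((idx, str(exc)))
            log.error("reference row %d: %s", idx, exc)
    report = {
        "rows_in": len(df),
        "rows_out": len(taxa),
        "rows_deleted": 0,
        "rows_errored": len(errored),
        "errors": errored,
    }
    return taxa, region_maps, report


def read_state_census(path: str | Path, rules: ConversionRuleSet):
    """Read and convert one jurisdictional census.

    Returns ``(records, report)``; ``records`` is a list of
    ``(scientific_name, converted_status, raw_row)`` for retained rows.
    Rows whose rule yields the delete action are dropped and counted.
    Duplicate names are retained here; the harmonizer condenses them.
    """
    df = read_table(path)
    if rules.name_column not in df.columns:
        raise SchemaError(rules.census_id, rules.name_column)
    for col in rules.required_columns:
        if col not in df.columns:
            raise SchemaError(rules.census_id, col)
    records = []
    deleted = errored = 0
    for idx, row in df.iterrows():
        raw = row.to_dict()
        name = str(raw.get(rules.name_column, "")).strip()
        if not name:
            errored += 1
            log.error("census %s row %d: empty name", rules.census_id, idx)
            continue
        status = convert_record(raw, rules)
        if status is DELETE:
            deleted += 1
            continue
        records.append((name, status, raw))
    report = {
        "rows_in": len(df),
        "rows_out": len(records),
        "rows_deleted": deleted,
        "rows_errored": errored,
    }
    return records, report


# ---------------------------------------------------------------------------
# introduced-species register
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegisterRecord:
    scientific_name: str
    canonical_name: str
    kingdom: str
    raw_status: str
    converted_status: InvasionStatus


def load_register_config(path: str | Path | None = None) -> dict:
    if path is None:
        text = resources.files("afa.config").joinpath("register.yaml").read_text()
    else:
        text = Path(path).read_text(encoding="utf-8")
    return yaml.safe_load(text)


def load_register(
    files: Iterable[str | Path], config: dict | None = None
) -> list[RegisterRecord]:
    """Merge up to three register files into deduplicated plant records.

    Non-plant kingdoms are dropped; impact-flagged "invasive" records become
    ``harmful_invasive``; duplicates keep the status furthest along the
    continuum.
    """
    from .taxonomy import canonicalize

    files = list(files)
    if not files:
        raise InputError("load_register: no register files given")
    config = config or load_register_config()
    ruleset = _parse_ruleset(
        {
            "census_id": "register",
            "name_column": config.get("name_column", "scientificName"),
            "rules": config["rules"],
            "default": config.get("default", "introduced"),
        },
        "register config",
    )
    keep = set(config.get("keep_kingdoms", ["Plantae"]))
    kingdom_col = config.get("kingdom_column", "kingdom")
    best: dict[str, RegisterRecord] = {}
    for path in files:
        df = read_table(path)
        if ruleset.name_column not in df.columns:
            raise SchemaError("register", ruleset.name_column)
        if kingdom_col not in df.columns:
            raise SchemaError("register", kingdom_col)
        for _, row in df.iterrows():
            raw = row.to_dict()
            if str(raw.get(kingdom_col, "")).strip() not in keep:
                continue
            name = str(raw.get(ruleset.name_column, "")).strip()
            if not name:
                continue
            status = convert_record(raw, ruleset)
            canonical, _ = canonicalize(name)
            key = canonical.lower()
            rec = RegisterRecord(
                scientific_name=name,
                canonical_name=canonical,
                kingdom=str(raw.get(kingdom_col, "")).strip(),
                raw_status=_raw_status(raw),
                converted_status=status,
            )
            prior = best.get(key)
            if prior is None or continuum_rank(status) > continuum_rank(
                prior.converted_status
            ):
                best[key] = rec
    return [best[k] for k in sorted(best)]


def _raw_status(raw: Mapping[str, str]) -> str:
    for col in ("isInvasive", "establishmentMeans", "status"):
        val = str(raw.get(col, "") or "").strip()
        if val:
            return val
    return ""


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a CSV atomically (write to a temp name, then rename)."""
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    df.to_csv(tmp, index=False, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
    tmp.replace(path)
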