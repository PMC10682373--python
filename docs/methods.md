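# Methods

## The harmonization model

The package treats invasion status as a single token combining presence,
origin and establishment, ordered along the
introduction–naturalisation–invasion continuum. The vocabulary has 14
members in three origin families:

* **native family** — `presumed_extinct` < `native` <
  `native_potentially_colonising` < `native_colonising`;
* **alien family** — `formerly_introduced` < `formerly_naturalised` <
  `doubtfully_introduced` < `introduced` < `doubtfully_naturalised` <
  `naturalised` < `harmful_invasive`;
* `uncertain_origin`, plus two bookkeeping codes (`absent`, `deleted`)
  that carry no information and never appear in outputs.

The order within each family is the continuum: each step is a barrier few
taxa cross (transport → establishment → spread), so when two sources
disagree the precautionary choice is the status further along. Absence
codes sit below the present codes of their family; the "doubtfully"
variants sit one notch below their firm counterparts (the paper-level
sources list the terms without ordering the doubt variants — placing doubt
below certainty is this package's reading, and it only matters for
tie-breaks between two alien claims).

### Two-source unification (state level)

`harmonizer.unify` is commutative, idempotent and total. Within a family
it is the continuum maximum. Across families the rules extend the
condensation conventions for combined within-state records:

| pair | result | rationale |
|---|---|---|
| native-family + alien ≥ naturalised | `native_colonising` | native here, self-sustaining alien population there |
| native-family + alien < naturalised (incl. `formerly_*`) | `native_potentially_colonising` | the alien claim is unconfirmed |
| `uncertain_origin` + alien | the alien status | precautionary |
| `uncertain_origin` + native-family | ≥ `native_potentially_colonising` | mirrors the printed "native and uncertain origin" condensation |
| `presumed_extinct` + any present status | the present status, flagged `extinction_conflict` | presence over absence |
| `presumed_extinct` + `formerly_*` | the `formerly_*` status | the alien history ran further before loss |

In every cross-family case involving a native status the result is also at
least the native input's own rank (so `native_colonising` + `introduced`
stays `native_colonising`).

### National integration

`national.integrate_national` folds per-state unified statuses by a
six-tier precedence: (1) `native` anywhere; (2) `native_colonising`
anywhere; (3) `native_potentially_colonising` anywhere; (4)
`uncertain_origin` anywhere; (5) the continuum maximum over present alien
statuses; (6) nothing present anywhere — `formerly_naturalised` if
anywhere, else `formerly_introduced`, else `presumed_extinct`.

Tier (3) is kept distinct nationally. The integration prose that folds
"potentially colonising" into "colonising" is available as
`potentially_colonising_national_mode: fold` in the run config; the
default preserves the finer distinction because the two categories answer
different management questions.

External territories (AR, CaI, ChI, CoI, CSI, HI, LHI, MDI, NI) pass
through from the reference census and feed the national integration **only
when a taxon has no state entry at all** (flagged
`national_from_territories`), so territory-endemic aliens are not dropped
while the eight-state semantics of the precedence are preserved. Setting
`include_territories_in_national: false` excludes territory-only taxa from
the national dataset entirely.

### Register cross-reference

An alien-family national status plus a register `harmful_invasive`
(impact-based "invasive", relabelled at load time) is promoted to
`harmful_invasive` (`promoted`). Any other disagreement with a present
register status leaves the integrated national status in place
(`register_conflict`) — the register is an impact overlay, not a better
distribution source. The operation never moves a status backwards along
the continuum. A register "introduced" never overrides a weaker national
status, because the national status already integrates every census.

## Status-code conversion

Each jurisdictional census ships with a YAML rule set transcribing its
printed code table (`src/afa/config/states/*.yaml`): ordered
first-match-wins condition sets over the census's own column names, each
yielding a vocabulary member or a delete action (e.g. VicFlora
`occurrenceStatus: excluded`). Two-column interactions (TAS/WA extinct
flags, VIC extinct × establishment means) are encoded purely by rule
order. `census_io.lint_rules` reports which rule pairs can fire on the
same row, so a curator editing a config can see which orderings carry
meaning.

Defaults when no rule fires: `native` for the censuses whose dialect uses
blank-means-native (ACT, SA, TAS), `uncertain_origin` elsewhere — an
unrecognised code is a claim of unknown reliability, and `uncertain_origin`
is the vocabulary's explicit don't-know. The SA extinction scan matches
the bare code "EX" case-sensitively and the word "extinct"
case-insensitively; substring scanning risks false positives if the
comment column carries free prose, which is why the rule is confined to
the status-comment column. The TAS combination `x` + `?i` is not printed
in any source table; under first-match ordering it falls through to
`doubtfully_naturalised`.

The packed distribution string of the reference census uses the dialect in
`config/reference_dialect.yaml`: comma-separated region tokens
("NSW, Vic (naturalised)"), bare token = native, parenthesised phrase =
status, "and"-joined phrases condensed to one status per region.
`parse_distribution` and `format_distribution` are exact inverses.

## Name resolution

Matching is exact — no fuzzy matching — but case-insensitive on canonical
names and with hybrid signs ("×"/"x") unified, because census
capitalisation and typography vary. `canonicalize` strips authorship by
token class (capitalised/dotted/parenthesised tokens end the canonical
part; `subsp.`/`var.`/`f.` are kept as rank markers when followed by a
lowercase epithet, which disambiguates "f." from author abbreviations like
"Hook.f."). A census name matching both an accepted name and, textually, a
synonym of a different taxon resolves to the accepted name; the collision
is logged. Pro-parte and pro-parte-misapplied names reaching exactly one
accepted taxon are kept; reaching two or more, the record is
`name_unresolved`: excluded from unified outputs, retained in the mismatch
report. Census names the reference excludes are treated as census-only
(the census status stands, the record is flagged), since exclusion from
the reference is semantically "not listed there". Author-only differences
(same canonical name, different authorship) resolve by canonical name and
are therefore not scored as mismatches; distinguishing them would require
an authority-aware comparison the sources do not support.

## Synthetic data generator

`afa.fixtures.generate` emulates the three source shapes end to end: a
reference census with packed distribution strings, synonyms,
misapplications, pro-parte names (always both the one-candidate and the
ambiguous case when the rate is non-zero) and combined within-state
statuses; eight state censuses written in each state's **raw code
dialect** (TAS "i"/"?i"/"x", WA "N"/"M"/"A", SA "*"/"EX", VicFlora Darwin
Core columns, …), so the shipped conversion rules are exercised
end-to-end; and a three-file register with impact-flagged records, a
cross-file duplicate, a non-plant record and an unmatchable name.

Ground truth is computed during generation by straight-line literal
transcriptions of the unification, six-tier and register rules
(`_truth_unify`, `_truth_national`, `_truth_crossref`) that do not import
the pipeline modules; the test suite carries a third independent
transcription. Equality of pipeline output with this truth on 100% of
taxa is the end-to-end acceptance check.

Default study conditions (chosen once as plausible for a flora-census
setting): `n_taxa=200`, `p_presence=0.4` per state, `rate_synonym=0.10`,
`rate_misapplied=0.03`, `rate_pro_parte=0.02`, `rate_status_mismatch=0.05`,
`rate_combined_status=0.003` (combined within-state records are rare in
real censuses, roughly three per thousand region records),
`rate_register_invasive=0.10`. Fixed secondary conditions: a reference
state entry lacks a census row with probability 0.10, a census row has no
reference state entry with probability 0.05, each external territory is
populated with probability 0.05, and 5% extra taxa exist only in state
censuses. Each state census can only express the statuses its real code
table can (NSW, for instance, has no naturalised code), which is itself a
faithful property of the sources.

What the generator does **not** emulate: realistic taxonomic composition,
misspelled names (the matcher is exact by design, so fuzzily corrupted
names would only ever land in `name_unresolved`), infraspecific taxonomy
conflicts between sources, and encoding corruption. Passing tests
therefore demonstrate correctness of the harmonization logic, not
robustness to arbitrarily dirty real-world exports.

## Determinism and atomicity

All randomness in the generator flows from one `random.Random(seed)`;
regeneration is byte-identical. The build path contains no randomness;
outputs are sorted on stable keys and written via write-then-rename, and
all computation happens before any file is written, so a failing input
never leaves a partial national dataset behind.

## Problem sizes

The test suite runs exhaustive checks over the 14-token vocabulary (14²
pairs, all ≤3-state mappings) and end-to-end fixture recovery over 20
seeds at 200 taxa; `scripts/acceptance.py` uses a 1000-taxon headline
build plus the same 20-seed sweep. These sizes exercise every code path of
the engine; the pipeline itself is linear in census rows and has been run
unchanged at several thousand taxa.

## Run configuration

```yaml
reference: demo_data/reference.csv
states:
  NSW: demo_data/states/NSW.csv   # any subset of the eight codes
  VIC: demo_data/states/VIC.csv
register:
  - demo_data/register/griis_1.csv
rules:                            # optional per-state rule overrides
  NSW: my_rules/nsw.yaml
darwin_core: my_dwc.yaml          # optional mapping override
output_dir: out
include_territories_in_national: true
potentially_colonising_national_mode: distinct   # or "fold"
```

Missing states are warned about and the national dataset is built from the
remaining ones. Unknown config keys and dangling paths are rejected before
any work starts.

## Known limitations

* Cross-referencing against external taxonomic backbones (GBIF, WFO) is
  out of scope; an offline pass-through hook (a taxon-id mapping file) is
  the supported integration point.
* The comparison column records that sources disagree, not which is
  factually right; the engine encodes a precautionary policy, not
  adjudication.
* Statuses are per-jurisdiction scalars; sub-state distribution detail is
  not modelled beyond the combined-status condensation.
* The Darwin Core mapping is many-to-one and lossy by construction
  (`formerly_naturalised` → introduced/casual, for example); the unified
  vocabulary column remains the authoritative one.
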