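# afa — checklist harmonization for multi-jurisdiction plant censuses

Plant censuses are maintained independently by jurisdictional herbaria and
environment departments, each with its own status codes ("i", "?i", "N/I",
"Exotic [Aust]", …), its own taxonomy lag, and its own view of whether a
species is native, introduced or naturalised. At a national scale those
views disagree, and the disagreements matter: a species recorded as casual
in one source and naturalised in another needs the precautionary reading
for biosecurity planning.

`afa` is a harmonization engine for exactly this situation, modelled on the
Australian setting (eight state/territory censuses, a national reference
census with accepted names, synonyms and misapplications, and a GRIIS-style
introduced-species register). It:

1. converts each census's raw status codes to one unified invasion-status
   vocabulary via declarative, per-census YAML rule sets (first match wins);
2. resolves census names against the reference taxonomy — exact matching
   only, with synonym/misapplication links followed and pro-parte names
   kept only when they reach exactly one accepted taxon;
3. compares the two statuses per species and state, reporting every
   mismatch, and unifies them precautionarily: **the status that has
   advanced the furthest along the introduction–naturalisation–invasion
   continuum prevails** (introduced < naturalised < invasive; a native
   taxon naturalised elsewhere in its home state becomes *native
   colonising*);
4. integrates the per-state statuses into a national status by a six-tier
   precedence (native anywhere → native; else native colonising; else
   native potentially colonising; else uncertain origin; else the furthest
   present alien status; else what was lost: formerly naturalised >
   formerly introduced > presumed extinct);
5. cross-references the national status with the register, promoting alien
   taxa flagged invasive-on-impact to *harmful invasive*; and
6. writes per-state datasets, the national dataset (with Darwin Core
   `establishmentMeans` / `degreeOfEstablishment` equivalents) and full
   mismatch reports.

A synthetic-census generator (`afa.fixtures`) produces all three source
shapes with known ground truth, so the whole pipeline is testable without
downloading anything.

## Worked example

```
$ printf 'n_taxa: 50\nseed: 11\n' > fixture.yaml
$ afa fixture --spec fixture.yaml --out demo_data
fixture written under demo_data
$ afa build --config run.yaml     # paths to demo_data, see docs/methods.md
$ afa report --run out
state   agree  status_mismatch  census_only  reference_only  name_unresolved
ACT     21     0                1            4               1
NSW     18     1                1            2               2
NT      15     1                0            2               1
QLD     16     3                1            1               1
SA      18     0                0            2               0
TAS     16     0                1            4               2
VIC     17     0                1            2               1
WA      17     0                0            2               2
TOTAL   138    5                5            19              10
national records: 50
```

Reading the report: 138 species–state pairs agree between census and
reference; 5 disagree on status (the unified column in each
`out/state_*.csv` carries the precautionary resolution); 5 census entries
have no reference entry for that state (the census status stands); 19
reference entries are missing from a census (the reference status stands);
10 census names could not be resolved to exactly one accepted taxon and are
excluded from the unified outputs but listed in `out/problem_taxa.csv`.
The national dataset `out/afa_national.csv` has one row per accepted
reference taxon, e.g.

```
apc-00001,Gudizi munsi subsp. munba,...,ACT=introduced,NSW=native colonising,
QLD=naturalised,TAS=naturalised,WA=presumed extinct,...,
national_status=native colonising,afa_status=native colonising,
establishment_means=native
```

— native colonising in one state outranks being naturalised elsewhere, so
the taxon is native colonising nationally.

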