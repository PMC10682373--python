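# Victoria (VicFlora) codes, already Darwin Core shaped.
# occurrenceStatus: "excluded" deletes the record; "extinct" becomes
# formerly introduced when establishment_means is introduced, presumed
# extinct otherwise.  Native taxa with has_introduced_occurrences = 1 are
# native colonising.  degree_of_establishment: Casual = introduced,
# Established/Reproducing = naturalised; blank falls back on
# establishment_means (uncertain -> uncertain origin, introduced ->
# introduced).
census_id: VIC
name_column: scientific_name
rules:
  - when:
      occurrenceStatus: {equals: "excluded"}
    action: delete
  - when:
      occurrenceStatus: {equals: "extinct"}
      establishment_means: {equals: "introduced"}
    status: formerly_introduced
  - when:
      occurrenceStatus: {equals: "extinct"}
    status: presumed_extinct
  - when:
      establishment_means: {equals: "native"}
      has_introduced_occurrences: {equals: "1"}
    status: native_colonising
  - when:
      establishment_means: {equals: "native"}
    status: native
  - when:
      degree_of_establishment: {equals: "Casual"}
    status: introduced
  - when:
      degree_of_establishment: {any_of: ["Established", "Reproducing"]}
    status: naturalised
  - when:
      establishment_means: {equals: "uncertain"}
    status: uncertain_origin
  - when:
      establishment_means: {equals: "introduced"}
    status: introduced
default: uncertain_origin
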