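# Column layout and status conversion for the introduced-species register
# (GRIIS-style occurrence checklists).  Records flagged invasive on impact
# are relabelled "harmful invasive"; only kingdom Plantae is retained.
name_column: scientificName
kingdom_column: kingdom
keep_kingdoms: [Plantae]
rules:
  - when:
      isInvasive: {contains: "invasive", case_sensitive: false}
    status: harmful_invasive
  - when:
      establishmentMeans: {contains: "uncertain", case_sensitive: false}
    status: uncertain_origin
  - when:
      establishmentMeans: {contains: "introduced", case_sensitive: false}
    status: introduced
default: introduced
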