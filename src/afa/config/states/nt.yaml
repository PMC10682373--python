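# Northern Territory (FloraNT) codes, all in the "Introduced Status" column.
census_id: NT
name_column: scientific_name
rules:
  - when:
      "Introduced Status": {equals: "Formerly introduced to NT extinct"}
    status: formerly_introduced
  - when:
      "Introduced Status": {equals: "Native to NT"}
    status: native
  - when:
      "Introduced Status": {equals: "Introduced to NT"}
    status: introduced
  - when:
      "Introduced Status": {equals: "Status uncertain in NT"}
    status: uncertain_origin
default: uncertain_origin
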