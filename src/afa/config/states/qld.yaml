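# Queensland flora census codes in the "Origin_Status" column.
census_id: QLD
name_column: scientific_name
rules:
  - when:
      Origin_Status: {equals: "Native to QLD"}
    status: native
  - when:
      Origin_Status: {equals: "Native and naturalised in QLD"}
    status: native_colonising
  - when:
      Origin_Status: {equals: "Formerly naturalised in QLD"}
    status: formerly_naturalised
  - when:
      Origin_Status: {equals: "Doubtfully naturalised in QLD"}
    status: doubtfully_naturalised
  - when:
      Origin_Status: {equals: "Naturalised in QLD"}
    status: naturalised
default: uncertain_origin
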