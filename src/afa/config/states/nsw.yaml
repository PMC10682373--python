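# New South Wales (PlantNET) codes in the "natural/introduced" column.
census_id: NSW
name_column: scientific_name
rules:
  - when:
      "natural/introduced": {equals: "N"}
    status: native
  - when:
      "natural/introduced": {equals: "N/I"}
    status: native_colonising
  - when:
      "natural/introduced": {equals: "I"}
    status: introduced
default: uncertain_origin
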