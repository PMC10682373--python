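# Western Australia (FloraBase) codes.  NATURALISED_STATUS: "N" = native,
# "M" = native colonising, "A" = naturalised.  IS_CURRENT "N" (no longer
# current) combines with origin: formerly introduced if it was naturalised,
# presumed extinct if native or native colonising.
census_id: WA
name_column: scientific_name
rules:
  - when:
      IS_CURRENT: {equals: "N"}
      NATURALISED_STATUS: {equals: "A"}
    status: formerly_introduced
  - when:
      IS_CURRENT: {equals: "N"}
    status: presumed_extinct
  - when:
      NATURALISED_STATUS: {equals: "N"}
    status: native
  - when:
      NATURALISED_STATUS: {equals: "M"}
    status: native_colonising
  - when:
      NATURALISED_STATUS: {equals: "A"}
    status: naturalised
default: uncertain_origin
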