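# South Australia (BDBSA) codes.  INTRODUCED: blank = native, "*" =
# introduced.  Extinction is flagged free-text in "NPW ACT STATUS COMMENT":
# the bare code "EX" is matched case-sensitively, the word "extinct"
# case-insensitively (substring scan, so the comment column should carry
# status text only).
census_id: SA
name_column: scientific_name
rules:
  - when:
      "NPW ACT STATUS COMMENT": {contains: "EX", case_sensitive: true}
    status: presumed_extinct
  - when:
      "NPW ACT STATUS COMMENT": {contains: "extinct", case_sensitive: false}
    status: presumed_extinct
  - when:
      INTRODUCED: {equals: "*"}
    status: introduced
  - when:
      INTRODUCED: {blank: true}
    status: native
default: native
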