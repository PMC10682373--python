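# Tasmania census codes.  INTRO: blank = native, "i" = naturalised,
# "?i" = doubtfully naturalised.  EXTINCT "x" interacts with INTRO:
# extinct native -> presumed extinct; extinct naturalised -> formerly
# introduced.  First-match-wins ordering disambiguates.
census_id: TAS
name_column: scientific_name
rules:
  - when:
      EXTINCT: {equals: "x"}
      INTRO: {blank: true}
    status: presumed_extinct
  - when:
      EXTINCT: {equals: "x"}
      INTRO: {equals: "i"}
    status: formerly_introduced
  - when:
      INTRO: {equals: "i"}
    status: naturalised
  - when:
      INTRO: {equals: "?i"}
    status: doubtfully_naturalised
  - when:
      INTRO: {blank: true}
    status: native
default: native
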