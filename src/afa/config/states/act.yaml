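# Australian Capital Territory census codes.
# ORIGIN: blank = native; "Exotic [Aust]"/"Exotic [EA]" = introduced;
# "Indigenous/Exotic [Aust]" = native colonising.
# NATURALISED STATUS: "Doubtfully" = doubtfully naturalised;
# "Formerly" = formerly naturalised.
census_id: ACT
name_column: scientific_name
rules:
  - when:
      "NATURALISED STATUS": {equals: "Doubtfully"}
    status: doubtfully_naturalised
  - when:
      "NATURALISED STATUS": {equals: "Formerly"}
    status: formerly_naturalised
  - when:
      ORIGIN: {equals: "Indigenous/Exotic [Aust]"}
    status: native_colonising
  - when:
      ORIGIN: {any_of: ["Exotic [Aust]", "Exotic [EA]"]}
    status: introduced
  - when:
      ORIGIN: {blank: true}
    status: native
default: native
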