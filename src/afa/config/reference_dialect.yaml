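# Dialect of the packed "Distribution" string in the reference census:
# region-token spellings as they appear in the string, mapped to canonical
# region codes.  A bare region token means the taxon is native there; a
# parenthesised phrase carries the status, with "and" joining combined
# statuses ("Qld (native and naturalised)").
region_spellings:
  ACT: ACT
  NSW: NSW
  NT: NT
  Qld: QLD
  SA: SA
  Tas: TAS
  Vic: VIC
  WA: WA
  AR: AR
  CaI: CaI
  ChI: ChI
  CoI: CoI
  CSI: CSI
  HI: HI
  LHI: LHI
  MDI: MDI
  NI: NI
separator: ", "
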