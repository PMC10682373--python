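# Default mapping from the unified invasion-status vocabulary to the Darwin
# Core controlled vocabularies establishmentMeans / degreeOfEstablishment.
# degreeOfEstablishment applies to introduced occurrences only, so native-
# family statuses carry an empty degree.  Curators can override this table
# via the darwin_core path in the run config.
native: [native, ""]
native_potentially_colonising: [native, ""]
native_colonising: [native, ""]
uncertain_origin: [uncertain, ""]
doubtfully_introduced: [uncertain, casual]
introduced: [introduced, casual]
doubtfully_naturalised: [introduced, casual]
naturalised: [introduced, established]
harmful_invasive: [introduced, invasive]
formerly_naturalised: [introduced, casual]
formerly_introduced: [introduced, ""]
presumed_extinct: [native, ""]
absent: ["", ""]
deleted: ["", ""]
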