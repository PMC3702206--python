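{
  "_note": "Published wild-type (n=130) marginal signature counts for the DLBCL screening cohort; mutant-side counts come per-case from mutant_cases_signatures.tsv. WT case identifiers were not published, so only marginals are shipped.",
  "n_wt": 130,
  "coo": {"GCB": 51, "ABC": 47, "unclassified": 32},
  "mbl": {"mBL": 9, "non-mBL": 90, "intermediate": 31},
  "cc": {"BCR": 66, "HR": 38, "OxPhos": 16},
  "pap": {"BL-PAP": 10, "mind-L": 38, "PAP-1": 25, "PAP-2": 27, "PAP-3": 21, "PAP-4": 9}
}
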