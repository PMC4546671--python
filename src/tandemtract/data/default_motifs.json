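{
  "canonical": "ATTCT",
  "known_interruptions": ["ATTTTCT", "ATATTCT", "ATTCTCT", "ATTCTTCT", "ATTCC", "ATCCT", "ATCCC"],
  "minor": ["ACT", "ATC", "ATT", "ATCT", "ATTTCT", "ATTTCC", "ATCC"]
}
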