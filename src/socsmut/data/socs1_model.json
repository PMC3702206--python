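{
  "gene_symbol": "SOCS1",
  "_note": "Editable default model. The 636-bp CDS and the flanking context are a synthetic SOCS1-like stand-in sequence; domain boundaries are literature-style stand-ins and freely replaceable.",
  "cds": "ATGAGTTATACAGACTTCGCAGCCCATCTAGTCGAAACGTTGGCCGCGCCACGCAGCGGTCCACCATTTGAGATTTACGTGTTACGAATTGCAACAGTCTGTATCACGTCGTTCGCCCGGACGGCTCCAAAAACTCGTTCACCCCGGATGGGACTCTTCACAGGGGTTGTATCCGACGAGAGTCATGCCGTCGGACATAGCGGGCTTAGGCCCCCTCCGTGCTGCATGGTCGTTCCCGGCTTACGTATTTTCGAGGCTTTAGACCCCGGAAACACACTCCGCCCGGATATTGAACTGCTCCGGCAATCTAGCGCGAAGGACAGTTTTTCCCACCTACTTGCACACTTTAAAAAGAGGTCCCAGCAACACTCCACCTCGATGGATCCTCGGAGACGTGAGACTATGCTTTTTGCGATTGGTTGTAGCGGGGATTATATCAAATACCCGATACACGTACTGTGTATTTACATAGGGATTTTGGAGGTTCAGCCCCTCCATCGTACGCGTGCTTACAGGTCAGCAGTGAAAGATTGCTACCCATTACACGTAGGCGATTTCGAGCGGCGTGTAGTGTTTGTCCTATGGCAGTCACGCCCGCAGGCAAGGAAGTCGAGGTGTTACTTAAGGTTCGGGTGA",
  "cds_offset_in_exon2": 705,
  "upstream_context": "ACCCCCGGACGCTATGATATTTTT",
  "downstream_context": "ATCCTGACGGAATTATTTATAGAA",
  "domains": [
    {
      "name": "SH3",
      "aa_start": 10,
      "aa_end": 40,
      "is_cterminal": false
    },
    {
      "name": "KIR",
      "aa_start": 56,
      "aa_end": 67,
      "is_cterminal": false
    },
    {
      "name": "SH2",
      "aa_start": 79,
      "aa_end": 155,
      "is_cterminal": false
    },
    {
      "name": "JAK",
      "aa_start": 56,
      "aa_end": 155,
      "is_cterminal": false
    },
    {
      "name": "NLS",
      "aa_start": 158,
      "aa_end": 173,
      "is_cterminal": true
    },
    {
      "name": "SOCS box",
      "aa_start": 174,
      "aa_end": 210,
      "is_cterminal": true
    }
  ]
}
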