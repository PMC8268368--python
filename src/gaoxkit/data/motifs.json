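{
  "description": "Default plant cis-regulatory element library. Consensus strings are widely published literature consensi for the named elements; the library is config-replaceable and makes no claim of parity with any curated database.",
  "motifs": [
    {"name": "ABRE", "consensus": "ACGTG", "category": "ABA"},
    {"name": "G-Box", "consensus": "CACGTG", "category": "light"},
    {"name": "Box-4", "consensus": "ATTAAT", "category": "light"},
    {"name": "GT1-motif", "consensus": "GGTTAA", "category": "light"},
    {"name": "GARE-motif", "consensus": "TCTGTTG", "category": "GA"},
    {"name": "P-box", "consensus": "CCTTTTG", "category": "GA"},
    {"name": "TATC-box", "consensus": "TATCCCA", "category": "GA"},
    {"name": "TGA-element", "consensus": "AACGAC", "category": "auxin"},
    {"name": "AuxRR-core", "consensus": "GGTCCAT", "category": "auxin"},
    {"name": "TCA-element", "consensus": "CCATCTTTTT", "category": "SA"},
    {"name": "TGACG-motif", "consensus": "TGACG", "category": "MeJA"},
    {"name": "CGTCA-motif", "consensus": "CGTCA", "category": "MeJA"},
    {"name": "LTR", "consensus": "CCGAAA", "category": "low-temperature"},
    {"name": "TC-rich-repeats", "consensus": "GTTTTCTTAC", "category": "defense-and-stress"},
    {"name": "ARE", "consensus": "AAACCA", "category": "defense-and-stress"},
    {"name": "ABRE-coupling", "consensus": "CACGCGGC", "category": "ABA"}
  ]
}
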