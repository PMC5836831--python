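# Symbolic alleles used by the packaged marker tables, resolved per gene.
# The same token can denote different sequences in different genes (for CETP
# "18bp" is an 18-bp deletion allele; for F3 it is one of three insertions),
# so lookup is keyed by gene symbol.
inserts:
  CETP:
    18bp: gggcggacatacatatac
  F3:
    30bp: agaccttcataagaaataatcctgatccaa
    17bp: tgctgcgtactggcaaa
    18bp: acggcgtagagactggga
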