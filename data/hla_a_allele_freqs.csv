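# Two-field HLA-A allele frequencies in a published Lacandon Maya sample
# (218 individuals, 2N = 436 chromosomes); input for diversity recomputation.
allele,frequency
A*24:02,0.1904
A*31:01,0.1697
A*68:01,0.1445
A*02:06,0.1399
A*68:03,0.1376
A*02:01,0.0940
A*24:14,0.0550
A*68:05,0.0275
A*29:02,0.0115
A*03:01,0.0069
A*33:01,0.0046
A*30:01,0.0046
A*68:02,0.0046
A*01:01,0.0023
A*26:01,0.0023
A*30:02,0.0023
A*33:03,0.0023
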