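# Published Bw4-ligand frequency components in the Lacandon Maya sample:
# the aggregate frequency of Bw4-positive HLA-B alleles and the frequency of
# the Bw4-positive HLA-A allotype A*24:14.  Input for the KIR-ligand
# haplotype-fraction recomputation.
name,frequency,ligand
HLA-B Bw4 aggregate,0.0503,Bw4
A*24:14,0.0568,Bw4
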