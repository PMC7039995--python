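# KIR ligand classes for two-field HLA class I alleles.
# Bw4: ligand of KIR3DL1 (some HLA-B and some HLA-A allotypes).
# C1 / C2: HLA-C epitopes, ligands of KIR2DL2/3 and KIR2DL1.
# Editable: rows are allele<TAB>class; unlisted alleles count as "none".
A*23:01	Bw4
A*24:02	Bw4
A*24:14	Bw4
A*25:01	Bw4
A*32:01	Bw4
B*13:02	Bw4
B*27:05	Bw4
B*37:01	Bw4
B*38:01	Bw4
B*44:02	Bw4
B*44:03	Bw4
B*49:01	Bw4
B*51:01	Bw4
B*52:01	Bw4
B*53:01	Bw4
B*57:01	Bw4
B*58:01	Bw4
C*01:02	C1
C*03:03	C1
C*03:04	C1
C*03:05	C1
C*07:01	C1
C*07:02	C1
C*08:01	C1
C*08:02	C1
C*12:02	C1
C*16:01	C1
C*04:01	C2
C*05:01	C2
C*06:02	C2
C*15:02	C2
C*15:04	C2
C*15:15	C2
C*17:01	C2
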