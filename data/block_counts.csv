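# Chromosome counts for selected HLA blocks in the published Lacandon Maya
# sample (2N = 436): n_pair chromosomes carry both units, n_left / n_right
# carry each unit.  Input for the linkage-disequilibrium recomputation.
left,right,n_pair,n_left,n_right,two_n
B*40:08,C*03:04,29,29,122,436
B*18:01,C*07:01,12,12,15,436
A*24:02,B*40:02~C*15:02~DRB1*14:06~DQB1*03:01,14,83,14,436
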