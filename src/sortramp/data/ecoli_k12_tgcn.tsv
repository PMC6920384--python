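# E. coli K-12 MG1655 tRNA gene copy numbers by genomic anticodon (5'->3', DNA
# alphabet), GtRNAdb-derived.  Met-CAT counts elongator + initiator genes; the
# lysidine-modified AUA-reading ileX tRNA is handled separately (TaiModel
# lysidine_copies) because its genomic anticodon collides with Met-CAT.
# The selenocysteine tRNA (selC, TCA) is excluded.
anticodon	copies
GGC	2
TGC	3
ACG	4
CCG	1
CCT	1
TCT	1
GTT	4
GTC	3
GCA	1
CTG	2
TTG	2
TTC	4
CCC	1
GCC	4
TCC	1
GTG	1
GAT	3
CAA	1
CAG	4
GAG	1
TAA	1
TAG	1
TTT	6
CAT	4
GAA	2
CGG	1
GGG	2
TGG	1
CGA	1
GCT	1
GGA	2
TGA	1
CGT	1
GGT	2
TGT	1
CCA	1
GTA	3
GAC	2
TAC	5
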