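# tRNA gene copy numbers by anticodon (DNA alphabet); approximate
# representative values for E. coli K-12-type genomes
anticodon	copies
ACG	4
CAA	1
CAG	4
CAT	8
CCA	1
CCC	1
CCG	1
CCT	1
CGA	1
CGG	1
CGT	1
CTG	2
GAA	2
GAC	2
GAG	1
GAT	3
GCA	1
GCC	4
GCT	1
GGA	2
GGC	2
GGG	1
GGT	2
GTA	3
GTC	3
GTG	1
GTT	4
TAA	1
TAC	2
TAG	1
TCC	1
TCT	1
TGA	1
TGC	3
TGG	1
TGT	1
TTC	4
TTG	2
TTT	6
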