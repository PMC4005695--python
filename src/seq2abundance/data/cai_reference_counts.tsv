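# CAI reference set codon counts, constructed stand-in for a
# highly-expressed-gene reference table
codon	count
AAA	300
AAC	300
AAG	100
AAT	100
ACA	40
ACC	300
ACG	40
ACT	100
AGA	40
AGC	100
AGG	40
AGT	40
ATA	40
ATC	300
ATG	300
ATT	100
CAA	100
CAC	300
CAG	300
CAT	100
CCA	100
CCC	40
CCG	300
CCT	40
CGA	40
CGC	100
CGG	40
CGT	300
CTA	40
CTC	40
CTG	300
CTT	40
GAA	300
GAC	300
GAG	100
GAT	100
GCA	100
GCC	40
GCG	40
GCT	300
GGA	40
GGC	100
GGG	40
GGT	300
GTA	100
GTC	40
GTG	40
GTT	300
TAC	300
TAT	100
TCA	40
TCC	40
TCG	40
TCT	300
TGC	300
TGG	300
TGT	100
TTA	100
TTC	300
TTG	40
TTT	100
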