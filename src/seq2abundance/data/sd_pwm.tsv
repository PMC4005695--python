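# Shine-Dalgarno position frequency matrix (counts), constructed
# consensus-based synthetic stand-in; rows A,C,G,T x 6 positions
base	1	2	3	4	5	6
A	70	10	8	70	10	15
C	5	5	4	5	5	5
G	15	75	80	15	75	60
T	10	10	8	10	10	20
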