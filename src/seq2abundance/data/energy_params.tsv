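# seq2abundance simplified nearest-neighbor energy set, v1
# constructed parameterization (stacks + hairpin penalties + dangles), kcal/mol
# schema: kind	k1	k2	k3	value
kind	k1	k2	k3	value
stack	AT	AT	.	-1.51
stack	AT	TA	.	-1.40
stack	AT	GC	.	-2.12
stack	AT	CG	.	-2.23
stack	AT	GT	.	-1.24
stack	AT	TG	.	-1.18
stack	TA	AT	.	-1.40
stack	TA	TA	.	-1.29
stack	TA	GC	.	-2.01
stack	TA	CG	.	-2.11
stack	TA	GT	.	-1.12
stack	TA	TG	.	-1.07
stack	GC	AT	.	-2.12
stack	GC	TA	.	-2.01
stack	GC	GC	.	-2.72
stack	GC	CG	.	-2.83
stack	GC	GT	.	-1.84
stack	GC	TG	.	-1.79
stack	CG	AT	.	-2.23
stack	CG	TA	.	-2.11
stack	CG	GC	.	-2.83
stack	CG	CG	.	-2.94
stack	CG	GT	.	-1.95
stack	CG	TG	.	-1.90
stack	GT	AT	.	-1.24
stack	GT	TA	.	-1.12
stack	GT	GC	.	-1.84
stack	GT	CG	.	-1.95
stack	GT	GT	.	-0.96
stack	GT	TG	.	-0.91
stack	TG	AT	.	-1.18
stack	TG	TA	.	-1.07
stack	TG	GC	.	-1.79
stack	TG	CG	.	-1.90
stack	TG	GT	.	-0.91
stack	TG	TG	.	-0.85
hairpin	3	.	.	4.50
hairpin	4	.	.	4.85
hairpin	5	.	.	5.11
hairpin	6	.	.	5.33
hairpin	7	.	.	5.52
hairpin	8	.	.	5.68
hairpin	9	.	.	5.82
hairpin	10	.	.	5.94
hairpin	11	.	.	6.06
hairpin	12	.	.	6.16
hairpin	13	.	.	6.26
hairpin	14	.	.	6.35
hairpin	15	.	.	6.43
hairpin	16	.	.	6.51
hairpin	17	.	.	6.58
hairpin	18	.	.	6.65
hairpin	19	.	.	6.71
hairpin	20	.	.	6.78
hairpin	21	.	.	6.84
hairpin	22	.	.	6.89
hairpin	23	.	.	6.94
hairpin	24	.	.	7.00
hairpin	25	.	.	7.04
hairpin	26	.	.	7.09
hairpin	27	.	.	7.14
hairpin	28	.	.	7.18
hairpin	29	.	.	7.22
hairpin	30	.	.	7.26
dangle	AT	A	5p	-0.28
dangle	AT	A	3p	-0.33
dangle	AT	C	5p	-0.32
dangle	AT	C	3p	-0.37
dangle	AT	G	5p	-0.35
dangle	AT	G	3p	-0.40
dangle	AT	T	5p	-0.24
dangle	AT	T	3p	-0.29
dangle	TA	A	5p	-0.28
dangle	TA	A	3p	-0.33
dangle	TA	C	5p	-0.32
dangle	TA	C	3p	-0.37
dangle	TA	G	5p	-0.35
dangle	TA	G	3p	-0.40
dangle	TA	T	5p	-0.24
dangle	TA	T	3p	-0.29
dangle	GC	A	5p	-0.38
dangle	GC	A	3p	-0.42
dangle	GC	C	5p	-0.42
dangle	GC	C	3p	-0.47
dangle	GC	G	5p	-0.45
dangle	GC	G	3p	-0.50
dangle	GC	T	5p	-0.34
dangle	GC	T	3p	-0.39
dangle	CG	A	5p	-0.38
dangle	CG	A	3p	-0.42
dangle	CG	C	5p	-0.42
dangle	CG	C	3p	-0.47
dangle	CG	G	5p	-0.45
dangle	CG	G	3p	-0.50
dangle	CG	T	5p	-0.34
dangle	CG	T	3p	-0.39
dangle	GT	A	5p	-0.38
dangle	GT	A	3p	-0.42
dangle	GT	C	5p	-0.42
dangle	GT	C	3p	-0.47
dangle	GT	G	5p	-0.45
dangle	GT	G	3p	-0.50
dangle	GT	T	5p	-0.34
dangle	GT	T	3p	-0.39
dangle	TG	A	5p	-0.38
dangle	TG	A	3p	-0.42
dangle	TG	C	5p	-0.42
dangle	TG	C	3p	-0.47
dangle	TG	G	5p	-0.45
dangle	TG	G	3p	-0.50
dangle	TG	T	5p	-0.34
dangle	TG	T	3p	-0.39
const	duplex_init	.	.	4.1
const	min_hairpin	.	.	3
const	loop_base	.	.	3.0
const	loop_per_nt	.	.	0.5
const	max_loop	.	.	3
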