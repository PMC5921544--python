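#probe=PHA
#target=GSO
# PHA whole-chromosome probes on Glossophaga soricina (2n=32, FN=60)
1	0	1	1
2	0	4	1
3	0	2	1
4	0	3	1
5	0	5	1
6	0	6	1
7	0	7	1
8	0	11	1
8	1	12	1
9	0	8	1
10	0	9	1
11	0	10	1
12	0	15	1
12	1	12	1
13	0	13	1
14	0	14	1
15	0	13	1
X	0	X	1
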