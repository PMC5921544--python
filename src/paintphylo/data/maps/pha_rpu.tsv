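#probe=PHA
#target=RPU
# PHA whole-chromosome probes on Rhinophylla pumilio (2n=34, FN=62)
1	0	1	1
2	0	2	1
3	0	4	1
4	0	3	1
5	0	5	1
6	0	6	1
7	0	7	1
8	0	8	1
9	0	9	1
10	0	10	1
11	0	11	1
12	0	12	1
13	0	13	1
14	0	14	1
15p	0	.	0
15q	0	13	1
16	0	15	1
X	0	X	1
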