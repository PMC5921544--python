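#probe=PHA
#target=RFI
# PHA whole-chromosome probes on Rhinophylla aff. fischerae (2n=38, FN=68)
1	0	8	1
1	1	5	1
2	0	2	1
2	1	3	1
3	0	6	1
3	1	4	1
4	0	8	1
4	1	7	1
5	0	6	1
6	0	1	1
7	0	1	1
8	0	3	1
9	0	9	1
10	0	11	1
11	0	12	1
12	0	14	1
13	0	10	1
13	1	13	1
14	0	4	1
15	0	2	1
16p	0	15	1
16q	0	.	0
17	0	7	1
18	0	13	1
X	0	X	1
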