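#probe=PHA
#target=TNI
# PHA whole-chromosome probes on Trinycteris nicefori (2n=28, FN=52)
1	0	1	1
2	0	4	1
2	1	3	1
3	0	3	1
3	1	2	1
4	0	5	1
4	1	2	1
5	0	6	1
6	0	7	1
7	0	8	1
8	0	9	1
9	0	10	1
10	0	11	1
11	0	12	1
11	1	15	1
11	2	14	1
12	0	13	1
12	1	5	1
13	0	13	1
13	1	4	1
X	0	X	1
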