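#probe=CBR
#target=GSO
# CBR whole-chromosome probes on Glossophaga soricina
1	0	3	1
1	1	4	1
2	0	2	1
2	1	5	1
3	0	2	1
3	1	Y2	1
3	2	2	1
3	3	Y2	1
4	0	1	1
5	0	1	1
6	0	1	1
6	1	Y2	1
7	0	3	1
7	1	1	1
8	0	7	1
8	1	6	1
9	0	4	1
9	1	2	1
10	0	2	1
10	1	1	1
11	0	3	1
12	0	6	1
13	0	8	1
14	0	9	1
15	0	5	1
X	0	X	1
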