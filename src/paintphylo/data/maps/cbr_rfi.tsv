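#probe=CBR
#target=RFI
# CBR whole-chromosome probes on Rhinophylla aff. fischerae
# RFI 16q is fully heterochromatic (unpainted block retained)
1	0	2	1
1	1	1	1
2	0	2	1
2	1	Y2	1
2	2	2	1
2	3	1	1
3	0	1	1
3	1	5	1
4	0	4	1
4	1	3	1
5	0	Y2	1
6	0	3	1
7	0	4	1
8	0	1	1
9	0	2	1
9	1	1	1
10	0	7	1
11	0	6	1
12	0	9	1
13	0	3	1
13	1	8	1
14	0	2	1
15	0	2	1
15	1	Y2	1
15	2	2	1
16p	0	6	1
16q	0	.	0
17	0	1	1
18	0	5	1
X	0	X	1
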