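#probe=CBR
#target=TNI
# CBR whole-chromosome probes on Trinycteris nicefori
1	0	4	1
1	1	3	1
2	0	2	1
2	1	1	1
3	0	1	1
3	1	Y2	1
4	0	1	1
4	1	2	1
5	0	1	1
5	1	Y2	1
6	0	3	1
6	1	1	1
7	0	4	1
7	1	2	1
8	0	2	1
8	1	1	1
9	0	3	1
10	0	7	1
11	0	6	1
11	1	9	1
12	0	8	1
12	1	1	1
13	0	5	1
X	0	X	1
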