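#probe=HSA
#target=GSO
# SYNTHETIC stand-in for the published human-probe map of Glossophaga
# soricina, assembled from the correspondences stated in text: HSA 4/10/4 and
# 14/15/14/15 on GSO 1 (PHA 1p/1q), HSA 5/7/16 on GSO 4q (PHA 3q), HSA 13/8/4
# on the PHA 11 portion of GSO 8, HSA 18/20 on GSO 10 (PHA 9), HSA 7a/7b on
# GSO 11 (PHA 10).  Regions with no stated human homology are encoded as
# unpainted placeholders.
1p	0	4	1
1p	1	10	1
1p	2	4	1
1q	0	14	1
1q	1	15	1
1q	2	14	1
1q	3	15	1
4p	0	.	0
4q	0	5	1
4q	1	7	1
4q	2	16	1
8	0	13	1	1
8	1	8	1	1
8	2	4	1	1
8	3	.	0	1
10	0	18	1
10	1	20	1
11	0	7a	1
11	1	7b	1
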