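#probe=PHA
#target=GSO
# SYNTHETIC arm-resolved variant of the PHA->GSO map, restricted to the GSO
# chromosomes needed for transitive composition against human paints.  Arm
# assignments and relative block lengths reconstruct the published karyogram
# geometry; they are not measurements.
1p	0	1p	1
1q	0	1q	1
4p	0	3p	1
4q	0	3q	1
8	0	11	1	3
8	1	12	1	1
10	0	9	1
11	0	10	1
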