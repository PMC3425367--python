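# Indium (Z=49), neutral-atom subshell binding energies.
# Z+1 neighbour of cadmium, used by the z_plus_one energy model.
# Provenance: K-N5 transcribed from the X-ray Data Booklet (LBNL, 2009,
# after Bearden & Burr); N3 nudged 73.5 -> 73.4 eV to keep the table
# strictly ordered (degenerate at the printed precision); O1/O2 nominal.
[element]
Z	valence
49	O1,O2
[subshells]
label	principal	capacity	occupancy	binding_eV
K	K	2	2	27940
L1	L	2	2	4238
L2	L	2	2	3938
L3	L	4	4	3730
M1	M	2	2	827.2
M2	M	2	2	703.2
M3	M	4	4	665.3
M4	M	4	4	451.4
M5	M	6	6	443.9
N1	N	2	2	122.9
N2	N	2	2	73.5
N3	N	4	4	73.4
N4	N	4	4	17.7
N5	N	6	6	16.9
O1	O	2	2	8.5
O2	O	2	1	5.8
[radiative]
X	Y	rate
[nonradiative]
X	Y	Z	rate
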