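# Ruthenium (Z=44), neutral-atom subshell binding energies.
# Z+1 neighbour of technetium, used by the z_plus_one energy model.
# Provenance: K-N3 transcribed from the X-ray Data Booklet (LBNL, 2009,
# after Bearden & Burr); N4/N5 and O1 nominal (see tc.tsv header).
[element]
Z	valence
44	O1
[subshells]
label	principal	capacity	occupancy	binding_eV
K	K	2	2	22117
L1	L	2	2	3224
L2	L	2	2	2967
L3	L	4	4	2838
M1	M	2	2	586.1
M2	M	2	2	483.5
M3	M	4	4	461.4
M4	M	4	4	284.2
M5	M	6	6	280.0
N1	N	2	2	75.0
N2	N	2	2	46.3
N3	N	4	4	43.2
N4	N	4	4	9.0
N5	N	6	3	8.8
O1	O	2	1	7.0
[radiative]
X	Y	rate
[nonradiative]
X	Y	Z	rate
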