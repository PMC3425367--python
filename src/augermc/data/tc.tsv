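# Technetium (Z=43), neutral-atom subshell binding energies.
# Provenance: K-N3 transcribed from the X-ray Data Booklet (LBNL, 2009,
# after Bearden & Burr); N4/N5 and O1 are not tabulated there and carry
# nominal few-eV values (outermost shells, below the 10 eV spectrum bin).
# No transition rates are bundled: single-vacancy rate libraries are
# distributed separately and loaded through the same dialect.
[element]
Z	valence
43	O1
[subshells]
label	principal	capacity	occupancy	binding_eV
K	K	2	2	21044
L1	L	2	2	3043
L2	L	2	2	2793
L3	L	4	4	2677
M1	M	2	2	544.0
M2	M	2	2	447.6
M3	M	4	4	417.7
M4	M	4	4	257.6
M5	M	6	6	253.9
N1	N	2	2	69.5
N2	N	2	2	42.3
N3	N	4	4	39.9
N4	N	4	4	8.0
N5	N	6	1	7.8
O1	O	2	2	6.5
[radiative]
X	Y	rate
[nonradiative]
X	Y	Z	rate
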