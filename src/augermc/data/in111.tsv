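# In-111 decay scheme: electron capture to Cd-111 (Z=48) followed by the
# 171/245 keV gamma cascade converting in cadmium.
# SYNTHETIC RECONSTRUCTION: occurrence intensities and conversion
# coefficients reconstructed from evaluated per-decay emission intensities
# (DDEP-scale values); subshell splits chosen to reproduce the evaluated
# principal-shell mean conversion-electron energies.  EC capture-ratio
# factors are adopted at Schonfeld-scale magnitudes.  Not a BrIcc export.
[parent]
nuclide	halflife	mode	daughter_Z	converter_Z
In-111	2.805 d	EC	48	48
[ec_branches]
q_plus_keV	level_keV	intensity	ratios
862.0	416.638	1.0	kLK=0.095,kML=0.20,kNM=0.22,kON=0.08
[transitions]
id	energy_keV	gamma_intensity	recoil_keV	icc_K	icc_L1	icc_L2	icc_L3	icc_M1	icc_M2	icc_M3	icc_M4	icc_M5	icc_N1	icc_N2	icc_N3	icc_O1
g1	150.81	3.3e-5	0	0.07
g2	171.28	0.9999	0	0.08973	0.009456	0.001013	0.000788	0.0017394	0.00021742	0.00013045	4.348e-5	4.348e-5	3.06e-4	6.1e-5	4.1e-5	2.65e-5
g3	245.35	1.0	0	0.05345	0.0050316	0.0020965	0.0012579	0.00080250	0.000321	0.00024075	0.00016050	0.00008025	1.6452e-4	6.855e-5	4.113e-5	1.275e-5
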