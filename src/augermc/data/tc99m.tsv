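# Tc-99m decay scheme (isomeric transition cascade in technetium, Z=43).
# SYNTHETIC RECONSTRUCTION: per-transition occurrence intensities and
# conversion coefficients are reconstructed from evaluated per-decay
# emission intensities (DDEP-scale values); subshell splits of the
# principal-shell coefficients are chosen to reproduce the evaluated
# principal-shell mean conversion-electron energies.  Not a BrIcc export.
# gamma_intensity = occurrence probability of the transition per decay;
# the photon share is gamma_intensity / (1 + sum of allowed alpha_X).
[parent]
nuclide	halflife	mode	converter_Z
Tc-99m	6.007 h	IT	43
[transitions]
id	energy_keV	gamma_intensity	recoil_keV	icc_K	icc_L1	icc_L2	icc_L3	icc_M1	icc_M2	icc_M3	icc_M4	icc_M5	icc_N1	icc_N2	icc_N3	icc_N4	icc_N5	icc_O1
g1	2.1726	0.9902	0					4.2e7	1.2e7	1.8e7	3.0e7	1.8e7	4.731e6	3.154e6	3.154e6	2.3655e6	2.3655e6	342
g2	140.511	0.9915	0	0.09870	0.010212	0.0012014	0.00060	0.0017424	0.0002178	0.000131	0.0000436	0.0000436	2.8e-4	4.3e-5	2.84e-5			2.39e-5
g3	142.683	0.00927	0	26.04	6.97	0.82	0.41	1.28	0.16	0.096	0.032	0.032	0.196	0.029	0.0198			0.006
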