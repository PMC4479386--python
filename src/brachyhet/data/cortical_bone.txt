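# material: cortical_bone
# density_g_cm3: 1.85
# Z_over_A: 0.51478
# provenance: mu_over_rho (total, with coherent) and mu_en_over_rho
#   transcribed from the NIST / Hubbell-Seltzer mass attenuation and
#   mass energy-absorption coefficient tables (liquid water; ICRP
#   cortical bone).  photoelectric_fraction derived as
#   1 - sigma_KN(E)*N_A*(Z/A)/(mu/rho), i.e. every non-Compton
#   interaction is treated as local absorption.
# columns: energy_MeV mu_over_rho mu_en_over_rho photoelectric_fraction
0.010 28.51 26.8 0.993036
0.015 9.032 8.388 0.978412
0.020 4.001 3.601 0.952117
0.030 1.331 1.07 0.860836
0.040 0.6655 0.4507 0.730408
0.050 0.4242 0.2336 0.589648
0.060 0.3148 0.14 0.462686
0.080 0.2229 0.06896 0.280563
0.100 0.1855 0.04585 0.176518
0.150 0.148 0.03183 0.070803
0.200 0.1309 0.03003 0.037336
0.300 0.1113 0.03032 0.015523
0.400 0.09908 0.03069 0.009153
0.500 0.09022 0.03073 0.006387
0.600 0.08332 0.03052 0.004726
0.800 0.07308 0.02973 0.003293
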