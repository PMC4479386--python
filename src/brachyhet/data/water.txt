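# material: water
# density_g_cm3: 1.0
# Z_over_A: 0.55509
# provenance: mu_over_rho (total, with coherent) and mu_en_over_rho
#   transcribed from the NIST / Hubbell-Seltzer mass attenuation and
#   mass energy-absorption coefficient tables (liquid water; ICRP
#   cortical bone).  photoelectric_fraction derived as
#   1 - sigma_KN(E)*N_A*(Z/A)/(mu/rho), i.e. every non-Compton
#   interaction is treated as local absorption.
# columns: energy_MeV mu_over_rho mu_en_over_rho photoelectric_fraction
0.010 5.329 4.944 0.959824
0.015 1.673 1.374 0.874327
0.020 0.8096 0.5503 0.744834
0.030 0.3756 0.1557 0.468232
0.040 0.2683 0.06947 0.278933
0.050 0.2269 0.04223 0.172753
0.060 0.2059 0.0319 0.114175
0.080 0.1837 0.02597 0.058684
0.100 0.1707 0.02546 0.035047
0.150 0.1505 0.02764 0.014686
0.200 0.137 0.02967 0.008174
0.300 0.1186 0.03192 0.003774
0.400 0.1061 0.03279 0.002256
0.500 0.09687 0.03299 0.002133
0.600 0.08956 0.03284 0.001566
0.800 0.07865 0.03206 0.001360
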