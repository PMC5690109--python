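# beryllium: photon mass attenuation / mass energy-absorption coefficients
# NIST (Hubbell & Seltzer) provenance; see DATA_SOURCES.md
# energy_keV mu_over_rho muen_over_rho   [cm^2/g]
   1.0000 6.041000e+02 6.004000e+02
   1.5000 1.797000e+02 1.785000e+02
   2.0000 7.469000e+01 7.380000e+01
   3.0000 2.127000e+01 2.066000e+01
   4.0000 8.685000e+00 8.211000e+00
   5.0000 4.369000e+00 3.988000e+00
   6.0000 2.527000e+00 2.188000e+00
   8.0000 1.124000e+00 8.548000e-01
  10.0000 6.466000e-01 4.945000e-01
  15.0000 3.070000e-01 1.902000e-01
  20.0000 2.251000e-01 8.686000e-02
  30.0000 1.792000e-01 4.360000e-02
  40.0000 1.640000e-01 3.262000e-02
  50.0000 1.554000e-01 2.913000e-02
  60.0000 1.493000e-01 2.759000e-02
  80.0000 1.401000e-01 2.647000e-02
 100.0000 1.328000e-01 2.580000e-02
 150.0000 1.190000e-01 2.430000e-02
 200.0000 1.089000e-01 2.310000e-02
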