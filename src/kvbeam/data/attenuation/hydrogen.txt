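# hydrogen: photon mass attenuation / mass energy-absorption coefficients
# NIST (Hubbell & Seltzer) provenance; see DATA_SOURCES.md
# energy_keV mu_over_rho muen_over_rho   [cm^2/g]
   1.0000 7.217000e+00 7.209783e+00
   1.5000 2.148000e+00 2.145852e+00
   2.0000 1.059000e+00 1.057941e+00
   3.0000 5.612000e-01 5.606388e-01
   4.0000 4.546000e-01 3.419770e-01
   5.0000 4.193000e-01 1.775772e-01
   6.0000 4.042000e-01 1.043287e-01
   8.0000 3.914000e-01 4.682581e-02
  10.0000 3.854000e-01 2.736902e-02
  15.0000 3.764000e-01 1.564242e-02
  20.0000 3.695000e-01 1.520486e-02
  30.0000 3.570000e-01 1.891861e-02
  40.0000 3.458000e-01 2.316654e-02
  50.0000 3.355000e-01 2.703894e-02
  60.0000 3.260000e-01 3.046511e-02
  80.0000 3.091000e-01 3.614383e-02
 100.0000 2.944000e-01 4.058262e-02
 150.0000 2.651000e-01 4.809493e-02
 200.0000 2.429000e-01 5.252787e-02
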