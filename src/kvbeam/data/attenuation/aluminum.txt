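# aluminum: photon mass attenuation / mass energy-absorption coefficients
# NIST (Hubbell & Seltzer) provenance; see DATA_SOURCES.md
# energy_keV mu_over_rho muen_over_rho   [cm^2/g]
   1.0000 1.185000e+03 1.183000e+03
   1.5000 4.022000e+02 4.001000e+02
   1.5596 3.621000e+02 3.600000e+02
   1.5597 3.957000e+03 3.829000e+03
   2.0000 2.263000e+03 2.204000e+03
   3.0000 7.880000e+02 7.732000e+02
   4.0000 3.605000e+02 3.545000e+02
   5.0000 1.934000e+02 1.902000e+02
   6.0000 1.153000e+02 1.133000e+02
   8.0000 5.033000e+01 4.918000e+01
  10.0000 2.623000e+01 2.543000e+01
  15.0000 7.955000e+00 7.487000e+00
  20.0000 3.441000e+00 3.094000e+00
  30.0000 1.128000e+00 8.778000e-01
  40.0000 5.685000e-01 3.601000e-01
  50.0000 3.681000e-01 1.840000e-01
  60.0000 2.778000e-01 1.099000e-01
  80.0000 2.018000e-01 5.511000e-02
 100.0000 1.704000e-01 3.794000e-02
 150.0000 1.378000e-01 2.827000e-02
 200.0000 1.223000e-01 2.745000e-02
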