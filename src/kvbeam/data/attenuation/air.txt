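# air: photon mass attenuation / mass energy-absorption coefficients
# NIST (Hubbell & Seltzer) provenance; see DATA_SOURCES.md
# energy_keV mu_over_rho muen_over_rho   [cm^2/g]
   1.0000 3.606000e+03 3.599000e+03
   1.5000 1.191000e+03 1.188000e+03
   2.0000 5.279000e+02 5.262000e+02
   3.0000 1.625000e+02 1.614000e+02
   4.0000 7.788000e+01 7.636000e+01
   5.0000 4.027000e+01 3.931000e+01
   6.0000 2.341000e+01 2.270000e+01
   8.0000 9.921000e+00 9.446000e+00
  10.0000 5.120000e+00 4.742000e+00
  15.0000 1.614000e+00 1.334000e+00
  20.0000 7.779000e-01 5.389000e-01
  30.0000 3.538000e-01 1.537000e-01
  40.0000 2.485000e-01 6.833000e-02
  50.0000 2.080000e-01 4.098000e-02
  60.0000 1.875000e-01 3.041000e-02
  80.0000 1.662000e-01 2.407000e-02
 100.0000 1.541000e-01 2.325000e-02
 150.0000 1.356000e-01 2.496000e-02
 200.0000 1.233000e-01 2.672000e-02
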