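# oxygen: photon mass attenuation / mass energy-absorption coefficients
# NIST (Hubbell & Seltzer) provenance; see DATA_SOURCES.md
# energy_keV mu_over_rho muen_over_rho   [cm^2/g]
   1.0000 4.590000e+03 4.140689e+03
   1.5000 1.549000e+03 1.366807e+03
   2.0000 6.949000e+02 6.053988e+02
   3.0000 2.171000e+02 1.856924e+02
   4.0000 9.315000e+01 8.785297e+01
   5.0000 4.790000e+01 4.522651e+01
   6.0000 2.770000e+01 2.611648e+01
   8.0000 1.163000e+01 1.086751e+01
  10.0000 5.952000e+00 5.455393e+00
  15.0000 1.836000e+00 1.534164e+00
  20.0000 8.651000e-01 6.191331e-01
  30.0000 3.779000e-01 1.755179e-01
  40.0000 2.585000e-01 7.693648e-02
  50.0000 2.132000e-01 4.516196e-02
  60.0000 1.907000e-01 3.273531e-02
  80.0000 1.678000e-01 2.500707e-02
 100.0000 1.551000e-01 2.372730e-02
 150.0000 1.361000e-01 2.512830e-02
 200.0000 1.232000e-01 2.681996e-02
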