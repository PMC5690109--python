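# argon: photon mass attenuation / mass energy-absorption coefficients
# NIST (Hubbell & Seltzer) provenance; see DATA_SOURCES.md
# energy_keV mu_over_rho muen_over_rho   [cm^2/g]
   1.0000 3.184000e+03 3.180816e+03
   1.5000 1.105000e+03 1.103895e+03
   2.0000 5.120000e+02 5.114880e+02
   3.0000 1.703000e+02 1.701297e+02
   3.2029 1.423000e+02 1.421577e+02
   3.2030 1.275000e+03 1.273725e+03
   4.0000 7.572000e+02 7.564428e+02
   5.0000 4.225000e+02 4.220775e+02
   6.0000 2.593000e+02 2.590407e+02
   8.0000 1.180000e+02 1.115371e+02
  10.0000 6.266000e+01 5.597968e+01
  15.0000 1.955000e+01 1.571434e+01
  20.0000 8.629000e+00 6.305683e+00
  30.0000 2.697000e+00 1.723321e+00
  40.0000 1.228000e+00 6.874327e-01
  50.0000 7.012000e-01 3.410178e-01
  60.0000 4.664000e-01 1.960996e-01
  80.0000 2.760000e-01 8.861638e-02
 100.0000 2.043000e-01 5.379503e-02
 150.0000 1.427000e-01 3.185357e-02
 200.0000 1.205000e-01 2.792934e-02
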