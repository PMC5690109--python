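# carbon: photon mass attenuation / mass energy-absorption coefficients
# NIST (Hubbell & Seltzer) provenance; see DATA_SOURCES.md
# energy_keV mu_over_rho muen_over_rho   [cm^2/g]
   1.0000 2.211000e+03 1.745144e+03
   1.5000 7.002000e+02 5.760576e+02
   2.0000 3.026000e+02 2.551528e+02
   3.0000 9.246000e+01 7.826243e+01
   4.0000 3.945000e+01 3.702687e+01
   5.0000 2.025000e+01 1.906154e+01
   6.0000 1.173000e+01 1.100753e+01
   8.0000 4.933000e+00 4.581031e+00
  10.0000 2.373000e+00 2.300446e+00
  15.0000 8.071000e-01 6.488775e-01
  20.0000 4.420000e-01 2.642312e-01
  30.0000 2.562000e-01 7.899030e-02
  40.0000 2.076000e-01 3.887529e-02
  50.0000 1.871000e-01 2.670057e-02
  60.0000 1.753000e-01 2.251103e-02
  80.0000 1.610000e-01 2.096095e-02
 100.0000 1.514000e-01 2.174161e-02
 150.0000 1.347000e-01 2.455048e-02
 200.0000 1.229000e-01 2.656679e-02
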