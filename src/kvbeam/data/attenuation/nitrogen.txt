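# nitrogen: photon mass attenuation / mass energy-absorption coefficients
# NIST (Hubbell & Seltzer) provenance; see DATA_SOURCES.md
# energy_keV mu_over_rho muen_over_rho   [cm^2/g]
   1.0000 3.311000e+03 2.772378e+03
   1.5000 1.083000e+03 9.151391e+02
   2.0000 4.769000e+02 4.053419e+02
   3.0000 1.456000e+02 1.243295e+02
   4.0000 6.166000e+01 5.882162e+01
   5.0000 3.144000e+01 3.028134e+01
   6.0000 1.809000e+01 1.748639e+01
   8.0000 7.562000e+00 7.276715e+00
  10.0000 3.879000e+00 3.653293e+00
  15.0000 1.236000e+00 1.028469e+00
  20.0000 6.178000e-01 4.163918e-01
  30.0000 3.066000e-01 1.203661e-01
  40.0000 2.288000e-01 5.518637e-02
  50.0000 1.980000e-01 3.461137e-02
  60.0000 1.817000e-01 2.689278e-02
  80.0000 1.639000e-01 2.269761e-02
 100.0000 1.529000e-01 2.259739e-02
 150.0000 1.353000e-01 2.480625e-02
 200.0000 1.229000e-01 2.668520e-02
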