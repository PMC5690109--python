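# water: photon mass attenuation / mass energy-absorption coefficients
# NIST (Hubbell & Seltzer) provenance; see DATA_SOURCES.md
# energy_keV mu_over_rho muen_over_rho   [cm^2/g]
   1.0000 4.078000e+03 4.065000e+03
   1.5000 1.376000e+03 1.372000e+03
   2.0000 6.173000e+02 6.152000e+02
   3.0000 1.929000e+02 1.917000e+02
   4.0000 8.278000e+01 8.191000e+01
   5.0000 4.258000e+01 4.188000e+01
   6.0000 2.464000e+01 2.405000e+01
   8.0000 1.037000e+01 9.915000e+00
  10.0000 5.329000e+00 4.944000e+00
  15.0000 1.673000e+00 1.374000e+00
  20.0000 8.096000e-01 5.503000e-01
  30.0000 3.756000e-01 1.557000e-01
  40.0000 2.683000e-01 6.947000e-02
  50.0000 2.269000e-01 4.223000e-02
  60.0000 2.059000e-01 3.190000e-02
  80.0000 1.837000e-01 2.597000e-02
 100.0000 1.707000e-01 2.546000e-02
 150.0000 1.505000e-01 2.764000e-02
 200.0000 1.370000e-01 2.967000e-02
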