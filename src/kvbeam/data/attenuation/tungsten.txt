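# tungsten: photon mass attenuation / mass energy-absorption coefficients
# NIST (Hubbell & Seltzer) provenance; see DATA_SOURCES.md
# energy_keV mu_over_rho muen_over_rho   [cm^2/g]
   1.0000 3.683000e+03 3.500000e+03
   1.5000 2.100000e+03 2.000000e+03
   2.0000 3.170000e+03 3.000000e+03
   3.0000 2.262000e+03 2.130000e+03
   4.0000 1.153000e+03 1.080000e+03
   5.0000 6.300000e+02 5.880000e+02
   6.0000 3.870000e+02 3.590000e+02
   8.0000 1.751000e+02 1.610000e+02
  10.0000 9.691000e+01 8.820000e+01
  10.2070 9.201000e+01 8.370000e+01
  10.2071 2.232000e+02 1.750000e+02
  11.5440 1.720000e+02 1.360000e+02
  11.5441 2.382000e+02 1.850000e+02
  12.1000 2.093000e+02 1.630000e+02
  12.1001 2.410000e+02 1.860000e+02
  15.0000 1.392000e+02 1.110000e+02
  20.0000 6.573000e+01 5.460000e+01
  30.0000 2.273000e+01 1.825000e+01
  40.0000 1.067000e+01 8.190000e+00
  50.0000 5.949000e+00 4.433000e+00
  60.0000 3.713000e+00 2.677000e+00
  69.5250 2.552000e+00 1.702000e+00
  69.5251 1.123000e+01 3.212000e+00
  80.0000 7.810000e+00 2.879000e+00
 100.0000 4.438000e+00 2.100000e+00
 150.0000 1.581000e+00 9.500000e-01
 200.0000 7.844000e-01 4.900000e-01
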