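# lead: photon mass attenuation / mass energy-absorption coefficients
# NIST (Hubbell & Seltzer) provenance; see DATA_SOURCES.md
# energy_keV mu_over_rho muen_over_rho   [cm^2/g]
   1.0000 5.210000e+03 5.000000e+03
   1.5000 2.356000e+03 2.260000e+03
   2.0000 1.285000e+03 1.230000e+03
   3.0000 1.965000e+03 1.860000e+03
   4.0000 1.251000e+03 1.180000e+03
   5.0000 7.304000e+02 6.870000e+02
   6.0000 4.672000e+02 4.380000e+02
   8.0000 2.287000e+02 2.120000e+02
  10.0000 1.306000e+02 1.190000e+02
  13.0350 6.701000e+01 6.010000e+01
  13.0351 1.621000e+02 1.280000e+02
  15.0000 1.116000e+02 9.100000e+01
  15.2000 1.078000e+02 8.760000e+01
  15.2001 1.457000e+02 1.160000e+02
  15.8610 1.318000e+02 1.050000e+02
  15.8611 1.541000e+02 1.220000e+02
  20.0000 8.636000e+01 6.900000e+01
  30.0000 3.032000e+01 2.536000e+01
  40.0000 1.436000e+01 1.211000e+01
  50.0000 8.041000e+00 6.740000e+00
  60.0000 5.021000e+00 4.149000e+00
  80.0000 2.419000e+00 1.916000e+00
  88.0050 1.910000e+00 1.482000e+00
  88.0051 7.683000e+00 2.160000e+00
 100.0000 5.549000e+00 2.280000e+00
 150.0000 2.014000e+00 1.056000e+00
 200.0000 9.985000e-01 5.870000e-01
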