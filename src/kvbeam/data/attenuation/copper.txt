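# copper: photon mass attenuation / mass energy-absorption coefficients
# NIST (Hubbell & Seltzer) provenance; see DATA_SOURCES.md
# energy_keV mu_over_rho muen_over_rho   [cm^2/g]
   1.0000 1.057000e+04 1.049000e+04
   1.5000 4.418000e+03 4.393000e+03
   2.0000 2.154000e+03 2.142000e+03
   3.0000 7.488000e+02 7.419000e+02
   4.0000 3.473000e+02 3.428000e+02
   5.0000 1.899000e+02 1.867000e+02
   6.0000 1.186000e+02 1.161000e+02
   8.0000 5.255000e+01 5.054000e+01
   8.9790 3.829000e+01 3.652000e+01
   8.9791 2.784000e+02 2.160000e+02
  10.0000 2.159000e+02 1.484000e+02
  15.0000 7.405000e+01 5.788000e+01
  20.0000 3.379000e+01 2.788000e+01
  30.0000 1.092000e+01 9.349000e+00
  40.0000 4.862000e+00 4.163000e+00
  50.0000 2.613000e+00 2.192000e+00
  60.0000 1.593000e+00 1.290000e+00
  80.0000 7.630000e-01 5.581000e-01
 100.0000 4.584000e-01 3.148000e-01
 150.0000 2.217000e-01 1.027000e-01
 200.0000 1.559000e-01 5.781000e-02
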