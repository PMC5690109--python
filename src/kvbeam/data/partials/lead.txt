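# lead: partial interaction coefficients (constructed split; see DATA_SOURCES.md)
# energy_keV photoelectric coherent incoherent   [cm^2/g]
   1.0000 5.000000e+03 2.099999e+02 1.269967e-04
   1.5000 2.260000e+03 9.599972e+01 2.849019e-04
   2.0000 1.230000e+03 5.499950e+01 5.048030e-04
   3.0000 1.860000e+03 1.049989e+02 1.126918e-03
   4.0000 1.180000e+03 7.099803e+01 1.984650e-03
   5.0000 6.870000e+02 4.339696e+01 3.067299e-03
   6.0000 4.380000e+02 2.919569e+01 4.362373e-03
   8.0000 2.119999e+02 1.669258e+01 7.532433e-03
  10.0000 1.189998e+02 1.158884e+01 1.136929e-02
  13.0350 6.009956e+01 6.892279e+00 1.815932e-02
  13.0351 1.279996e+02 3.408228e+01 1.815956e-02
  15.0000 9.099937e+01 2.057765e+01 2.298135e-02
  15.2000 8.759934e+01 2.017717e+01 2.348476e-02
  15.2001 1.159993e+02 2.967717e+01 2.348501e-02
  15.8610 1.049993e+02 2.677557e+01 2.516100e-02
  15.8611 1.219993e+02 3.207557e+01 2.516126e-02
  20.0000 6.899871e+01 1.732543e+01 3.586560e-02
  30.0000 2.535689e+01 4.903300e+00 5.981286e-02
  40.0000 1.210481e+01 2.177561e+00 7.763137e-02
  50.0000 6.732786e+00 1.218829e+00 8.938531e-02
  60.0000 4.139950e+00 7.843888e-01 9.666157e-02
  80.0000 1.903909e+00 4.118618e-01 1.032293e-01
  88.0050 1.468904e+00 3.369688e-01 1.041272e-01
  88.0051 2.146904e+00 5.431969e+00 1.041272e-01
 100.0000 2.265586e+00 3.178968e+00 1.044454e-01
 150.0000 1.037811e+00 8.760093e-01 1.001794e-01
 200.0000 5.666744e-01 3.378789e-01 9.394673e-02
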