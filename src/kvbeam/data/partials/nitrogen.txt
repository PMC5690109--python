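# nitrogen: partial interaction coefficients (constructed split; see DATA_SOURCES.md)
# energy_keV photoelectric coherent incoherent   [cm^2/g]
   1.0000 2.772378e+03 5.386198e+02 1.863669e-03
   1.5000 9.151391e+02 1.678568e+02 4.136821e-03
   2.0000 4.053419e+02 7.155090e+01 7.223416e-03
   3.0000 1.243294e+02 2.125508e+01 1.548663e-02
   4.0000 5.882142e+01 2.812728e+00 2.585367e-02
   5.0000 3.028098e+01 1.121543e+00 3.747940e-02
   6.0000 1.748582e+01 5.545744e-01 4.960333e-02
   8.0000 7.275609e+00 2.132769e-01 7.311433e-02
  10.0000 3.651537e+00 1.338766e-01 9.358684e-02
  15.0000 1.024919e+00 8.237178e-02 1.287094e-01
  20.0000 4.110896e-01 5.963241e-02 1.470780e-01
  30.0000 1.119910e-01 3.366949e-02 1.609395e-01
  40.0000 4.425626e-02 2.111876e-02 1.634250e-01
  50.0000 2.152145e-02 1.428955e-02 1.621890e-01
  60.0000 1.195100e-02 1.016444e-02 1.595846e-01
  80.0000 4.751708e-03 5.932738e-03 1.532156e-01
 100.0000 2.337187e-03 3.753314e-03 1.468095e-01
 150.0000 6.690346e-04 1.688029e-03 1.329429e-01
 200.0000 2.754782e-04 5.563161e-04 1.220682e-01
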