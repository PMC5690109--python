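# copper: partial interaction coefficients (constructed split; see DATA_SOURCES.md)
# energy_keV photoelectric coherent incoherent   [cm^2/g]
   1.0000 1.049000e+04 7.999959e+01 4.136386e-04
   1.5000 4.393000e+03 2.499908e+01 9.262525e-04
   2.0000 2.142000e+03 1.199837e+01 1.637000e-03
   3.0000 7.419000e+02 6.896393e+00 3.628171e-03
   4.0000 3.428000e+02 4.493722e+00 6.326660e-03
   5.0000 1.866999e+02 3.190436e+00 9.657001e-03
   6.0000 1.160998e+02 2.486622e+00 1.353302e-02
   8.0000 5.053966e+01 1.987791e+00 2.255081e-02
   8.9790 3.651954e+01 1.743064e+00 2.739995e-02
   8.9791 2.159995e+02 6.237306e+01 2.740046e-02
  10.0000 1.483994e+02 6.746797e+01 3.264132e-02
  15.0000 5.787839e+01 1.611306e+01 5.855395e-02
  20.0000 2.787708e+01 5.831963e+00 8.095586e-02
  30.0000 9.343257e+00 1.466376e+00 1.103678e-01
  40.0000 4.154652e+00 5.825304e-01 1.248176e-01
  50.0000 2.181404e+00 3.003116e-01 1.312841e-01
  60.0000 1.277484e+00 1.818406e-01 1.336753e-01
  80.0000 5.425142e-01 8.741975e-02 1.330661e-01
 100.0000 2.968933e-01 3.175146e-02 1.297552e-01
 150.0000 8.098329e-02 2.110542e-02 1.196113e-01
 200.0000 3.389705e-02 1.147506e-02 1.105279e-01
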