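# argon: partial interaction coefficients (constructed split; see DATA_SOURCES.md)
# energy_keV photoelectric coherent incoherent   [cm^2/g]
   1.0000 3.180816e+03 3.183344e+00 6.570213e-04
   1.5000 1.103895e+03 1.103536e+00 1.468723e-03
   2.0000 5.114880e+02 5.094205e-01 2.589534e-03
   3.0000 1.701297e+02 1.646320e-01 5.701035e-03
   3.2029 1.421577e+02 1.358756e-01 6.464335e-03
   3.2030 1.273725e+03 1.268575e+00 6.464721e-03
   4.0000 7.564427e+02 7.474242e-01 9.851652e-03
   5.0000 4.220774e+02 4.077713e-01 1.487118e-02
   6.0000 2.590405e+02 2.389620e-01 2.057352e-02
   8.0000 1.115366e+02 6.430147e+00 3.328335e-02
  10.0000 5.597880e+01 6.634563e+00 4.663561e-02
  15.0000 1.571221e+01 3.760620e+00 7.716592e-02
  20.0000 6.302088e+00 2.227186e+00 9.972641e-02
  30.0000 1.716845e+00 8.557066e-01 1.244483e-01
  40.0000 6.784575e-01 4.153471e-01 1.341953e-01
  50.0000 3.299282e-01 2.338683e-01 1.374035e-01
  60.0000 1.832112e-01 1.455358e-01 1.376530e-01
  80.0000 7.284466e-02 6.850214e-02 1.346532e-01
 100.0000 3.582955e-02 3.828892e-02 1.301815e-01
 150.0000 1.025644e-02 1.349089e-02 1.189527e-01
 200.0000 4.223137e-03 6.704604e-03 1.095723e-01
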