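# aluminum: partial interaction coefficients (constructed split; see DATA_SOURCES.md)
# energy_keV photoelectric coherent incoherent   [cm^2/g]
   1.0000 1.183000e+03 1.999031e+00 9.713738e-04
   1.5000 4.001000e+02 2.097839e+00 2.167665e-03
   1.5596 3.600000e+02 2.097666e+00 2.340660e-03
   1.5597 3.829000e+03 1.279977e+02 2.340956e-03
   2.0000 2.204000e+03 5.899620e+01 3.812682e-03
   3.0000 7.732000e+02 1.479171e+01 8.338095e-03
   4.0000 3.544999e+02 5.985829e+00 1.428126e-02
   5.0000 1.901998e+02 3.178876e+00 2.132838e-02
   6.0000 1.132997e+02 1.971181e+00 2.915222e-02
   8.0000 4.917930e+01 1.104775e+00 4.592010e-02
  10.0000 2.542883e+01 7.385873e-01 6.258702e-02
  15.0000 7.484316e+00 3.733594e-01 9.732475e-02
  20.0000 3.089668e+00 2.311653e-01 1.201668e-01
  30.0000 8.703970e-01 1.153443e-01 1.422587e-01
  40.0000 3.500985e-01 6.886101e-02 1.495405e-01
  50.0000 1.718092e-01 4.524227e-02 1.510485e-01
  60.0000 9.584391e-02 3.183112e-02 1.501250e-01
  80.0000 3.805210e-02 1.811378e-02 1.456341e-01
 100.0000 1.858732e-02 1.157925e-02 1.402334e-01
 150.0000 5.099743e-03 5.083141e-03 1.276171e-01
 200.0000 2.053888e-03 2.862923e-03 1.173832e-01
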