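# tungsten: partial interaction coefficients (constructed split; see DATA_SOURCES.md)
# energy_keV photoelectric coherent incoherent   [cm^2/g]
   1.0000 3.500000e+03 1.829999e+02 1.431348e-04
   1.5000 2.000000e+03 9.999968e+01 3.210710e-04
   2.0000 3.000000e+03 1.699994e+02 5.688031e-04
   3.0000 2.130000e+03 1.319987e+02 1.269245e-03
   4.0000 1.080000e+03 7.299778e+01 2.233974e-03
   5.0000 5.880000e+02 4.199658e+01 3.450021e-03
   6.0000 3.589999e+02 2.799515e+01 4.902227e-03
   8.0000 1.609999e+02 1.409168e+01 8.445629e-03
  10.0000 8.819976e+01 8.697526e+00 1.271278e-02
  10.2070 8.369975e+01 8.297063e+00 1.318928e-02
  10.2071 1.749997e+02 4.818706e+01 1.318951e-02
  11.5440 1.359996e+02 3.598395e+01 1.639929e-02
  11.5441 1.849996e+02 5.318395e+01 1.639954e-02
  12.1000 1.629996e+02 4.628261e+01 1.779413e-02
  12.1001 1.859996e+02 5.498261e+01 1.779438e-02
  15.0000 1.109993e+02 2.817522e+01 2.548157e-02
  20.0000 5.459858e+01 1.109203e+01 3.938966e-02
  30.0000 1.824664e+01 4.418865e+00 6.449065e-02
  40.0000 8.184483e+00 2.403032e+00 8.248450e-02
  50.0000 4.425416e+00 1.429617e+00 9.396666e-02
  60.0000 2.667558e+00 9.445934e-01 1.008490e-01
  69.5250 1.690998e+00 7.564048e-01 1.045970e-01
  69.5251 3.200998e+00 7.924405e+00 1.045971e-01
  80.0000 2.866503e+00 4.836800e+00 1.066977e-01
 100.0000 2.085178e+00 2.245421e+00 1.074004e-01
 150.0000 9.314035e-01 5.471706e-01 1.024259e-01
 200.0000 4.692638e-01 2.192914e-01 9.584479e-02
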