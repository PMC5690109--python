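# hydrogen: partial interaction coefficients (constructed split; see DATA_SOURCES.md)
# energy_keV photoelectric coherent incoherent   [cm^2/g]
   1.0000 7.192486e+00 2.289835e-16 2.451390e-02
   1.5000 2.096905e+00 0.000000e+00 5.109493e-02
   2.0000 9.766244e-01 0.000000e+00 8.237559e-02
   3.0000 4.147915e-01 0.000000e+00 1.464085e-01
   4.0000 2.535770e-01 0.000000e+00 2.010230e-01
   5.0000 1.752517e-01 1.281033e-03 2.427672e-01
   6.0000 1.011995e-01 2.962903e-02 2.733714e-01
   8.0000 4.210772e-02 3.756548e-02 3.117268e-01
  10.0000 2.113334e-02 3.193841e-02 3.323283e-01
  15.0000 5.931737e-03 1.837337e-02 3.520949e-01
  20.0000 2.379189e-03 1.134972e-02 3.557711e-01
  30.0000 6.481501e-04 5.259853e-03 3.510920e-01
  40.0000 2.561340e-04 2.991655e-03 3.425522e-01
  50.0000 1.245558e-04 1.896132e-03 3.334793e-01
  60.0000 6.916662e-05 1.289324e-03 3.246415e-01
  80.0000 2.750060e-05 7.244563e-04 3.083480e-01
 100.0000 1.352651e-05 4.146643e-04 2.939718e-01
 150.0000 1.131475e-05 2.537852e-04 2.648349e-01
 200.0000 2.846801e-05 2.144320e-04 2.426571e-01
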