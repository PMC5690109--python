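# beryllium: partial interaction coefficients (constructed split; see DATA_SOURCES.md)
# energy_keV photoelectric coherent incoherent   [cm^2/g]
   1.0000 6.004000e+02 3.697130e+00 2.875168e-03
   1.5000 1.785000e+02 1.193690e+00 6.328179e-03
   2.0000 7.379996e+01 8.791182e-01 1.092420e-02
   3.0000 2.065987e+01 5.874056e-01 2.272609e-02
   4.0000 8.210719e+00 4.377116e-01 3.656982e-02
   5.0000 3.987512e+00 3.305492e-01 5.093878e-02
   6.0000 2.187259e+00 2.749869e-01 6.475426e-02
   8.0000 8.534593e-01 1.819568e-01 8.858399e-02
  10.0000 4.924999e-01 4.750530e-02 1.065948e-01
  15.0000 1.745540e-01 0.000000e+00 1.324460e-01
  20.0000 8.164731e-02 0.000000e+00 1.434527e-01
  30.0000 2.956622e-02 0.000000e+00 1.496338e-01
  40.0000 1.494914e-02 0.000000e+00 1.490509e-01
  50.0000 8.861639e-03 0.000000e+00 1.465384e-01
  60.0000 5.870459e-03 0.000000e+00 1.434295e-01
  80.0000 3.126705e-03 0.000000e+00 1.369733e-01
 100.0000 1.881773e-03 0.000000e+00 1.309182e-01
 150.0000 7.427993e-04 0.000000e+00 1.182572e-01
 200.0000 0.000000e+00 4.116124e-04 1.084884e-01
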