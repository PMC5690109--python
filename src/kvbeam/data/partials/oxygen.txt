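# oxygen: partial interaction coefficients (constructed split; see DATA_SOURCES.md)
# energy_keV photoelectric coherent incoherent   [cm^2/g]
   1.0000 4.140689e+03 4.493097e+02 1.633159e-03
   1.5000 1.366807e+03 1.821894e+02 3.630347e-03
   2.0000 6.053988e+02 8.949485e+01 6.351442e-03
   3.0000 1.856924e+02 3.139395e+01 1.368914e-02
   4.0000 8.785279e+01 5.274201e+00 2.300645e-02
   5.0000 4.522619e+01 2.640206e+00 3.360669e-02
   6.0000 2.611597e+01 1.539194e+00 4.483763e-02
   8.0000 1.086649e+01 6.963513e-01 6.715541e-02
  10.0000 5.453756e+00 4.110380e-01 8.720574e-02
  15.0000 1.530769e+00 1.821139e-01 1.231175e-01
  20.0000 6.139834e-01 1.082668e-01 1.428499e-01
  30.0000 1.672643e-01 5.203138e-02 1.586043e-01
  40.0000 6.609899e-02 3.036084e-02 1.620402e-01
  50.0000 3.214338e-02 1.975157e-02 1.613050e-01
  60.0000 1.784942e-02 1.386300e-02 1.589876e-01
  80.0000 7.096919e-03 7.792744e-03 1.529103e-01
 100.0000 3.490707e-03 4.970883e-03 1.466384e-01
 150.0000 9.992373e-04 2.202748e-03 1.328980e-01
 200.0000 4.114408e-04 7.259263e-04 1.220626e-01
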