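# water: partial interaction coefficients (constructed split; see DATA_SOURCES.md)
# energy_keV photoelectric coherent incoherent   [cm^2/g]
   1.0000 4.065000e+03 1.299781e+01 2.193324e-03
   1.5000 1.372000e+03 3.995149e+00 4.865192e-03
   2.0000 6.152000e+02 2.091546e+00 8.487246e-03
   3.0000 1.916999e+02 1.181955e+00 1.815025e-02
   4.0000 8.190977e+01 8.400284e-01 3.020407e-02
   5.0000 4.187958e+01 6.567884e-01 4.362952e-02
   6.0000 2.404934e+01 5.331315e-01 5.752693e-02
   8.0000 9.913726e+00 3.720981e-01 8.417594e-02
  10.0000 4.941991e+00 2.799541e-01 1.070546e-01
  15.0000 1.369985e+00 1.574486e-01 1.455661e-01
  20.0000 5.443418e-01 9.998374e-02 1.652745e-01
  30.0000 1.463451e-01 4.948693e-02 1.797680e-01
  40.0000 5.729145e-02 2.891709e-02 1.820915e-01
  50.0000 2.766288e-02 1.874503e-02 1.804921e-01
  60.0000 1.528353e-02 1.314551e-02 1.774710e-01
  80.0000 6.026766e-03 7.405159e-03 1.702681e-01
 100.0000 2.952362e-03 4.652767e-03 1.630949e-01
 150.0000 8.341696e-04 2.024709e-03 1.476411e-01
 200.0000 3.438440e-04 1.107937e-03 1.355482e-01
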