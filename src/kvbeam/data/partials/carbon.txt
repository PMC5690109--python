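# carbon: partial interaction coefficients (constructed split; see DATA_SOURCES.md)
# energy_keV photoelectric coherent incoherent   [cm^2/g]
   1.0000 1.745144e+03 4.658537e+02 2.168738e-03
   1.5000 5.760576e+02 1.241376e+02 4.804847e-03
   2.0000 2.551528e+02 4.743887e+01 8.368233e-03
   3.0000 7.826233e+01 1.417986e+01 1.781745e-02
   4.0000 3.702664e+01 2.393872e+00 2.948833e-02
   5.0000 1.906113e+01 1.146531e+00 4.233645e-02
   6.0000 1.100690e+01 6.676339e-01 5.547009e-02
   8.0000 4.579817e+00 2.729972e-01 8.018560e-02
  10.0000 2.272086e+00 1.665335e-16 1.009137e-01
  15.0000 6.451612e-01 2.719062e-02 1.347482e-01
  20.0000 2.587708e-01 3.176283e-02 1.514663e-01
  30.0000 7.049559e-02 2.246687e-02 1.632375e-01
  40.0000 2.785823e-02 1.501670e-02 1.647251e-01
  50.0000 1.354722e-02 1.057785e-02 1.629749e-01
  60.0000 7.522858e-03 7.697123e-03 1.600800e-01
  80.0000 2.991084e-03 4.588728e-03 1.534202e-01
 100.0000 1.471202e-03 3.045358e-03 1.468834e-01
 150.0000 4.211409e-04 1.379306e-03 1.328996e-01
 200.0000 1.734068e-04 7.339226e-04 1.219927e-01
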