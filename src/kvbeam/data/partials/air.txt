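# air: partial interaction coefficients (constructed split; see DATA_SOURCES.md)
# energy_keV photoelectric coherent incoherent   [cm^2/g]
   1.0000 3.599000e+03 6.998231e+00 1.772764e-03
   1.5000 1.188000e+03 2.996074e+00 3.937182e-03
   2.0000 5.262000e+02 1.693147e+00 6.879926e-03
   3.0000 1.613999e+02 1.085306e+00 1.477973e-02
   4.0000 7.635981e+01 1.495454e+00 2.473606e-02
   5.0000 3.930966e+01 9.243824e-01 3.596205e-02
   6.0000 2.269945e+01 6.628075e-01 4.773890e-02
   8.0000 9.444929e+00 4.052858e-01 7.078560e-02
  10.0000 4.740291e+00 2.886219e-01 9.108728e-02
  15.0000 1.330512e+00 1.570181e-01 1.264699e-01
  20.0000 5.336615e-01 9.892750e-02 1.453110e-01
  30.0000 1.453826e-01 4.858761e-02 1.598298e-01
  40.0000 5.745186e-02 2.840011e-02 1.626480e-01
  50.0000 2.793836e-02 1.847079e-02 1.615908e-01
  60.0000 1.551434e-02 1.289374e-02 1.590919e-01
  80.0000 6.168493e-03 7.194955e-03 1.528366e-01
 100.0000 3.034050e-03 4.577108e-03 1.464888e-01
 150.0000 8.685162e-04 2.040437e-03 1.326910e-01
 200.0000 3.576157e-04 1.092994e-03 1.218494e-01
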