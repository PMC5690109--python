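# Bundled photon interaction data

## attenuation/*.txt

Whitespace-separated columns `energy_keV  mu_over_rho  muen_over_rho` (cm^2/g),
`#` comment headers. One file per material:
water, air, aluminum, copper, beryllium, tungsten, lead, and the elements
hydrogen, carbon, nitrogen, oxygen, argon.

Provenance: knot values transcribed from the NIST standard reference tables of
photon mass attenuation and mass energy-absorption coefficients
(J. H. Hubbell and S. M. Seltzer, NIST Standard Reference Database 126),
on the NIST knot grid from 1 to 200 keV. Absorption edges in band (Al K,
Cu K, W L1/L2/L3 and K, Pb L3/L2/L1 and K, Ar K) are carried as duplicated
rows just below / just above the edge (the upper row is offset by +1e-4 keV so
the grid stays strictly ascending); log-log interpolation therefore never
crosses an edge pair.

Caveats, recorded so nobody over-trusts a column:

- Tungsten and lead `muen_over_rho` are smoothed approximate values consistent
  with `muen <= mu`; they are used only in invariant checks, never in a dose
  pathway (filters use `mu_over_rho` only).
- Element (H, C, N, O, Ar) `muen_over_rho` columns are *derived*, not
  transcribed: the photoelectric part is apportioned from the bundled air
  table by a Z^4.0/A per-element scaling and the Compton part is the
  Klein-Nishina energy-transfer term, so that the mass-fraction mixture rule
  reproduces the bundled air table. Internal consistency of the authored
  element `mu_over_rho` values against the air table is 0.25 % or better over
  10-150 keV.
- The sub-keV M edges of W and Pb and the fine structure below 4 keV are
  smoothed; photons there do not survive the beryllium window in any modeled
  beam.

## partials/*.txt

Columns `energy_keV  photoelectric  coherent  incoherent` (cm^2/g).
This split is *constructed*, not transcribed:

- incoherent = sigma_KN(E) x electrons/g x s(E), with s(E) = E^2/(E^2+Es^2)
  an empirical binding suppression (Es = 10 keV x sqrt(Zbar/6.6), calibrated
  once against the water and air tables);
- photoelectric = muen_over_rho - incoherent x f_tr(E), where f_tr is the
  Klein-Nishina mean energy-transfer fraction;
- coherent = total - photoelectric - incoherent (residual, clipped >= 0).

The three partials sum to the total attenuation coefficient exactly at every
knot, and the expected collision kerma implied by the split equals the
bundled muen_over_rho by construction. The individual coherent/photoelectric
partition for tungsten and lead above their K edges is approximate (see the
muen caveat above).
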