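"""Tungsten-anode X-ray spectra: generation, filtration, air-kerma HVL, tuning.

The spectrum model is parametric rather than a full electron-transport anode
simulation: a Kramers bremsstrahlung continuum corrected for target
self-filtration (Thomson-Whiddington electron penetration along the anode
exit path) plus the tungsten K characteristic lines above their excitation
threshold.  The free knobs a clinical physicist actually has — kVp, anode
angle, inherent and added filtration — are the function arguments; everything
else is fixed at literature values (module constants below).

Beam quality is expressed as the first half-value layer (HVL) in mm Al,
defined on *air kerma*: the Al thickness at which the kerma-weighted
transmission integral falls to one half.  That is the quantity an ionization
chamber measures in a TG-61-style HVL determination, and it is the quantity
the inherent-filtration tuner matches to a measured HVL.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import physdata

__all__ = [
    "EnergySpectrum", "FilterStack", "generate_spectrum", "air_kerma_hvl",
    "tune_inherent_filtration", "import_spectrum", "kerma_integral",
    "harden_to_hvl",
]

# --- fixed model constants (tungsten anode) ---------------------------------
#: Thomson-Whiddington constant, keV^2 cm^2/g: electron energy loss vs depth
TW_CONSTANT = 1.0e6
#: K characteristic line energies (keV) and relative intensities
K_LINES = ((59.32, 100.0), (57.98, 57.6), (67.24, 33.6), (69.07, 8.7))
#: K-shell excitation threshold, keV
K_EDGE_W = 69.525
#: K-line yield coefficient and threshold exponent (thick-target scaling)
K_YIELD, K_EXPONENT = 0.06, 1.67
#: anode density g/cm^3
RHO_W = 19.30
#: default inherent filtration of the modeled tube: 0.8 mm Be window
DEFAULT_INHERENT = (("beryllium", 0.8),)


@dataclass(frozen=True)
class FilterStack:
    """Ordered list of (material_id, thickness_mm) attenuating layers."""

    layers: tuple[tuple[str, float], ...]

    def __post_init__(self):
        for mat, t in self.layers:
            physdata.get_table(mat)  # raises on unknown material
            if t < 0:
                raise ValueError(f"negative thickness {t} mm for {mat}")

    @classmethod
    def of(cls, *layers) -> "FilterStack":
        return cls(tuple((m, float(t)) for m, t in layers))

    def __add__(self, other: "FilterStack") -> "FilterStack":
        return FilterStack(self.layers + other.layers)

    def transmission(self, energy) -> np.ndarray:
        """exp(-sum mu(E) t) across the stack; ``energy`` keV scalar/array."""
        e = np.atleast_1d(np.asarray(energy, dtype=float))
        tau = np.zeros_like(e)
        for mat, t_mm in self.layers:
            tab = physdata.get_table(mat)
            ec = np.clip(e, tab.energies[0], tab.energies[-1])
            tau += tab.mu(ec) * tab.density_default * (t_mm / 10.0)
        out = np.exp(-tau)
        return out if np.ndim(energy) else float(out[0])


@dataclass(frozen=True)
class EnergySpectrum:
    """Binned photon fluence on a uniform keV grid.

    ``fluence`` holds relative photons *per bin* (arbitrary scale, >= 0);
    bins above the peak tube potential are identically zero.
    """

    bin_centers: np.ndarray
    fluence: np.ndarray
    kvp: float

    def __post_init__(self):
        w = np.diff(self.bin_centers)
        if len(self.bin_centers) > 1 and not np.allclose(w, w[0], rtol=1e-9):
            raise ValueError("bins not uniform")
        if np.any(self.fluence < 0):
            raise ValueError("negative fluence")
        if not np.any(self.fluence > 0):
            raise ValueError("spectrum has no positive bin")
        if np.any(self.fluence[self.bin_centers > self.kvp] > 0):
            raise ValueError("fluence above kvp")

    @property
    def bin_width(self) -> float:
        if len(self.bin_centers) == 1:
            return 0.5
        return float(self.bin_centers[1] - self.bin_centers[0])

    @property
    def total_fluence(self) -> float:
        return float(self.fluence.sum())

    @property
    def mean_energy(self) -> float:
        return float(np.average(self.bin_centers, weights=self.fluence))

    def attenuated(self, filters: FilterStack) -> "EnergySpectrum":
        """Bin-wise analytic attenuation through ``filters``."""
        return EnergySpectrum(self.bin_centers,
                              self.fluence * filters.transmission(self.bin_centers),
                              self.kvp)

    def scaled(self, factor: float) -> "EnergySpectrum":
        return EnergySpectrum(self.bin_centers, self.fluence * factor, self.kvp)


def _bin_grid(kvp: float, bin_width: float) -> np.ndarray:
    n = int(np.ceil(kvp / bin_width))
    return (np.arange(n) + 0.5) * bin_width


def generate_spectrum(kvp: float,
                      anode_angle_deg: float = 30.0,
                      inherent: FilterStack | None = None,
                      added: FilterStack | None = None,
                      bin_width: float = 0.5) -> EnergySpectrum:
    """Parametric tungsten-anode spectrum.

    Kramers photon-number continuum (kvp - E)/E, multiplied by the target
    self-filtration factor for electrons penetrating to the
    Thomson-Whiddington depth and photons escaping along the anode exit path
    (depth / sin(anode angle)), plus K lines when kvp exceeds the tungsten
    K edge; the result is attenuated bin-wise through the inherent and added
    filter stacks.  Units of fluence are arbitrary (relative spectrum).
    """
    if not 40.0 <= kvp <= 160.0:
        raise ValueError(f"kvp {kvp} outside supported range [40, 160]")
    if not 0.0 < anode_angle_deg <= 90.0:
        raise ValueError("anode angle must be in (0, 90] degrees")
    inherent = inherent if inherent is not None else FilterStack.of(*DEFAULT_INHERENT)
    added = added if added is not None else FilterStack.of()

    centers = _bin_grid(kvp, bin_width)
    e = np.minimum(centers, kvp - 1e-9)
    cont = np.clip(kvp - e, 0.0, None) / e

    # target self-filtration: photons of energy E are produced down to the
    # depth where the electron energy has degraded to E; average escape
    # attenuation along depth/sin(theta) assuming uniform production in depth
    w_tab = physdata.get_table("tungsten")
    ec = np.clip(e, w_tab.energies[0], w_tab.energies[-1])
    mu_w = w_tab.mu(ec) * RHO_W                       # 1/cm
    x_max = (kvp**2 - e**2) / (TW_CONSTANT * RHO_W)   # cm
    a = mu_w * x_max / np.sin(np.radians(anode_angle_deg))
    with np.errstate(divide="ignore", invalid="ignore"):
        self_filter = np.where(a > 1e-12, -np.expm1(-a) / np.maximum(a, 1e-12), 1.0)
    fluence = cont * self_filter

    if kvp > K_EDGE_W:
        n_cont = fluence.sum()
        yield_total = K_YIELD * (kvp / K_EDGE_W - 1.0) ** K_EXPONENT * n_cont
        rel = np.array([r for _, r in K_LINES])
        rel = rel / rel.sum()
        x_k = (kvp**2 - K_EDGE_W**2) / (TW_CONSTANT * RHO_W)
        for (e_line, _), frac in zip(K_LINES, rel):
            a_k = w_tab.mu(e_line) * RHO_W * x_k / np.sin(np.radians(anode_angle_deg))
            f_k = -np.expm1(-a_k) / a_k if a_k > 1e-12 else 1.0
            idx = int(np.argmin(np.abs(centers - e_line)))
            fluence[idx] += yield_total * frac * f_k

    spec = EnergySpectrum(centers, fluence, float(kvp))
    return spec.attenuated(inherent + added)


def kerma_integral(spectrum: EnergySpectrum, material_id: str = "air") -> float:
    """Relative collision kerma: sum over bins of fluence x (muen/rho)(E) x E.

    With uniform bins this is the midpoint-rule value of the kerma integral;
    the result is relative (units follow the spectrum's arbitrary fluence).
    """
    tab = physdata.get_table(material_id)
    e = np.clip(spectrum.bin_centers, tab.energies[0], tab.energies[-1])
    return float(np.sum(spectrum.fluence * tab.muen(e) * e))


def _kerma_transmission(spectrum: EnergySpectrum, attenuator: str,
                        thickness_mm: float, material_id: str = "air") -> float:
    stack = FilterStack.of((attenuator, thickness_mm))
    return kerma_integral(spectrum.attenuated(stack), material_id) / \
        kerma_integral(spectrum, material_id)


def air_kerma_hvl(spectrum: EnergySpectrum,
                  attenuator_material: str = "aluminum",
                  which: int = 1) -> float:
    """First (or second) half-value layer of ``spectrum`` in mm of attenuator.

    Solves kerma-transmission(t) = 0.5 (resp. 0.25 continuing from the first
    HVL) by bracketing root-find; the returned thickness satisfies
    |transmission - target| < 1e-6.
    """
    if which not in (1, 2):
        raise ValueError("which must be 1 (first) or 2 (second HVL)")
    target = 0.5 if which == 1 else 0.25
    f = lambda t: _kerma_transmission(spectrum, attenuator_material, t) - target
    if f(0.0) < 0 or f(100.0) > 0:
        raise ValueError("no HVL bracket within [0, 100] mm")
    t_star = brentq(f, 0.0, 100.0, xtol=1e-9, rtol=1e-14)
    assert abs(f(t_star)) < 1e-6
    if which == 2:
        return t_star - air_kerma_hvl(spectrum, attenuator_material, which=1)
    return t_star


def tune_inherent_filtration(kvp: float,
                             anode_angle_deg: float = 30.0,
                             added: FilterStack | None = None,
                             target_hvl_mm_al: float = None,
                             bin_width: float = 0.5,
                             tol_mm: float = 0.01):
    """Tune inherent Al-equivalent thickness so the model matches a measured HVL.

    The tuning knob is an Al layer added to the fixed 0.8 mm Be window
    (the inherent filtration of the modeled tube); HVL is monotone in that
    thickness, so plain bisection on [0, 20] mm converges.  Returns
    ``(tuned_thickness_mm_al, spectrum)`` with
    |air_kerma_hvl(spectrum) - target| < ``tol_mm``.
    """
    if target_hvl_mm_al is None:
        raise ValueError("target_hvl_mm_al is required")

    def spec_at(t_al: float) -> EnergySpectrum:
        inh = FilterStack.of(*DEFAULT_INHERENT, ("aluminum", t_al))
        return generate_spectrum(kvp, anode_angle_deg, inh, added, bin_width)

    lo, hi = 0.0, 20.0
    h_lo = air_kerma_hvl(spec_at(lo))
    h_hi = air_kerma_hvl(spec_at(hi))
    if not h_lo <= target_hvl_mm_al <= h_hi:
        raise ValueError(
            f"target HVL {target_hvl_mm_al} mm Al unreachable: inherent "
            f"Al in [0, 20] mm spans [{h_lo:.3f}, {h_hi:.3f}] mm Al")
    while True:
        mid = 0.5 * (lo + hi)
        s = spec_at(mid)
        h = air_kerma_hvl(s)
        if abs(h - target_hvl_mm_al) < tol_mm:
            return mid, s
        if h < target_hvl_mm_al:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-7:  # tolerance met by monotonicity before this point
            return mid, s


def harden_to_hvl(spectrum: EnergySpectrum, target_hvl_mm_al: float,
                  material: str = "aluminum", tol_mm: float = 0.005
                  ) -> EnergySpectrum:
    """Add attenuator until the spectrum's air-kerma HVL reaches the target.

    Only hardening is possible (adding material raises the HVL); raises if the
    spectrum is already harder than the target.
    """
    h0 = air_kerma_hvl(spectrum)
    if h0 > target_hvl_mm_al + tol_mm:
        raise ValueError(f"spectrum HVL {h0:.3f} already above target")

    def f(t):
        s = spectrum.attenuated(FilterStack.of((material, t)))
        return air_kerma_hvl(s) - target_hvl_mm_al

    if abs(f(0.0)) < tol_mm:
        return spectrum
    t = brentq(f, 0.0, 50.0, xtol=1e-4)
    return spectrum.attenuated(FilterStack.of((material, t)))


def import_spectrum(energies, fluence_density, bin_width: float = 0.5,
                    kvp: float | None = None) -> EnergySpectrum:
    """Resample an externally generated spectrum onto the internal grid.

    ``fluence_density`` is relative fluence per keV sampled at ascending
    ``energies`` (the natural export format of spectrum-generator tools);
    rebinning integrates the trapezoid interpolant over each uniform bin, so
    total fluence is conserved to within numerical round-off.  A single-row
    table is interpreted as a monoenergetic line.
    """
    e = np.asarray(energies, dtype=float)
    f = np.asarray(fluence_density, dtype=float)
    if e.ndim != 1 or e.shape != f.shape:
        raise ValueError("malformed table")
    if np.any(np.diff(e) <= 0):
        raise ValueError("energies must be strictly ascending")
    if np.any(f < 0):
        raise ValueError("negative fluence")

    if kvp is None:
        kvp = float(np.ceil(e[-1]))
    centers = _bin_grid(kvp, bin_width)

    if len(e) == 1:
        out = np.zeros_like(centers)
        out[int(np.argmin(np.abs(centers - e[0])))] = f[0]
        return EnergySpectrum(centers, out, kvp)

    edges = np.concatenate([centers - bin_width / 2, [centers[-1] + bin_width / 2]])
    # cumulative integral of the trapezoid interpolant, zero outside the data
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * np.diff(e))])

    def cum_at(x):
        x = np.clip(x, e[0], e[-1])
        i = np.clip(np.searchsorted(e, x, side="right") - 1, 0, len(e) - 2)
        fl = f[i] + (f[i + 1] - f[i]) * (x - e[i]) / (e[i + 1] - e[i])
        return cum[i] + 0.5 * (f[i] + fl) * (x - e[i])

    binned = np.diff(cum_at(edges))
    total_in, total_out = cum[-1], binned.sum()
    if total_in > 0 and abs(total_out / total_in - 1) > 1e-6:
        raise AssertionError("rebinning lost fluence")  # pragma: no cover
    return EnergySpectrum(centers, np.clip(binned, 0.0, None), kvp)


def export_density(spectrum: EnergySpectrum):
    """(energies, fluence per keV) pair suitable for :func:`import_spectrum`."""
    return spectrum.bin_centers.copy(), spectrum.fluence / spectrum.bin_width
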