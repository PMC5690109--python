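"""Bundled photon interaction data with log-log interpolation.

This module is the numerical substrate for everything else in :mod:`kvbeam`:
mass attenuation coefficients (mu/rho), mass energy-absorption coefficients
(muen/rho) and the partial-interaction split (photoelectric / coherent /
incoherent) for the materials that occur in a superficial-therapy beamline —
water, air, the filter metals (Al, Cu, Be), the anode (W), shielding (Pb) and
the elements needed for mixture rules.

Data are shipped as plain-text tables under ``kvbeam/data`` (provenance in
``DATA_SOURCES.md``); interpolation is linear in (log E, log coefficient),
the standard choice for photon cross sections.  Tables carry duplicated rows
just below/above every absorption edge in band, so interpolation never
crosses an edge discontinuity.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "AttenuationTable",
    "Material",
    "MATERIALS",
    "available_materials",
    "get_table",
    "mass_attenuation",
    "mass_energy_absorption",
    "mixture_coefficient",
    "partial_coefficients",
]

#: default densities, g/cm^3
_DENSITY = {
    "water": 1.0,
    "air": 1.2048e-3,
    "aluminum": 2.699,
    "copper": 8.960,
    "beryllium": 1.848,
    "tungsten": 19.30,
    "lead": 11.35,
    "hydrogen": 8.375e-5,
    "carbon": 2.000,
    "nitrogen": 1.1653e-3,
    "oxygen": 1.3315e-3,
    "argon": 1.6608e-3,
}

_ALIASES = {
    "h2o": "water", "al": "aluminum", "cu": "copper", "be": "beryllium",
    "w": "tungsten", "pb": "lead", "h": "hydrogen", "c": "carbon",
    "n": "nitrogen", "o": "oxygen", "ar": "argon",
}


def _canonical(material_id: str) -> str:
    key = material_id.strip().lower()
    key = _ALIASES.get(key, key)
    if key not in _DENSITY:
        raise KeyError(
            f"unknown material {material_id!r}; known: {sorted(_DENSITY)}")
    return key


@dataclass(frozen=True)
class Material:
    """Elemental composition (mass fractions) and default density."""

    composition: tuple[tuple[str, float], ...]
    density: float

    def __post_init__(self):
        total = sum(f for _, f in self.composition)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mass fractions sum to {total}, not 1")


#: compositions for the compound materials (NIST conventions)
MATERIALS = {
    "water": Material((("hydrogen", 0.111898), ("oxygen", 0.888102)), 1.0),
    "air": Material((("carbon", 0.000124), ("nitrogen", 0.755268),
                     ("oxygen", 0.231781), ("argon", 0.012827)), 1.2048e-3),
}


@dataclass(frozen=True)
class AttenuationTable:
    """Photon coefficients for one material on an ascending keV grid."""

    material_id: str
    energies: np.ndarray          # keV, strictly ascending
    mu_over_rho: np.ndarray       # cm^2/g
    muen_over_rho: np.ndarray     # cm^2/g
    density_default: float        # g/cm^3
    # partial split, same grid (photoelectric + coherent + incoherent = total)
    photoelectric: np.ndarray = field(repr=False, default=None)
    coherent: np.ndarray = field(repr=False, default=None)
    incoherent: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if not np.all(np.diff(self.energies) > 0):
            raise ValueError("energies not strictly ascending")
        if np.any(self.mu_over_rho <= 0) or np.any(self.muen_over_rho <= 0):
            raise ValueError("coefficients must be positive")
        if np.any(self.muen_over_rho > self.mu_over_rho * (1 + 1e-12)):
            raise ValueError("muen/rho exceeds mu/rho")

    # -- interpolation -----------------------------------------------------
    def _interp(self, column: np.ndarray, energy):
        e = np.asarray(energy, dtype=float)
        lo, hi = self.energies[0], self.energies[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"energy outside table span [{lo}, {hi}] keV for "
                f"{self.material_id}")
        out = np.exp(np.interp(np.log(e), np.log(self.energies),
                               np.log(column)))
        return float(out) if np.isscalar(energy) else out

    def mu(self, energy):
        """mu/rho at ``energy`` keV (log-log interpolated), cm^2/g."""
        return self._interp(self.mu_over_rho, energy)

    def muen(self, energy):
        """muen/rho at ``energy`` keV, cm^2/g."""
        return self._interp(self.muen_over_rho, energy)

    def partials(self, energy):
        """(photoelectric, coherent, incoherent) mu/rho at ``energy``."""
        return tuple(self._interp(np.maximum(c, 1e-30), energy)
                     for c in (self.photoelectric, self.coherent,
                               self.incoherent))


def _read_columns(package_dir: str, name: str) -> np.ndarray:
    ref = resources.files("kvbeam.data") / package_dir / f"{name}.txt"
    rows = []
    for line in ref.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            rows.append([float(v) for v in line.split()])
    return np.asarray(rows)


@lru_cache(maxsize=None)
def get_table(material_id: str) -> AttenuationTable:
    """Load (cached) the bundled :class:`AttenuationTable` for a material."""
    name = _canonical(material_id)
    att = _read_columns("attenuation", name)
    par = _read_columns("partials", name)
    if par.shape[0] != att.shape[0]:
        raise ValueError(f"partials/{name}.txt grid mismatch")
    return AttenuationTable(
        material_id=name,
        energies=att[:, 0],
        mu_over_rho=att[:, 1],
        muen_over_rho=att[:, 2],
        density_default=_DENSITY[name],
        photoelectric=par[:, 1],
        coherent=par[:, 2],
        incoherent=par[:, 3],
    )


def available_materials() -> list[str]:
    return sorted(_DENSITY)


def mass_attenuation(material_id: str, energy):
    """Mass attenuation coefficient mu/rho, cm^2/g.

    ``energy`` in keV (scalar or array), within the table span (1-200 keV).
    """
    return get_table(material_id).mu(energy)


def mass_energy_absorption(material_id: str, energy):
    """Mass energy-absorption coefficient muen/rho, cm^2/g."""
    return get_table(material_id).muen(energy)


def partial_coefficients(material_id: str, energy):
    """(photoelectric, coherent, incoherent) partial mu/rho, cm^2/g."""
    return get_table(material_id).partials(energy)


def mixture_coefficient(components, energy, kind: str = "mu"):
    """Mass-fraction-weighted coefficient of a mixture.

    Parameters
    ----------
    components : iterable of (material_id, mass_fraction)
        Fractions must sum to 1 within 1e-6.
    energy : float or array, keV
    kind : {'mu', 'muen'}
    """
    comps = list(components)
    total = sum(f for _, f in comps)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"mass fractions sum to {total}, not 1")
    if kind not in ("mu", "muen"):
        raise ValueError("kind must be 'mu' or 'muen'")
    acc = None
    for mat, frac in comps:
        tab = get_table(mat)
        val = tab.mu(energy) if kind == "mu" else tab.muen(energy)
        acc = frac * np.asarray(val) if acc is None else acc + frac * np.asarray(val)
    return float(acc) if np.ndim(acc) == 0 else acc


def linear_attenuation(material_id: str, energy, density: float | None = None):
    """Linear attenuation coefficient mu, 1/cm, at the given density."""
    tab = get_table(material_id)
    rho = tab.density_default if density is None else density
    return tab.mu(energy) * rho
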