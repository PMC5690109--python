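"""Synthetic-measurement generators: every pipeline stage testable without
an X-ray machine.

A :class:`TruthSource` is a fully specified effective point source whose
generating parameters (true fluence profiles, per-station spectra, noise
level) stay attached to it, so recovery tests can assert against the truth.
The generators emulate the measurement campaign of a superficial therapy
unit: heel-effect hardening along the inline axis (HVL rising toward the
cathode side), an asymmetric inline fluence profile with up to ~10% droop at
the applicator edges, flat-topped symmetric crossline fluence, in-air scans
at the applicator base, and Al transmission series at the HVL stations.

Noise model: multiplicative Gaussian on readings (relative
ionization-chamber noise), default SD 0.3% — the stated average reading
uncertainty of the emulated measurements.  What the generators do *not*
emulate: chamber energy response, scatter into the detector, setup drift;
recovery tests passing here demonstrate the correctness of the inversion
pipeline, not the absence of those systematic effects in real data.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hvl_measure import TransmissionSeries
from .source_model import FluenceMap, InAirScan, SourceModel, build_source
from .spectra import (EnergySpectrum, FilterStack, air_kerma_hvl,
                      kerma_integral, tune_inherent_filtration)

__all__ = ["TruthSource", "make_heel_source", "synthetic_inair_scan",
           "synthetic_transmission", "recover_source"]

#: default reading noise (relative SD)
DEFAULT_NOISE_SD = 0.003
#: HVL station spacing along the inline axis, cm
STATION_SPACING = 3.0


@dataclass(frozen=True)
class TruthSource:
    """A source model plus the parameters that generated it."""

    source: SourceModel
    kvp: float
    hvl_center: float
    hvl_gradient_per_cm: float
    noise_sd: float
    seed: int

    def true_x(self, x):
        return self.source.fluence.x(x)

    def true_y(self, y):
        return self.source.fluence.y(y)


def _edge_droop(u: np.ndarray) -> np.ndarray:
    """Flat top with rounded edges: unity inside 85% of the radius, falling
    quadratically to 0.90 at the edge (|u| = 1)."""
    t = np.clip((np.abs(u) - 0.85) / 0.15, 0.0, 1.0)
    return 1.0 - 0.10 * t * t


def make_heel_source(kvp: float = 140.0,
                     hvl_center: float = 7.0,
                     hvl_gradient_per_cm: float = 0.1,
                     aperture: float = 15.0,
                     ssd: float = 25.0,
                     seed: int = 0,
                     added: FilterStack | None = None,
                     anode_angle_deg: float = 30.0,
                     noise_sd: float = DEFAULT_NOISE_SD) -> TruthSource:
    """Ground-truth source with a heel effect along the inline axis.

    Spectra at stations every 3 cm are tuned so HVL(x) = hvl_center +
    gradient * x; with a positive gradient +x is the anode side (more target
    self-filtration: harder beam), so the inline fluence is reduced there by
    5% per aperture radius on top of the rounded-edge droop; crossline
    fluence is symmetric flat-topped.
    """
    if aperture <= 0 or ssd <= 0:
        raise ValueError("aperture and ssd must be positive")
    R = aperture / 2.0
    # stations every 3 cm from the center out past the aperture edge
    n_st = int(np.ceil(R / STATION_SPACING))
    stations = np.arange(-n_st, n_st + 1) * STATION_SPACING
    spectra = []
    for x in stations:
        target = hvl_center + hvl_gradient_per_cm * x
        _, spec = tune_inherent_filtration(
            kvp, anode_angle_deg, added, target_hvl_mm_al=target)
        spectra.append((float(x), spec))

    # fluence truth sampled finely enough that linear interpolation is exact
    # for the recovery tests (0.25 cm spacing)
    grid = np.arange(-np.ceil(R / 0.25) * 0.25, R + 0.25, 0.25)
    grid = np.unique(np.concatenate([grid, [0.0]]))
    xv = (1.0 - 0.05 * grid / R) * _edge_droop(grid / R)
    xv = xv / xv[np.argmin(np.abs(grid))]
    yv = _edge_droop(grid / R)
    yv = yv / yv[np.argmin(np.abs(grid))]

    src = SourceModel(ssd=ssd, applicator_diameter=aperture,
                      fluence=FluenceMap(grid, xv, grid, yv),
                      spectra=tuple(spectra))
    return TruthSource(source=src, kvp=kvp, hvl_center=hvl_center,
                       hvl_gradient_per_cm=hvl_gradient_per_cm,
                       noise_sd=noise_sd, seed=seed)


def synthetic_inair_scan(truth: TruthSource, axis: str,
                         spacing: float = 0.5,
                         noise_sd: float | None = None,
                         seed: int | None = None) -> InAirScan:
    """In-air relative dose scan of the truth source along one axis.

    Samples the forward model X(x) Y(y) K(U(x)) at the applicator base every
    ``spacing`` cm across the aperture, applies multiplicative Gaussian
    reading noise, and normalizes to the center.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    noise = truth.noise_sd if noise_sd is None else noise_sd
    seed = truth.seed if seed is None else seed
    R = truth.source.aperture_radius
    pos = np.arange(-np.floor(R / spacing) * spacing, R + 1e-9, spacing)
    pos = np.unique(np.concatenate([pos, [0.0]]))
    if axis == "inline":
        readings = np.array([truth.source.inair_dose_at(p, 0.0) for p in pos])
    elif axis == "crossline":
        readings = np.array([truth.source.inair_dose_at(0.0, p) for p in pos])
    else:
        raise ValueError("axis must be 'inline' or 'crossline'")
    rng = np.random.Generator(np.random.Philox(seed))
    readings = readings * (1.0 + noise * rng.standard_normal(len(pos)))
    return InAirScan(axis=axis, positions=pos, relative_dose=readings,
                     applicator_diameter=truth.source.applicator_diameter,
                     ssd=truth.source.ssd)


def synthetic_transmission(spectrum: EnergySpectrum, thicknesses,
                           noise_sd: float = DEFAULT_NOISE_SD,
                           seed: int = 0,
                           attenuator: str = "aluminum",
                           position=(0.0, 0.0),
                           axis: str = "inline") -> TransmissionSeries:
    """Al transmission series of a spectrum as an ionization chamber sees it.

    Readings are proportional to the air-kerma integral of the attenuated
    spectrum, with multiplicative Gaussian noise; thicknesses must include 0.
    """
    t = np.asarray(thicknesses, dtype=float)
    if 0.0 not in t:
        raise ValueError("thicknesses must include 0 (open beam)")
    readings = np.array([
        kerma_integral(spectrum.attenuated(FilterStack.of((attenuator, ti))))
        for ti in t])
    rng = np.random.Generator(np.random.Philox(seed))
    noisy = readings * (1.0 + noise_sd * rng.standard_normal(len(t)))
    # chamber practice: the open-beam reading is the normalization anchor and
    # is re-measured until stable; keep it maximal under noise
    i0 = int(np.argmin(t))
    noisy[i0] = max(noisy[i0], noisy.max() * (1 + 1e-12))
    return TransmissionSeries(thicknesses=t, readings=noisy,
                              attenuator_material=attenuator,
                              position=tuple(position), axis=axis)


def recover_source(kvp: float, ssd: float, applicator_diameter: float,
                   inline_scan: InAirScan, crossline_scan: InAirScan,
                   hvl_by_x, anode_angle_deg: float = 30.0,
                   added: FilterStack | None = None) -> SourceModel:
    """The measurement-to-model inversion: measured HVLs -> tuned spectra,
    in-air scans -> fluence map, assembled into an effective point source.

    ``hvl_by_x``: list of (inline position, measured HVL mm Al).  Measured
    HVLs are clamped into the tube's reachable quality range (a measured
    value below the bare-tube HVL can only be reading noise).
    """
    from .spectra import generate_spectrum
    floor = air_kerma_hvl(generate_spectrum(kvp, anode_angle_deg,
                                            added=added))
    spectra = []
    for x, h in hvl_by_x:
        _, spec = tune_inherent_filtration(
            kvp, anode_angle_deg, added,
            target_hvl_mm_al=max(h, floor + 5e-3))
        spectra.append((float(x), spec))
    return build_source(kvp, ssd, applicator_diameter,
                        inline_scan, crossline_scan, spectra)
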