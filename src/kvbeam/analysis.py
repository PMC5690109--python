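"""Depth-dose and profile analysis: PDD extraction, surface extrapolation,
percent-difference statistics, uncertainty quadrature, reference comparison.

PDD convention: kV beams have their maximum at (or within a fraction of a
millimeter of) the surface, which is also where measurements cannot reach an
ionization chamber, so curves are normalized to 100 at the *extrapolated
surface* value (least-squares polynomial over the shallowest points,
evaluated at depth 0).  A flag allows normalizing at the shallowest measured
depth instead.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import physdata
from .spectra import EnergySpectrum
from .transport import DoseResult

__all__ = ["DepthDoseCurve", "ProfileCurve", "ComparisonStats",
           "extract_pdd", "surface_extrapolate", "percent_difference_stats",
           "quadrature_uncertainty", "compare_to_reference",
           "primary_kerma_pdd"]


@dataclass(frozen=True)
class DepthDoseCurve:
    """Central-axis relative dose vs depth, normalization point at 100."""

    depths: np.ndarray        # cm, ascending
    dose: np.ndarray          # percent of the normalization value
    stderr: np.ndarray | None = None   # percent, same scale

    def __post_init__(self):
        d = np.asarray(self.depths, dtype=float)
        v = np.asarray(self.dose, dtype=float)
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "dose", v)
        if np.any(np.diff(d) <= 0):
            raise ValueError("depths must be ascending")
        if self.stderr is not None:
            object.__setattr__(self, "stderr",
                               np.asarray(self.stderr, dtype=float))


@dataclass(frozen=True)
class ProfileCurve:
    """Off-axis relative dose at fixed depth, 100 on the central axis."""

    positions: np.ndarray
    dose: np.ndarray
    depth: float
    axis: str = "inline"

    def __post_init__(self):
        p = np.asarray(self.positions, dtype=float)
        v = np.asarray(self.dose, dtype=float)
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "dose", v)
        i0 = np.argmin(np.abs(p))
        if abs(p[i0]) > 1e-9 or abs(v[i0] - 100.0) > 1e-6:
            raise ValueError("profile must contain position 0 at value 100")


@dataclass(frozen=True)
class ComparisonStats:
    """Summary of signed percent differences between two matched curves."""

    signed: np.ndarray
    min: float
    max: float
    mean_abs: float
    sd_abs: float
    mean_signed: float = 0.0
    sd_signed: float = 0.0

    @classmethod
    def from_signed(cls, pd: np.ndarray) -> "ComparisonStats":
        pd = np.asarray(pd, dtype=float)
        return cls(signed=pd, min=float(pd.min()), max=float(pd.max()),
                   mean_abs=float(np.mean(np.abs(pd))),
                   sd_abs=float(np.std(np.abs(pd), ddof=0)),
                   mean_signed=float(np.mean(pd)),
                   sd_signed=float(np.std(pd, ddof=0)))


def surface_extrapolate(depths, dose, order: int = 3, k: int = 5) -> float:
    """Polynomial extrapolation of a depth-dose curve to depth zero.

    Least-squares polynomial of the given order over the ``k`` shallowest
    points (all points if fewer), evaluated at 0.  Exact on polynomial data
    of degree <= order.
    """
    d = np.asarray(depths, dtype=float)
    v = np.asarray(dose, dtype=float)
    if order < 1:
        raise ValueError("order must be >= 1")
    k = min(k, len(d))
    if k < order + 1:
        raise ValueError(f"underdetermined fit: {k} points for order {order}")
    sel = np.argsort(d)[:k]
    return float(np.polyval(np.polyfit(d[sel], v[sel], order), 0.0))


def extract_pdd(result: DoseResult, ssd: float,
                normalize: str = "surface",
                order: int = 3, k: int = 5,
                axis_tol: float = 1e-6) -> DepthDoseCurve:
    """Central-axis PDD from a dose result whose tallies sit on the axis."""
    centers = np.array([t.center for t in result.tallies], dtype=float)
    if len(centers) < 2:
        raise ValueError("need at least two axial tallies")
    if np.any(np.abs(centers[:, :2]) > axis_tol):
        raise ValueError("tallies are not on the central axis")
    depths = centers[:, 2] - ssd
    order_idx = np.argsort(depths)
    depths = depths[order_idx]
    dose = result.dose[order_idx]
    se = result.stderr[order_idx]
    if normalize == "surface":
        ref = surface_extrapolate(depths, dose, order=order, k=k)
        if ref <= 0:
            raise ValueError("non-positive extrapolated surface dose")
    elif normalize == "shallowest":
        ref = dose[0]
    else:
        raise ValueError("normalize must be 'surface' or 'shallowest'")
    return DepthDoseCurve(depths, 100.0 * dose / ref, 100.0 * se / ref)


def percent_difference_stats(x_a, v_a, x_b, v_b) -> ComparisonStats:
    """Pointwise signed percent difference 100 (a - b)/b at a's abscissae.

    Curve b is linearly interpolated onto curve a's points; points of a
    outside b's range are excluded.  Both signed and absolute summaries are
    carried (the headline numbers of a PDD comparison are the mean and SD of
    the absolute differences alongside the signed range).
    """
    x_a = np.asarray(x_a, dtype=float)
    v_a = np.asarray(v_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    v_b = np.asarray(v_b, dtype=float)
    sel = (x_a >= x_b.min() - 1e-12) & (x_a <= x_b.max() + 1e-12)
    if not np.any(sel):
        raise ValueError("no overlapping abscissa range")
    b_on_a = np.interp(x_a[sel], x_b, v_b)
    if np.any(b_on_a == 0):
        raise ValueError("zero reference value in comparison")
    pd = 100.0 * (v_a[sel] - b_on_a) / b_on_a
    return ComparisonStats.from_signed(pd)


def quadrature_uncertainty(components) -> float:
    """Total uncertainty: root-sum-square of components, one decimal place."""
    c = np.asarray(list(components), dtype=float)
    if np.any(c < 0):
        raise ValueError("uncertainty components must be >= 0")
    return round(float(np.sqrt(np.sum(c**2))), 1)


def compare_to_reference(curve: DepthDoseCurve, ref_depths, ref_pdd,
                         ref_meta: dict | None = None,
                         curve_meta: dict | None = None) -> ComparisonStats:
    """Percent-difference statistics against a published reference PDD table.

    If both metadata dicts are given, the technique settings (kvp, ssd,
    field) must match; a mismatch is an explicit refusal, never a silent
    comparison of different beam qualities.
    """
    if ref_meta and curve_meta:
        for key in ("kvp", "ssd_cm", "field"):
            a, b = curve_meta.get(key), ref_meta.get(key)
            if a is not None and b is not None and a != b:
                raise ValueError(
                    f"technique mismatch on {key}: curve has {a!r}, "
                    f"reference has {b!r}")
    return percent_difference_stats(curve.depths, curve.dose,
                                    ref_depths, ref_pdd)


def primary_kerma_pdd(spectrum: EnergySpectrum, depths, ssd: float,
                      material_id: str = "water") -> DepthDoseCurve:
    """Deterministic narrow-beam primary kerma PDD.

    P(d) = sum_E U(E) exp(-mu(E) d) (muen/rho)(E) E x (ssd/(ssd+d))^2,
    normalized to 100 at the extrapolated surface.  No scatter buildup is
    modeled: this is the fast comparator for spectrum-sensitivity studies
    (two beams of equal kVp and HVL produce near-identical primary curves),
    not a substitute for the Monte Carlo engine in broad fields.
    """
    tab = physdata.get_table(material_id)
    d = np.asarray(depths, dtype=float)
    e = np.clip(spectrum.bin_centers, tab.energies[0], tab.energies[-1])
    mu = tab.mu(e) * tab.density_default
    muen = tab.muen(e)
    vals = np.array([
        np.sum(spectrum.fluence * np.exp(-mu * di) * muen * e)
        * (ssd / (ssd + di)) ** 2
        for di in d])
    ref = surface_extrapolate(d, vals) if len(d) >= 4 else vals[0]
    return DepthDoseCurve(d, 100.0 * vals / ref,
                          np.zeros_like(vals))
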