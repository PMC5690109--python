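"""HVL determination from measured transmission series.

An HVL measurement adds increasing attenuator (Al) thicknesses to the beam
and records an ionization-chamber reading for each, including the open beam.
The half-value layer is recovered by the three-point semilogarithmic
interpolation technique: a quadratic in (thickness, ln relative reading)
through the three measured thicknesses whose transmissions bracket and are
nearest to 50%, solved for the 50% crossing.  The quadratic is exact for a
monoenergetic (single-exponential) beam and second-order accurate for a
hardening polyenergetic beam.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TransmissionSeries", "HvlMap", "hvl_three_point", "hvl_map"]


@dataclass(frozen=True)
class TransmissionSeries:
    """Attenuator thicknesses (mm, including 0 = open beam) and readings."""

    thicknesses: np.ndarray
    readings: np.ndarray
    attenuator_material: str = "aluminum"
    position: tuple[float, float] = (0.0, 0.0)   # (x, y) cm in applicator plane
    axis: str = "inline"

    def __post_init__(self):
        t = np.asarray(self.thicknesses, dtype=float)
        r = np.asarray(self.readings, dtype=float)
        object.__setattr__(self, "thicknesses", t)
        object.__setattr__(self, "readings", r)
        if t.shape != r.shape or t.ndim != 1:
            raise ValueError("thicknesses/readings shape mismatch")
        if len(np.unique(t)) != len(t) or np.any(t < 0):
            raise ValueError("thicknesses must be distinct and >= 0")
        if 0.0 not in t:
            raise ValueError("open-beam reading (thickness 0) required")
        if r[np.argmin(t)] < r.max() * (1 - 1e-9):
            raise ValueError("open-beam reading must be maximal")

    @property
    def transmission(self) -> np.ndarray:
        """Readings relative to the open beam, sorted by thickness."""
        order = np.argsort(self.thicknesses)
        t = self.thicknesses[order]
        r = self.readings[order]
        return t, r / r[0]


@dataclass(frozen=True)
class HvlMap:
    """HVL (mm Al) versus off-axis position along one axis."""

    positions: np.ndarray
    hvl: np.ndarray
    axis: str = "inline"
    errors: dict = field(default_factory=dict)   # position -> error message

    def __post_init__(self):
        p = np.asarray(self.positions, dtype=float)
        h = np.asarray(self.hvl, dtype=float)
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "hvl", h)
        if np.any(np.diff(p) <= 0):
            raise ValueError("positions must be ascending")
        if np.any(h <= 0):
            raise ValueError("hvl values must be positive")


def _select_three(t: np.ndarray, ln_rel: np.ndarray, prefer_below: bool = True):
    """Indices of the three nonzero thicknesses nearest 50% transmission.

    Ties (four points symmetric about 50%) are broken toward the set with two
    points *below* 50% transmission: beam hardening makes the semilog curve
    shallower at depth, so that side carries more information.
    """
    mask = t > 0
    idx = np.where(mask)[0]
    dist = np.abs(np.exp(ln_rel[idx]) - 0.5)
    order = idx[np.argsort(dist, kind="stable")]
    chosen = list(order[:3])
    if len(order) > 3:
        d3, d4 = np.sort(dist)[2], np.sort(dist)[3]
        if abs(d3 - d4) < 1e-12:
            # symmetric tie: candidates for the third slot
            cands = [i for i in order[2:] if abs(np.abs(np.exp(ln_rel[i]) - 0.5) - d3) < 1e-12]
            below = [i for i in cands if np.exp(ln_rel[i]) < 0.5]
            if prefer_below and below:
                chosen = list(order[:2]) + [below[0]]
    return sorted(chosen, key=lambda i: t[i])


def hvl_three_point(series: TransmissionSeries, prefer_below: bool = True) -> float:
    """HVL in mm of attenuator from a measured transmission series.

    Requires at least three nonzero thicknesses with transmissions straddling
    50%.  Non-monotone readings signal a measurement error and are rejected.
    """
    t, rel = series.transmission
    if np.any(np.diff(rel) >= 0):
        raise ValueError("non-monotone readings (measurement error?)")
    nonzero = t > 0
    if nonzero.sum() < 3:
        raise ValueError("need at least three nonzero attenuator thicknesses")
    if rel[nonzero].max() <= 0.5 - 1e-12 or rel[nonzero].min() >= 0.5 + 1e-12:
        raise ValueError("readings do not bracket 50% transmission")

    ln_rel = np.log(rel)
    i1, i2, i3 = _select_three(t, ln_rel, prefer_below)
    ts = t[[i1, i2, i3]]
    ys = ln_rel[[i1, i2, i3]]

    # exact hit on a measured thickness
    hit = np.isclose(np.exp(ys), 0.5, rtol=0, atol=1e-12)
    if hit.any():
        return float(ts[hit][0])

    coeffs = np.polyfit(ts, ys, 2)
    coeffs[-1] -= np.log(0.5)
    roots = np.roots(coeffs)
    roots = roots[np.isreal(roots)].real

    # the 50% crossing must lie inside the thicknesses bracketing 50%
    above = t[(t > 0) & (rel > 0.5)]
    below = t[rel < 0.5]
    lo = above.max() if len(above) else 0.0
    hi = below.min()
    inside = roots[(roots >= lo - 1e-9) & (roots <= hi + 1e-9)]
    if len(inside) == 0:
        raise ValueError(
            f"no 50% crossing inside bracket [{lo:.4g}, {hi:.4g}] mm")
    return float(inside[0])


def hvl_map(series_list, prefer_below: bool = True) -> HvlMap:
    """Per-position :func:`hvl_three_point` over a list of series.

    All series must share axis and attenuator; positions are sorted.  Series
    that fail the three-point method are reported in ``errors`` keyed by
    position rather than aborting the whole map.
    """
    series_list = list(series_list)
    if not series_list:
        raise ValueError("empty series list")
    axis = series_list[0].axis
    att = series_list[0].attenuator_material
    if any(s.axis != axis or s.attenuator_material != att for s in series_list):
        raise ValueError("series mix axes or attenuator materials")

    pos, vals, errors = [], [], {}
    for s in series_list:
        p = s.position[0] if axis == "inline" else s.position[1]
        try:
            vals.append(hvl_three_point(s, prefer_below))
            pos.append(p)
        except ValueError as exc:
            errors[p] = str(exc)
    order = np.argsort(pos)
    return HvlMap(np.asarray(pos)[order], np.asarray(vals)[order], axis, errors)
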