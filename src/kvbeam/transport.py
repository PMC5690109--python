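"""Monte Carlo photon transport in a voxel phantom under the kerma approximation.

Physics scope (kV therapy range, 1-160 keV): photoelectric absorption,
coherent (Thomson-shaped) scattering and incoherent (Klein-Nishina, Kahn
sampling) Compton scattering.  Electrons are not transported: their range at
these energies is below voxel resolution, so the energy transferred to them
is deposited at the interaction site (photoelectric: the whole photon
energy; incoherent: the electron share E - E').  Photons degraded below the
5 keV cutoff are absorbed on the spot, which keeps the per-history energy
balance (deposited + escaped = launched) exact.

Two dose estimators are available per tally box:

``collision``
    Analog scoring of energy imparted at interaction sites — the direct
    reading of the kerma approximation.
``tracklength``
    Track-length kerma estimator: every photon flight segment of length L in
    a tally adds E (muen/rho)(E) rho L.  Same expectation as collision
    scoring (by construction of the bundled partial split) with far lower
    variance for small tallies; preferred for point-of-interest dose.

Reproducibility: emissions are drawn with numpy's counter-based Philox
generator and in-phantom transport uses an explicit-state PCG32 stream, both
keyed by ``seed``; a run is bit-identical for identical inputs and seed.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np

from . import _kernels, physdata
from .phantom import VoxelPhantom
from .source_model import SourceModel

__all__ = ["Tally", "DoseResult", "compute_dose", "sample_interaction",
           "sample_free_path", "voxel_chord_lengths", "pcg_state"]

#: fine energy grid for in-kernel table lookup, keV
_E0, _DE, _NE = 1.0, 0.25, 637  # 1.0 .. 160.0
#: low-energy cutoff, keV (local deposition below)
CUTOFF_KEV = 5.0
#: default tally box edge lengths, cm
DEFAULT_TALLY_SIZE = (0.4, 0.4, 0.3)


@dataclass(frozen=True)
class Tally:
    """Axis-aligned scoring box centered on a point of interest."""

    center: tuple[float, float, float]
    size: tuple[float, float, float] = DEFAULT_TALLY_SIZE

    def bounds(self) -> np.ndarray:
        c, s = self.center, self.size
        return np.array([c[0] - s[0] / 2, c[0] + s[0] / 2,
                         c[1] - s[1] / 2, c[1] + s[1] / 2,
                         c[2] - s[2] / 2, c[2] + s[2] / 2])

    @property
    def volume(self) -> float:
        return self.size[0] * self.size[1] * self.size[2]


@dataclass
class DoseResult:
    """Per-tally relative dose with history-by-history statistics."""

    tallies: tuple
    dose: np.ndarray          # mean energy per history / tally mass
    stderr: np.ndarray        # standard error of the mean, same units
    histories: int
    seed: int
    launched_energy: float    # keV, total over histories
    deposited_energy: float
    escaped_energy: float
    deposited_per_history: np.ndarray | None = None
    escaped_per_history: np.ndarray | None = None
    launched_per_history: np.ndarray | None = None

    def relative_stderr(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.dose > 0, self.stderr / self.dose, np.inf)


def _material_tables(names: tuple[str, ...]):
    """Flatten per-material coefficients onto the kernel's fine energy grid."""
    e = _E0 + _DE * np.arange(_NE)
    mu = np.empty((len(names), _NE))
    pe_frac = np.empty_like(mu)
    coh_frac = np.empty_like(mu)
    muen = np.empty_like(mu)
    for i, name in enumerate(names):
        tab = physdata.get_table(name)
        ec = np.clip(e, tab.energies[0], tab.energies[-1])
        mu[i] = tab.mu(ec)
        muen[i] = tab.muen(ec)
        pe, coh, inc = tab.partials(ec)
        tot = pe + coh + inc
        pe_frac[i] = pe / tot
        coh_frac[i] = coh / tot
    return mu, pe_frac, coh_frac, muen


def _phantom_arrays(ph: VoxelPhantom):
    (x0, x1), (y0, y1), (z0, z1) = ph.bounds()
    lo = np.array([x0, y0, z0])
    hi = np.array([x1, y1, z1])
    return (ph.material.astype(np.uint8), ph.density.astype(np.float64),
            lo, hi, np.asarray(ph.spacing, dtype=float))


def _tally_mass(ph: VoxelPhantom, tally: Tally) -> float:
    """Mass of the tally box, sampling the phantom density on a 3^3 stencil."""
    c = np.asarray(tally.center)
    s = np.asarray(tally.size)
    offsets = np.array([-0.33, 0.0, 0.33])
    dens = []
    for ox in offsets:
        for oy in offsets:
            for oz in offsets:
                p = c + np.array([ox, oy, oz]) * s
                i, j, k = ph.voxel_index(p)
                dens.append(ph.density[i, j, k])
    rho = float(np.mean(dens))
    return rho * tally.volume


def compute_dose(source: SourceModel, phantom: VoxelPhantom, tallies,
                 n_histories: int, seed: int,
                 score: str = "collision",
                 primary_only: bool = False,
                 cutoff_kev: float = CUTOFF_KEV,
                 keep_history: bool = False) -> DoseResult:
    """Transport ``n_histories`` photons and score dose at the tallies.

    Dose is reported per launched history divided by tally mass (relative
    units), so results from runs with different history counts are directly
    comparable.  ``primary_only`` terminates photons at their first
    interaction (attenuation studies).  See the module docstring for the
    ``score`` estimators.
    """
    tallies = tuple(tallies)
    if n_histories < 1000:
        raise ValueError("n_histories must be >= 1000")
    if score not in ("collision", "tracklength"):
        raise ValueError("score must be 'collision' or 'tracklength'")
    mat, rho, lo, hi, spacing = _phantom_arrays(phantom)
    for t in tallies:
        b = t.bounds()
        if (b[0] < lo[0] or b[1] > hi[0] or b[2] < lo[1] or b[3] > hi[1]
                or b[4] < lo[2] or b[5] > hi[2]):
            raise ValueError(f"tally at {t.center} outside phantom")
    masses = np.array([_tally_mass(phantom, t) for t in tallies])
    if np.any(masses <= 0):
        raise ValueError("zero-mass tally (box in vacuum?)")

    # the central ray must reach the phantom box, else the beam misses it
    hit, _ = _kernels._box_entry(0.0, 0.0, 0.0, 0.0, 0.0, 1.0, lo, hi)
    if not hit:
        raise ValueError("source aimed outside phantom (central ray misses)")

    rng = np.random.Generator(np.random.Philox(seed))
    dirs, energies, _ = source.sample_emission(rng, n_histories)

    mu_tab, pe_tab, coh_tab, muen_tab = _material_tables(phantom.material_names)
    nt = len(tallies)
    tally_bounds = (np.stack([t.bounds() for t in tallies])
                    if nt else np.zeros((0, 6)))
    tally_sum = np.zeros(nt)
    tally_sum2 = np.zeros(nt)
    dep = np.zeros(n_histories)
    esc = np.zeros(n_histories)

    _kernels.run_histories(
        np.ascontiguousarray(dirs), np.ascontiguousarray(energies),
        np.uint64(seed), mat, rho, lo, hi, spacing,
        mu_tab, pe_tab, coh_tab, muen_tab, _E0, _DE,
        float(cutoff_kev), tally_bounds, np.zeros(max(nt, 1)),
        tally_sum, tally_sum2, dep, esc,
        primary_only, score == "tracklength")

    n = n_histories
    mean = tally_sum / n
    var = np.maximum(tally_sum2 / n - mean**2, 0.0)
    stderr = np.sqrt(var / max(n - 1, 1))
    return DoseResult(
        tallies=tallies,
        dose=mean / masses if nt else mean,
        stderr=stderr / masses if nt else stderr,
        histories=n, seed=seed,
        launched_energy=float(energies.sum()),
        deposited_energy=float(dep.sum()),
        escaped_energy=float(esc.sum()),
        deposited_per_history=dep if keep_history else None,
        escaped_per_history=esc if keep_history else None,
        launched_per_history=energies.copy() if keep_history else None,
    )


# --- single-event / single-ray helpers (shared kernel code paths) ------------

@functools.lru_cache(maxsize=4096)
def _partials_memo(material_id: str, energy: float):
    return physdata.partial_coefficients(material_id, energy)


def pcg_state(seed: int, stream: int = 54) -> np.ndarray:
    """Explicit PCG32 state for the helpers below."""
    return _kernels.pcg_init(np.uint64(seed), np.uint64(stream))


def sample_interaction(energy: float, material_id: str, state: np.ndarray):
    """Draw one interaction: ('photoelectric'|'coherent'|'incoherent',
    outgoing energy keV, cos scattering angle).

    Event kinds are drawn proportionally to the bundled partial cross
    sections at ``energy``; incoherent kinematics follow Klein-Nishina via
    Kahn's method, coherent scattering preserves energy.
    """
    if energy <= CUTOFF_KEV:
        raise ValueError(f"energy {energy} below transport cutoff")
    pe, coh, inc = _partials_memo(material_id, float(energy))
    tot = pe + coh + inc
    u = _kernels.pcg_next(state)
    if u < pe / tot:
        return "photoelectric", 0.0, 1.0
    if u < (pe + coh) / tot:
        return "coherent", float(energy), float(_kernels.thomson_cos(state))
    cos_t, eps = _kernels.kahn_sample(float(energy), state)
    return "incoherent", float(energy * eps), float(cos_t)


# repeated single-ray calls reuse the flattened arrays (keyed by object id;
# entries are tiny and the cache lives for the session)
_PREPARED: dict[int, tuple] = {}


def _prepared(phantom: VoxelPhantom):
    key = id(phantom)
    if key not in _PREPARED:
        _PREPARED[key] = (_phantom_arrays(phantom),
                          _material_tables(phantom.material_names))
    return _PREPARED[key]


def sample_free_path(position, direction, energy: float,
                     phantom: VoxelPhantom, state: np.ndarray):
    """Sample one free path through the phantom.

    Returns ``(site, path_cm)`` where ``site`` is the interaction position or
    ``None`` if the photon exits the phantom; ``path_cm`` is the geometric
    path traveled inside the phantom.
    """
    (mat, rho, lo, hi, spacing), (mu_tab, _, _, _) = _prepared(phantom)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    ok, x, y, z, path = _kernels.free_path(
        float(position[0]), float(position[1]), float(position[2]),
        d[0], d[1], d[2], float(energy), lo, hi, spacing, mat, rho,
        mu_tab, _E0, _DE, state)
    return ((x, y, z) if ok else None), float(path)


def voxel_chord_lengths(position, direction, phantom: VoxelPhantom):
    """Per-voxel intersection lengths of a ray with the phantom grid.

    Returns ``(lengths, flat_indices)``; the lengths sum to the geometric
    chord of the ray through the phantom box.
    """
    mat, _, lo, hi, spacing = _phantom_arrays(phantom)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    cap = int(np.sum(phantom.dims) * 4 + 16)
    lengths = np.zeros(cap)
    idx = np.zeros(cap, dtype=np.int64)
    n = _kernels.voxel_chords(
        float(position[0]), float(position[1]), float(position[2]),
        d[0], d[1], d[2], lo, hi, spacing,
        np.asarray(phantom.dims, dtype=np.int64), lengths, idx)
    return lengths[:n], idx[:n]
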