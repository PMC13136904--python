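"""Canonical NVT* Metropolis Monte Carlo for an ensemble of independent dimers.

Each dimer is two hard cylinders tethered by an infinite-square-well linker
(rim patches, width 2*R0) with a finite stacking well (base-centre patches,
width 2*R1, depth u0).  Dimers do not interact with one another: the measured
SAXS observable is built from independent dimeric configurations, so the
simulation box only sets the initial placement density.

Moves are single-cylinder rigid-body displacements: a random translation
within ``max_translation`` combined with a random rotation about a random
axis within ``max_rotation``.  One sweep attempts ``2 * n_dimers`` such
moves.  Acceptance follows Metropolis with ``exp(-dE/T*)``; hard-constraint
violations (overlap or a broken linker) are always rejected.  ``T* = 0``
rejects every energy increase and ``T* = inf`` accepts every feasible move
(a separate code path, avoiding floating-point infinities).

Because dimers are mutually independent, a sweep is executed as two
vectorised half-sweeps, each proposing one move per dimer; this is
statistically identical to sequential single-dimer updates.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (CylinderGeometry, CylinderPose, DimerState,
                       EffectiveTemperature, PatchSpec)
from .overlap import overlap_pairs

__all__ = ["SimulationConfig", "Ensemble", "Trajectory", "initialize",
           "mc_sweep", "run", "stacked_fraction"]

_CONTACT_GAP = 1e-4  # nm, initial base-to-base clearance of a stacked dimer


@dataclass
class SimulationConfig:
    """Simulation settings.  Defaults are the reduced desk-scale profile;
    ``paper_scale()`` returns the full-size study conditions."""

    n_dimers: int = 300
    t_star: float = math.inf
    geometry: CylinderGeometry = field(default_factory=CylinderGeometry)
    patches: PatchSpec = field(default_factory=PatchSpec)
    box_length: float | None = None        # nm; None -> 0.5% volume fraction
    n_thermalization_sweeps: int = 800
    n_snapshots: int = 10
    snapshot_interval: int = 40
    max_translation: float = 0.25          # nm
    max_rotation: float = 0.4              # rad
    auto_tune: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_dimers < 1:
            raise ValueError("n_dimers must be >= 1")
        if not (self.t_star >= 0):
            raise ValueError("t_star must be >= 0 (math.inf allowed)")
        if self.snapshot_interval < 1:
            raise ValueError("snapshot_interval must be >= 1")

    @property
    def effective_temperature(self) -> EffectiveTemperature:
        return EffectiveTemperature(self.t_star)

    def resolved_box_length(self) -> float:
        if self.box_length is not None:
            return float(self.box_length)
        # dilute by construction: 0.5% cylinder volume fraction
        total_v = 2.0 * self.n_dimers * self.geometry.volume
        return (total_v / 0.005) ** (1.0 / 3.0)

    @classmethod
    def paper_scale(cls, **kw) -> "SimulationConfig":
        """Full-size study conditions: 3000 dimers, 50 snapshots, and at
        least 5e5 attempted single-cylinder moves of thermalization."""
        base = dict(n_dimers=3000, n_thermalization_sweeps=1000,
                    n_snapshots=50, snapshot_interval=100)
        base.update(kw)
        return cls(**base)


class Ensemble:
    """Array-of-structs state of ``n`` dimers.

    ``centers``/``axes``/``radials`` have shape (n, 2, 3): index 1 selects
    cylinder A (linker patch on its +axis base) or B (-axis base).
    """

    def __init__(self, centers, axes, radials, geometry, patches):
        self.centers = np.asarray(centers, dtype=float)
        self.axes = np.asarray(axes, dtype=float)
        self.radials = np.asarray(radials, dtype=float)
        self.geometry = geometry
        self.patches = patches

    @property
    def n_dimers(self) -> int:
        return self.centers.shape[0]

    def copy(self) -> "Ensemble":
        return Ensemble(self.centers.copy(), self.axes.copy(),
                        self.radials.copy(), self.geometry, self.patches)

    # -- patch positions ----------------------------------------------------
    def _junction_points(self, centers=None, axes=None, radials=None):
        c = self.centers if centers is None else centers
        a = self.axes if axes is None else axes
        r = self.radials if radials is None else radials
        h = 0.5 * self.geometry.height_H
        rhc = self.geometry.radius_RHC
        stack_a = c[:, 0] + h * a[:, 0]
        stack_b = c[:, 1] - h * a[:, 1]
        link_a = stack_a + rhc * r[:, 0]
        link_b = stack_b + rhc * r[:, 1]
        return link_a, link_b, stack_a, stack_b

    def linker_distances(self) -> np.ndarray:
        la, lb, _, _ = self._junction_points()
        return np.linalg.norm(la - lb, axis=1)

    def stacking_distances(self) -> np.ndarray:
        _, _, sa, sb = self._junction_points()
        return np.linalg.norm(sa - sb, axis=1)

    def stacked_mask(self) -> np.ndarray:
        return self.stacking_distances() <= 2.0 * self.patches.stacking_radius_R1

    def overlaps(self) -> np.ndarray:
        out = np.empty(self.n_dimers, dtype=np.bool_)
        overlap_pairs(np.ascontiguousarray(self.centers[:, 0]),
                      np.ascontiguousarray(self.axes[:, 0]),
                      np.ascontiguousarray(self.centers[:, 1]),
                      np.ascontiguousarray(self.axes[:, 1]),
                      self.geometry.radius_RHC, self.geometry.height_H, out)
        return out

    def total_energy(self) -> float:
        """Total stacking energy in u0 units (= -number of stacked dimers)."""
        return -float(np.count_nonzero(self.stacked_mask()))

    def dimer_state(self, i: int) -> DimerState:
        pa = CylinderPose.from_frame(self.centers[i, 0], self.axes[i, 0], self.radials[i, 0])
        pb = CylinderPose.from_frame(self.centers[i, 1], self.axes[i, 1], self.radials[i, 1])
        return DimerState(pa, pb, self.geometry, self.patches)


@dataclass
class Trajectory:
    snapshots: list
    energy_trace: np.ndarray
    acceptance: float
    equilibrated: bool
    config: SimulationConfig


def _random_units(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _perp_units(rng, axes):
    v = rng.normal(size=axes.shape)
    v -= np.einsum("ij,ij->i", v, axes)[:, None] * axes
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def initialize(config: SimulationConfig, rng=None, start: str = "stacked") -> Ensemble:
    """Place ``n_dimers`` dimers uniformly in the box with uniform random
    orientations.  ``start='stacked'`` puts every dimer in the stacked,
    azimuth-aligned conformation; ``start='extended'`` places the two
    cylinders coaxially with the linker taut (unstacked), for ergodicity
    checks."""
    if start not in ("stacked", "extended"):
        raise ValueError("start must be 'stacked' or 'extended'")
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    n = config.n_dimers
    L = config.resolved_box_length()
    geom, patches = config.geometry, config.patches
    if 2.0 * n * geom.volume / L**3 > 0.05:
        raise ValueError("box too small: cylinder volume fraction exceeds 5%")

    axes0 = _random_units(rng, n)
    rad0 = _perp_units(rng, axes0)
    c0 = rng.uniform(0.0, L, size=(n, 3))
    if start == "stacked":
        gap = _CONTACT_GAP
    else:
        # coaxial, bases separated but within the linker well, outside the
        # stacking well
        gap = 1.5 * 2.0 * patches.stacking_radius_R1
        if gap > 2.0 * patches.linker_radius_R0:
            gap = 0.5 * (2.0 * patches.stacking_radius_R1 + 2.0 * patches.linker_radius_R0)
    c1 = c0 + (geom.height_H + gap) * axes0

    centers = np.stack([c0, c1], axis=1)
    axes = np.stack([axes0, axes0.copy()], axis=1)
    radials = np.stack([rad0, rad0.copy()], axis=1)
    ens = Ensemble(centers, axes, radials, geom, patches)
    # hard-constraint sanity (guaranteed by construction)
    if ens.overlaps().any() or (ens.linker_distances() > 2 * patches.linker_radius_R0).any():
        raise RuntimeError("initialization produced an infeasible configuration")
    return ens


def _rotate(vecs, units, angles):
    """Rodrigues rotation of ``vecs`` about unit axes ``units`` by ``angles``."""
    cos = np.cos(angles)[:, None]
    sin = np.sin(angles)[:, None]
    dot = np.einsum("ij,ij->i", units, vecs)[:, None]
    return vecs * cos + np.cross(units, vecs) * sin + units * dot * (1.0 - cos)


def _half_sweep(ens: Ensemble, config: SimulationConfig, rng,
                max_t: float, max_r: float) -> int:
    """Propose one single-cylinder move per dimer; returns accepted count."""
    n = ens.n_dimers
    which = rng.integers(0, 2, size=n)
    idx = np.arange(n)

    old_stacked = ens.stacked_mask()

    new_c = ens.centers[idx, which] + rng.uniform(-max_t, max_t, size=(n, 3))
    rot_u = _random_units(rng, n)
    rot_ang = rng.uniform(-max_r, max_r, size=n)
    new_a = _rotate(ens.axes[idx, which], rot_u, rot_ang)
    new_r = _rotate(ens.radials[idx, which], rot_u, rot_ang)
    # re-orthonormalize against numerical drift
    new_a /= np.linalg.norm(new_a, axis=1, keepdims=True)
    new_r -= np.einsum("ij,ij->i", new_r, new_a)[:, None] * new_a
    new_r /= np.linalg.norm(new_r, axis=1, keepdims=True)

    cand_c = ens.centers.copy()
    cand_a = ens.axes.copy()
    cand_r = ens.radials.copy()
    cand_c[idx, which] = new_c
    cand_a[idx, which] = new_a
    cand_r[idx, which] = new_r

    overlap = np.empty(n, dtype=np.bool_)
    overlap_pairs(np.ascontiguousarray(cand_c[:, 0]), np.ascontiguousarray(cand_a[:, 0]),
                  np.ascontiguousarray(cand_c[:, 1]), np.ascontiguousarray(cand_a[:, 1]),
                  ens.geometry.radius_RHC, ens.geometry.height_H, overlap)

    la, lb, sa, sb = ens._junction_points(cand_c, cand_a, cand_r)
    link_ok = np.linalg.norm(la - lb, axis=1) <= 2.0 * ens.patches.linker_radius_R0
    new_stacked = np.linalg.norm(sa - sb, axis=1) <= 2.0 * ens.patches.stacking_radius_R1

    feasible = link_ok & ~overlap
    delta_e = old_stacked.astype(int) - new_stacked.astype(int)  # -1, 0 or +1

    if math.isinf(config.t_star):
        accept = feasible
    elif config.t_star == 0.0:
        accept = feasible & (delta_e <= 0)
    else:
        u = rng.random(n)
        accept = feasible & ((delta_e <= 0) | (u < np.exp(-delta_e / config.t_star)))

    acc_idx = idx[accept]
    ens.centers[acc_idx, which[accept]] = new_c[accept]
    ens.axes[acc_idx, which[accept]] = new_a[accept]
    ens.radials[acc_idx, which[accept]] = new_r[accept]
    return int(np.count_nonzero(accept))


def mc_sweep(ens: Ensemble, config: SimulationConfig, rng,
             max_t: float | None = None, max_r: float | None = None) -> float:
    """One sweep = ``2 * n_dimers`` attempted single-cylinder moves.
    Returns the acceptance fraction."""
    max_t = config.max_translation if max_t is None else max_t
    max_r = config.max_rotation if max_r is None else max_r
    acc = 0
    for _ in range(2):
        acc += _half_sweep(ens, config, rng, max_t, max_r)
    return acc / (2.0 * ens.n_dimers)


def _trend_ok(trace: np.ndarray, n_batches: int = 8) -> bool:
    """True if the tail of the energy trace shows no significant drift.

    The energy series is strongly autocorrelated sweep-to-sweep, so the test
    compares batch means: the tail is split into batches and the first-half
    and second-half batch means must agree within three batch standard
    errors."""
    tail = trace[len(trace) // 2:]
    if len(tail) < 2 * n_batches or np.ptp(tail) == 0:
        return True
    usable = len(tail) - len(tail) % n_batches
    batches = tail[:usable].reshape(n_batches, -1).mean(axis=1)
    half = n_batches // 2
    se = batches.std(ddof=1) / math.sqrt(half)
    drift = abs(batches[half:].mean() - batches[:half].mean())
    return drift <= 3.0 * se * math.sqrt(2.0) + 1e-12


def run(config: SimulationConfig) -> Trajectory:
    """Thermalize, then collect ``n_snapshots`` ensembles separated by
    ``snapshot_interval`` sweeps.  Fully reproducible from ``rng_seed``."""
    rng = np.random.default_rng(config.rng_seed)
    ens = initialize(config, rng)

    max_t, max_r = config.max_translation, config.max_rotation
    trace = []
    acc_window: list[float] = []
    for sweep in range(config.n_thermalization_sweeps):
        acc = mc_sweep(ens, config, rng, max_t, max_r)
        trace.append(ens.total_energy())
        acc_window.append(acc)
        if config.auto_tune and (sweep + 1) % 50 == 0 and sweep < config.n_thermalization_sweeps // 2:
            mean_acc = float(np.mean(acc_window[-50:]))
            if mean_acc < 0.30:
                max_t = max(0.02, max_t * 0.8)
                max_r = max(0.02, max_r * 0.8)
            elif mean_acc > 0.50:
                max_t = min(2.0, max_t * 1.25)
                max_r = min(math.pi, max_r * 1.25)
    # amplitudes frozen from here on (detailed balance during production)

    equilibrated = _trend_ok(np.asarray(trace)) if trace else True
    if not equilibrated:
        warnings.warn("stacking-energy trace still drifting after thermalization",
                      RuntimeWarning, stacklevel=2)

    snapshots = []
    production_acc = []
    for _ in range(config.n_snapshots):
        for _ in range(config.snapshot_interval):
            production_acc.append(mc_sweep(ens, config, rng, max_t, max_r))
            trace.append(ens.total_energy())
        snapshots.append(ens.copy())

    acceptance = float(np.mean(production_acc)) if production_acc else float("nan")
    return Trajectory(snapshots=snapshots, energy_trace=np.asarray(trace),
                      acceptance=acceptance, equilibrated=equilibrated,
                      config=replace(config))


def stacked_fraction(traj: Trajectory) -> tuple[float, float]:
    """Mean stacked fraction over snapshots and its between-snapshot
    standard error."""
    if not traj.snapshots:
        raise ValueError("trajectory has no snapshots")
    fracs = np.array([s.stacked_mask().mean() for s in traj.snapshots])
    if len(fracs) == 1:
        return float(fracs[0]), 0.0
    return float(fracs.mean()), float(fracs.std(ddof=1) / math.sqrt(len(fracs)))
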