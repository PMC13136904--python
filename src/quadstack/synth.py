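"""Synthetic stand-ins for the experimental SAXS and CD measurements.

Every generator is seed-deterministic and returns a machine-readable truth
record carrying all ground-truth parameters, so recovery tests never need to
hard-code expected values.

* :func:`gen_saxs` — dimer SAXS profiles at a known stacked fraction: the
  hard-cylinder model is simulated at T* = 0 (fully stacked) and T* = inf
  (stacking-blind), the two ensemble intensities are mixed as
  ``I = p_st I0 + (1 - p_st) Iinf`` and Q-dependent Gaussian noise is added
  with ``sigma(Q) = I (alpha + beta / sqrt(I/I(0)))`` — about 1% relative
  at low Q, growing where the signal is weak, mimicking synchrotron BioSAXS
  profiles.
* :func:`gen_ratio` — intensity-ratio curves from the closed-form dimer
  structure-factor ratio at known centre-of-mass distances.
* :func:`gen_cd_melt` — CD melting surfaces from a three-state unfolding
  model with Gaussian-band basis spectra mimicking hybrid (folded),
  parallel-like (intermediate) and unfolded G-quadruplex signatures
  (folded: maximum ~290 nm, shoulder ~270 nm, minimum ~240 nm).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import CylinderGeometry
from .mc import SimulationConfig, run
from .cd_melting import CDMeltingMatrix, three_state_fractions
from .scattering import (SAXSProfile, PointCloudConfig, default_q_grid,
                         trajectory_intensity, _sinc)

__all__ = ["SyntheticSAXSSpec", "SyntheticCDSpec", "gen_saxs", "gen_ratio",
           "gen_cd_melt", "simulate_basis"]


@dataclass
class SyntheticSAXSSpec:
    geometry: CylinderGeometry = field(default_factory=CylinderGeometry)
    p_st_true: float = 0.5
    noise_alpha: float = 0.008
    noise_beta: float = 0.002
    q_grid: np.ndarray | None = None
    n_dimers: int = 300
    n_snapshots: int = 10
    points_per_cylinder: int = 50
    paper_scale: bool = False
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_st_true <= 1.0):
            raise ValueError("p_st_true must lie in [0, 1]")
        if self.noise_alpha < 0 or self.noise_beta < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class SyntheticCDSpec:
    wavelengths: np.ndarray | None = None      # default 220-330 nm step 1
    temperatures: np.ndarray | None = None     # default 24-100 C step 2
    dH1: float = 200.0     # kJ/mol
    Tm1: float = 62.0      # C
    dH2: float = 250.0     # kJ/mol
    Tm2: float = 75.0      # C
    noise_mdeg: float = 0.25
    rng_seed: int = 0


def simulate_basis(spec: SyntheticSAXSSpec):
    """Simulated (I0, Iinf) basis intensities for the spec's geometry.

    These are the expensive ingredients of :func:`gen_saxs`; compute them
    once and pass to ``gen_saxs(..., basis=...)`` when generating many noisy
    replicates over the same ensemble.
    """
    q = default_q_grid() if spec.q_grid is None else np.asarray(spec.q_grid, float)
    if spec.paper_scale:
        n, snaps, m = 3000, 50, 100
    else:
        n, snaps, m = spec.n_dimers, spec.n_snapshots, spec.points_per_cylinder
    cfg0 = SimulationConfig(n_dimers=n, t_star=0.0, geometry=spec.geometry,
                            n_snapshots=snaps, rng_seed=spec.rng_seed * 2 + 1)
    cfgi = SimulationConfig(n_dimers=n, t_star=math.inf, geometry=spec.geometry,
                            n_snapshots=snaps, rng_seed=spec.rng_seed * 2 + 2)
    pc = PointCloudConfig(points_per_cylinder=m, rng_seed=spec.rng_seed + 17)
    i0 = trajectory_intensity(run(cfg0), q, pc)
    iinf = trajectory_intensity(run(cfgi), q, pc)
    return i0, iinf


def gen_saxs(spec: SyntheticSAXSSpec, basis=None):
    """Synthetic experimental dimer profile at known p_st.

    Returns ``(I_exp, I0, Iinf, truth)``; ``truth`` records the generator
    parameters and seeds.
    """
    if basis is None:
        basis = simulate_basis(spec)
    i0, iinf = basis
    q = i0.q
    clean = spec.p_st_true * i0.intensity + (1.0 - spec.p_st_true) * iinf.intensity
    i_max = clean.max()
    rel = spec.noise_alpha + spec.noise_beta / np.sqrt(np.maximum(clean / i_max, 1e-12))
    sigma = np.maximum(clean * rel, 1e-12 * i_max)
    rng = np.random.default_rng(spec.rng_seed)
    noisy = clean + rng.normal(0.0, sigma)
    i_exp = SAXSProfile(q=q, intensity=noisy, sigma=sigma)
    truth = {
        "p_st_true": spec.p_st_true,
        "geometry": {"radius_RHC": spec.geometry.radius_RHC,
                     "height_H": spec.geometry.height_H},
        "noise_alpha": spec.noise_alpha,
        "noise_beta": spec.noise_beta,
        "rng_seed": spec.rng_seed,
        "n_dimers": spec.n_dimers if not spec.paper_scale else 3000,
        "n_snapshots": spec.n_snapshots if not spec.paper_scale else 50,
        "points_per_cylinder": spec.points_per_cylinder if not spec.paper_scale else 100,
    }
    return i_exp, i0, iinf, truth


def gen_ratio(R_cm_T: float, R_cm_TL: float, k: float = 1.0,
              noise: float = 0.01, q_grid: np.ndarray | None = None,
              rng_seed: int = 0):
    """Closed-form dimer intensity-ratio curve with Gaussian noise.

    ``noise`` is the relative standard deviation applied pointwise.
    Returns ``(q, ratio, sigma, truth)``.
    """
    if R_cm_T <= 0 or R_cm_TL <= 0:
        raise ValueError("distances must be positive")
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, float)
    clean = k * (1.0 + _sinc(q * R_cm_T)) / (1.0 + _sinc(q * R_cm_TL))
    sigma = np.maximum(np.abs(clean) * noise, 1e-12)
    rng = np.random.default_rng(rng_seed)
    ratio = clean + rng.normal(0.0, sigma) if noise > 0 else clean.copy()
    truth = {"R_cm_T": R_cm_T, "R_cm_TL": R_cm_TL, "k": k,
             "noise": noise, "rng_seed": rng_seed}
    return q, ratio, sigma, truth


def _gaussian_bands(lam: np.ndarray, bands) -> np.ndarray:
    out = np.zeros_like(lam)
    for center, width, amp in bands:
        out += amp * np.exp(-0.5 * ((lam - center) / width) ** 2)
    return out


# Species basis spectra (mdeg): folded hybrid G4 (max 290, shoulder 270,
# min 240), parallel-like intermediate (max ~262, min ~240), unfolded coil
# (weak residual signal).
_FOLDED_BANDS = [(290.0, 9.0, 10.0), (270.0, 8.0, 5.0), (240.0, 8.0, -8.0)]
_INTERMEDIATE_BANDS = [(262.0, 9.0, 12.0), (240.0, 7.0, -8.0)]
_UNFOLDED_BANDS = [(275.0, 20.0, 1.5)]


def gen_cd_melt(spec: SyntheticCDSpec):
    """Synthetic CD melting surface D = B F(T) + noise.

    ``B`` holds the three species basis spectra (columns) and ``F`` the
    sequential three-state fraction curves.  Returns
    ``(CDMeltingMatrix, truth)``.
    """
    lam = (np.arange(220.0, 330.0 + 0.5, 1.0) if spec.wavelengths is None
           else np.asarray(spec.wavelengths, float))
    temp = (np.arange(24.0, 100.0 + 0.5, 2.0) if spec.temperatures is None
            else np.asarray(spec.temperatures, float))
    B = np.column_stack([_gaussian_bands(lam, _FOLDED_BANDS),
                         _gaussian_bands(lam, _INTERMEDIATE_BANDS),
                         _gaussian_bands(lam, _UNFOLDED_BANDS)])
    F = three_state_fractions(temp, spec.dH1, spec.Tm1, spec.dH2, spec.Tm2)
    clean = B @ F
    rng = np.random.default_rng(spec.rng_seed)
    noisy = clean + rng.normal(0.0, spec.noise_mdeg, size=clean.shape) \
        if spec.noise_mdeg > 0 else clean
    mat = CDMeltingMatrix(wavelengths=lam, temperatures=temp, ellipticity=noisy)
    truth = {"dH1": spec.dH1, "Tm1": spec.Tm1, "dH2": spec.dH2, "Tm2": spec.Tm2,
             "noise_mdeg": spec.noise_mdeg, "rng_seed": spec.rng_seed,
             "basis_bands": {"folded": _FOLDED_BANDS,
                             "intermediate": _INTERMEDIATE_BANDS,
                             "unfolded": _UNFOLDED_BANDS}}
    return mat, truth
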