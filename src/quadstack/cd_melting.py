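"""Thermal-melting analysis of circular dichroism spectra.

The spectra-vs-temperature matrix D (wavelengths x temperatures, mdeg) is
factorized by SVD, D = U S V^T.  The number of spectroscopically distinct
species is read off from the singular values and the smoothness of the U and
V columns: a component counts as significant when its relative variance
exceeds a floor and the lag-1 autocorrelation of both its (unit-normalized)
basis spectrum and amplitude vector exceeds a threshold (default 0.8) —
noise components decorrelate point-to-point, real spectral components do not.

The significant amplitude vectors are then fitted globally to a sequential
three-state unfolding model, folded <=> intermediate <=> unfolded, with
van't Hoff equilibrium constants

    K_i(T) = exp[-dH_i/R (1/T - 1/T_m,i)],   T in kelvin,

species fractions f_F = 1/(1 + K1 + K1 K2), f_I = K1 f_F, f_U = K1 K2 f_F,
and per-column amplitudes obtained by linear projection (so the nonlinear
search runs over the four thermodynamic parameters only).  The headline
melting temperature is reported as the temperature where f_F = 1/2.

RSQ, the root of the summed squared pointwise differences between two
spectra (mdeg), quantifies global topology changes upon ligand binding.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import lmfit
import numpy as np

GAS_CONSTANT_KJ = 8.31446261815324e-3  # kJ/(mol K)

__all__ = ["CDMeltingMatrix", "CDSpectrum", "SVDResult", "ThreeStateFit",
           "svd_decompose", "significant_components", "fit_three_state",
           "three_state_fractions", "rsq"]


@dataclass
class CDMeltingMatrix:
    """Ellipticity (mdeg) vs wavelength (rows, nm) and temperature (cols, C)."""

    wavelengths: np.ndarray
    temperatures: np.ndarray
    ellipticity: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0) or np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("wavelength and temperature grids must be strictly increasing")
        if self.ellipticity.shape != (len(self.wavelengths), len(self.temperatures)):
            raise ValueError("ellipticity matrix shape does not match the grids")


@dataclass
class CDSpectrum:
    wavelengths: np.ndarray
    ellipticity: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.wavelengths.shape != self.ellipticity.shape:
            raise ValueError("spectrum grids mismatch")


@dataclass
class SVDResult:
    U: np.ndarray
    S: np.ndarray
    V: np.ndarray               # columns are amplitude-vs-temperature vectors
    temperatures: np.ndarray
    wavelengths: np.ndarray
    relative_variance: np.ndarray
    autocorr_U: np.ndarray
    autocorr_V: np.ndarray


@dataclass
class ThreeStateFit:
    dH1: float
    dH1_err: float
    Tm1: float
    Tm1_err: float
    dH2: float
    dH2_err: float
    Tm2: float
    Tm2_err: float
    amplitudes: np.ndarray      # (n_components, 3) species -> V-column weights
    chi2_reduced: float
    fractions: np.ndarray       # (3, n_T): f_F, f_I, f_U
    temperatures: np.ndarray
    headline_Tm: float


def _lag1_autocorr(x: np.ndarray) -> float:
    """Lag-1 autocorrelation sum of a unit-normalized vector."""
    x = np.asarray(x, dtype=float)
    n = np.linalg.norm(x)
    if n == 0:
        return 0.0
    x = x / n
    return float(np.sum(x[:-1] * x[1:]))


def svd_decompose(D: CDMeltingMatrix) -> SVDResult:
    """Full SVD of the melting matrix with a deterministic sign convention
    (largest-magnitude element of each U column made positive)."""
    M = D.ellipticity
    if not np.all(np.isfinite(M)):
        raise ValueError("melting matrix contains non-finite entries")
    if M.shape[0] < 3 or M.shape[1] < 3:
        raise ValueError("need at least 3 wavelengths and 3 temperatures")
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    V = Vt.T
    for j in range(U.shape[1]):
        k = np.argmax(np.abs(U[:, j]))
        if U[k, j] < 0:
            U[:, j] = -U[:, j]
            V[:, j] = -V[:, j]
    tot = float(np.sum(S**2))
    rel = S**2 / tot if tot > 0 else np.zeros_like(S)
    ac_u = np.array([_lag1_autocorr(U[:, j]) for j in range(U.shape[1])])
    ac_v = np.array([_lag1_autocorr(V[:, j]) for j in range(V.shape[1])])
    return SVDResult(U=U, S=S, V=V, temperatures=D.temperatures,
                     wavelengths=D.wavelengths, relative_variance=rel,
                     autocorr_U=ac_u, autocorr_V=ac_v)


def significant_components(res: SVDResult, ac_threshold: float = 0.8,
                           variance_floor: float = 1e-3) -> int:
    """Number of leading significant components: relative variance above the
    floor and lag-1 autocorrelation of both U and V columns above the
    threshold.  Counting stops at the first insignificant component."""
    count = 0
    for j in range(len(res.S)):
        ok = (res.relative_variance[j] >= variance_floor
              and res.autocorr_U[j] >= ac_threshold
              and res.autocorr_V[j] >= ac_threshold)
        if not ok:
            break
        count += 1
    return count


def three_state_fractions(T_celsius: np.ndarray, dH1: float, Tm1: float,
                          dH2: float, Tm2: float) -> np.ndarray:
    """Species fractions (f_F, f_I, f_U) of the sequential F<=>I<=>U model.
    Enthalpies in kJ/mol, temperatures in Celsius."""
    T = np.asarray(T_celsius, dtype=float) + 273.15
    k1 = np.exp(-dH1 / GAS_CONSTANT_KJ * (1.0 / T - 1.0 / (Tm1 + 273.15)))
    k2 = np.exp(-dH2 / GAS_CONSTANT_KJ * (1.0 / T - 1.0 / (Tm2 + 273.15)))
    f_f = 1.0 / (1.0 + k1 + k1 * k2)
    return np.vstack([f_f, k1 * f_f, k1 * k2 * f_f])


def _project_amplitudes(F: np.ndarray, V_cols: np.ndarray, weights: np.ndarray):
    """Least-squares amplitudes mapping species fractions to each V column
    (variable projection); returns (amplitudes, weighted residual vector)."""
    A, *_ = np.linalg.lstsq(F.T, V_cols, rcond=None)
    resid = (F.T @ A - V_cols) * weights[None, :]
    return A.T, resid.T.ravel()


def fit_three_state(res: SVDResult, n_components: int | None = None,
                    tm_starts=((45.0, 65.0), (55.0, 75.0), (65.0, 85.0), (35.0, 55.0)),
                    ) -> ThreeStateFit:
    """Global three-state fit of the significant V columns.

    Columns are weighted by their singular values so dominant components
    steer the thermodynamics.  Multi-start over (Tm1, Tm2) grids; the
    transition ordering Tm1 <= Tm2 is restored after fitting if needed.
    """
    if n_components is None:
        n_components = max(significant_components(res), 2)
    n_components = int(n_components)
    if n_components < 1:
        raise ValueError("need at least one significant component")
    V_cols = res.V[:, :n_components]
    weights = res.S[:n_components] / res.S[0]
    T = res.temperatures

    def residual(p):
        F = three_state_fractions(T, p["dH1"].value, p["Tm1"].value,
                                  p["dH2"].value, p["Tm2"].value)
        _, r = _project_amplitudes(F, V_cols, weights)
        return r

    t_lo, t_hi = float(T[0]), float(T[-1])
    best = None
    messages = []
    for tm1_0, tm2_0 in tm_starts:
        p = lmfit.Parameters()
        p.add("dH1", value=200.0, min=20.0, max=1500.0)
        p.add("Tm1", value=tm1_0, min=t_lo - 40.0, max=t_hi + 60.0)
        p.add("dH2", value=250.0, min=20.0, max=1500.0)
        p.add("Tm2", value=tm2_0, min=t_lo - 40.0, max=t_hi + 60.0)
        try:
            out = lmfit.minimize(residual, p, method="leastsq")
        except Exception as exc:  # pragma: no cover
            messages.append(f"start {(tm1_0, tm2_0)}: {exc}")
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None:
        raise RuntimeError("three-state fit failed for all starts: " + "; ".join(messages))

    pars = {k: best.params[k].value for k in ("dH1", "Tm1", "dH2", "Tm2")}
    errs = {k: (best.params[k].stderr if best.params[k].stderr is not None else float("nan"))
            for k in ("dH1", "Tm1", "dH2", "Tm2")}
    if pars["Tm1"] > pars["Tm2"]:
        pars["dH1"], pars["dH2"] = pars["dH2"], pars["dH1"]
        pars["Tm1"], pars["Tm2"] = pars["Tm2"], pars["Tm1"]
        errs["dH1"], errs["dH2"] = errs["dH2"], errs["dH1"]
        errs["Tm1"], errs["Tm2"] = errs["Tm2"], errs["Tm1"]

    F = three_state_fractions(T, pars["dH1"], pars["Tm1"], pars["dH2"], pars["Tm2"])
    amps, resid = _project_amplitudes(F, V_cols, weights)
    dof = max(resid.size - 4 - amps.size, 1)
    chi2_red = float(resid @ resid) / dof

    # headline Tm: temperature where the folded fraction crosses 1/2
    f_f = F[0]
    if f_f[0] < 0.5:
        headline = float(T[0])
    elif f_f[-1] > 0.5:
        headline = float(T[-1])
    else:
        headline = float(np.interp(0.5, f_f[::-1], T[::-1]))

    return ThreeStateFit(dH1=pars["dH1"], dH1_err=errs["dH1"],
                         Tm1=pars["Tm1"], Tm1_err=errs["Tm1"],
                         dH2=pars["dH2"], dH2_err=errs["dH2"],
                         Tm2=pars["Tm2"], Tm2_err=errs["Tm2"],
                         amplitudes=amps, chi2_reduced=chi2_red,
                         fractions=F, temperatures=T, headline_Tm=headline)


def rsq(spec_a: CDSpectrum, spec_b: CDSpectrum, resample: bool = False) -> float:
    """Root of the sum of squared pointwise spectral differences (mdeg).

    Requires identical wavelength grids unless ``resample`` is set, in which
    case ``spec_b`` is linearly interpolated onto ``spec_a``'s grid.
    """
    if spec_a.wavelengths.shape != spec_b.wavelengths.shape or \
            not np.allclose(spec_a.wavelengths, spec_b.wavelengths):
        if not resample:
            raise ValueError("wavelength grids differ; pass resample=True to interpolate")
        b = np.interp(spec_a.wavelengths, spec_b.wavelengths, spec_b.ellipticity)
    else:
        b = spec_b.ellipticity
    diff = spec_a.ellipticity - b
    return float(math.sqrt(np.sum(diff**2)))
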