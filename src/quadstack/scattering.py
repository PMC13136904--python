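"""SAXS observables for point-decorated hard-cylinder ensembles.

The simulated intensity replaces every cylinder by scattering points drawn
uniformly from its volume and evaluates orientation-averaged Debye sums over
intra-dimer point pairs (dimers are dilute and mutually non-interacting, so
cross-dimer interference is absent and the ensemble intensity is the average
of independent single-dimer intensities).

The Debye estimator is unbiased: diagonal self-terms are dropped and
same-cylinder / cross-cylinder pair classes are weighted ``1/(m(m-1))`` and
``1/m**2`` respectively, so that ``I(0) = 1`` and ``E[I(Q)]`` equals the
continuous normalized dimer intensity for any number of points per cylinder.
A naive raw double sum instead carries an incoherent floor of order the point
count that swamps the coherent signal at high Q.

Also here: the closed-form dimer structure factor ``S(Q) = 2(1 + sinc(QR))``,
the orientation-averaged cylinder form factor, automated Guinier fitting,
regularized indirect-Fourier p(r) reconstruction and dimensionless Kratky
transforms.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy.optimize import nnls

from .geometry import CylinderGeometry

__all__ = [
    "SAXSProfile", "GuinierFit", "PairDistanceDistribution", "PointCloudConfig",
    "default_q_grid", "decorate_points", "debye_intensity", "trajectory_intensity",
    "cylinder_form_factor", "closed_form_s", "guinier_rg", "pofr", "kratky",
]


@dataclass
class SAXSProfile:
    """A scattering profile I(Q) on a strictly increasing Q grid (nm^-1)."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    q_unit: str = "nm^-1"

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be matching 1-D arrays")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if np.any(self.q <= 0):
            raise ValueError("q values must be positive")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma shape mismatch")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where present")
        if self.q_unit not in ("nm^-1", "A^-1"):
            raise ValueError("q_unit must be 'nm^-1' or 'A^-1'")

    def to_nm(self) -> "SAXSProfile":
        if self.q_unit == "nm^-1":
            return self
        return SAXSProfile(self.q * 10.0, self.intensity, self.sigma, "nm^-1")


@dataclass
class GuinierFit:
    Rg: float
    Rg_err: float
    I0: float
    I0_err: float
    q_range_used: tuple[float, float]
    n_points: int
    r_squared: float
    q_rg_max: float


@dataclass
class PairDistanceDistribution:
    r: np.ndarray
    p: np.ndarray
    D_max: float
    Rg_real: float
    regularization: float


@dataclass
class PointCloudConfig:
    points_per_cylinder: int = 100
    rng_seed: int = 0

    def __post_init__(self):
        if self.points_per_cylinder < 1:
            raise ValueError("points_per_cylinder must be >= 1")


def default_q_grid(n: int = 200, q_min: float = 0.044, q_max: float = 5.21) -> np.ndarray:
    """Log-spaced Q grid (nm^-1) spanning the measured BioSAXS range."""
    return np.geomspace(q_min, q_max, n)


def _sinc(x: np.ndarray) -> np.ndarray:
    """sin(x)/x with the x -> 0 limit handled (numpy sinc is sin(pi x)/(pi x))."""
    return np.sinc(np.asarray(x) / np.pi)


# ---------------------------------------------------------------------------
# point decoration and Debye sums
# ---------------------------------------------------------------------------

def decorate_points(ensemble, geometry: CylinderGeometry | None = None,
                    cfg: PointCloudConfig | None = None, rng=None) -> np.ndarray:
    """Uniform scattering points inside every cylinder of an MC snapshot.

    Returns an array of shape ``(n_dimers, 2, m, 3)``.  Fresh points should
    be drawn for every snapshot (pass a shared ``rng``).
    """
    cfg = PointCloudConfig() if cfg is None else cfg
    geometry = ensemble.geometry if geometry is None else geometry
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    centers = ensemble.centers  # (n, 2, 3)
    axes = ensemble.axes
    radials = ensemble.radials
    n = centers.shape[0]
    m = cfg.points_per_cylinder

    z = rng.uniform(-0.5 * geometry.height_H, 0.5 * geometry.height_H, size=(n, 2, m))
    rad = geometry.radius_RHC * np.sqrt(rng.uniform(0.0, 1.0, size=(n, 2, m)))
    theta = rng.uniform(0.0, 2.0 * math.pi, size=(n, 2, m))

    e1 = radials
    e2 = np.cross(axes, radials)
    pts = (centers[:, :, None, :]
           + z[..., None] * axes[:, :, None, :]
           + (rad * np.cos(theta))[..., None] * e1[:, :, None, :]
           + (rad * np.sin(theta))[..., None] * e2[:, :, None, :])
    return pts


def _pair_histograms(pts: np.ndarray, bin_width: float, chunk: int = 64):
    """(same-cylinder, cross-cylinder) pair-distance histograms for a
    snapshot's point array of shape (n, 2, m, 3).

    Alongside counts, per-bin distance sums are accumulated so the transform
    can evaluate sinc at the mean distance of each bin (first-order exact in
    the bin width)."""
    n, _, m, _ = pts.shape
    d_cap = 2.0 * np.linalg.norm(pts.reshape(n, 2 * m, 3) -
                                 pts.reshape(n, 2 * m, 3).mean(axis=1, keepdims=True),
                                 axis=2).max() + bin_width
    nbins = int(np.ceil(d_cap / bin_width)) + 1
    edges = np.arange(nbins + 1) * bin_width
    hist_same = np.zeros(nbins)
    hist_cross = np.zeros(nbins)
    dsum_same = np.zeros(nbins)
    dsum_cross = np.zeros(nbins)
    iu = np.triu_indices(m, k=1)
    for lo in range(0, n, chunk):
        p = pts[lo:lo + chunk]
        for cyl in (0, 1):
            x = p[:, cyl]  # (c, m, 3)
            d = np.linalg.norm(x[:, :, None, :] - x[:, None, :, :], axis=-1)
            dd = d[:, iu[0], iu[1]].ravel()
            hist_same += np.histogram(dd, bins=edges)[0]
            dsum_same += np.histogram(dd, bins=edges, weights=dd)[0]
        d = np.linalg.norm(p[:, 0][:, :, None, :] - p[:, 1][:, None, :, :], axis=-1).ravel()
        hist_cross += np.histogram(d, bins=edges)[0]
        dsum_cross += np.histogram(d, bins=edges, weights=d)[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    mean_same = np.where(hist_same > 0, dsum_same / np.maximum(hist_same, 1), centers)
    mean_cross = np.where(hist_cross > 0, dsum_cross / np.maximum(hist_cross, 1), centers)
    return mean_same, mean_cross, hist_same, hist_cross


def debye_intensity(points: np.ndarray, q: np.ndarray, method: str = "histogram",
                    bin_width: float = 0.005) -> SAXSProfile:
    """Normalized ensemble intensity from one snapshot's point decoration.

    ``points`` has shape (n_dimers, 2, m, 3).  The same-cylinder and
    cross-cylinder Debye sums are weighted so the estimator is unbiased for
    the continuous normalized dimer intensity, with I(0) = 1.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 4 or points.shape[1] != 2 or points.shape[0] < 1:
        raise ValueError("points must have shape (n_dimers, 2, m, 3), n_dimers >= 1")
    q = np.asarray(q, dtype=float)
    n, _, m, _ = points.shape

    if method == "direct":
        intensity = np.zeros_like(q)
        for i in range(n):
            flat = points[i].reshape(2 * m, 3)
            d = np.linalg.norm(flat[:, None, :] - flat[None, :, :], axis=-1)
            same = np.zeros(d.shape, dtype=bool)
            same[:m, :m] = True
            same[m:, m:] = True
            np.fill_diagonal(same, False)
            cross = ~same
            np.fill_diagonal(cross, False)
            qr_same = np.outer(q, d[same])
            qr_cross = np.outer(q, d[cross])
            if m > 1:
                term_same = _sinc(qr_same).sum(axis=1) / (2.0 * m * (m - 1))
            else:
                term_same = 1.0  # point-particle convention: no intra structure
            term_cross = _sinc(qr_cross).sum(axis=1) / (2.0 * m * m)
            intensity += 0.25 * 2.0 * (term_same + term_cross)
        intensity /= n
    elif method == "histogram":
        mean_same, mean_cross, hist_same, hist_cross = _pair_histograms(points, bin_width)
        ks = hist_same > 0
        kc = hist_cross > 0
        # hist_same counts unordered same-cylinder pairs (both cylinders)
        if m > 1:
            w_same = (_sinc(np.outer(q, mean_same[ks])) @ hist_same[ks]) / (n * m * (m - 1))
        else:
            w_same = 1.0
        w_cross = (_sinc(np.outer(q, mean_cross[kc])) @ hist_cross[kc]) / (n * m * m)
        intensity = 0.25 * 2.0 * (w_same + w_cross)
    else:
        raise ValueError("method must be 'direct' or 'histogram'")
    return SAXSProfile(q=q, intensity=intensity)


def trajectory_intensity(trajectory, q: np.ndarray,
                         cfg: PointCloudConfig | None = None) -> SAXSProfile:
    """Snapshot-averaged normalized intensity of an MC trajectory, with the
    between-snapshot standard error as sigma."""
    cfg = PointCloudConfig() if cfg is None else cfg
    rng = np.random.default_rng(cfg.rng_seed)
    curves = []
    for snap in trajectory.snapshots:
        pts = decorate_points(snap, snap.geometry, cfg, rng)
        curves.append(debye_intensity(pts, q).intensity)
    curves = np.array(curves)
    mean = curves.mean(axis=0)
    k = len(curves)
    if k > 1:
        sigma = curves.std(axis=0, ddof=1) / math.sqrt(k)
        sigma = np.maximum(sigma, 1e-12 * mean.max())
    else:
        sigma = None
    return SAXSProfile(q=q, intensity=mean, sigma=sigma)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def cylinder_form_factor(q: np.ndarray, geometry: CylinderGeometry,
                         n_nodes: int = 256) -> SAXSProfile:
    """Orientation-averaged form factor of a uniform cylinder, P(0) = 1.

    Gauss-Legendre quadrature over the angle between Q and the cylinder axis:
    ``P(Q) = int_0^{pi/2} [2 J1(x)/x * sin(y)/y]^2 sin(a) da`` with
    ``x = Q R sin(a)`` and ``y = Q H cos(a) / 2``.
    """
    q = np.asarray(q, dtype=float)
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    alpha = 0.25 * math.pi * (nodes + 1.0)
    w = 0.25 * math.pi * weights
    sin_a = np.sin(alpha)
    cos_a = np.cos(alpha)
    x = np.outer(q, sin_a) * geometry.radius_RHC
    y = np.outer(q, cos_a) * (0.5 * geometry.height_H)
    with np.errstate(invalid="ignore", divide="ignore"):
        bess = np.where(x > 1e-12, 2.0 * special.j1(x) / np.where(x > 1e-12, x, 1.0), 1.0)
    amp = bess * _sinc(y)
    p = (amp**2 * sin_a) @ w
    return SAXSProfile(q=q, intensity=p)


def closed_form_s(q: np.ndarray, R: float) -> np.ndarray:
    """Structure factor of a rigid two-site dimer at fixed centre separation
    R, orientation-averaged: ``S(Q) = 2 (1 + sin(QR)/(QR))``; S(0) = 4."""
    if R <= 0:
        raise ValueError("R must be positive")
    return 2.0 * (1.0 + _sinc(np.asarray(q, dtype=float) * R))


# ---------------------------------------------------------------------------
# Guinier analysis
# ---------------------------------------------------------------------------

def guinier_rg(profile: SAXSProfile, q_rg_limit: float = 1.3,
               min_points: int = 10) -> GuinierFit:
    """Automated Guinier fit: scan candidate low-Q windows, keep those whose
    fitted Rg satisfies ``q_max * Rg <= q_rg_limit`` and whose linear fit in
    (Q^2, ln I) is of acceptable quality, and return the longest admissible
    window (ties: smaller q_min)."""
    prof = profile.to_nm()
    pos = prof.intensity > 0
    q = prof.q[pos]
    i = prof.intensity[pos]
    sig = prof.sigma[pos] if prof.sigma is not None else None
    if len(q) < min_points:
        raise ValueError("profile has too few positive low-Q points")

    x = q**2
    y = np.log(i)
    w = (i / sig) ** 2 if sig is not None else np.ones_like(y)  # var(ln I) = (sig/I)^2

    # candidate windows only in the low-Q third of the grid for starts
    n = len(q)
    best = None
    max_start = max(1, n // 3)
    for a in range(max_start):
        for b in range(a + min_points, n + 1):
            xs, ys, ws = x[a:b], y[a:b], w[a:b]
            W = ws.sum()
            xm = (ws * xs).sum() / W
            ym = (ws * ys).sum() / W
            sxx = (ws * (xs - xm) ** 2).sum()
            if sxx <= 0:
                continue
            slope = (ws * (xs - xm) * (ys - ym)).sum() / sxx
            if slope >= 0:
                break
            rg = math.sqrt(-3.0 * slope)
            if q[b - 1] * rg > q_rg_limit:
                break  # larger windows only get worse
            inter = ym - slope * xm
            resid = ys - (inter + slope * xs)
            ss_res = (ws * resid**2).sum()
            ss_tot = (ws * (ys - ym) ** 2).sum()
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            dof = (b - a) - 2
            chi2_red = ss_res / dof if dof > 0 else 0.0
            ok = (chi2_red < 3.0) if sig is not None else (r2 > 0.995)
            if not ok:
                continue
            slope_var = (chi2_red if sig is None else max(chi2_red, 1.0)) / sxx
            cand = (b - a, -a, rg, inter, slope_var, sxx, xm, W, a, b, r2)
            if best is None or cand[:2] > best[:2]:
                best = cand
    if best is None:
        raise ValueError("Guinier range not found")
    length, _, rg, inter, slope_var, sxx, xm, W, a, b, r2 = best
    slope_err = math.sqrt(slope_var)
    rg_err = 1.5 * slope_err / rg  # d(rg)/d(slope) = 3/(2 rg)
    i0 = math.exp(inter)
    inter_var = slope_var * (sxx / W + xm**2)
    return GuinierFit(Rg=rg, Rg_err=rg_err, I0=i0, I0_err=i0 * math.sqrt(inter_var),
                      q_range_used=(q[a], q[b - 1]), n_points=length,
                      r_squared=r2, q_rg_max=q[b - 1] * rg)


# ---------------------------------------------------------------------------
# indirect Fourier transform p(r)
# ---------------------------------------------------------------------------

def pofr(profile: SAXSProfile, D_max: float, n_r: int = 80,
         alpha: float | None = None) -> PairDistanceDistribution:
    """Regularized indirect-Fourier reconstruction of the pair-distance
    distribution on [0, D_max].

    Solves a non-negative least-squares problem for p(r) with a
    second-difference smoothness penalty and endpoint constraints
    p(0) = p(D_max) = 0.  When ``alpha`` is None, the penalty weight is
    chosen by a discrepancy heuristic: the largest weight whose chi-square
    stays within 10% of the minimum over a log-spaced scan.
    """
    if D_max <= 0:
        raise ValueError("D_max must be positive")
    prof = profile.to_nm()
    q = prof.q
    i_obs = prof.intensity
    sig = prof.sigma if prof.sigma is not None else np.full_like(i_obs, max(1e-12, 1e-3 * i_obs.max()))

    r = np.linspace(0.0, D_max, n_r)
    dr = r[1] - r[0]
    # I(q) = 4 pi int p(r) sinc(qr) dr ; interior nodes only (endpoints = 0)
    A = 4.0 * math.pi * _sinc(np.outer(q, r[1:-1])) * dr
    Aw = A / sig[:, None]
    bw = i_obs / sig

    m = n_r - 2
    D2 = np.zeros((m, m))
    for j in range(m):
        D2[j, j] = -2.0
        if j > 0:
            D2[j, j - 1] = 1.0
        if j < m - 1:
            D2[j, j + 1] = 1.0

    scale = np.linalg.norm(Aw.T @ Aw) / max(np.linalg.norm(D2.T @ D2), 1e-30)

    def solve(al):
        stacked = np.vstack([Aw, math.sqrt(al * scale) * D2])
        rhs = np.concatenate([bw, np.zeros(m)])
        sol, _ = nnls(stacked, rhs, maxiter=10 * m)
        chi2 = float(np.sum((Aw @ sol - bw) ** 2)) / len(q)
        return sol, chi2

    if alpha is None:
        alphas = np.geomspace(1e-10, 1e0, 11)
        results = [solve(al) for al in alphas]
        chi2s = np.array([c for _, c in results])
        chi_min = chi2s.min()
        admissible = np.where(chi2s <= chi_min * 1.1 + 1e-12)[0]
        pick = admissible[-1]  # smoothest admissible solution
        sol = results[pick][0]
        alpha_used = float(alphas[pick])
    else:
        sol, _ = solve(alpha)
        alpha_used = float(alpha)

    p = np.zeros(n_r)
    p[1:-1] = sol
    norm = np.trapezoid(p, r)
    if norm <= 0:
        raise ValueError("p(r) inversion ill-conditioned: zero mass recovered")
    rg2 = np.trapezoid(r**2 * p, r) / (2.0 * norm)
    return PairDistanceDistribution(r=r, p=p, D_max=float(D_max),
                                    Rg_real=math.sqrt(rg2), regularization=alpha_used)


# ---------------------------------------------------------------------------
# Kratky transform
# ---------------------------------------------------------------------------

def kratky(profile: SAXSProfile, i0: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Dimensionless Kratky curve ``(Q, Q^2 I(Q)/I(0))``.  If ``i0`` is not
    given it is taken from the automated Guinier fit."""
    prof = profile.to_nm()
    if i0 is None:
        i0 = guinier_rg(prof).I0
    if not (i0 > 0):
        raise ValueError("I(0) must be positive")
    return prof.q, prof.q**2 * prof.intensity / i0
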