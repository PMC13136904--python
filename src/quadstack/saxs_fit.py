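"""Fitting SAXS data with the hard-cylinder dimer model.

Three fits are provided:

* :func:`fit_pst` — the stacked fraction p_st from the two-state linear
  combination ``I(Q) = A (p_st I0(Q) + (1 - p_st) Iinf(Q)) + bckg``, where
  ``I0`` and ``Iinf`` are simulated ensemble intensities at T* = 0 (fully
  stacked) and T* = inf (stacking-blind).  Reparametrized as a0 = A p_st,
  a1 = A (1 - p_st) and solved as a bound-constrained weighted linear least
  squares, which enforces 0 <= p_st <= 1 by construction.
* :func:`fit_ratio` — the effective inter-unit centre-of-mass distances from
  the intensity ratio model
  ``R(Q) = k (1 + sinc(Q R_T)) / (1 + sinc(Q R_TL))``
  fitted simultaneously over a set of free/complex curve ratios with the
  free-dimer distance R_T shared across the dataset.
* :func:`grid_search_geometry` — the cylinder-dimension scan: R_HC over a
  grid, and for each R_HC three heights in 0.06 nm steps centred on the
  value that keeps the single-cylinder Rg constant.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.optimize import lsq_linear

from .geometry import CylinderGeometry
from .scattering import SAXSProfile, PointCloudConfig, _sinc, trajectory_intensity

__all__ = ["PstFit", "RatioDataset", "RatioFit", "GeometrySearchResult",
           "fit_pst", "compute_ratio", "fit_ratio", "grid_search_geometry"]


@dataclass
class PstFit:
    p_st: float
    p_st_err: float
    A: float
    A_err: float
    bckg: float
    bckg_err: float
    chi2_reduced: float
    at_boundary: bool


@dataclass
class RatioDataset:
    q: np.ndarray
    ratio: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""


@dataclass
class RatioFit:
    R_cm_T: float
    R_cm_T_err: float
    R_cm_TL: np.ndarray
    R_cm_TL_err: np.ndarray
    k: np.ndarray
    k_err: np.ndarray
    chi2_reduced: float
    labels: list


@dataclass
class GeometrySearchResult:
    best_geometry: CylinderGeometry
    best_pst_fit: PstFit
    table: list  # dicts: radius_RHC, height_H, chi2_reduced, p_st
    rg_ref: float


def _common_grid(I_exp: SAXSProfile, I0: SAXSProfile, Iinf: SAXSProfile):
    """Interpolate the two model curves onto the experimental Q grid
    (restricted to the overlapping range)."""
    e = I_exp.to_nm()
    m0 = I0.to_nm()
    mi = Iinf.to_nm()
    lo = max(m0.q[0], mi.q[0], e.q[0])
    hi = min(m0.q[-1], mi.q[-1], e.q[-1])
    sel = (e.q >= lo) & (e.q <= hi)
    if sel.sum() < 5:
        raise ValueError("fewer than 5 overlapping Q points between data and model")
    q = e.q[sel]
    y = e.intensity[sel]
    sig = e.sigma[sel] if e.sigma is not None else None

    def interp(prof):
        val = np.interp(q, prof.q, prof.intensity)
        err = np.interp(q, prof.q, prof.sigma) if prof.sigma is not None else None
        return val, err

    b0, s0 = interp(m0)
    bi, si = interp(mi)
    return q, y, sig, b0, s0, bi, si


def fit_pst(I_exp: SAXSProfile, I0: SAXSProfile, Iinf: SAXSProfile,
            cond_limit: float = 1e6) -> PstFit:
    """Weighted two-state linear-combination fit for the stacked fraction.

    Weights are 1/sigma^2 with the experimental and simulated (Monte Carlo)
    uncertainties added in quadrature where available.
    """
    q, y, sig, b0, s0, bi, si = _common_grid(I_exp, I0, Iinf)

    var = np.zeros_like(y)
    if sig is not None:
        var += sig**2
    if s0 is not None:
        var += s0**2
    if si is not None:
        var += si**2
    w = 1.0 / np.sqrt(var) if var.any() else np.ones_like(y)

    X = np.column_stack([b0, bi, np.ones_like(y)])
    # collinearity guard: the two basis curves must be distinguishable
    basis = (X[:, :2] * w[:, None])
    cond = np.linalg.cond(basis)
    if cond > cond_limit:
        raise ValueError("basis indistinguishable: I0 and Iinf are collinear "
                         f"(condition number {cond:.2e})")

    res = lsq_linear(X * w[:, None], y * w,
                     bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]))
    a0, a1, bckg = res.x
    resid = (X @ res.x - y) * w
    dof = max(len(y) - 3, 1)
    chi2_red = float(resid @ resid) / dof

    # covariance from the weighted normal matrix (interior-point approx.)
    Xw = X * w[:, None]
    cov = np.linalg.pinv(Xw.T @ Xw) * max(chi2_red, 1.0)
    A = a0 + a1
    if A <= 0:
        raise ValueError("degenerate fit: total scale A <= 0")
    p_st = a0 / A
    # p = a0/(a0+a1): grad = [a1, -a0]/A^2
    g = np.array([a1, -a0, 0.0]) / A**2
    p_err = float(np.sqrt(g @ cov @ g))
    gA = np.array([1.0, 1.0, 0.0])
    a_err = float(np.sqrt(gA @ cov @ gA))
    boundary = bool(p_st < 1e-9 or p_st > 1 - 1e-9)
    return PstFit(p_st=float(p_st), p_st_err=p_err, A=float(A), A_err=a_err,
                  bckg=float(bckg), bckg_err=float(np.sqrt(cov[2, 2])),
                  chi2_reduced=chi2_red, at_boundary=boundary)


def compute_ratio(I_T: SAXSProfile, I_TL: SAXSProfile,
                  max_rel_err: float = 0.5, label: str = "") -> RatioDataset:
    """Pointwise intensity ratio R(Q) = I_T / I_TL with first-order error
    propagation.  The denominator is interpolated onto the numerator grid;
    points with near-zero denominator or relative error above
    ``max_rel_err`` are dropped."""
    t = I_T.to_nm()
    d = I_TL.to_nm()
    sel = (t.q >= d.q[0]) & (t.q <= d.q[-1])
    q = t.q[sel]
    num = t.intensity[sel]
    den = np.interp(q, d.q, d.intensity)
    num_s = t.sigma[sel] if t.sigma is not None else None
    den_s = np.interp(q, d.q, d.sigma) if d.sigma is not None else None

    floor = 1e-12 * np.abs(den).max()
    good = np.abs(den) > floor
    ratio = np.where(good, num / np.where(good, den, 1.0), np.nan)
    if num_s is not None or den_s is not None:
        rel2 = np.zeros_like(ratio)
        if num_s is not None:
            rel2 += (num_s / np.where(np.abs(num) > 0, num, 1.0)) ** 2
        if den_s is not None:
            rel2 += (den_s / np.where(good, den, 1.0)) ** 2
        sigma = np.abs(ratio) * np.sqrt(rel2)
        good &= (sigma / np.abs(ratio)) <= max_rel_err
    else:
        sigma = None
    keep = good & np.isfinite(ratio)
    return RatioDataset(q=q[keep], ratio=ratio[keep],
                        sigma=sigma[keep] if sigma is not None else None,
                        label=label)


def _ratio_model(q, r_t, r_tl, k):
    return k * (1.0 + _sinc(q * r_t)) / (1.0 + _sinc(q * r_tl))


def fit_ratio(datasets: list[RatioDataset], share_k: bool = False,
              r_t_starts=(2.5, 3.5, 4.5)) -> RatioFit:
    """Simultaneous fit of the dimer intensity-ratio model over all datasets,
    with the free-dimer distance R_cm_T shared; each dataset carries its own
    compacted distance R_cm_TL and prefactor k (shared if ``share_k``).
    Multi-start over R_cm_T initial values."""
    if not datasets:
        raise ValueError("need at least one ratio dataset")

    def make_params(r_t0):
        p = lmfit.Parameters()
        p.add("r_t", value=r_t0, min=0.5, max=20.0)
        for j in range(len(datasets)):
            p.add(f"r_tl_{j}", value=0.9 * r_t0, min=0.5, max=20.0)
            if share_k and j > 0:
                p.add(f"k_{j}", expr="k_0")
            else:
                p.add(f"k_{j}", value=float(np.mean(datasets[j].ratio)), min=1e-6)
        return p

    def residual(p):
        out = []
        for j, ds in enumerate(datasets):
            model = _ratio_model(ds.q, p["r_t"].value, p[f"r_tl_{j}"].value,
                                 p[f"k_{j}"].value)
            r = model - ds.ratio
            if ds.sigma is not None:
                r = r / ds.sigma
            out.append(r)
        return np.concatenate(out)

    best = None
    diagnostics = []
    for r_t0 in r_t_starts:
        try:
            res = lmfit.minimize(residual, make_params(r_t0), method="leastsq")
        except Exception as exc:  # pragma: no cover - depends on data
            diagnostics.append(f"start {r_t0}: {exc}")
            continue
        if not res.success:
            diagnostics.append(f"start {r_t0}: {res.message}")
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("ratio fit failed for all starts: " + "; ".join(diagnostics))

    p = best.params
    n = len(datasets)

    def err(name):
        e = p[name].stderr
        return float(e) if e is not None else float("nan")

    return RatioFit(
        R_cm_T=float(p["r_t"].value), R_cm_T_err=err("r_t"),
        R_cm_TL=np.array([p[f"r_tl_{j}"].value for j in range(n)]),
        R_cm_TL_err=np.array([err(f"r_tl_{j}") for j in range(n)]),
        k=np.array([p[f"k_{j}"].value for j in range(n)]),
        k_err=np.array([err(f"k_{j}") for j in range(n)]),
        chi2_reduced=float(best.redchi), labels=[ds.label for ds in datasets])


def grid_search_geometry(I_exp: SAXSProfile, rg_ref: float | None = None,
                         rhc_values=None, h_step: float = 0.06,
                         mc_config=None, point_cfg: PointCloudConfig | None = None,
                         ) -> GeometrySearchResult:
    """Scan cylinder dimensions against an experimental (or synthetic) dimer
    profile.

    For each candidate radius R_HC, three heights are examined in ``h_step``
    increments centred on the height that keeps the single-cylinder Rg equal
    to ``rg_ref`` (``H = sqrt(12 (rg_ref^2 - R_HC^2/2))``).  Each candidate
    runs the T* = 0 and T* = inf ensembles, fits p_st, and is scored by the
    reduced chi-square; failed candidates are recorded and skipped.
    """
    from .mc import SimulationConfig, run  # local import to avoid cycle

    if rhc_values is None:
        rhc_values = np.arange(1.18, 1.26 + 1e-9, 0.01)
    if mc_config is None:
        mc_config = SimulationConfig()
    point_cfg = PointCloudConfig() if point_cfg is None else point_cfg
    if rg_ref is None:
        rg_ref = mc_config.geometry.rg

    from dataclasses import replace
    q = I_exp.to_nm().q
    table = []
    best = None
    for rhc in rhc_values:
        h_mid2 = 12.0 * (rg_ref**2 - rhc**2 / 2.0)
        if h_mid2 <= 0:
            table.append(dict(radius_RHC=float(rhc), height_H=float("nan"),
                              chi2_reduced=float("inf"), p_st=float("nan"),
                              status="no height keeps Rg"))
            continue
        h_mid = math.sqrt(h_mid2)
        for h in (h_mid - h_step, h_mid, h_mid + h_step):
            if h <= 0:
                continue
            try:
                geom = CylinderGeometry(radius_RHC=float(rhc), height_H=float(h))
                cfg0 = replace(mc_config, geometry=geom, t_star=0.0)
                cfgi = replace(mc_config, geometry=geom, t_star=math.inf,
                               rng_seed=mc_config.rng_seed + 1)
                i0 = trajectory_intensity(run(cfg0), q, point_cfg)
                ii = trajectory_intensity(run(cfgi), q, point_cfg)
                fit = fit_pst(I_exp, i0, ii)
                row = dict(radius_RHC=float(rhc), height_H=float(h),
                           chi2_reduced=fit.chi2_reduced, p_st=fit.p_st, status="ok")
                table.append(row)
                if best is None or fit.chi2_reduced < best[0].chi2_reduced:
                    best = (fit, geom)
            except Exception as exc:
                table.append(dict(radius_RHC=float(rhc), height_H=float(h),
                                  chi2_reduced=float("inf"), p_st=float("nan"),
                                  status=f"failed: {exc}"))
    if best is None:
        raise RuntimeError("geometry grid search: every candidate failed")
    fit, geom = best
    return GeometrySearchResult(best_geometry=geom, best_pst_fit=fit,
                                table=table, rg_ref=float(rg_ref))
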