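"""Independent oracles shared by the test suite.

These deliberately avoid the code paths they check: cylinder overlap is
decided by dense point-membership sampling, the stacking probability of the
stacking-blind ensemble by direct rejection sampling of the linker-tethered
geometry, and the dimer structure factor by averaging plane-wave phases over
random orientations.
"""
from __future__ import annotations

import math

import numpy as np

from quadstack.geometry import CylinderGeometry, PatchSpec
from quadstack.overlap import overlap_pairs


def frame(axis):
    t = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = t - np.dot(t, axis) * axis
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(axis, e1)


def random_axis(rng, n=None):
    v = rng.normal(size=3 if n is None else (n, 3))
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def sample_in_cylinder(rng, center, axis, radius, height, n):
    """n points uniform in the solid cylinder (membership oracle helper)."""
    z = rng.uniform(-height / 2, height / 2, n)
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    th = rng.uniform(0, 2 * np.pi, n)
    e1, e2 = frame(axis)
    return (center + z[:, None] * axis
            + (r * np.cos(th))[:, None] * e1 + (r * np.sin(th))[:, None] * e2)


def point_in_cylinder(pts, center, axis, radius, height):
    d = pts - center
    z = d @ axis
    rad2 = np.einsum("ij,ij->i", d, d) - z**2
    return (np.abs(z) <= height / 2) & (rad2 <= radius**2)


def overlap_oracle(rng, c1, a1, c2, a2, radius, height, n_points=30000):
    """Dense point-membership intersection oracle (one-sided: may miss
    razor-thin overlaps; pair with a boundary-margin classification)."""
    p1 = sample_in_cylinder(rng, c1, a1, radius, height, n_points)
    if point_in_cylinder(p1, c2, a2, radius, height).any():
        return True
    p2 = sample_in_cylinder(rng, c2, a2, radius, height, n_points)
    return bool(point_in_cylinder(p2, c1, a1, radius, height).any())


def stacking_probability_oracle(n_samples, seed,
                                geometry: CylinderGeometry | None = None,
                                patches: PatchSpec | None = None):
    """Rejection-sampling estimate of P(stacked) for the stacking-blind
    (T* = inf) linker-tethered dimer measure.

    Cylinder A is fixed at the origin (the relative measure is invariant);
    B's orientation is uniform, and B's linker patch centre is uniform in
    the linker ball of radius 2 R0 about A's linker patch.  Overlapping
    configurations are rejected.  Returns (p, standard_error, n_kept).
    """
    geometry = CylinderGeometry() if geometry is None else geometry
    patches = PatchSpec() if patches is None else patches
    rng = np.random.default_rng(seed)
    r0 = patches.linker_radius_R0
    r1 = patches.stacking_radius_R1
    h, rhc = geometry.height_H, geometry.radius_RHC

    link_a = np.array([rhc, 0.0, h / 2])
    stack_a = np.array([0.0, 0.0, h / 2])
    a_a = np.tile(np.array([0.0, 0.0, 1.0]), (n_samples, 1))
    c_a = np.zeros((n_samples, 3))

    a_b = random_axis(rng, n_samples)
    w = rng.normal(size=(n_samples, 3))
    w -= np.einsum("ij,ij->i", w, a_b)[:, None] * a_b
    rad_b = w / np.linalg.norm(w, axis=1, keepdims=True)

    u = random_axis(rng, n_samples)
    rr = 2 * r0 * rng.uniform(0, 1, n_samples) ** (1 / 3)
    link_b = link_a + u * rr[:, None]
    c_b = link_b + (h / 2) * a_b - rhc * rad_b

    out = np.empty(n_samples, dtype=np.bool_)
    overlap_pairs(np.ascontiguousarray(c_a), np.ascontiguousarray(a_a),
                  np.ascontiguousarray(c_b), np.ascontiguousarray(a_b), rhc, h, out)
    feasible = ~out
    stack_b = c_b - (h / 2) * a_b
    stacked = np.linalg.norm(stack_b - stack_a, axis=1) <= 2 * r1
    kept = int(feasible.sum())
    p = float(stacked[feasible].mean())
    se = math.sqrt(max(p * (1 - p), 1e-12) / kept)
    return p, se, kept


def two_point_phase_oracle(q, separation, n_orient, seed):
    """Monte-Carlo orientation average of |sum exp(iq.r)|^2 for two points a
    fixed distance apart; returns (mean, standard_error)."""
    rng = np.random.default_rng(seed)
    u = random_axis(rng, n_orient)
    vals = 2.0 + 2.0 * np.cos(q * separation * u[:, 2])
    return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(n_orient))


def kratky_inflections(profile, q_lo=0.4, q_hi=2.3, degree=8):
    """Count inflections of a polynomial-smoothed dimensionless Kratky curve
    over the mid-Q window: a compact single-domain shape gives one, a
    two-domain (shoulder) shape gives three."""
    from quadstack.scattering import guinier_rg, kratky

    g = guinier_rg(profile)
    q, k = kratky(profile, i0=g.I0)
    sel = (q >= q_lo) & (q <= q_hi)
    coef = np.polynomial.polynomial.polyfit(q[sel], k[sel], degree)
    qq = np.linspace(q[sel][0], q[sel][-1], 400)
    d2 = np.diff(np.polynomial.polynomial.polyval(qq, coef), 2)
    return int(np.sum(np.abs(np.diff(np.sign(d2))) > 0))
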