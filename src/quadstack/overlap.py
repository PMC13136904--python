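"""Exact intersection test for two finite solid cylinders.

A solid cylinder is convex, so two cylinders intersect iff the origin lies in
their Minkowski difference.  This is decided with the GJK algorithm driven by
the cylinder support function

    supp(d) = c + (H/2) sign(d.a) a + R * d_perp / |d_perp|,

which is exact for the capped-cylinder shape (lateral surface, caps and rims
all arise as support points).  Touching configurations count as intersecting;
the Monte Carlo engine never proposes exact-contact states, so the closed/open
distinction is immaterial there.
"""
from __future__ import annotations

import numpy as np
from numba import njit

_MAX_ITER = 64


@njit(cache=True, fastmath=False)
def _support(cx, cy, cz, ax, ay, az, radius, half_h, dx, dy, dz):
    ad = ax * dx + ay * dy + az * dz
    s = half_h if ad >= 0.0 else -half_h
    px = cx + s * ax
    py = cy + s * ay
    pz = cz + s * az
    rx = dx - ad * ax
    ry = dy - ad * ay
    rz = dz - ad * az
    rn = (rx * rx + ry * ry + rz * rz) ** 0.5
    if rn > 1e-14:
        f = radius / rn
        px += f * rx
        py += f * ry
        pz += f * rz
    return px, py, pz


@njit(cache=True)
def _gjk(c1, a1, c2, a2, radius, height):
    half_h = 0.5 * height
    scale = 2.0 * (radius + half_h)
    tol = 1e-10 * scale
    tol2 = tol * tol

    # (near-)parallel axes: exact closed form.  This is also the regime
    # (flat cap-to-cap contact) where GJK's simplex degenerates, so the
    # special case doubles as a robustness guard for stacked dimers.
    cxp = a1[1] * a2[2] - a1[2] * a2[1]
    cyp = a1[2] * a2[0] - a1[0] * a2[2]
    czp = a1[0] * a2[1] - a1[1] * a2[0]
    if cxp * cxp + cyp * cyp + czp * czp < 1e-12:
        dx0 = c2[0] - c1[0]
        dy0 = c2[1] - c1[1]
        dz0 = c2[2] - c1[2]
        z = dx0 * a1[0] + dy0 * a1[1] + dz0 * a1[2]
        if abs(z) > height:
            return False
        px = dx0 - z * a1[0]
        py = dy0 - z * a1[1]
        pz = dz0 - z * a1[2]
        return px * px + py * py + pz * pz <= 4.0 * radius * radius

    W = np.empty((4, 3))

    dx = c1[0] - c2[0]
    dy = c1[1] - c2[1]
    dz = c1[2] - c2[2]
    if dx * dx + dy * dy + dz * dz < 1e-24:
        dx, dy, dz = 1.0, 0.0, 0.0

    # first support point
    p1x, p1y, p1z = _support(c1[0], c1[1], c1[2], a1[0], a1[1], a1[2],
                             radius, half_h, dx, dy, dz)
    p2x, p2y, p2z = _support(c2[0], c2[1], c2[2], a2[0], a2[1], a2[2],
                             radius, half_h, -dx, -dy, -dz)
    W[0, 0] = p1x - p2x
    W[0, 1] = p1y - p2y
    W[0, 2] = p1z - p2z
    n = 1
    dx, dy, dz = -W[0, 0], -W[0, 1], -W[0, 2]

    for _ in range(_MAX_ITER):
        dn2 = dx * dx + dy * dy + dz * dz
        if dn2 < tol2:
            return True  # origin on the current simplex
        dn = dn2 ** 0.5
        p1x, p1y, p1z = _support(c1[0], c1[1], c1[2], a1[0], a1[1], a1[2],
                                 radius, half_h, dx, dy, dz)
        p2x, p2y, p2z = _support(c2[0], c2[1], c2[2], a2[0], a2[1], a2[2],
                                 radius, half_h, -dx, -dy, -dz)
        wx = p1x - p2x
        wy = p1y - p2y
        wz = p1z - p2z
        if wx * dx + wy * dy + wz * dz < tol * dn:
            return False  # support plane separates origin
        # stagnation guard: a repeated support point cannot make progress and
        # the origin has not been enclosed, so the bodies are disjoint (or
        # exactly touching, which we do not need to distinguish here)
        dup_tol2 = (1e-9 * scale) ** 2
        for k in range(n):
            ex = wx - W[k, 0]
            ey = wy - W[k, 1]
            ez = wz - W[k, 2]
            if ex * ex + ey * ey + ez * ez < dup_tol2:
                return False
        W[n, 0] = wx
        W[n, 1] = wy
        W[n, 2] = wz
        n += 1

        # ---- do-simplex: reduce W/n, pick new direction -------------------
        while True:
            if n == 2:
                b0, b1, b2 = W[0, 0], W[0, 1], W[0, 2]
                A0, A1, A2 = W[1, 0], W[1, 1], W[1, 2]
                abx, aby, abz = b0 - A0, b1 - A1, b2 - A2
                aox, aoy, aoz = -A0, -A1, -A2
                if abx * aox + aby * aoy + abz * aoz > 0.0:
                    # d = AB x AO x AB
                    cx_ = aby * aoz - abz * aoy
                    cy_ = abz * aox - abx * aoz
                    cz_ = abx * aoy - aby * aox
                    dx = cy_ * abz - cz_ * aby
                    dy = cz_ * abx - cx_ * abz
                    dz = cx_ * aby - cy_ * abx
                    if dx * dx + dy * dy + dz * dz < tol2 * (abx * abx + aby * aby + abz * abz):
                        return True  # origin on segment
                else:
                    W[0, 0], W[0, 1], W[0, 2] = A0, A1, A2
                    n = 1
                    dx, dy, dz = aox, aoy, aoz
                break
            elif n == 3:
                C0, C1, C2 = W[0, 0], W[0, 1], W[0, 2]
                B0, B1, B2 = W[1, 0], W[1, 1], W[1, 2]
                A0, A1, A2 = W[2, 0], W[2, 1], W[2, 2]
                abx, aby, abz = B0 - A0, B1 - A1, B2 - A2
                acx, acy, acz = C0 - A0, C1 - A1, C2 - A2
                aox, aoy, aoz = -A0, -A1, -A2
                # triangle normal
                nx = aby * acz - abz * acy
                ny = abz * acx - abx * acz
                nz = abx * acy - aby * acx
                nn_ = nx * nx + ny * ny + nz * nz
                ab2 = abx * abx + aby * aby + abz * abz
                ac2 = acx * acx + acy * acy + acz * acz
                if nn_ < 1e-20 * ab2 * ac2:
                    # sliver triangle: fall back to the newest segment [B, A]
                    W[0, 0], W[0, 1], W[0, 2] = B0, B1, B2
                    W[1, 0], W[1, 1], W[1, 2] = A0, A1, A2
                    n = 2
                    continue
                # edge AC region test: (n x AC) . AO
                e1x = ny * acz - nz * acy
                e1y = nz * acx - nx * acz
                e1z = nx * acy - ny * acx
                if e1x * aox + e1y * aoy + e1z * aoz > 0.0:
                    if acx * aox + acy * aoy + acz * aoz > 0.0:
                        # keep [C, A]
                        W[1, 0], W[1, 1], W[1, 2] = A0, A1, A2
                        n = 2
                        cx_ = acy * aoz - acz * aoy
                        cy_ = acz * aox - acx * aoz
                        cz_ = acx * aoy - acy * aox
                        dx = cy_ * acz - cz_ * acy
                        dy = cz_ * acx - cx_ * acz
                        dz = cx_ * acy - cy_ * acx
                        if dx * dx + dy * dy + dz * dz < tol2 * (acx * acx + acy * acy + acz * acz):
                            return True
                        break
                    # fall through to AB check
                    if abx * aox + aby * aoy + abz * aoz > 0.0:
                        W[0, 0], W[0, 1], W[0, 2] = B0, B1, B2
                        W[1, 0], W[1, 1], W[1, 2] = A0, A1, A2
                        n = 2
                        cx_ = aby * aoz - abz * aoy
                        cy_ = abz * aox - abx * aoz
                        cz_ = abx * aoy - aby * aox
                        dx = cy_ * abz - cz_ * aby
                        dy = cz_ * abx - cx_ * abz
                        dz = cx_ * aby - cy_ * abx
                        if dx * dx + dy * dy + dz * dz < tol2 * (abx * abx + aby * aby + abz * abz):
                            return True
                        break
                    W[0, 0], W[0, 1], W[0, 2] = A0, A1, A2
                    n = 1
                    dx, dy, dz = aox, aoy, aoz
                    break
                # edge AB region test: (AB x n) . AO
                e2x = aby * nz - abz * ny
                e2y = abz * nx - abx * nz
                e2z = abx * ny - aby * nx
                if e2x * aox + e2y * aoy + e2z * aoz > 0.0:
                    if abx * aox + aby * aoy + abz * aoz > 0.0:
                        W[0, 0], W[0, 1], W[0, 2] = B0, B1, B2
                        W[1, 0], W[1, 1], W[1, 2] = A0, A1, A2
                        n = 2
                        cx_ = aby * aoz - abz * aoy
                        cy_ = abz * aox - abx * aoz
                        cz_ = abx * aoy - aby * aox
                        dx = cy_ * abz - cz_ * aby
                        dy = cz_ * abx - cx_ * abz
                        dz = cx_ * aby - cy_ * abx
                        if dx * dx + dy * dy + dz * dz < tol2 * (abx * abx + aby * aby + abz * abz):
                            return True
                        break
                    W[0, 0], W[0, 1], W[0, 2] = A0, A1, A2
                    n = 1
                    dx, dy, dz = aox, aoy, aoz
                    break
                # origin above/below triangle interior (a plane-coincidence
                # shortcut here is numerically unsafe for thin triangles;
                # true containment is caught by the zero-direction check and
                # the stagnation guard instead)
                nd = nx * aox + ny * aoy + nz * aoz
                if nd > 0.0:
                    dx, dy, dz = nx, ny, nz
                else:
                    # swap winding: [B, C, A]
                    W[0, 0], W[0, 1], W[0, 2] = B0, B1, B2
                    W[1, 0], W[1, 1], W[1, 2] = C0, C1, C2
                    dx, dy, dz = -nx, -ny, -nz
                break
            else:  # n == 4
                D0, D1, D2 = W[0, 0], W[0, 1], W[0, 2]
                C0, C1, C2 = W[1, 0], W[1, 1], W[1, 2]
                B0, B1, B2 = W[2, 0], W[2, 1], W[2, 2]
                A0, A1, A2 = W[3, 0], W[3, 1], W[3, 2]
                abx, aby, abz = B0 - A0, B1 - A1, B2 - A2
                acx, acy, acz = C0 - A0, C1 - A1, C2 - A2
                adx, ady, adz = D0 - A0, D1 - A1, D2 - A2
                aox, aoy, aoz = -A0, -A1, -A2
                # flat-tetra guard: if A,B,C,D are (near-)coplanar the
                # outward-orientation tests are pure rounding noise and the
                # containment conclusion would be unreliable; demote to the
                # newest triangle and keep iterating
                n1x = aby * acz - abz * acy
                n1y = abz * acx - abx * acz
                n1z = abx * acy - aby * acx
                vol = n1x * adx + n1y * ady + n1z * adz
                n1sq = n1x * n1x + n1y * n1y + n1z * n1z
                adsq = adx * adx + ady * ady + adz * adz
                if vol * vol < 1e-20 * n1sq * adsq:
                    W[0, 0], W[0, 1], W[0, 2] = C0, C1, C2
                    W[1, 0], W[1, 1], W[1, 2] = B0, B1, B2
                    W[2, 0], W[2, 1], W[2, 2] = A0, A1, A2
                    n = 3
                    continue
                # face ABC, outward = away from D
                if vol > 0.0:
                    n1x, n1y, n1z = -n1x, -n1y, -n1z
                if n1x * aox + n1y * aoy + n1z * aoz > 0.0:
                    W[0, 0], W[0, 1], W[0, 2] = C0, C1, C2
                    W[1, 0], W[1, 1], W[1, 2] = B0, B1, B2
                    W[2, 0], W[2, 1], W[2, 2] = A0, A1, A2
                    n = 3
                    continue
                # face ACD, outward = away from B
                n2x = acy * adz - acz * ady
                n2y = acz * adx - acx * adz
                n2z = acx * ady - acy * adx
                if n2x * abx + n2y * aby + n2z * abz > 0.0:
                    n2x, n2y, n2z = -n2x, -n2y, -n2z
                if n2x * aox + n2y * aoy + n2z * aoz > 0.0:
                    W[0, 0], W[0, 1], W[0, 2] = D0, D1, D2
                    W[1, 0], W[1, 1], W[1, 2] = C0, C1, C2
                    W[2, 0], W[2, 1], W[2, 2] = A0, A1, A2
                    n = 3
                    continue
                # face ADB, outward = away from C
                n3x = ady * abz - adz * aby
                n3y = adz * abx - adx * abz
                n3z = adx * aby - ady * abx
                if n3x * acx + n3y * acy + n3z * acz > 0.0:
                    n3x, n3y, n3z = -n3x, -n3y, -n3z
                if n3x * aox + n3y * aoy + n3z * aoz > 0.0:
                    W[0, 0], W[0, 1], W[0, 2] = B0, B1, B2
                    W[1, 0], W[1, 1], W[1, 2] = D0, D1, D2
                    W[2, 0], W[2, 1], W[2, 2] = A0, A1, A2
                    n = 3
                    continue
                return True  # origin enclosed by tetrahedron
    return True  # iteration cap: treat as intersecting (conservative)


@njit(cache=True)
def overlap_pairs(c1s, a1s, c2s, a2s, radius, height, out):
    """Pairwise overlap flags for matched arrays of cylinder poses."""
    half_h = 0.5 * height
    reach2 = 4.0 * (half_h * half_h + radius * radius)
    for i in range(c1s.shape[0]):
        ddx = c1s[i, 0] - c2s[i, 0]
        ddy = c1s[i, 1] - c2s[i, 1]
        ddz = c1s[i, 2] - c2s[i, 2]
        if ddx * ddx + ddy * ddy + ddz * ddz > reach2:
            out[i] = False
        else:
            out[i] = _gjk(c1s[i], a1s[i], c2s[i], a2s[i], radius, height)
    return out


def cylinders_intersect(c1, a1, c2, a2, radius, height):
    """Single-pair convenience wrapper around the numba kernel."""
    c1 = np.ascontiguousarray(c1, dtype=np.float64)
    a1 = np.ascontiguousarray(a1, dtype=np.float64)
    c2 = np.ascontiguousarray(c2, dtype=np.float64)
    a2 = np.ascontiguousarray(a2, dtype=np.float64)
    return bool(_gjk(c1, a1, c2, a2, float(radius), float(height)))
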