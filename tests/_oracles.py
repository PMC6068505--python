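"""Independent reference implementations used as test oracles.

Each function here re-derives a quantity by a route independent of the
package code path it checks: explicit per-pixel loops for the edge map,
a two-unknown linear solve for skew-line nearest points, generic nonlinear
minimisation for the 3D circle, and quaternion construction for minimal
rotations.
"""

import math

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation


def literal_edge_map(pixels, center_margin_frac=0.05, corner_margin_frac=0.05,
                     spot_threshold=250.0, spot_dilation_px=3,
                     threshold_scale=0.6):
    """Literal per-pixel re-evaluation of the adaptive gradient edge map."""
    img = np.asarray(pixels, dtype=float)
    n, m = img.shape

    # central-difference gradient, one-sided at the borders (x = column)
    gx = np.zeros((n, m))
    gy = np.zeros((n, m))
    for y in range(n):
        for x in range(m):
            if 0 < x < m - 1:
                gx[y, x] = (img[y, x + 1] - img[y, x - 1]) / 2.0
            elif x == 0:
                gx[y, x] = img[y, 1] - img[y, 0]
            else:
                gx[y, x] = img[y, m - 1] - img[y, m - 2]
            if 0 < y < n - 1:
                gy[y, x] = (img[y + 1, x] - img[y - 1, x]) / 2.0
            elif y == 0:
                gy[y, x] = img[1, x] - img[0, x]
            else:
                gy[y, x] = img[n - 1, x] - img[n - 2, x]
    g = np.sqrt(gx ** 2 + gy ** 2)

    cmx = int(round(center_margin_frac * m))
    cmy = int(round(center_margin_frac * n))
    cx, cy = m // 2, n // 2
    if cmx > 0 and cmy > 0:
        for y in range(max(0, cy - cmy), min(n, cy + cmy + 1)):
            for x in range(max(0, cx - cmx), min(m, cx + cmx + 1)):
                g[y, x] = 0.0
    kx = int(round(corner_margin_frac * m))
    ky = int(round(corner_margin_frac * n))
    if kx > 0 and ky > 0:
        for y in range(n):
            for x in range(m):
                if (y < ky or y >= n - ky) and (x < kx or x >= m - kx):
                    g[y, x] = 0.0

    rb = (0, n // 3, (2 * n) // 3, n)
    cb = (0, m // 3, (2 * m) // 3, m)
    for i in range(3):
        for j in range(3):
            vals = [g[y, x]
                    for y in range(rb[i], rb[i + 1])
                    for x in range(cb[j], cb[j + 1]) if g[y, x] > 0]
            if not vals:
                continue
            mean = np.sum(np.asarray(vals)) / len(vals)
            for y in range(rb[i], rb[i + 1]):
                for x in range(cb[j], cb[j + 1]):
                    if g[y, x] <= mean:
                        g[y, x] = 0.0

    spots = [(y, x) for y in range(n) for x in range(m)
             if img[y, x] >= spot_threshold]
    if spots and spot_dilation_px > 0:
        mask = np.zeros((n, m), dtype=bool)
        r = spot_dilation_px
        for (sy, sx) in spots:
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    if dy * dy + dx * dx <= r * r:
                        yy, xx = sy + dy, sx + dx
                        if 0 <= yy < n and 0 <= xx < m:
                            mask[yy, xx] = True
        g[mask] = 0.0

    # 3×3 neighborhood sums, same shift order as the production code
    padded = np.zeros((n + 2, m + 2))
    padded[1:-1, 1:-1] = g
    neigh = np.zeros((n, m))
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            neigh = neigh + padded[1 + dy:1 + dy + n, 1 + dx:1 + dx + m]
    threshold = threshold_scale * neigh.sum() / (m * n)
    return g, neigh > threshold


def nearest_points_linear_solve(a0, a1, b0, b1):
    """Nearest points of two lines by the textbook 2-unknown solve."""
    a0, a1, b0, b1 = (np.asarray(v, dtype=float) for v in (a0, a1, b0, b1))
    da = a1 - a0
    db = b1 - b0
    M = np.array([[da @ da, -(da @ db)], [da @ db, -(db @ db)]])
    rhs = np.array([(b0 - a0) @ da, (b0 - a0) @ db])
    t, s = np.linalg.solve(M, rhs)
    return a0 + t * da, b0 + s * db


def circle3d_nonlinear(points, x0=None):
    """Generic 6-parameter nonlinear 3D circle fit (center, axis angles, r)."""
    pts = np.asarray(points, dtype=float)

    def residuals(p):
        c = p[:3]
        theta, phi = p[3], p[4]
        r = p[5]
        nvec = np.array([math.sin(theta) * math.cos(phi),
                         math.sin(theta) * math.sin(phi),
                         math.cos(theta)])
        d = pts - c
        off = d @ nvec
        inplane = np.linalg.norm(d - np.outer(off, nvec), axis=1) - r
        return np.concatenate([off, inplane])

    if x0 is None:
        c0 = pts.mean(axis=0)
        r0 = np.linalg.norm(pts - c0, axis=1).mean()
        x0 = np.concatenate([c0, [0.1, 0.1, r0]])
    sol = least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    c = sol.x[:3]
    r = abs(sol.x[5])
    return c, r


def minimal_rotation_quaternion(u, w):
    """Minimal rotation u→w built directly from the half-angle quaternion."""
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    uh = u / np.linalg.norm(u)
    wh = w / np.linalg.norm(w)
    axis = np.cross(uh, wh)
    s = np.linalg.norm(axis)
    c = float(uh @ wh)
    angle = math.atan2(s, c)
    if s < 1e-15:
        return np.eye(3) if c > 0 else None
    q = np.concatenate([np.sin(angle / 2) * axis / s, [np.cos(angle / 2)]])
    return Rotation.from_quat(q).as_matrix()


def shape_error_direct(points, L):
    """Direct re-evaluation of the board-shape statistic."""
    p = np.asarray(points, dtype=float)
    total = 0.0
    for i in range(3):
        total += abs(np.linalg.norm(p[i] - p[i + 1]) - L)
    total += abs(np.linalg.norm(p[0] - p[3]) - L)
    return total
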