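"""Compiled inner loops for the trajectory simulator."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _point_in_polygon(px: float, py: float, vx: np.ndarray, vy: np.ndarray) -> bool:
    # crossing-number test; polygon vertices without repeated closing point
    n = vx.shape[0]
    inside = False
    j = n - 1
    for i in range(n):
        if (vy[i] > py) != (vy[j] > py):
            x_cross = vx[j] + (py - vy[j]) * (vx[i] - vx[j]) / (vy[i] - vy[j])
            if px < x_cross:
                inside = not inside
        j = i
    return inside


@njit(cache=True)
def movement_loop(
    x0: np.ndarray,
    y0: np.ndarray,
    heading0: np.ndarray,
    noise: np.ndarray,  # (n_steps, n_fish) heading innovations, pre-scaled
    speed: np.ndarray,  # (n_steps,) cruise speed m/s
    radial_bias: np.ndarray,  # (n_steps,) signed: + shoreward, - toward centre
    member: np.ndarray,  # (n_steps, n_fish) int16 group ids
    n_groups: int,
    dt: float,
    attract_frac: float,  # fraction of fish->centroid vector closed per step
    site_frac: float,  # fraction of fish->group-anchor vector closed per step
    ax: np.ndarray,  # (n_groups,) group site-anchor coordinates
    ay: np.ndarray,
    cx: float,
    cy: float,
    vx: np.ndarray,
    vy: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    n_steps, n_fish = noise.shape
    xs = np.empty((n_steps, n_fish), dtype=np.float32)
    ys = np.empty((n_steps, n_fish), dtype=np.float32)
    x = x0.copy()
    y = y0.copy()
    heading = heading0.copy()
    for f in range(n_fish):
        xs[0, f] = x[f]
        ys[0, f] = y[f]
    gx = np.zeros(n_groups)
    gy = np.zeros(n_groups)
    gn = np.zeros(n_groups)
    for t in range(1, n_steps):
        step_len = speed[t] * dt
        if attract_frac > 0.0:
            for g in range(n_groups):
                gx[g] = 0.0
                gy[g] = 0.0
                gn[g] = 0.0
            for f in range(n_fish):
                g = member[t, f]
                gx[g] += x[f]
                gy[g] += y[f]
                gn[g] += 1.0
            for g in range(n_groups):
                if gn[g] > 0:
                    gx[g] /= gn[g]
                    gy[g] /= gn[g]
        bias = radial_bias[t]
        cap = 2.0 * step_len
        for f in range(n_fish):
            heading[f] += noise[t, f]
            dx = step_len * np.cos(heading[f])
            dy = step_len * np.sin(heading[f])
            if attract_frac > 0.0:
                g = member[t, f]
                dx += attract_frac * (gx[g] - x[f])
                dy += attract_frac * (gy[g] - y[f])
                if site_frac > 0.0:
                    dx += site_frac * (ax[g] - x[f])
                    dy += site_frac * (ay[g] - y[f])
            rx = x[f] - cx
            ry = y[f] - cy
            rn = np.sqrt(rx * rx + ry * ry) + 1e-9
            dx += bias * step_len * rx / rn
            dy += bias * step_len * ry / rn
            dn = np.sqrt(dx * dx + dy * dy)
            if dn > cap:
                dx *= cap / dn
                dy *= cap / dn
            nx = x[f] + dx
            ny = y[f] + dy
            if _point_in_polygon(nx, ny, vx, vy):
                x[f] = nx
                y[f] = ny
            else:
                heading[f] += np.pi  # bounce: stay put, reverse heading
            xs[t, f] = x[f]
            ys[t, f] = y[f]
    return xs, ys


@njit(cache=True)
def dist_to_boundary(px: np.ndarray, py: np.ndarray, vx: np.ndarray, vy: np.ndarray) -> np.ndarray:
    """Min distance from each point to the polygon's boundary segments."""
    n = vx.shape[0]
    out = np.empty(px.shape[0])
    for k in range(px.shape[0]):
        best = 1e30
        j = n - 1
        for i in range(n):
            ex = vx[i] - vx[j]
            ey = vy[i] - vy[j]
            wx = px[k] - vx[j]
            wy = py[k] - vy[j]
            seg2 = ex * ex + ey * ey
            t = 0.0 if seg2 == 0.0 else (wx * ex + wy * ey) / seg2
            if t < 0.0:
                t = 0.0
            elif t > 1.0:
                t = 1.0
            dx = wx - t * ex
            dy = wy - t * ey
            d2 = dx * dx + dy * dy
            if d2 < best:
                best = d2
            j = i
        out[k] = np.sqrt(best)
    return out
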