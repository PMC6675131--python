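"""Numba-compiled inner loop shared by the SPH engine and MarbleSim.

Both engines integrate the same state with the same naive (semi-implicit
Euler) scheme, gravity, velocity damping and particle-obstacle collision
handling; they differ only in the pair interaction: SPH pressure +
Monaghan artificial viscosity for the fluids engine, inelastic rigid
sphere-sphere collisions for MarbleSim.  Keeping one compiled routine for
both guarantees the particle-obstacle code path is genuinely shared.

Scenes are compiled to flat arrays: a vertex pool + offsets for polygons
(obstacles, cup walls and the three boundary slabs for floor and side
walls) and an (n, 3) array of circle obstacles.
"""

from __future__ import annotations

import numpy as np
from numba import njit

GRAVITY = -9.81

# status codes returned by run_engine
OK = 0


@njit(cache=True, fastmath=False)
def kernel_w_scalar(r: float, h: float) -> float:
    """Cubic spline kernel in 2D with compact support radius h (W=0 for r>=h)."""
    q = r / h
    if q >= 1.0:
        return 0.0
    sigma = 40.0 / (7.0 * np.pi * h * h)
    if q <= 0.5:
        return sigma * (1.0 - 6.0 * q * q + 6.0 * q * q * q)
    t = 1.0 - q
    return sigma * 2.0 * t * t * t


@njit(cache=True, fastmath=False)
def kernel_dwdr_scalar(r: float, h: float) -> float:
    """Radial derivative dW/dr of the cubic spline kernel (<= 0)."""
    q = r / h
    if q >= 1.0:
        return 0.0
    sigma = 40.0 / (7.0 * np.pi * h * h)
    if q <= 0.5:
        return sigma / h * (-12.0 * q + 18.0 * q * q)
    t = 1.0 - q
    return sigma / h * (-6.0 * t * t)


@njit(cache=True)
def _density(pos, mass, h, rho):
    n = pos.shape[0]
    h2 = h * h
    for i in range(n):
        acc = 0.0
        for j in range(n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            r2 = dx * dx + dy * dy
            if r2 < h2:
                acc += mass * kernel_w_scalar(np.sqrt(r2), h)
        rho[i] = acc


@njit(cache=True)
def _sph_forces(pos, vel, rho, press, mass, h, alpha, c, fx, fy):
    """Pressure-gradient + Monaghan artificial-viscosity accelerations.

    Pair terms are antisymmetric by construction.  Gravity is added here.
    """
    n = pos.shape[0]
    h2 = h * h
    eps = 0.01 * h2
    for i in range(n):
        fx[i] = 0.0
        fy[i] = GRAVITY
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            r2 = dx * dx + dy * dy
            if r2 >= h2 or r2 < 1e-24:
                continue
            r = np.sqrt(r2)
            dwdr = kernel_dwdr_scalar(r, h)
            # symmetric pressure term
            pij = press[i] / (rho[i] * rho[i]) + press[j] / (rho[j] * rho[j])
            # artificial viscosity: active only for approaching pairs
            dvx = vel[i, 0] - vel[j, 0]
            dvy = vel[i, 1] - vel[j, 1]
            vdotr = dvx * dx + dvy * dy
            visc = 0.0
            if vdotr < 0.0:
                mu = h * vdotr / (r2 + eps)
                rhobar = 0.5 * (rho[i] + rho[j])
                visc = -alpha * c * mu / rhobar
            coef = -mass * (pij + visc) * dwdr / r
            fx[i] += coef * dx
            fy[i] += coef * dy
            fx[j] -= coef * dx
            fy[j] -= coef * dy


@njit(cache=True)
def _point_in_poly(px, py, verts, lo, hi):
    """Crossing-number parity test for the polygon verts[lo:hi]."""
    inside = False
    j = hi - 1
    for i in range(lo, hi):
        xi, yi = verts[i, 0], verts[i, 1]
        xj, yj = verts[j, 0], verts[j, 1]
        if (yi > py) != (yj > py):
            xc = xi + (py - yi) / (yj - yi) * (xj - xi)
            if px < xc:
                inside = not inside
        j = i
    return inside


@njit(cache=True)
def _deepest_contact(px, py, pr, poly_verts, poly_off, poly_obst, circ):
    """Deepest particle-solid overlap at (px, py).

    Returns (penetration, nx, ny, is_obstacle).  penetration <= 0 means no
    contact; the normal points away from the solid (resolution direction).
    """
    best_pen = -1.0e30
    bnx = 0.0
    bny = 1.0
    bobst = 0
    n_poly = poly_off.shape[0] - 1
    for p in range(n_poly):
        lo = poly_off[p]
        hi = poly_off[p + 1]
        # distance to polygon boundary (min over edges)
        best_d2 = 1.0e30
        cx = 0.0
        cy = 0.0
        j = hi - 1
        for i in range(lo, hi):
            ax, ay = poly_verts[j, 0], poly_verts[j, 1]
            bx, by = poly_verts[i, 0], poly_verts[i, 1]
            ex = bx - ax
            ey = by - ay
            L2 = ex * ex + ey * ey
            if L2 > 0.0:
                t = ((px - ax) * ex + (py - ay) * ey) / L2
                if t < 0.0:
                    t = 0.0
                elif t > 1.0:
                    t = 1.0
            else:
                t = 0.0
            qx = ax + t * ex
            qy = ay + t * ey
            dx = px - qx
            dy = py - qy
            d2 = dx * dx + dy * dy
            if d2 < best_d2:
                best_d2 = d2
                cx = qx
                cy = qy
            j = i
        d = np.sqrt(best_d2)
        inside = _point_in_poly(px, py, poly_verts, lo, hi)
        pen = pr + d if inside else pr - d
        if pen > best_pen:
            if d > 1e-12:
                nx = (px - cx) / d
                ny = (py - cy) / d
                if inside:
                    nx = -nx
                    ny = -ny
            else:
                nx = 0.0
                ny = 1.0
            best_pen = pen
            bnx = nx
            bny = ny
            bobst = poly_obst[p]
    for ci in range(circ.shape[0]):
        dx = px - circ[ci, 0]
        dy = py - circ[ci, 1]
        d = np.sqrt(dx * dx + dy * dy)
        pen = circ[ci, 2] + pr - d
        if pen > best_pen:
            if d > 1e-12:
                nx = dx / d
                ny = dy / d
            else:
                nx = 0.0
                ny = 1.0
            best_pen = pen
            bnx = nx
            bny = ny
            bobst = 1
    return best_pen, bnx, bny, bobst


@njit(cache=True)
def _resolve_obstacles(pos, vel, pr, sticky, kn, kt,
                       poly_verts, poly_off, poly_obst, circ,
                       contact_seen, in_contact):
    """Project penetrating particles out, zero inward normal velocity
    (perfectly inelastic), then apply stickiness while in contact."""
    n = pos.shape[0]
    for i in range(n):
        in_contact[i] = False
        for _pass in range(3):
            pen, nx, ny, obst = _deepest_contact(
                pos[i, 0], pos[i, 1], pr, poly_verts, poly_off, poly_obst, circ)
            if pen <= 0.0:
                break
            if obst == 1:  # real obstacles only: floor/wall rest is not "stuck"
                in_contact[i] = True
                contact_seen[i] = True
            pos[i, 0] += nx * pen
            pos[i, 1] += ny * pen
            vn = vel[i, 0] * nx + vel[i, 1] * ny
            if vn < 0.0:
                vel[i, 0] -= vn * nx
                vel[i, 1] -= vn * ny
            if sticky:
                vn = vel[i, 0] * nx + vel[i, 1] * ny
                tx = vel[i, 0] - vn * nx
                ty = vel[i, 1] - vn * ny
                vel[i, 0] = (1.0 - kn) * vn * nx + (1.0 - kt) * tx
                vel[i, 1] = (1.0 - kn) * vn * ny + (1.0 - kt) * ty


@njit(cache=True)
def _marble_pairs(pos, vel, pr, n_sweeps):
    """Inelastic rigid sphere-sphere collisions, equal masses.

    Overlapping pairs are separated symmetrically along the center line and
    the approaching relative normal velocity is zeroed (both particles take
    the mean normal velocity, conserving pair momentum).  Tangential
    velocities are untouched.  Index-order sweeps give stable stacking.
    """
    n = pos.shape[0]
    d_min = 2.0 * pr
    d_min2 = d_min * d_min
    for _sweep in range(n_sweeps):
        for i in range(n):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                r2 = dx * dx + dy * dy
                if r2 >= d_min2:
                    continue
                r = np.sqrt(r2)
                if r > 1e-12:
                    nx = dx / r
                    ny = dy / r
                else:
                    nx = 1.0
                    ny = 0.0
                overlap = d_min - r
                pos[i, 0] += 0.5 * overlap * nx
                pos[i, 1] += 0.5 * overlap * ny
                pos[j, 0] -= 0.5 * overlap * nx
                pos[j, 1] -= 0.5 * overlap * ny
                vni = vel[i, 0] * nx + vel[i, 1] * ny
                vnj = vel[j, 0] * nx + vel[j, 1] * ny
                if vni - vnj < 0.0:  # approaching
                    vmean = 0.5 * (vni + vnj)
                    vel[i, 0] += (vmean - vni) * nx
                    vel[i, 1] += (vmean - vni) * ny
                    vel[j, 0] += (vmean - vnj) * nx
                    vel[j, 1] += (vmean - vnj) * ny


@njit(cache=True)
def run_engine(pos, vel, n_steps, dt, marble,
               mass, h, rho0, stiffness, alpha, zeta,
               sticky, kn, kt, pr, v_cap,
               poly_verts, poly_off, poly_obst, circ,
               contact_seen, stuck_steps, rho, press,
               traj, record_every):
    """Integrate n_steps; returns 0 on success or the 1-based step index at
    which a particle speed exceeded v_cap (numerical instability)."""
    n = pos.shape[0]
    fx = np.zeros(n)
    fy = np.zeros(n)
    in_contact = np.zeros(n, dtype=np.bool_)
    c = np.sqrt(stiffness)
    v_cap2 = v_cap * v_cap
    for step_i in range(n_steps):
        if not marble:
            _density(pos, mass, h, rho)
            for i in range(n):
                p = stiffness * (rho[i] - rho0)
                press[i] = p if p > 0.0 else 0.0  # free-surface clamp
            _sph_forces(pos, vel, rho, press, mass, h, alpha, c, fx, fy)
        else:
            for i in range(n):
                fx[i] = 0.0
                fy[i] = GRAVITY
        # damping: a = f - zeta * v, then naive Euler update
        for i in range(n):
            ax = fx[i] - zeta * vel[i, 0]
            ay = fy[i] - zeta * vel[i, 1]
            vel[i, 0] += ax * dt
            vel[i, 1] += ay * dt
            pos[i, 0] += vel[i, 0] * dt
            pos[i, 1] += vel[i, 1] * dt
        if marble:
            _marble_pairs(pos, vel, pr, 4)
        _resolve_obstacles(pos, vel, pr, sticky, kn, kt,
                           poly_verts, poly_off, poly_obst, circ,
                           contact_seen, in_contact)
        for i in range(n):
            v2 = vel[i, 0] * vel[i, 0] + vel[i, 1] * vel[i, 1]
            if v2 > v_cap2:
                return step_i + 1
            if in_contact[i] and v2 < 0.005 * 0.005:
                stuck_steps[i] += 1
            else:
                stuck_steps[i] = 0
        if record_every > 0 and (step_i + 1) % record_every == 0:
            f = (step_i + 1) // record_every - 1
            if f < traj.shape[0]:
                for i in range(n):
                    traj[f, i, 0] = pos[i, 0]
                    traj[f, i, 1] = pos[i, 1]
    return 0
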