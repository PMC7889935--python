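"""Numba-compiled inner loops of the simulator.

These mirror ``membrane.membrane_force`` (assuming a counter-clockwise
contour) and fuse the mechanical substeps with the per-focus Gaussian actin
force.  The numpy implementations in ``membrane``/``actin`` remain the
reference; the test suite checks the two paths agree to machine precision.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SQRT2PI = np.sqrt(2.0 * np.pi)


@njit(cache=True)
def mem_force(v, P, tau, kappa):
    """Helfrich force for a CCW closed polyline; returns an (n, 2) array."""
    n = v.shape[0]
    f = np.zeros((n, 2))
    # edge vectors e_k = x_{k+1} - x_k and lengths
    ex = np.empty(n)
    ey = np.empty(n)
    el = np.empty(n)
    for k in range(n):
        k1 = k + 1 if k + 1 < n else 0
        ex[k] = v[k1, 0] - v[k, 0]
        ey[k] = v[k1, 1] - v[k, 1]
        el[k] = np.sqrt(ex[k] * ex[k] + ey[k] * ey[k])
    theta = np.empty(n)
    lmean = np.empty(n)
    for k in range(n):
        km = k - 1 if k > 0 else n - 1
        cross = ex[km] * ey[k] - ey[km] * ex[k]
        dot = ex[km] * ex[k] + ey[km] * ey[k]
        theta[k] = np.arctan2(cross, dot)
        lmean[k] = 0.5 * (el[km] + el[k])
    for k in range(n):
        km = k - 1 if k > 0 else n - 1
        kp = k + 1 if k + 1 < n else 0
        # pressure: d|A|/dx_k for CCW contour
        gx = P * 0.5 * (v[kp, 1] - v[km, 1])
        gy = P * 0.5 * (v[km, 0] - v[kp, 0])
        # tension: incoming-unit minus outgoing-unit edge
        uhx, uhy = ex[km] / el[km], ey[km] / el[km]
        ehx, ehy = ex[k] / el[k], ey[k] / el[k]
        gx += tau * (uhx - ehx)
        gy += tau * (uhy - ehy)
        # bending: joints k-1, k, k+1
        # joint k: dtheta/dx_k = -perp(u)/|u|^2 - perp(e)/|e|^2
        ak = 2.0 * theta[k] / lmean[k]
        bk = (theta[k] / lmean[k]) ** 2
        pux, puy = -ey[km] / (el[km] * el[km]), ex[km] / (el[km] * el[km])
        pex, pey = -ey[k] / (el[k] * el[k]), ex[k] / (el[k] * el[k])
        bx = ak * (-pux - pex) - bk * 0.5 * (uhx - ehx)
        by = ak * (-puy - pey) - bk * 0.5 * (uhy - ehy)
        # joint k+1 (k is its x_{j-1}): u_j = e_k
        a1 = 2.0 * theta[kp] / lmean[kp]
        b1 = (theta[kp] / lmean[kp]) ** 2
        bx += a1 * (-ey[k] / (el[k] * el[k])) + b1 * 0.5 * ehx
        by += a1 * (ex[k] / (el[k] * el[k])) + b1 * 0.5 * ehy
        # joint k-1 (k is its x_{j+1}): e_j = e_{k-1} = u
        a2 = 2.0 * theta[km] / lmean[km]
        b2 = (theta[km] / lmean[km]) ** 2
        bx += a2 * (-ey[km] / (el[km] * el[km])) - b2 * 0.5 * uhx
        by += a2 * (ex[km] / (el[km] * el[km])) - b2 * 0.5 * uhy
        gx += 2.0 * kappa * bx
        gy += 2.0 * kappa * by
        f[k, 0] = -gx
        f[k, 1] = -gy
    return f


@njit(cache=True)
def resolve_contacts(v, free, r_c, exclude=3):
    """Excluded-volume pass: push vertices away from non-neighbouring
    *segments* they approach closer than ``r_c`` (the membrane cannot
    self-intersect).

    Vertex-to-segment distances catch wall approaches at any phase of the
    discretization.  Pairs within ``exclude`` contour positions are
    skipped — their proximity is legitimate local geometry.  Only free
    vertices move; reaction is shared with the segment's free endpoints.
    Returns the number of contacts resolved.
    """
    n = v.shape[0]
    moved = 0
    # sort-and-sweep on x; the window covers r_c plus a segment's extent
    order = np.argsort(v[:, 0])
    window = 3.0 * r_c
    for a in range(n):
        for b in range(a + 1, n):
            if v[order[b], 0] - v[order[a], 0] > window:
                break
            moved += _vertex_segment_push(v, free, order[a], order[b],
                                          n, r_c, exclude)
            moved += _vertex_segment_push(v, free, order[b], order[a],
                                          n, r_c, exclude)
    return moved


@njit(cache=True)
def _vertex_segment_push(v, free, i, j, n, r_c, exclude):
    """Push vertex ``i`` and segment ``j -> j+1`` apart if closer than
    ``r_c``; returns 1 when a push happened."""
    j1 = j + 1 if j + 1 < n else 0
    ri = i - j if i >= j else j - i
    if min(ri, n - ri) <= exclude:
        return 0
    ri2 = i - j1 if i >= j1 else j1 - i
    if min(ri2, n - ri2) <= exclude:
        return 0
    ex = v[j1, 0] - v[j, 0]
    ey = v[j1, 1] - v[j, 1]
    e2 = ex * ex + ey * ey
    if e2 < 1e-24:
        return 0
    t = ((v[i, 0] - v[j, 0]) * ex + (v[i, 1] - v[j, 1]) * ey) / e2
    if t < 0.0:
        t = 0.0
    elif t > 1.0:
        t = 1.0
    dx = v[i, 0] - (v[j, 0] + t * ex)
    dy = v[i, 1] - (v[j, 1] + t * ey)
    d2 = dx * dx + dy * dy
    if d2 >= r_c * r_c or d2 < 1e-24:
        return 0
    d = np.sqrt(d2)
    push = 0.5 * (r_c - d)
    ux, uy = dx / d, dy / d
    if free[i]:
        v[i, 0] += push * ux
        v[i, 1] += push * uy
    if free[j]:
        v[j, 0] -= push * ux * (1.0 - t)
        v[j, 1] -= push * uy * (1.0 - t)
    if free[j1]:
        v[j1, 0] -= push * ux * t
        v[j1, 1] -= push * uy * t
    return 1


@njit(cache=True)
def run_substeps(v, free, P, tau, kappa, zeta, dt_sub, n_sub,
                 cx, cy, fx, fy, fB, amp, sigma, floor_y, d_max, d_min):
    """Advance the membrane by up to ``n_sub`` Euler substeps under
    Helfrich + actin forces.  Modifies ``v`` in place.

    Each focus pushes with the Gaussian kernel centred on (cx, cy) (the
    tracked membrane contact point) along the direction away from its
    nucleation point (fx, fy).  Returns (status, min_edge, max_edge,
    area, substeps_done); status 1 flags a displacement larger than
    ``d_max`` in one substep (time step too large), status 2 an early
    exit because an edge collapsed below 0.7*d_min — the bending term
    turns explicit-unstable on such edges, so the caller must remesh
    before continuing.
    """
    n = v.shape[0]
    nf = fx.shape[0]
    w0 = amp / (sigma * _SQRT2PI)
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    lim2 = d_max * d_max
    done = 0
    for _ in range(n_sub):
        f = mem_force(v, P, tau, kappa)
        for j in range(nf):
            for k in range(n):
                wx = v[k, 0] - cx[j]
                wy = v[k, 1] - cy[j]
                w2 = wx * wx + wy * wy
                dx = v[k, 0] - fx[j]
                dy = v[k, 1] - fy[j]
                r2 = dx * dx + dy * dy
                if r2 > 1e-24:
                    w = w0 * np.exp(-w2 * inv2s2) * fB[j] / np.sqrt(r2)
                    f[k, 0] += w * dx
                    f[k, 1] += w * dy
        for k in range(n):
            if free[k]:
                sx = zeta * dt_sub * f[k, 0]
                sy = zeta * dt_sub * f[k, 1]
                if sx * sx + sy * sy > lim2:
                    return 1, 0.0, 0.0, 0.0, done
                v[k, 0] += sx
                v[k, 1] += sy
                if v[k, 1] < floor_y:
                    v[k, 1] = floor_y
        done += 1
        collapse = (0.7 * d_min) ** 2
        for k in range(n):
            k1 = k + 1 if k + 1 < n else 0
            dx = v[k1, 0] - v[k, 0]
            dy = v[k1, 1] - v[k, 1]
            if dx * dx + dy * dy < collapse:
                mn, mx, area = _edge_stats(v)
                return 2, mn, mx, area, done
    mn, mx, area = _edge_stats(v)
    return 0, mn, mx, area, done


@njit(cache=True)
def _edge_stats(v):
    n = v.shape[0]
    mn = 1e30
    mx = 0.0
    area2 = 0.0
    for k in range(n):
        k1 = k + 1 if k + 1 < n else 0
        dx = v[k1, 0] - v[k, 0]
        dy = v[k1, 1] - v[k, 1]
        d = np.sqrt(dx * dx + dy * dy)
        if d < mn:
            mn = d
        if d > mx:
            mx = d
        area2 += v[k, 0] * v[k1, 1] - v[k1, 0] * v[k, 1]
    return mn, mx, abs(0.5 * area2)
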