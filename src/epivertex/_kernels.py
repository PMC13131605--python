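"""Numba kernels for polyhedral cell geometry, energy, and analytic forces.

Faces are stored once, in the frame of their first adjacent cell (``c1``).
The second cell (``c2``) sees the same face translated by ``-pair_shift``
(periodic images).  Each face polygon is triangulated about its own centroid
(the mean of its vertices), so the two cells sharing a face triangulate it
identically and signed volumes cancel exactly -- this is what makes the
confluence audit exact to round-off.
"""

import numpy as np
from numba import njit

_TINY = 1e-300


@njit(cache=True)
def cell_geometry_kernel(
    verts, f_off, f_vidx, f_shift, pair_shift,
    cf_off, cf_faces, cf_side, seeds,
):
    """Per-cell volume, surface area and (volume-weighted) centroid.

    Volumes are signed sums of tetrahedra (cell seed, face centroid, edge)
    with the face wound outward; surface areas are sums of triangle areas.
    """
    C = cf_off.shape[0] - 1
    vol = np.zeros(C)
    area = np.zeros(C)
    cen = np.zeros((C, 3))
    P = np.empty((64, 3))
    for c in range(C):
        Ox, Oy, Oz = seeds[c, 0], seeds[c, 1], seeds[c, 2]
        for j in range(cf_off[c], cf_off[c + 1]):
            f = cf_faces[j]
            side = cf_side[j]
            b0 = f_off[f]
            m = f_off[f + 1] - b0
            fx = 0.0
            fy = 0.0
            fz = 0.0
            for k in range(m):
                vi = f_vidx[b0 + k]
                px = verts[vi, 0] + f_shift[b0 + k, 0]
                py = verts[vi, 1] + f_shift[b0 + k, 1]
                pz = verts[vi, 2] + f_shift[b0 + k, 2]
                if side < 0:
                    px -= pair_shift[f, 0]
                    py -= pair_shift[f, 1]
                    pz -= pair_shift[f, 2]
                P[k, 0] = px
                P[k, 1] = py
                P[k, 2] = pz
                fx += px
                fy += py
                fz += pz
            fx /= m
            fy /= m
            fz /= m
            for k in range(m):
                k2 = (k + 1) % m
                ax, ay, az = P[k, 0], P[k, 1], P[k, 2]
                bx, by, bz = P[k2, 0], P[k2, 1], P[k2, 2]
                # triangle area (side-independent)
                ux, uy, uz = ax - fx, ay - fy, az - fz
                vx, vy, vz = bx - fx, by - fy, bz - fz
                nx = uy * vz - uz * vy
                ny = uz * vx - ux * vz
                nz = ux * vy - uy * vx
                area[c] += 0.5 * np.sqrt(nx * nx + ny * ny + nz * nz)
                # signed tetra (O, fc, a, b); reverse winding for side -1
                u1x, u1y, u1z = fx - Ox, fy - Oy, fz - Oz
                v1x, v1y, v1z = ax - Ox, ay - Oy, az - Oz
                w1x, w1y, w1z = bx - Ox, by - Oy, bz - Oz
                det = (
                    u1x * (v1y * w1z - v1z * w1y)
                    - u1y * (v1x * w1z - v1z * w1x)
                    + u1z * (v1x * w1y - v1y * w1x)
                )
                vt = side * det / 6.0
                vol[c] += vt
                cen[c, 0] += vt * (Ox + fx + ax + bx) * 0.25
                cen[c, 1] += vt * (Oy + fy + ay + by) * 0.25
                cen[c, 2] += vt * (Oz + fz + az + bz) * 0.25
    for c in range(C):
        if abs(vol[c]) > 1e-14:
            cen[c, 0] /= vol[c]
            cen[c, 1] /= vol[c]
            cen[c, 2] /= vol[c]
        else:
            cen[c, 0] = seeds[c, 0]
            cen[c, 1] = seeds[c, 1]
            cen[c, 2] = seeds[c, 2]
    return vol, area, cen


@njit(cache=True)
def face_area_kernel(verts, f_off, f_vidx, f_shift):
    F = f_off.shape[0] - 1
    area = np.zeros(F)
    P = np.empty((64, 3))
    for f in range(F):
        b0 = f_off[f]
        m = f_off[f + 1] - b0
        fx = 0.0
        fy = 0.0
        fz = 0.0
        for k in range(m):
            vi = f_vidx[b0 + k]
            P[k, 0] = verts[vi, 0] + f_shift[b0 + k, 0]
            P[k, 1] = verts[vi, 1] + f_shift[b0 + k, 1]
            P[k, 2] = verts[vi, 2] + f_shift[b0 + k, 2]
            fx += P[k, 0]
            fy += P[k, 1]
            fz += P[k, 2]
        fx /= m
        fy /= m
        fz /= m
        for k in range(m):
            k2 = (k + 1) % m
            ux, uy, uz = P[k, 0] - fx, P[k, 1] - fy, P[k, 2] - fz
            vx, vy, vz = P[k2, 0] - fx, P[k2, 1] - fy, P[k2, 2] - fz
            nx = uy * vz - uz * vy
            ny = uz * vx - ux * vz
            nz = ux * vy - uy * vx
            area[f] += 0.5 * np.sqrt(nx * nx + ny * ny + nz * nz)
    return area


@njit(cache=True)
def forces_kernel(
    verts, f_off, f_vidx, f_shift, face_cells, pair_shift,
    cf_off, cf_faces, cf_side, seeds,
    V0, S0, active, face_sigma, KV, KS,
):
    """Total energy and its analytic gradient with respect to the vertices.

    Returns (E, grad).  The force on vertex i is ``-grad[i]``; pinning is
    applied by the caller.
    """
    vol, area, _cen = cell_geometry_kernel(
        verts, f_off, f_vidx, f_shift, pair_shift, cf_off, cf_faces, cf_side, seeds
    )
    C = vol.shape[0]
    Nv = verts.shape[0]
    F = f_off.shape[0] - 1
    cV = np.zeros(C)
    cS = np.zeros(C)
    E = 0.0
    for c in range(C):
        if active[c]:
            dv = vol[c] - V0[c]
            ds = area[c] - S0[c]
            cV[c] = 2.0 * KV * dv
            cS[c] = 2.0 * KS * ds
            E += KV * dv * dv + KS * ds * ds
    grad = np.zeros((Nv, 3))
    P = np.empty((64, 3))
    vids = np.empty(64, dtype=np.int64)
    for f in range(F):
        c1 = face_cells[f, 0]
        c2 = face_cells[f, 1]
        b0 = f_off[f]
        m = f_off[f + 1] - b0
        fx = 0.0
        fy = 0.0
        fz = 0.0
        for k in range(m):
            vi = f_vidx[b0 + k]
            vids[k] = vi
            P[k, 0] = verts[vi, 0] + f_shift[b0 + k, 0]
            P[k, 1] = verts[vi, 1] + f_shift[b0 + k, 1]
            P[k, 2] = verts[vi, 2] + f_shift[b0 + k, 2]
            fx += P[k, 0]
            fy += P[k, 1]
            fz += P[k, 2]
        fx /= m
        fy /= m
        fz /= m
        wA = cS[c1] + face_sigma[f]
        cv1 = cV[c1]
        O1x, O1y, O1z = seeds[c1, 0], seeds[c1, 1], seeds[c1, 2]
        has2 = c2 >= 0
        cv2 = 0.0
        O2x = O2y = O2z = 0.0
        if has2:
            wA += cS[c2]
            cv2 = cV[c2]
            O2x = seeds[c2, 0] + pair_shift[f, 0]
            O2y = seeds[c2, 1] + pair_shift[f, 1]
            O2z = seeds[c2, 2] + pair_shift[f, 2]
        gfx = 0.0
        gfy = 0.0
        gfz = 0.0
        A_f = 0.0
        for k in range(m):
            k2 = (k + 1) % m
            ax, ay, az = P[k, 0], P[k, 1], P[k, 2]
            bx, by, bz = P[k2, 0], P[k2, 1], P[k2, 2]
            ux, uy, uz = ax - fx, ay - fy, az - fz
            vx, vy, vz = bx - fx, by - fy, bz - fz
            nx = uy * vz - uz * vy
            ny = uz * vx - ux * vz
            nz = ux * vy - uy * vx
            nn = np.sqrt(nx * nx + ny * ny + nz * nz)
            A_f += 0.5 * nn
            if nn > 1e-14 and wA != 0.0:
                hx, hy, hz = nx / nn, ny / nn, nz / nn
                # d(area)/d(a) = (v x nh)/2 ; d/d(b) = (nh x u)/2 ; d/d(fc) = (nh x (b-a))/2
                half = 0.5 * wA
                grad[vids[k], 0] += half * (vy * hz - vz * hy)
                grad[vids[k], 1] += half * (vz * hx - vx * hz)
                grad[vids[k], 2] += half * (vx * hy - vy * hx)
                grad[vids[k2], 0] += half * (hy * uz - hz * uy)
                grad[vids[k2], 1] += half * (hz * ux - hx * uz)
                grad[vids[k2], 2] += half * (hx * uy - hy * ux)
                dx, dy, dz = bx - ax, by - ay, bz - az
                gfx += half * (hy * dz - hz * dy)
                gfy += half * (hz * dx - hx * dz)
                gfz += half * (hx * dy - hy * dx)
            # volume gradients: tetra (O, fc, a, b), V = (fc-O).((a-O)x(b-O))/6
            if cv1 != 0.0:
                u1x, u1y, u1z = fx - O1x, fy - O1y, fz - O1z
                v1x, v1y, v1z = ax - O1x, ay - O1y, az - O1z
                w1x, w1y, w1z = bx - O1x, by - O1y, bz - O1z
                s6 = cv1 / 6.0
                gfx += s6 * (v1y * w1z - v1z * w1y)
                gfy += s6 * (v1z * w1x - v1x * w1z)
                gfz += s6 * (v1x * w1y - v1y * w1x)
                grad[vids[k], 0] += s6 * (w1y * u1z - w1z * u1y)
                grad[vids[k], 1] += s6 * (w1z * u1x - w1x * u1z)
                grad[vids[k], 2] += s6 * (w1x * u1y - w1y * u1x)
                grad[vids[k2], 0] += s6 * (u1y * v1z - u1z * v1y)
                grad[vids[k2], 1] += s6 * (u1z * v1x - u1x * v1z)
                grad[vids[k2], 2] += s6 * (u1x * v1y - u1y * v1x)
            if has2 and cv2 != 0.0:
                u1x, u1y, u1z = fx - O2x, fy - O2y, fz - O2z
                v1x, v1y, v1z = ax - O2x, ay - O2y, az - O2z
                w1x, w1y, w1z = bx - O2x, by - O2y, bz - O2z
                s6 = -cv2 / 6.0
                gfx += s6 * (v1y * w1z - v1z * w1y)
                gfy += s6 * (v1z * w1x - v1x * w1z)
                gfz += s6 * (v1x * w1y - v1y * w1x)
                grad[vids[k], 0] += s6 * (w1y * u1z - w1z * u1y)
                grad[vids[k], 1] += s6 * (w1z * u1x - w1x * u1z)
                grad[vids[k], 2] += s6 * (w1x * u1y - w1y * u1x)
                grad[vids[k2], 0] += s6 * (u1y * v1z - u1z * v1y)
                grad[vids[k2], 1] += s6 * (u1z * v1x - u1x * v1z)
                grad[vids[k2], 2] += s6 * (u1x * v1y - u1y * v1x)
        E += face_sigma[f] * A_f
        gfx /= m
        gfy /= m
        gfz /= m
        for k in range(m):
            grad[vids[k], 0] += gfx
            grad[vids[k], 1] += gfy
            grad[vids[k], 2] += gfz
    return E, grad
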