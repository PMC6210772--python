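"""Low-level ray-tracing engine: BVH build and Numba traversal kernels.

The BVH is built by recursive object-median splits along the widest
centroid axis (explicit node arrays, leaves of up to ``LEAF_SIZE``
triangles).  Geometry and node bounds are stored float32 for cache
efficiency — node bounds are inflated past the rounding slack so the
cast-down stays conservative — while traversal arithmetic runs in float64.

Scene tiling (clone instancing) is handled at traversal time: a ray is
tested against every tile by translating its origin, nearest-first by tile
entry distance.  All kernels are single-threaded and deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

LEAF_SIZE = 8

__all__ = ["BVH", "build_bvh", "cast_rays", "render_band_kernel", "openness_kernel"]


@dataclass
class BVH:
    """Bounding-volume hierarchy over a triangle soup.

    ``node_count[i] == 0`` marks an internal node with children
    ``node_a[i]``/``node_b[i]``; otherwise the node is a leaf over the
    triangle range ``[node_a[i], node_a[i] + node_count[i])`` of the
    reordered arrays.  ``order`` maps internal triangle index back to the
    caller's original index.
    """

    nodes_min: np.ndarray  # (n_nodes, 3) float32, conservatively inflated
    nodes_max: np.ndarray
    node_a: np.ndarray  # (n_nodes,) int64
    node_b: np.ndarray
    node_count: np.ndarray  # (n_nodes,) int64
    v0: np.ndarray  # (n, 3) float32
    e1: np.ndarray
    e2: np.ndarray
    order: np.ndarray  # (n,) int64
    n: int

    def args(self):
        return (self.nodes_min, self.nodes_max, self.node_a, self.node_b,
                self.node_count, self.v0, self.e1, self.e2, self.n)


@njit(cache=True)
def _build_nodes(cent, tri_min, tri_max, leaf_size):
    n = cent.shape[0]
    max_nodes = 4 * (n // leaf_size + 2)
    nodes_min = np.empty((max_nodes, 3), dtype=np.float64)
    nodes_max = np.empty((max_nodes, 3), dtype=np.float64)
    node_a = np.zeros(max_nodes, dtype=np.int64)
    node_b = np.zeros(max_nodes, dtype=np.int64)
    node_count = np.zeros(max_nodes, dtype=np.int64)
    tri_idx = np.arange(n)
    tmp = np.empty(n, dtype=np.int64)
    # stack of (node_id, start, end)
    stack = np.empty((128, 3), dtype=np.int64)
    stack[0, 0] = 0
    stack[0, 1] = 0
    stack[0, 2] = n
    sp = 1
    n_nodes = 1
    nb = 16
    counts = np.empty(nb, dtype=np.int64)
    while sp > 0:
        sp -= 1
        node = stack[sp, 0]
        start = stack[sp, 1]
        end = stack[sp, 2]
        # bounds over the range (triangle and centroid)
        bx0 = by0 = bz0 = np.inf
        bx1 = by1 = bz1 = -np.inf
        cx0 = cy0 = cz0 = np.inf
        cx1 = cy1 = cz1 = -np.inf
        for ii in range(start, end):
            t = tri_idx[ii]
            if tri_min[t, 0] < bx0:
                bx0 = tri_min[t, 0]
            if tri_min[t, 1] < by0:
                by0 = tri_min[t, 1]
            if tri_min[t, 2] < bz0:
                bz0 = tri_min[t, 2]
            if tri_max[t, 0] > bx1:
                bx1 = tri_max[t, 0]
            if tri_max[t, 1] > by1:
                by1 = tri_max[t, 1]
            if tri_max[t, 2] > bz1:
                bz1 = tri_max[t, 2]
            if cent[t, 0] < cx0:
                cx0 = cent[t, 0]
            if cent[t, 0] > cx1:
                cx1 = cent[t, 0]
            if cent[t, 1] < cy0:
                cy0 = cent[t, 1]
            if cent[t, 1] > cy1:
                cy1 = cent[t, 1]
            if cent[t, 2] < cz0:
                cz0 = cent[t, 2]
            if cent[t, 2] > cz1:
                cz1 = cent[t, 2]
        nodes_min[node, 0] = bx0
        nodes_min[node, 1] = by0
        nodes_min[node, 2] = bz0
        nodes_max[node, 0] = bx1
        nodes_max[node, 1] = by1
        nodes_max[node, 2] = bz1
        count = end - start
        ex = cx1 - cx0
        ey = cy1 - cy0
        ez = cz1 - cz0
        degenerate = ex <= 0.0 and ey <= 0.0 and ez <= 0.0
        if count <= leaf_size or degenerate or sp >= 125:
            node_a[node] = start
            node_count[node] = count
            continue
        if ex >= ey and ex >= ez:
            axis = 0
            c0, c1 = cx0, cx1
        elif ey >= ez:
            axis = 1
            c0, c1 = cy0, cy1
        else:
            axis = 2
            c0, c1 = cz0, cz1
        # object-median split via 16 centroid bins on the widest axis
        for b in range(nb):
            counts[b] = 0
        inv = nb / (c1 - c0)
        for ii in range(start, end):
            t = tri_idx[ii]
            b = int((cent[t, axis] - c0) * inv)
            if b > nb - 1:
                b = nb - 1
            counts[b] += 1
        half = count // 2
        acc = 0
        split_bin = nb - 1
        for b in range(nb):
            acc += counts[b]
            if acc >= half:
                split_bin = b
                break
        # stable partition: bins <= split_bin left, rest right
        left = start
        right = 0
        for ii in range(start, end):
            t = tri_idx[ii]
            b = int((cent[t, axis] - c0) * inv)
            if b > nb - 1:
                b = nb - 1
            if b <= split_bin:
                tri_idx[left] = t
                left += 1
            else:
                tmp[right] = t
                right += 1
        for ii in range(right):
            tri_idx[left + ii] = tmp[ii]
        mid = left
        if mid == start or mid == end:
            mid = start + half  # all centroids in one bin: split by count
        child_a = n_nodes
        child_b = n_nodes + 1
        n_nodes += 2
        node_a[node] = child_a
        node_b[node] = child_b
        stack[sp, 0] = child_a
        stack[sp, 1] = start
        stack[sp, 2] = mid
        stack[sp + 1, 0] = child_b
        stack[sp + 1, 1] = mid
        stack[sp + 1, 2] = end
        sp += 2
    return nodes_min[:n_nodes], nodes_max[:n_nodes], node_a[:n_nodes], \
        node_b[:n_nodes], node_count[:n_nodes], tri_idx, n_nodes


def build_bvh(tris: np.ndarray) -> BVH:
    """Build a BVH from triangles shaped (n, 3 vertices, 3 coords)."""
    tris = np.ascontiguousarray(tris, dtype=np.float64)
    n = len(tris)
    if n == 0:
        inf3 = np.full((1, 3), np.inf, dtype=np.float32)
        zero = np.zeros(1, dtype=np.int64)
        empty = np.empty((0, 3), dtype=np.float32)
        return BVH(inf3, -inf3, zero, zero.copy(), zero.copy(),
                   empty, empty.copy(), empty.copy(),
                   np.empty(0, dtype=np.int64), 0)
    cent = tris.mean(axis=1)
    tri_min = tris.min(axis=1)
    tri_max = tris.max(axis=1)
    nmin, nmax, na, nb, ncount, order, n_nodes = _build_nodes(
        cent, tri_min, tri_max, LEAF_SIZE
    )
    tris = tris[order]
    # inflate bounds past the float32 rounding slack
    slack = 1e-5 * (1.0 + np.abs(nmin))
    nmin = nmin - slack
    slack = 1e-5 * (1.0 + np.abs(nmax))
    nmax = nmax + slack
    v0 = np.ascontiguousarray(tris[:, 0], dtype=np.float32)
    e1 = np.ascontiguousarray(tris[:, 1] - tris[:, 0], dtype=np.float32)
    e2 = np.ascontiguousarray(tris[:, 2] - tris[:, 0], dtype=np.float32)
    return BVH(
        np.ascontiguousarray(nmin, dtype=np.float32),
        np.ascontiguousarray(nmax, dtype=np.float32),
        na, nb, ncount, v0, e1, e2, order.astype(np.int64), n,
    )


@njit(cache=True)
def _inv_dir(d):
    if d > 1e-300 or d < -1e-300:
        return 1.0 / d
    return 1e300 if d >= 0.0 else -1e300


@njit(cache=True, inline="always")
def _tri_hit(j, ox, oy, oz, dx, dy, dz, t_min, t_max, v0, e1, e2):
    """Moller-Trumbore; returns hit distance or -1."""
    e1x = e1[j, 0]
    e1y = e1[j, 1]
    e1z = e1[j, 2]
    e2x = e2[j, 0]
    e2y = e2[j, 1]
    e2z = e2[j, 2]
    px = dy * e2z - dz * e2y
    py = dz * e2x - dx * e2z
    pz = dx * e2y - dy * e2x
    det = e1x * px + e1y * py + e1z * pz
    if det < 1e-14 and det > -1e-14:
        return -1.0
    inv = 1.0 / det
    tx = ox - v0[j, 0]
    ty = oy - v0[j, 1]
    tz = oz - v0[j, 2]
    u = (tx * px + ty * py + tz * pz) * inv
    if u < -1e-9 or u > 1.0 + 1e-9:
        return -1.0
    qx = ty * e1z - tz * e1y
    qy = tz * e1x - tx * e1z
    qz = tx * e1y - ty * e1x
    v = (dx * qx + dy * qy + dz * qz) * inv
    if v < -1e-9 or u + v > 1.0 + 1e-9:
        return -1.0
    t = (e2x * qx + e2y * qy + e2z * qz) * inv
    if t > t_min and t < t_max:
        return t
    return -1.0


@njit(cache=True, inline="always")
def _slab(node, ox, oy, oz, ix, iy, iz, t_min, t_max, nodes_min, nodes_max):
    lo = (nodes_min[node, 0] - ox) * ix
    hi = (nodes_max[node, 0] - ox) * ix
    if lo > hi:
        lo, hi = hi, lo
    t0 = lo if lo > t_min else t_min
    t1 = hi if hi < t_max else t_max
    lo = (nodes_min[node, 1] - oy) * iy
    hi = (nodes_max[node, 1] - oy) * iy
    if lo > hi:
        lo, hi = hi, lo
    if lo > t0:
        t0 = lo
    if hi < t1:
        t1 = hi
    lo = (nodes_min[node, 2] - oz) * iz
    hi = (nodes_max[node, 2] - oz) * iz
    if lo > hi:
        lo, hi = hi, lo
    if lo > t0:
        t0 = lo
    if hi < t1:
        t1 = hi
    if t0 > t1:
        return np.inf
    return t0


@njit(cache=True)
def _traverse(ox, oy, oz, dx, dy, dz, t_min, t_best,
              nodes_min, nodes_max, node_a, node_b, node_count,
              v0, e1, e2, n, stack, any_hit):
    """One-tile traversal; returns (t, reordered triangle index or -1).

    Children are descended nearest-first; with ``any_hit`` the first
    intersection in (t_min, t_best) wins.
    """
    if n == 0:
        return t_best, -1
    ix = _inv_dir(dx)
    iy = _inv_dir(dy)
    iz = _inv_dir(dz)
    best_t = t_best
    best_i = -1
    if _slab(0, ox, oy, oz, ix, iy, iz, t_min, best_t, nodes_min, nodes_max) == np.inf:
        return best_t, best_i
    stack[0] = 0
    sp = 1
    while sp > 0:
        sp -= 1
        node = stack[sp]
        cnt = node_count[node]
        if cnt > 0:
            j0 = node_a[node]
            for j in range(j0, j0 + cnt):
                t = _tri_hit(j, ox, oy, oz, dx, dy, dz, t_min, best_t, v0, e1, e2)
                if t > 0.0:
                    best_t = t
                    best_i = j
                    if any_hit:
                        return best_t, best_i
        else:
            a = node_a[node]
            b = node_b[node]
            ta = _slab(a, ox, oy, oz, ix, iy, iz, t_min, best_t, nodes_min, nodes_max)
            tb = _slab(b, ox, oy, oz, ix, iy, iz, t_min, best_t, nodes_min, nodes_max)
            if ta > tb:
                a, b = b, a
                ta, tb = tb, ta
            if tb != np.inf:
                stack[sp] = b
                sp += 1
            if ta != np.inf:
                stack[sp] = a
                sp += 1
    return best_t, best_i


@njit(cache=True)
def _tile_order(ox, oy, oz, dx, dy, dz, t_min, t_max, offsets,
                nodes_min, nodes_max, entry, order):
    """Entry distance into each tile's root bounds, sorted ascending."""
    ix = _inv_dir(dx)
    iy = _inv_dir(dy)
    iz = _inv_dir(dz)
    n_tiles = offsets.shape[0]
    for k in range(n_tiles):
        entry[k] = _slab(0, ox - offsets[k, 0], oy - offsets[k, 1], oz,
                         ix, iy, iz, t_min, t_max, nodes_min, nodes_max)
        order[k] = k
    for a in range(1, n_tiles):
        e = entry[a]
        o = order[a]
        b = a - 1
        while b >= 0 and entry[b] > e:
            entry[b + 1] = entry[b]
            order[b + 1] = order[b]
            b -= 1
        entry[b + 1] = e
        order[b + 1] = o


@njit(cache=True)
def _intersect_tiled_ws(ox, oy, oz, dx, dy, dz, t_min, t_max, offsets,
                        nodes_min, nodes_max, node_a, node_b, node_count,
                        v0, e1, e2, n, stack, entry, order):
    """Nearest hit over all clone tiles; returns (t, tri index, tile index)."""
    _tile_order(ox, oy, oz, dx, dy, dz, t_min, t_max, offsets,
                nodes_min, nodes_max, entry, order)
    best_t = t_max
    best_i = -1
    best_k = -1
    for a in range(offsets.shape[0]):
        if entry[a] >= best_t:
            break
        k = order[a]
        t, i = _traverse(
            ox - offsets[k, 0], oy - offsets[k, 1], oz, dx, dy, dz,
            t_min, best_t, nodes_min, nodes_max, node_a, node_b, node_count,
            v0, e1, e2, n, stack, False,
        )
        if i >= 0 and t < best_t:
            best_t = t
            best_i = i
            best_k = k
    return best_t, best_i, best_k


@njit(cache=True)
def _occluded_ws(ox, oy, oz, dx, dy, dz, t_min, t_max, offsets,
                 nodes_min, nodes_max, node_a, node_b, node_count,
                 v0, e1, e2, n, stack, entry, order):
    _tile_order(ox, oy, oz, dx, dy, dz, t_min, t_max, offsets,
                nodes_min, nodes_max, entry, order)
    for a in range(offsets.shape[0]):
        if entry[a] == np.inf:
            break
        k = order[a]
        t, i = _traverse(
            ox - offsets[k, 0], oy - offsets[k, 1], oz, dx, dy, dz,
            t_min, t_max, nodes_min, nodes_max, node_a, node_b, node_count,
            v0, e1, e2, n, stack, True,
        )
        if i >= 0:
            return True
    return False


@njit(cache=True)
def _intersect_tiled(ox, oy, oz, dx, dy, dz, t_min, t_max, offsets,
                     nodes_min, nodes_max, node_a, node_b, node_count,
                     v0, e1, e2, n):
    """Convenience wrapper allocating its own workspace (single queries)."""
    stack = np.empty(128, dtype=np.int64)
    entry = np.empty(offsets.shape[0])
    order = np.empty(offsets.shape[0], dtype=np.int64)
    return _intersect_tiled_ws(ox, oy, oz, dx, dy, dz, t_min, t_max, offsets,
                               nodes_min, nodes_max, node_a, node_b, node_count,
                               v0, e1, e2, n, stack, entry, order)


@njit(cache=True)
def cast_rays(origin, dirs, t_min, t_max, offsets,
              nodes_min, nodes_max, node_a, node_b, node_count,
              v0, e1, e2, n):
    """Cast many rays from one origin; returns (t, reordered tri, tile)."""
    m = dirs.shape[0]
    out_t = np.empty(m)
    out_i = np.empty(m, dtype=np.int64)
    out_k = np.empty(m, dtype=np.int64)
    stack = np.empty(128, dtype=np.int64)
    entry = np.empty(offsets.shape[0])
    order = np.empty(offsets.shape[0], dtype=np.int64)
    for r in range(m):
        t, i, k = _intersect_tiled_ws(
            origin[0], origin[1], origin[2],
            dirs[r, 0], dirs[r, 1], dirs[r, 2],
            t_min, t_max, offsets, nodes_min, nodes_max,
            node_a, node_b, node_count, v0, e1, e2, n,
            stack, entry, order,
        )
        out_t[r] = t
        out_i[r] = i
        out_k[r] = k
    return out_t, out_i, out_k


@njit(cache=True)
def render_band_kernel(
    nodes_min, nodes_max, node_a, node_b, node_count, v0, e1, e2, n,
    mats, offsets,
    rho_by_mat, tau_by_mat,
    sun_dir, e_sun_perp, l_sky, e_horiz,
    x0, x1, y0, y1, z_start,
    n_paths, seed, max_depth, rr_depth, rr_prob,
):
    """Monte Carlo HDRF estimate for one band.

    Nadir orthographic sensor over the footprint [x0,x1]x[y0,y1]; per-path
    radiance accumulates next-event contributions from the directional sun
    plus isotropic sky radiance collected when a path escapes the scene.
    Leaf materials are bi-Lambertian (reflect rho / transmit tau / absorb),
    opaque materials Lambertian.  Returns (mean, standard error) of
    pi * L_nadir / e_horiz.
    """
    np.random.seed(seed)
    acc = 0.0
    acc2 = 0.0
    eps = 1e-5
    stack = np.empty(128, dtype=np.int64)
    entry = np.empty(offsets.shape[0])
    order = np.empty(offsets.shape[0], dtype=np.int64)
    for _ in range(n_paths):
        ox = x0 + (x1 - x0) * np.random.random()
        oy = y0 + (y1 - y0) * np.random.random()
        oz = z_start
        dx = 0.0
        dy = 0.0
        dz = -1.0
        tput = 1.0
        lrad = 0.0
        for depth in range(max_depth):
            t, i, k = _intersect_tiled_ws(
                ox, oy, oz, dx, dy, dz, 1e-7, 1e30, offsets,
                nodes_min, nodes_max, node_a, node_b, node_count,
                v0, e1, e2, n, stack, entry, order,
            )
            if i < 0:
                if dz > 0.0:
                    lrad += tput * l_sky
                break
            hx = ox + t * dx
            hy = oy + t * dy
            hz = oz + t * dz
            # geometric normal, flipped to face the incoming ray
            nx = e1[i, 1] * e2[i, 2] - e1[i, 2] * e2[i, 1]
            ny = e1[i, 2] * e2[i, 0] - e1[i, 0] * e2[i, 2]
            nz = e1[i, 0] * e2[i, 1] - e1[i, 1] * e2[i, 0]
            nl = np.sqrt(nx * nx + ny * ny + nz * nz)
            if nl < 1e-18:
                break
            nx /= nl
            ny /= nl
            nz /= nl
            if nx * dx + ny * dy + nz * dz > 0.0:
                nx = -nx
                ny = -ny
                nz = -nz
            m = mats[i]
            rho = rho_by_mat[m]
            tau = tau_by_mat[m]
            # next-event estimation toward the sun (delta light; diffuse
            # transmission does not propagate the beam, so binary visibility)
            if e_sun_perp > 0.0:
                cos_s = nx * sun_dir[0] + ny * sun_dir[1] + nz * sun_dir[2]
                fval = rho if cos_s > 0.0 else tau
                if fval > 0.0:
                    side = eps if cos_s > 0.0 else -eps
                    sx = hx + nx * side + sun_dir[0] * eps
                    sy = hy + ny * side + sun_dir[1] * eps
                    sz = hz + nz * side + sun_dir[2] * eps
                    if not _occluded_ws(
                        sx, sy, sz, sun_dir[0], sun_dir[1], sun_dir[2],
                        0.0, 1e30, offsets, nodes_min, nodes_max,
                        node_a, node_b, node_count, v0, e1, e2, n,
                        stack, entry, order,
                    ):
                        cs = cos_s if cos_s > 0.0 else -cos_s
                        lrad += tput * (fval / np.pi) * cs * e_sun_perp
            # scatter: event sampled by albedo, cosine-weighted direction
            xi = np.random.random()
            if xi < rho:
                ax = nx
                ay = ny
                az = nz
            elif xi < rho + tau:
                ax = -nx
                ay = -ny
                az = -nz
            else:
                break
            if depth >= rr_depth:
                if np.random.random() > rr_prob:
                    break
                tput /= rr_prob
            # orthonormal basis about the scattering axis
            if ax < 0.9 and ax > -0.9:
                bx = 0.0
                by = az
                bz = -ay
            else:
                bx = -az
                by = 0.0
                bz = ax
            bl = np.sqrt(bx * bx + by * by + bz * bz)
            bx /= bl
            by /= bl
            bz /= bl
            cx = ay * bz - az * by
            cy = az * bx - ax * bz
            cz = ax * by - ay * bx
            u1 = np.random.random()
            u2 = np.random.random()
            sr = np.sqrt(u1)
            ch = np.sqrt(1.0 - u1)
            phi = 2.0 * np.pi * u2
            dx = sr * np.cos(phi) * bx + sr * np.sin(phi) * cx + ch * ax
            dy = sr * np.cos(phi) * by + sr * np.sin(phi) * cy + ch * ay
            dz = sr * np.cos(phi) * bz + sr * np.sin(phi) * cz + ch * az
            ox = hx + ax * eps
            oy = hy + ay * eps
            oz = hz + az * eps
        val = np.pi * lrad / e_horiz
        acc += val
        acc2 += val * val
    mean = acc / n_paths
    var = acc2 / n_paths - mean * mean
    if var < 0.0:
        var = 0.0
    denom = n_paths - 1 if n_paths > 1 else 1
    return mean, np.sqrt(var / denom)


@njit(cache=True)
def openness_kernel(
    nodes_min, nodes_max, node_a, node_b, node_count, v0, e1, e2, n,
    offsets, vx, vy, vz, n_rays, seed,
):
    """Fraction of uniform upper-hemisphere rays that escape to the sky."""
    np.random.seed(seed)
    free = 0
    stack = np.empty(128, dtype=np.int64)
    entry = np.empty(offsets.shape[0])
    order = np.empty(offsets.shape[0], dtype=np.int64)
    for _ in range(n_rays):
        cz = np.random.random()  # cos(theta) ~ U(0,1): uniform solid angle
        phi = 2.0 * np.pi * np.random.random()
        st = np.sqrt(1.0 - cz * cz)
        dx = st * np.cos(phi)
        dy = st * np.sin(phi)
        dz = cz
        if not _occluded_ws(
            vx, vy, vz, dx, dy, dz, 1e-7, 1e30, offsets,
            nodes_min, nodes_max, node_a, node_b, node_count,
            v0, e1, e2, n, stack, entry, order,
        ):
            free += 1
    frac = free / n_rays
    se = np.sqrt(frac * (1.0 - frac) / n_rays)
    return frac, se
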