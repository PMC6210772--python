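"""Ball-pivoting surface reconstruction.

A compact implementation of the classic ball-pivoting algorithm: a ball of
fixed radius pivots around front edges of a growing triangulation, adding
the first point it touches.  Every emitted triangle admits a circumscribing
ball of the given radius that touches its three vertices and contains no
other sample point (up to a small numerical slack).

Intended for trunk-scale point sets (10^3-10^4 points); candidate balls
are evaluated vectorized per pivot with k-d-tree emptiness queries.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["ball_pivot", "boundary_edge_fraction"]

_EPS = 1e-9


def _ball_centers_many(pa, pb, pc, radius):
    """Both radius-ball centers through (pa, pb, pc[i]) for many third points.

    Returns (c_plus (m,3), c_minus (m,3), valid (m,)).
    """
    pc = np.atleast_2d(pc)
    ab = pb - pa
    ac = pc - pa
    n = np.cross(np.broadcast_to(ab, ac.shape), ac)
    n2 = np.einsum("ij,ij->i", n, n)
    valid = n2 > 1e-18
    n2s = np.where(valid, n2, 1.0)
    d = 2.0 * n2s
    ab2 = float(ab @ ab)
    ac2 = np.einsum("ij,ij->i", ac, ac)
    u = (np.cross(n, np.broadcast_to(ab, n.shape)) * ac2[:, None]
         + np.cross(ac, n) * ab2) / d[:, None]
    r2 = radius * radius - np.einsum("ij,ij->i", u, u)
    valid &= r2 > 0.0
    h = np.sqrt(np.where(valid, r2, 0.0))
    nh = n / np.sqrt(n2s)[:, None]
    circum = pa + u
    return circum + h[:, None] * nh, circum - h[:, None] * nh, valid


def _empty_mask(tree, centers, radius, ignore_sets):
    """For each candidate ball center: does it contain no point besides the
    (up to three) touching ones?"""
    if len(centers) == 0:
        return np.zeros(0, dtype=bool)
    k = min(5, tree.n)
    dist, idx = tree.query(centers, k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    thresh = radius * (1.0 - 1e-7)
    out = np.ones(len(centers), dtype=bool)
    for r in range(len(centers)):
        ign = ignore_sets[r]
        for c in range(k):
            if dist[r, c] >= thresh:
                break
            if idx[r, c] not in ign:
                out[r] = False
                break
    return out


class _Front:
    """Advancing front: directed edges with their opposite vertex and ball.

    Also tracks which vertices currently sit on the front, so pivots can be
    restricted to unused or on-front vertices (interior vertices are done).
    """

    def __init__(self):
        self.edges: dict[tuple[int, int], tuple[int, np.ndarray]] = {}
        self.vertex_count: dict[int, int] = {}

    def _vref(self, v, d):
        c = self.vertex_count.get(v, 0) + d
        if c <= 0:
            self.vertex_count.pop(v, None)
        else:
            self.vertex_count[v] = c

    def add(self, a, b, opp, center):
        if (b, a) in self.edges:
            del self.edges[(b, a)]  # glue: interior edge
            self._vref(a, -1)
            self._vref(b, -1)
        else:
            self.edges[(a, b)] = (opp, center)
            self._vref(a, 1)
            self._vref(b, 1)

    def pop(self):
        key = next(iter(self.edges))
        val = self.edges.pop(key)
        self._vref(key[0], -1)
        self._vref(key[1], -1)
        return key, val

    def on_front(self, v) -> bool:
        return v in self.vertex_count

    def __len__(self):
        return len(self.edges)


def _find_seed(tree, pts, radius, used, order, start_at):
    # seed triangles use only virgin points, so restarting the front never
    # drapes a second sheet over an already-reconstructed region
    for oi in range(start_at, len(order)):
        i = order[oi]
        if used[i]:
            continue
        nbr = tree.query_ball_point(pts[i], 2.0 * radius)
        nbr = np.array([j for j in nbr if j != i and not used[j]])
        if len(nbr) < 2:
            continue
        d2 = ((pts[nbr] - pts[i]) ** 2).sum(axis=1)
        nbr = nbr[np.argsort(d2)][:24]
        jj, kk = np.triu_indices(len(nbr), k=1)
        pairs_j = nbr[jj]
        pairs_k = nbr[kk]
        # loop over unique second vertices (few) with vectorized thirds
        for j in np.unique(pairs_j):
            thirds = pairs_k[pairs_j == j]
            cp, cm, valid = _ball_centers_many(pts[i], pts[j], pts[thirds], radius)
            for centers in (cp, cm):
                cand = np.flatnonzero(valid)
                if len(cand) == 0:
                    continue
                ign = [{i, j, int(thirds[c])} for c in cand]
                empty = _empty_mask(tree, centers[cand], radius, ign)
                hit = np.flatnonzero(empty)
                if len(hit):
                    c = cand[hit[0]]
                    return (i, int(j), int(thirds[c])), centers[c], oi
    return None


def _edge_free(edge_use, u, v):
    return edge_use.get((u, v) if u < v else (v, u), 0) < 2


def _pivot(tree, pts, a, b, opp, center, radius, used, front, edge_use):
    """Pivot the ball around edge (a, b); return (new point, new center).

    Candidates are limited to virgin or on-front vertices whose two new
    edges are not yet interior, keeping the output surface 2-manifold-ish.
    """
    pa, pb = pts[a], pts[b]
    mid = 0.5 * (pa + pb)
    axis = pb - pa
    al = np.linalg.norm(axis)
    if al < _EPS:
        return None
    axis = axis / al
    rv = center - mid
    rv = rv - (rv @ axis) * axis
    rvl = np.linalg.norm(rv)
    if rvl < _EPS:
        return None
    rhat = rv / rvl
    that = np.cross(axis, rhat)
    cands = np.array(tree.query_ball_point(mid, 2.0 * radius))
    cands = cands[(cands != a) & (cands != b) & (cands != opp)]
    cands = np.array(
        [c for c in cands
         if (not used[c] or front.on_front(c))
         and _edge_free(edge_use, a, c) and _edge_free(edge_use, c, b)],
        dtype=np.int64,
    )
    if len(cands) == 0:
        return None
    cp, cm, valid = _ball_centers_many(pa, pb, pts[cands], radius)
    centers = np.concatenate([cp, cm])
    cand2 = np.concatenate([cands, cands])
    valid2 = np.concatenate([valid, valid])
    v = centers - mid
    v = v - (v @ axis)[:, None] * axis
    vl = np.linalg.norm(v, axis=1)
    ok = valid2 & (vl > _EPS)
    if not ok.any():
        return None
    ang = np.arctan2(v @ that, v @ rhat)
    ang = np.where(ang <= 1e-9, ang + 2.0 * np.pi, ang)  # rotation in (0, 2pi]
    ang[~ok] = np.inf
    sel = np.argsort(ang)
    sel = sel[np.isfinite(ang[sel])]
    ign = [{a, b, int(cand2[s])} for s in sel]
    empty = _empty_mask(tree, centers[sel], radius, ign)
    hit = np.flatnonzero(empty)
    if len(hit) == 0:
        return None
    s = sel[hit[0]]
    return int(cand2[s]), centers[s]


def ball_pivot(points: np.ndarray, radius: float, max_triangles: int | None = None) -> np.ndarray:
    """Reconstruct a triangle surface; returns faces as an (m, 3) int array.

    Raises ``ValueError`` for fewer than 3 points or a collinear set.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("ball_pivot needs at least 3 points of dimension 3")
    span = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(span, tol=1e-10) < 2:
        raise ValueError("points are collinear; no surface exists")
    if len(pts) == 3:
        return np.array([[0, 1, 2]], dtype=np.int64)
    tree = cKDTree(pts)
    used = np.zeros(len(pts), dtype=bool)
    faces: list[tuple[int, int, int]] = []
    seen = set()
    edge_use: dict[tuple[int, int], int] = {}

    def add_face(u, v, w):
        faces.append((u, v, w))
        for p, q in ((u, v), (v, w), (w, u)):
            key = (p, q) if p < q else (q, p)
            edge_use[key] = edge_use.get(key, 0) + 1

    cap = max_triangles if max_triangles is not None else 40 * len(pts)
    order = np.argsort(pts[:, 2], kind="stable")
    seed_cursor = 0
    while len(faces) < cap:
        seed = _find_seed(tree, pts, radius, used, order, seed_cursor)
        if seed is None:
            break
        (i, j, k), center, seed_cursor = seed
        key = tuple(sorted((i, j, k)))
        if key in seen:
            used[i] = True
            continue
        seen.add(key)
        add_face(i, j, k)
        used[[i, j, k]] = True
        front = _Front()
        front.add(i, j, k, center)
        front.add(j, k, i, center)
        front.add(k, i, j, center)
        while len(front) and len(faces) < cap:
            (a, b), (opp, cen) = front.pop()
            if not _edge_free(edge_use, a, b):
                continue
            hit = _pivot(tree, pts, a, b, opp, cen, radius, used, front, edge_use)
            if hit is None:
                continue
            x, cx = hit
            fkey = tuple(sorted((a, x, b)))
            if fkey in seen:
                continue
            seen.add(fkey)
            add_face(a, x, b)
            used[x] = True
            front.add(a, x, b, cx)
            front.add(x, b, a, cx)
    return np.array(faces, dtype=np.int64) if faces else np.empty((0, 3), dtype=np.int64)


def boundary_edge_fraction(faces: np.ndarray) -> float:
    """Fraction of mesh edges used by exactly one triangle."""
    if len(faces) == 0:
        return 1.0
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return float(np.mean(counts == 1))
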