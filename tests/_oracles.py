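"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written by the most direct route available —
exhaustive enumeration, naive per-edge summation, textbook variance
components — and stays independent of the code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# --------------------------------------------------------------------------
# tree traversal / morphometry
# --------------------------------------------------------------------------

def segment_oracle(cell):
    """Recursive traversal: returns a set of (node-id tuple, order, terminal)."""
    children = {}
    parent_of = {}
    for nid, par in zip(cell.ids, cell.parents):
        nid, par = int(nid), int(par)
        parent_of[nid] = par
        children.setdefault(nid, [])
        if par != -1:
            children.setdefault(par, []).append(nid)
    root = next(n for n, p in parent_of.items() if p == -1)
    branch = {n for n, ch in children.items() if n != root and len(ch) >= 2}

    segments = set()

    def walk(start, child, order):
        path = [start, child]
        while child not in branch and children[child]:
            child = children[child][0]
            path.append(child)
        terminal = not children[child]
        segments.add((tuple(path), order, terminal))
        if not terminal:
            for c in children[child]:
                walk(child, c, order + 1)

    for c in children[root]:
        walk(root, c, 1)
    return segments


def total_length_oracle(cell):
    pos = {int(i): cell.xyz[k] for k, i in enumerate(cell.ids)}
    total = 0.0
    for nid, par in zip(cell.ids, cell.parents):
        if int(par) != -1:
            total += math.dist(pos[int(nid)], pos[int(par)])
    return total


def frustum_oracle(cell):
    pos = {int(i): (cell.xyz[k], cell.radius[k])
           for k, i in enumerate(cell.ids)}
    area = vol = 0.0
    for nid, par in zip(cell.ids, cell.parents):
        if int(par) == -1:
            continue
        (p1, r1), (p2, r2) = pos[int(par)], pos[int(nid)]
        h = math.dist(p1, p2)
        area += math.pi * (r1 + r2) * math.hypot(h, r1 - r2)
        vol += math.pi * h * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0
    return area, vol


def planar_angle_oracle(cell):
    children = {}
    for nid, par in zip(cell.ids, cell.parents):
        children.setdefault(int(par), []).append(int(nid))
    pos = {int(i): cell.xyz[k] for k, i in enumerate(cell.ids)}
    root = children[-1][0]
    vals = []
    for node, ch in children.items():
        if node in (-1, root) or len(ch) < 2:
            continue
        dirs = []
        for c in ch:
            v = pos[c] - pos[node]
            n = np.linalg.norm(v)
            if n > 0:
                dirs.append(v / n)
        angs = [math.degrees(math.acos(max(-1.0, min(1.0, float(np.dot(a, b))))))
                for a, b in itertools.combinations(dirs, 2)]
        if angs:
            vals.append(float(np.mean(angs)))
    return float(np.mean(vals)) if vals else float("nan")


def vertex_oracle(cell):
    segs = segment_oracle(cell)
    by_end = {}
    for path, order, term in segs:
        by_end.setdefault(path[0], []).append(term)
    # path[0] is the segment's origin; origins with >= 2 daughters and that
    # are not the root are branch points
    children_of_root = {p: None for p, _, _ in
                        ((path, o, t) for path, o, t in segs if o == 1)}
    root = next(iter(children_of_root))[0]
    va = vb = vc = 0
    for origin, terms in by_end.items():
        if origin == root or len(terms) < 2:
            continue
        t = sum(terms)
        if t >= 2:
            va += 1
        elif t == 1:
            vb += 1
        else:
            vc += 1
    return va, vb, vc


# --------------------------------------------------------------------------
# brute-force convex hulls
# --------------------------------------------------------------------------

def brute_hull_2d(points, tol=1e-9):
    """Perimeter and area from exhaustive candidate-edge enumeration."""
    pts = np.asarray(points, float)
    n = len(pts)
    edges = []
    for i, j in itertools.combinations(range(n), 2):
        e = pts[j] - pts[i]
        normal = np.array([-e[1], e[0]])
        s = (pts - pts[i]) @ normal
        if (s >= -tol).all() or (s <= tol).all():
            edges.append((i, j))
    verts = sorted({k for e in edges for k in e})
    c = pts[verts].mean(axis=0)
    # order hull vertices by angle around the centroid
    verts.sort(key=lambda k: math.atan2(pts[k][1] - c[1], pts[k][0] - c[0]))
    per = 0.0
    area = 0.0
    for a, b in zip(verts, verts[1:] + verts[:1]):
        per += math.dist(pts[a], pts[b])
        area += (pts[a][0] * pts[b][1] - pts[b][0] * pts[a][1]) / 2.0
    return per, abs(area), set(verts)


def brute_hull_3d(points, tol=1e-9):
    """Surface area and volume from exhaustive candidate-facet enumeration."""
    pts = np.asarray(points, float)
    n = len(pts)
    centroid = pts.mean(axis=0)
    tris = np.array(list(itertools.combinations(range(n), 3)))
    a, b, c = pts[tris[:, 0]], pts[tris[:, 1]], pts[tris[:, 2]]
    normals = np.cross(b - a, c - a)
    norms = np.linalg.norm(normals, axis=1)
    ok = norms > tol
    offs = np.einsum("ij,ij->i", normals, a)
    side = pts @ normals.T - offs          # (n, T)
    scale = np.maximum(norms, 1.0)
    is_facet = ((side >= -tol * scale).all(axis=0)
                | (side <= tol * scale).all(axis=0)) & ok
    area = vol = 0.0
    verts = set()
    for t in np.flatnonzero(is_facet):
        i, j, k = tris[t]
        verts.update((int(i), int(j), int(k)))
        tri_area = norms[t] / 2.0
        area += tri_area
        vol += abs(np.dot(pts[i] - centroid,
                          np.cross(pts[j] - centroid, pts[k] - centroid))) / 6.0
    return area, vol, verts


# --------------------------------------------------------------------------
# fractal dimension (set-of-tuples box counting)
# --------------------------------------------------------------------------

def kdim_oracle(cell, n_scales=6):
    pos = {int(i): cell.xyz[k] for k, i in enumerate(cell.ids)}
    probe = _align(np.asarray(cell.xyz, float))
    extent = float(np.ptp(probe, axis=0).max())
    if extent <= 0:
        return 0.0
    scales = [extent / 2.0 / 2.0 ** i for i in range(n_scales)]
    spacing = min(scales) / 4.0
    pts = [cell.xyz]
    for nid, par in zip(cell.ids, cell.parents):
        if int(par) == -1:
            continue
        a, b = pos[int(par)], pos[int(nid)]
        L = math.dist(a, b)
        m = int(math.ceil(L / spacing))
        for i in range(1, m):
            pts.append([a + (i / m) * (b - a)])
    pts = _align(np.vstack(pts))
    lo = pts.min(axis=0)
    counts = []
    for s in scales:
        boxes = {tuple(v) for v in np.floor((pts - lo) / s).astype(int)}
        counts.append(len(boxes))
    slope = np.polyfit(np.log(1.0 / np.asarray(scales)), np.log(counts), 1)[0]
    return float(min(max(slope, 0.0), 3.0))


def _align(points):
    p = points - points.mean(axis=0)
    _, vecs = np.linalg.eigh(np.cov(p.T))
    q = p @ vecs
    for j in range(q.shape[1]):
        if np.sum(q[:, j] ** 3) < 0:
            q[:, j] = -q[:, j]
    return q


# --------------------------------------------------------------------------
# naive Ward agglomeration (O(n^3))
# --------------------------------------------------------------------------

def naive_ward(X):
    """Centroid-based Ward agglomeration; returns merge heights and the
    partition (as frozensets of row indices) at each cluster count."""
    clusters = {i: ([i], X[i].astype(float), 1) for i in range(len(X))}
    heights = []
    partitions = {len(clusters): {frozenset(v[0]) for v in clusters.values()}}
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            mi, ci, ni = clusters[i]
            mj, cj, nj = clusters[j]
            h = math.sqrt(2.0 * ni * nj / (ni + nj)) * np.linalg.norm(ci - cj)
            if best is None or h < best[0]:
                best = (h, i, j)
        h, i, j = best
        mi, ci, ni = clusters.pop(i)
        mj, cj, nj = clusters.pop(j)
        clusters[i] = (mi + mj, (ni * ci + nj * cj) / (ni + nj), ni + nj)
        heights.append(h)
        partitions[len(clusters)] = {frozenset(v[0]) for v in clusters.values()}
    return heights, partitions


# --------------------------------------------------------------------------
# Weir-Cockerham theta via nested ANOVA on allele indicators
# --------------------------------------------------------------------------

def wc_theta_anova(pops):
    """theta from variance components of a pop / individual / copy nested
    ANOVA on per-allele indicator variables; ``pops`` is a list of (n_i, 2)
    genotype arrays."""
    alleles = np.unique(np.concatenate([p.ravel() for p in pops]))
    r = len(pops)
    n_i = np.array([len(p) for p in pops], float)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    num = den = 0.0
    for al in alleles:
        gm = sum(int((p == al).sum()) for p in pops) / (2 * n_i.sum())
        SSA = SSB = SSW = 0.0
        for p in pops:
            y = (p == al).astype(float)
            ind_means = y.mean(axis=1)
            pm = y.mean()
            SSA += 2 * len(p) * (pm - gm) ** 2
            SSB += 2 * ((ind_means - pm) ** 2).sum()
            SSW += ((y - ind_means[:, None]) ** 2).sum()
        MSA = SSA / (r - 1)
        MSB = SSB / (n_i.sum() - r)
        MSW = SSW / n_i.sum()
        s2_c = MSW
        s2_b = (MSB - MSW) / 2.0
        s2_a = (MSA - MSB) / (2.0 * nc)
        num += s2_a
        den += s2_a + s2_b + s2_c
    return num / den


def classical_anova_f(values, groups):
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    grand = values.mean()
    levels = np.unique(groups)
    ssb = sum(len(values[groups == g]) * (values[groups == g].mean() - grand) ** 2
              for g in levels)
    ssw = sum(((values[groups == g] - values[groups == g].mean()) ** 2).sum()
              for g in levels)
    return (ssb / (len(levels) - 1)) / (ssw / (len(values) - len(levels)))
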