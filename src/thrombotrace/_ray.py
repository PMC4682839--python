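"""Vectorized ray–triangle intersection against triangle meshes.

A Möller–Trumbore intersector with a KD-tree broad phase over triangle
centroids.  Kept dependency-light on purpose: it backs the growth mapping
(normal-ray surface-to-surface distances), seed validity checks and the
obstacle voxelization for the flow solver.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

_EPS = 1e-12


class MeshIntersector:
    """First-hit ray queries and point containment for a triangle mesh."""

    def __init__(self, mesh):
        self.triangles = np.asarray(mesh.triangles, dtype=float)  # (F, 3, 3)
        self.centroids = self.triangles.mean(axis=1)
        # circumscribing radius of each triangle about its centroid
        self.radii = np.linalg.norm(
            self.triangles - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self.rmax = float(self.radii.max()) if len(self.radii) else 0.0
        self.tree = cKDTree(self.centroids)
        self.tree_xy = cKDTree(self.centroids[:, :2])
        self.rmax_xy = (
            float(
                np.linalg.norm(
                    self.triangles[:, :, :2] - self.centroids[:, None, :2], axis=2
                ).max()
            )
            if len(self.radii)
            else 0.0
        )

    # -- core ------------------------------------------------------------
    def _moller_trumbore(self, pairs_ray, pairs_tri, origins, directions):
        """Intersection parameter t for (ray, triangle) candidate pairs.

        Returns (ray_idx, t) for actual hits with t >= 0.
        """
        tri = self.triangles[pairs_tri]
        o = origins[pairs_ray]
        d = directions[pairs_ray]
        e1 = tri[:, 1] - tri[:, 0]
        e2 = tri[:, 2] - tri[:, 0]
        p = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, p)
        ok = np.abs(det) > _EPS
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        s = o - tri[:, 0]
        u = np.einsum("ij,ij->i", s, p) * inv
        q = np.cross(s, e1)
        v = np.einsum("ij,ij->i", d, q) * inv
        t = np.einsum("ij,ij->i", e2, q) * inv
        hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1.0 + 1e-9) & (t >= 0.0)
        return pairs_ray[hit], t[hit]

    def first_hit(
        self, origins, directions, max_dist: float, chunk: int = 512
    ) -> np.ndarray:
        """Distance to the nearest hit within ``max_dist`` per ray (NaN if none).

        Rays are processed in chunks to bound the candidate-pair memory on
        dense meshes.
        """
        origins = np.atleast_2d(np.asarray(origins, dtype=float))
        directions = np.atleast_2d(np.asarray(directions, dtype=float))
        n = len(origins)
        directions = directions / np.linalg.norm(directions, axis=1, keepdims=True)
        out = np.full(n, np.nan)
        if len(self.triangles) == 0:
            return out
        for start in range(0, n, chunk):
            sl = slice(start, min(start + chunk, n))
            out[sl] = self._first_hit_chunk(origins[sl], directions[sl], max_dist)
        return out

    def _first_hit_chunk(self, origins, directions, max_dist):
        n = len(origins)
        out = np.full(n, np.nan)
        # broad phase: cover each ray segment with balls along its length
        k = 4
        step = max_dist / k
        rball = step / 2.0 + self.rmax * 1.01 + 1e-9
        pr_list, pt_list = [], []
        for i in range(k):
            centers = origins + directions * (step * (i + 0.5))
            groups = self.tree.query_ball_point(centers, rball)
            for ri, g in enumerate(groups):
                if g:
                    pr_list.append(np.full(len(g), ri))
                    pt_list.append(np.asarray(g))
        if not pr_list:
            return out
        pr = np.concatenate(pr_list)
        pt = np.concatenate(pt_list)
        # duplicate (ray, tri) pairs from overlapping balls are harmless:
        # the first-hit reduction below keeps the minimum t per ray
        ray_idx, t = self._moller_trumbore(pr, pt, origins, directions)
        sel = t <= max_dist
        ray_idx, t = ray_idx[sel], t[sel]
        if len(ray_idx):
            order = np.lexsort((t, ray_idx))
            ray_idx, t = ray_idx[order], t[order]
            first = np.ones(len(ray_idx), dtype=bool)
            first[1:] = ray_idx[1:] != ray_idx[:-1]
            out[ray_idx[first]] = t[first]
        return out

    def contains(self, points, chunk: int = 4096) -> np.ndarray:
        """Point-in-mesh test by +z ray crossing parity (watertight mesh)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        inside = np.zeros(n, dtype=bool)
        if len(self.triangles) == 0:
            return inside
        if n > chunk:
            for start in range(0, n, chunk):
                sl = slice(start, min(start + chunk, n))
                inside[sl] = self.contains(points[sl], chunk=chunk)
            return inside
        # slightly tilted ray avoids exact vertex/edge crossings (parity killers)
        tilt = np.array([1.3e-4, 0.7e-4, 1.0])
        tilt = tilt / np.linalg.norm(tilt)
        zspan = float(self.triangles[:, :, 2].max() - self.triangles[:, :, 2].min())
        margin = self.rmax_xy * 1.01 + 2e-4 * zspan + 1e-9
        groups = self.tree_xy.query_ball_point(points[:, :2], margin)
        pr_list, pt_list = [], []
        for ri, g in enumerate(groups):
            if g:
                pr_list.append(np.full(len(g), ri))
                pt_list.append(np.asarray(g))
        if not pr_list:
            return inside
        pr = np.concatenate(pr_list)
        pt = np.concatenate(pt_list)
        dirs = np.tile(tilt[None, :], (n, 1))
        ray_idx, t = self._moller_trumbore(pr, pt, points, dirs)
        # parity of strictly-positive crossings, deduplicating coincident hits
        pos = t > 1e-9
        ray_idx, t = ray_idx[pos], t[pos]
        if len(ray_idx):
            order = np.lexsort((t, ray_idx))
            ray_idx, t = ray_idx[order], t[order]
            keep = np.ones(len(t), dtype=bool)
            same_ray = ray_idx[1:] == ray_idx[:-1]
            close_t = np.abs(t[1:] - t[:-1]) <= 1e-9 * np.maximum(1.0, t[1:])
            keep[1:] = ~(same_ray & close_t)
            counts = np.bincount(ray_idx[keep], minlength=n)
            inside = counts % 2 == 1
        return inside
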