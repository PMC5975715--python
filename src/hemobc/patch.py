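"""Planar inlet patches: triangulated cross-sections with a local frame.

An inlet patch is a planar, triangulated vessel cross-section expressed
in a local in-plane coordinate frame whose origin is the area centroid.
The axial unit normal points in the flow-positive direction; the shear
axis e1 is the in-plane direction along which skewed (linear/cubic
shear) profiles vary — anatomically the inner-to-outer arch direction.

Profile generators need three geometric services from the patch:

* nodal quadrature weights (one third of each incident facet's area),
  used for discrete flux integrals,
* the effective radius R of the area-equivalent circle (D = 2R),
* the normalized boundary distance rho(x, y) = r / R_boundary(theta),
  which maps any star-shaped cross-section onto the unit disk so that
  analytic profile shapes (parabolic, Womersley) can be evaluated on
  non-circular inlets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "InletPatch",
    "read_patch",
    "read_patch_csv",
    "read_patch_off",
    "read_patch_vtk",
    "write_patch_csv",
]

_CENTROID_TOL = 1e-6


def _triangle_areas(a, b, c) -> np.ndarray:
    """Unsigned areas of 2-D triangles given their vertex arrays."""
    u, v = b - a, c - a
    return 0.5 * np.abs(u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0])


@dataclass(frozen=True)
class InletPatch:
    """Triangulated planar inlet cross-section in its local frame.

    Parameters
    ----------
    node_coords
        (N, 2) in-plane node coordinates in meters, centroid at origin.
    facets
        (M, 3) integer node indices of the triangles.
    unit_normal
        Axial unit vector (3,) in the parent frame; defaults to +z.
    shear_axis
        In-plane unit vector (3,) along which shear profiles vary
        (the local +x direction by default).
    """

    node_coords: np.ndarray
    facets: np.ndarray
    unit_normal: np.ndarray = None
    shear_axis: np.ndarray = None

    def __post_init__(self):
        xy = np.asarray(self.node_coords, dtype=float)
        tri = np.asarray(self.facets, dtype=int)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError("node_coords must be (N, 2)")
        if tri.ndim != 2 or tri.shape[1] != 3:
            raise ValueError("facets must be (M, 3) triangles")
        n_hat = np.array([0.0, 0.0, 1.0]) if self.unit_normal is None else np.asarray(
            self.unit_normal, dtype=float
        )
        e1 = np.array([1.0, 0.0, 0.0]) if self.shear_axis is None else np.asarray(
            self.shear_axis, dtype=float
        )
        n_hat = n_hat / np.linalg.norm(n_hat)
        e1 = e1 / np.linalg.norm(e1)
        if abs(float(n_hat @ e1)) > 1e-9:
            raise ValueError("shear_axis must be perpendicular to unit_normal")
        object.__setattr__(self, "node_coords", xy)
        object.__setattr__(self, "facets", tri)
        object.__setattr__(self, "unit_normal", n_hat)
        object.__setattr__(self, "shear_axis", e1)

        a, b, c = xy[tri[:, 0]], xy[tri[:, 1]], xy[tri[:, 2]]
        areas = _triangle_areas(a, b, c)
        if not np.all(areas > 0):
            raise ValueError("every facet must have positive area")
        object.__setattr__(self, "facet_areas", areas)

        nodal = np.zeros(xy.shape[0])
        np.add.at(nodal, tri.ravel(), np.repeat(areas / 3.0, 3))
        object.__setattr__(self, "nodal_areas", nodal)

        total = float(areas.sum())
        if total <= 0:
            raise ValueError("patch has zero area")
        object.__setattr__(self, "area", total)
        R = float(np.sqrt(total / np.pi))
        object.__setattr__(self, "effective_radius", R)

        centroid = (nodal[:, None] * xy).sum(axis=0) / total
        if np.linalg.norm(centroid) > _CENTROID_TOL * R:
            raise ValueError(
                f"area-weighted node centroid {centroid} is not at the origin "
                f"(tolerance {_CENTROID_TOL:g}*R); recenter the patch"
            )

        object.__setattr__(self, "_boundary_cache", None)

    # -- derived geometry -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    def _boundary_polygon(self):
        """Ordered boundary vertex angles/radii (cached).

        Boundary edges are those incident to exactly one facet.  The
        patch is assumed star-shaped about the centroid, which holds for
        any convex cross-section (circles, ellipses, realistic inlets).
        """
        cached = self._boundary_cache
        if cached is not None:
            return cached
        tri = self.facets
        edges = np.vstack(
            [tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]
        )
        edges_sorted = np.sort(edges, axis=1)
        _, idx, counts = np.unique(
            edges_sorted, axis=0, return_index=True, return_counts=True
        )
        boundary_nodes = np.unique(edges_sorted[idx[counts == 1]])
        pts = self.node_coords[boundary_nodes]
        theta = np.arctan2(pts[:, 1], pts[:, 0])
        order = np.argsort(theta)
        theta = theta[order]
        radius = np.hypot(pts[order, 0], pts[order, 1])
        # wrap for periodic interpolation in angle
        theta = np.concatenate([[theta[-1] - 2 * np.pi], theta, [theta[0] + 2 * np.pi]])
        radius = np.concatenate([[radius[-1]], radius, [radius[0]]])
        object.__setattr__(self, "_boundary_cache", (theta, radius))
        return theta, radius

    def boundary_radius(self, theta):
        """Boundary polygon radius R(theta) via ray-segment intersection."""
        th_b, r_b = self._boundary_polygon()
        theta = np.asarray(theta, dtype=float)
        i = np.searchsorted(th_b, theta, side="right")
        i = np.clip(i, 1, th_b.size - 1)
        th0, th1 = th_b[i - 1], th_b[i]
        r0, r1 = r_b[i - 1], r_b[i]
        # segment endpoints in Cartesian form
        p0 = np.stack([r0 * np.cos(th0), r0 * np.sin(th0)], axis=-1)
        p1 = np.stack([r1 * np.cos(th1), r1 * np.sin(th1)], axis=-1)
        d = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
        seg = p1 - p0
        denom = d[..., 0] * (-seg[..., 1]) - d[..., 1] * (-seg[..., 0])
        cross = p0[..., 0] * (-seg[..., 1]) - p0[..., 1] * (-seg[..., 0])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(np.abs(denom) > 0, cross / denom, 0.5 * (r0 + r1))
        return np.abs(t)

    def boundary_rho(self, coords=None):
        """Normalized boundary distance rho in [0, 1] for the given points.

        ``rho = r / R_boundary(theta)``: 0 at the centroid, 1 on the
        boundary.  Defaults to the patch's own nodes.
        """
        xy = self.node_coords if coords is None else np.asarray(coords, dtype=float)
        r = np.hypot(xy[..., 0], xy[..., 1])
        theta = np.arctan2(xy[..., 1], xy[..., 0])
        rb = self.boundary_radius(theta)
        return np.clip(r / rb, 0.0, 1.0)

    def shear_coordinate(self, coords=None):
        """In-plane coordinate s along the shear axis (local x), meters."""
        xy = self.node_coords if coords is None else np.asarray(coords, dtype=float)
        return xy[..., 0]

    def contains(self, point) -> bool:
        """True if ``point`` (x, y) lies strictly inside the boundary."""
        x, y = float(point[0]), float(point[1])
        r = np.hypot(x, y)
        return r < float(self.boundary_radius(np.arctan2(y, x)))


# -- construction from 3-D surfaces ---------------------------------------


def _project_to_plane(points3d, facets, normal_hint=None, shear_hint=None):
    """Fit a plane through 3-D nodes and express them in a local 2-D frame."""
    pts = np.asarray(points3d, dtype=float)
    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center)
    n_hat = vt[2]
    if normal_hint is not None and float(np.dot(n_hat, normal_hint)) < 0:
        n_hat = -n_hat
    e1 = vt[0] if shear_hint is None else np.asarray(shear_hint, dtype=float)
    e1 = e1 - n_hat * float(e1 @ n_hat)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n_hat, e1)
    xy = np.stack([(pts - center) @ e1, (pts - center) @ e2], axis=1)
    patch = _recenter_and_build(xy, facets, n_hat, e1)
    return patch


def _recenter_and_build(xy, facets, n_hat=None, e1=None) -> InletPatch:
    """Shift node coordinates so the area-weighted centroid is the origin."""
    xy = np.asarray(xy, dtype=float)
    tri = np.asarray(facets, dtype=int)
    a, b, c = xy[tri[:, 0]], xy[tri[:, 1]], xy[tri[:, 2]]
    areas = _triangle_areas(a, b, c)
    nodal = np.zeros(xy.shape[0])
    np.add.at(nodal, tri.ravel(), np.repeat(areas / 3.0, 3))
    centroid = (nodal[:, None] * xy).sum(axis=0) / areas.sum()
    return InletPatch(xy - centroid, tri, unit_normal=n_hat, shear_axis=e1)


def read_patch_csv(nodes_path, facets_path) -> InletPatch:
    """Read a node/facet CSV pair.

    ``nodes_path`` has columns ``x,y`` (meters, planar) or ``x,y,z``;
    ``facets_path`` has columns ``n0,n1,n2`` (0-based node indices).
    """
    nodes = pd.read_csv(nodes_path).to_numpy(dtype=float)
    tri = pd.read_csv(facets_path).to_numpy(dtype=int)[:, :3]
    if nodes.shape[1] == 2:
        return _recenter_and_build(nodes, tri)
    return _project_to_plane(nodes[:, :3], tri)


def write_patch_csv(patch: InletPatch, nodes_path, facets_path) -> None:
    pd.DataFrame(patch.node_coords, columns=["x", "y"]).to_csv(nodes_path, index=False)
    pd.DataFrame(patch.facets, columns=["n0", "n1", "n2"]).to_csv(
        facets_path, index=False
    )


def read_patch_off(path) -> InletPatch:
    """Read an ASCII OFF triangulated surface as an inlet patch."""
    with open(path) as fh:
        tokens = []
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    if not tokens or tokens[0] != "OFF":
        raise ValueError(f"{path}: not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4
    verts = np.array(tokens[pos : pos + 3 * nv], dtype=float).reshape(nv, 3)
    pos += 3 * nv
    faces = []
    for _ in range(nf):
        k = int(tokens[pos])
        if k != 3:
            raise ValueError(f"{path}: only triangular facets are supported")
        faces.append([int(t) for t in tokens[pos + 1 : pos + 4]])
        pos += 1 + k
    return _project_to_plane(verts, np.array(faces, dtype=int))


def read_patch_vtk(path) -> InletPatch:
    """Read a legacy ASCII VTK polydata/unstructured triangulated surface."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    it = iter(lines)
    verts = faces = None
    for line in it:
        tok = line.split()
        if not tok:
            continue
        key = tok[0].upper()
        if key == "POINTS":
            n = int(tok[1])
            vals = []
            while len(vals) < 3 * n:
                vals.extend(next(it).split())
            verts = np.array(vals[: 3 * n], dtype=float).reshape(n, 3)
        elif key in ("POLYGONS", "CELLS"):
            n, total = int(tok[1]), int(tok[2])
            vals = []
            while len(vals) < total:
                vals.extend(next(it).split())
            vals = [int(v) for v in vals[:total]]
            faces, pos = [], 0
            for _ in range(n):
                k = vals[pos]
                if k == 3:
                    faces.append(vals[pos + 1 : pos + 4])
                pos += 1 + k
    if verts is None or not faces:
        raise ValueError(f"{path}: no triangulated surface found")
    return _project_to_plane(verts, np.array(faces, dtype=int))


def read_patch(path, facets_path=None) -> InletPatch:
    """Dispatch on file extension: ``.vtk``, ``.off``, or a CSV pair."""
    p = str(path)
    if p.endswith(".vtk"):
        return read_patch_vtk(p)
    if p.endswith(".off"):
        return read_patch_off(p)
    if p.endswith(".csv"):
        if facets_path is None:
            raise ValueError("CSV patches need both a nodes and a facets file")
        return read_patch_csv(p, facets_path)
    raise ValueError(f"unrecognized patch format: {path}")
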