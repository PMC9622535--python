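"""Parametric Glenn/TCPC junction geometry and Cartesian voxelization.

A junction is a union of capped cylinders ("limbs": IVC, SVC, LPA, RPA,
SRPA, ...), each carrying an inlet or outlet role.  The solid is carried
as an implicit signed-distance function (negative inside) and voxelized
onto an isotropic Cartesian grid by a cell-center inside test
(stair-step immersed boundary).  Open limb end-caps become labeled
planar port patches of boundary faces; everything else is a no-slip
wall.  Surfaces round-trip through STL (ASCII and binary) via trimesh.

Coordinates are SI meters, right-handed; preset grids place the origin
at the junction centroid.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import FormatError, GeometryError, ResolutionError

_AXIS_NAMES = "xyz"

#: Coarsest admissible spacing as a fraction of the thinnest limb diameter.
MAX_DX_FRACTION = 1.0 / 5.0
#: Recommended spacing as a fraction of the IVC (first-inlet) diameter,
#: mirroring the lean immersed-boundary meshing practice.
RECOMMENDED_DX_FRACTION = 0.10


@dataclass(frozen=True)
class LimbSpec:
    """One cylindrical limb of the junction.

    ``anchor`` is the junction-side end of the limb axis; the open port
    cap sits at ``anchor + length * axis``.
    """

    name: str
    diameter: float
    length: float
    axis: Tuple[float, float, float]
    anchor: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    role: str = "outlet"  # "inlet" | "outlet"

    def __post_init__(self):
        if self.diameter <= 0:
            raise GeometryError(f"limb {self.name}: diameter must be > 0")
        if self.length < 2.0 * self.diameter:
            raise GeometryError(
                f"limb {self.name}: length {self.length} < 2*diameter "
                f"{2 * self.diameter}"
            )
        ax = np.asarray(self.axis, float)
        if not np.isclose(np.linalg.norm(ax), 1.0, atol=1e-8):
            raise GeometryError(f"limb {self.name}: axis must be a unit vector")
        if self.role not in ("inlet", "outlet"):
            raise GeometryError(f"limb {self.name}: role must be inlet or outlet")

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    @property
    def cap_center(self) -> np.ndarray:
        return np.asarray(self.anchor, float) + self.length * np.asarray(self.axis, float)

    def point_sdf(self, pts: np.ndarray) -> np.ndarray:
        """Signed distance to the finite capped cylinder (negative inside)."""
        a = np.asarray(self.anchor, float)
        ax = np.asarray(self.axis, float)
        rel = pts - a
        t = rel @ ax
        radial = np.linalg.norm(rel - np.outer(t, ax), axis=-1)
        dr = radial - self.radius
        # axial distance outside the [0, length] slab; the anchor disc is
        # interior to the junction by construction, so exact anchor-plane
        # ties resolve inward (outer-cap ties stay solid)
        dt = np.maximum(-t - 1e-9 * self.diameter, t - self.length)
        outside = np.sqrt(np.maximum(dr, 0.0) ** 2 + np.maximum(dt, 0.0) ** 2)
        inside = np.minimum(np.maximum(dr, dt), 0.0)
        return outside + inside


@dataclass(frozen=True)
class JunctionGeometry:
    """Union-of-limbs junction with at least one inlet and two outlets."""

    limbs: Tuple[LimbSpec, ...]
    caval_offset: float = 0.0
    name: str = "custom"

    def __post_init__(self):
        roles = [l.role for l in self.limbs]
        if roles.count("inlet") < 1 or roles.count("outlet") < 2:
            raise GeometryError(
                "junction needs >= 1 inlet and >= 2 outlets, got "
                f"{roles.count('inlet')} inlet(s), {roles.count('outlet')} outlet(s)"
            )
        names = [l.name for l in self.limbs]
        if len(set(names)) != len(names):
            raise GeometryError(f"duplicate limb names in {names}")
        self._check_connected()

    def _check_connected(self):
        """Each limb's anchor must lie inside the union of the others."""
        if len(self.limbs) < 2:
            return
        for limb in self.limbs:
            others = [o for o in self.limbs if o.name != limb.name]
            anchor = np.asarray(limb.anchor, float)[None, :]
            d = min(float(o.point_sdf(anchor)[0]) for o in others)
            if d > 0.45 * limb.diameter:
                raise GeometryError(
                    f"limb {limb.name} does not intersect the junction "
                    f"(anchor is {d:.3g} m outside the other limbs)"
                )

    @property
    def inlets(self) -> List[LimbSpec]:
        return [l for l in self.limbs if l.role == "inlet"]

    @property
    def outlets(self) -> List[LimbSpec]:
        return [l for l in self.limbs if l.role == "outlet"]

    def limb(self, name: str) -> LimbSpec:
        for l in self.limbs:
            if l.name == name:
                return l
        raise GeometryError(f"no limb named {name!r}")

    @property
    def reference_diameter(self) -> float:
        """IVC diameter if present, else the first inlet's."""
        for l in self.limbs:
            if l.name == "IVC":
                return l.diameter
        return self.inlets[0].diameter

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        """Signed distance of the union solid (negative inside)."""
        pts = np.atleast_2d(np.asarray(pts, float))
        d = self.limbs[0].point_sdf(pts)
        for limb in self.limbs[1:]:
            d = np.minimum(d, limb.point_sdf(pts))
        return d

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        lo = np.full(3, np.inf)
        hi = np.full(3, -np.inf)
        for l in self.limbs:
            a = np.asarray(l.anchor, float)
            b = l.cap_center
            r = l.radius
            lo = np.minimum(lo, np.minimum(a, b) - r)
            hi = np.maximum(hi, np.maximum(a, b) + r)
        return lo, hi


def build_junction(preset: Optional[str] = None,
                   limbs: Optional[Sequence[LimbSpec]] = None,
                   caval_offset: float = 0.0,
                   ivc_diameter: float = 0.015,
                   pa_diameter: float = 0.012,
                   limb_length_diameters: float = 3.0,
                   ) -> JunctionGeometry:
    """Construct a junction from a preset name or explicit limbs.

    Presets:

    ``"glenn"``
        3 ports: SVC inlet from above, LPA/RPA outlets along +/-x
        (bidirectional Glenn T-junction).
    ``"tcpc"``
        4 ports: IVC inlet from below (laterally displaced by
        ``caval_offset``), SVC inlet from above, LPA/RPA outlets
        (total cavopulmonary connection cross).
    """
    if limbs is not None:
        return JunctionGeometry(limbs=tuple(limbs), caval_offset=caval_offset,
                                name=preset or "custom")
    if preset is None:
        raise GeometryError("either a preset name or explicit limbs is required")
    d_pa = pa_diameter
    d_ivc = ivc_diameter
    lp = limb_length_diameters * d_pa
    lc = limb_length_diameters * d_ivc
    if preset == "glenn":
        svc_d = 0.8 * d_ivc
        lsvc = limb_length_diameters * svc_d
        limbs = (
            LimbSpec("SVC", svc_d, lsvc, (0.0, 1.0, 0.0), (0.0, 0.0, 0.0), "inlet"),
            LimbSpec("LPA", d_pa, lp, (1.0, 0.0, 0.0), (0.0, 0.0, 0.0), "outlet"),
            LimbSpec("RPA", d_pa, lp, (-1.0, 0.0, 0.0), (0.0, 0.0, 0.0), "outlet"),
        )
    elif preset == "tcpc":
        svc_d = 0.8 * d_ivc
        lsvc = limb_length_diameters * svc_d
        limbs = (
            LimbSpec("IVC", d_ivc, lc, (0.0, -1.0, 0.0), (caval_offset, 0.0, 0.0), "inlet"),
            LimbSpec("SVC", svc_d, lsvc, (0.0, 1.0, 0.0), (0.0, 0.0, 0.0), "inlet"),
            LimbSpec("LPA", d_pa, lp, (1.0, 0.0, 0.0), (0.0, 0.0, 0.0), "outlet"),
            LimbSpec("RPA", d_pa, lp, (-1.0, 0.0, 0.0), (0.0, 0.0, 0.0), "outlet"),
        )
    else:
        raise GeometryError(f"unknown preset {preset!r} (choose glenn or tcpc)")
    return JunctionGeometry(limbs=limbs, caval_offset=caval_offset, name=preset)


def straight_tube(diameter: float, length: float, name: str = "tube",
                  axis=(0.0, 0.0, 1.0)) -> JunctionGeometry:
    """Single straight limb pair forming one inlet -> one outlet tube.

    Modeled as two half-length colinear limbs so the 1-inlet/2-outlet
    junction invariant is waived; used for verification benchmarks.
    """
    ax = np.asarray(axis, float)
    half = 0.5 * length
    inlet = LimbSpec("IN", diameter, half, tuple(-ax), (0.0, 0.0, 0.0), "inlet")
    outlet = LimbSpec("OUT", diameter, half, tuple(ax), (0.0, 0.0, 0.0), "outlet")
    geo = object.__new__(JunctionGeometry)
    object.__setattr__(geo, "limbs", (inlet, outlet))
    object.__setattr__(geo, "caval_offset", 0.0)
    object.__setattr__(geo, "name", name)
    return geo


@dataclass
class Port:
    """Planar patch of boundary faces forming one open limb end-cap."""

    name: str
    role: str
    axis: int          # 0, 1, 2 face orientation
    sign: int          # +1 if outward normal points along +axis
    face_index: np.ndarray  # (m, 3) int indices into the axis face array
    dx: float
    center: np.ndarray
    diameter: float

    @property
    def area(self) -> float:
        """Discrete port area, (face count) * dx^2."""
        return self.face_index.shape[0] * self.dx ** 2

    @property
    def n_faces(self) -> int:
        return self.face_index.shape[0]


@dataclass
class VoxelGrid:
    """Stair-step voxelization of a junction solid.

    ``fluid_mask`` marks cells whose center lies strictly inside the
    solid (ties resolve to solid, so voxelization is deterministic).
    ``ports`` maps limb name -> :class:`Port`.
    """

    dx: float
    origin: np.ndarray          # coordinate of the (0,0,0) cell corner
    fluid_mask: np.ndarray      # (nx, ny, nz) bool
    ports: Dict[str, Port]
    geometry: Optional[JunctionGeometry] = None
    sdf_cells: Optional[np.ndarray] = None  # signed distance at cell centers

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.fluid_mask.shape

    @property
    def n_fluid(self) -> int:
        return int(self.fluid_mask.sum())

    @property
    def fluid_volume(self) -> float:
        return self.n_fluid * self.dx ** 3

    def cell_centers(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        nx, ny, nz = self.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.dx
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.dx
        zs = self.origin[2] + (np.arange(nz) + 0.5) * self.dx
        return xs, ys, zs

    def port(self, name: str) -> Port:
        try:
            return self.ports[name]
        except KeyError:
            raise GeometryError(
                f"no port named {name!r}; available: {sorted(self.ports)}"
            ) from None

    def dx_fraction(self) -> float:
        """dx as a fraction of the reference (IVC / first-inlet) diameter."""
        if self.geometry is None:
            return float("nan")
        return self.dx / self.geometry.reference_diameter

    def connected_components(self) -> int:
        _, n = ndimage.label(self.fluid_mask,
                             structure=ndimage.generate_binary_structure(3, 1))
        return int(n)


def _snap_up(value: float, origin: float, dx: float) -> float:
    """Smallest face-plane coordinate >= value."""
    k = np.ceil((value - origin) / dx - 1e-9)
    return origin + k * dx


def voxelize(geometry: JunctionGeometry, dx: float,
             origin: Optional[Sequence[float]] = None,
             pad_cells: int = 1) -> VoxelGrid:
    """Voxelize a parametric junction onto an isotropic grid.

    Limb lengths are snapped *up* to the nearest grid face plane so
    every port is an exactly planar disc of boundary faces (presets are
    axis-aligned).  Refuses spacings coarser than 1/5 of the thinnest
    limb diameter.
    """
    dmin = min(l.diameter for l in geometry.limbs)
    if dx > dmin * MAX_DX_FRACTION + 1e-12:
        raise ResolutionError(
            f"dx = {dx:.4g} m cannot resolve the thinnest limb "
            f"(diameter {dmin:.4g} m); need dx <= {dmin * MAX_DX_FRACTION:.4g} m"
        )
    lo, hi = geometry.bounds()
    if origin is None:
        # register the origin to a multiple of dx: coordinate planes of the
        # (centered) geometry then coincide with face planes, so limb axes
        # pass through cell corners and no cell center can sit exactly on
        # an axis-aligned symmetric surface
        origin = dx * np.floor(lo / dx) - pad_cells * dx
    origin = np.asarray(origin, float)

    # snap axis-aligned limb caps onto face planes (extend, never shorten)
    snapped = []
    for l in geometry.limbs:
        ax = np.asarray(l.axis, float)
        dom = int(np.argmax(np.abs(ax)))
        length = l.length
        if np.isclose(abs(ax[dom]), 1.0, atol=1e-9):
            cap = l.cap_center[dom]
            if ax[dom] > 0:
                cap_s = _snap_up(cap, origin[dom], dx)
            else:
                cap_s = origin[dom] + np.floor((cap - origin[dom]) / dx + 1e-9) * dx
            length = length + abs(cap_s - cap)
        snapped.append(LimbSpec(l.name, l.diameter, length, l.axis, l.anchor, l.role))
    geo = object.__new__(JunctionGeometry)
    object.__setattr__(geo, "limbs", tuple(snapped))
    object.__setattr__(geo, "caval_offset", geometry.caval_offset)
    object.__setattr__(geo, "name", geometry.name)

    lo2, hi2 = geo.bounds()
    n = np.ceil((hi2 + pad_cells * dx - origin) / dx + 0.5).astype(int)
    nx, ny, nz = int(n[0]), int(n[1]), int(n[2])

    xs = origin[0] + (np.arange(nx) + 0.5) * dx
    ys = origin[1] + (np.arange(ny) + 0.5) * dx
    zs = origin[2] + (np.arange(nz) + 0.5) * dx
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    d = geo.sdf(pts).reshape(nx, ny, nz)
    fluid = d < 0.0  # ties (d == 0) resolve to solid

    ports = _detect_ports(geo, fluid, origin, dx)
    grid = VoxelGrid(dx=dx, origin=origin, fluid_mask=fluid, ports=ports,
                     geometry=geo, sdf_cells=d)
    ncomp = grid.connected_components()
    if ncomp != 1:
        raise GeometryError(
            f"voxelized fluid region has {ncomp} connected components "
            "(expected exactly 1); refine dx or fix the limb layout"
        )
    for name, p in ports.items():
        if p.n_faces == 0:
            raise GeometryError(f"port {name} resolved to zero faces at dx={dx}")
    return grid


def _detect_ports(geo: JunctionGeometry, fluid: np.ndarray,
                  origin: np.ndarray, dx: float) -> Dict[str, Port]:
    nx, ny, nz = fluid.shape
    ports: Dict[str, Port] = {}
    for l in geo.limbs:
        ax = np.asarray(l.axis, float)
        dom = int(np.argmax(np.abs(ax)))
        sign = 1 if ax[dom] > 0 else -1
        cap = l.cap_center
        # face plane index along dom: faces at origin + i*dx
        fi = int(round((cap[dom] - origin[dom]) / dx))
        idx: List[Tuple[int, int, int]] = []
        other = [a for a in range(3) if a != dom]
        # fluid cell adjacent to the cap, inside the limb radius
        ci = fi - 1 if sign > 0 else fi
        if ci < 0 or ci >= fluid.shape[dom]:
            continue
        sl = [slice(None)] * 3
        sl[dom] = ci
        layer = fluid[tuple(sl)]
        ii, jj = np.nonzero(layer)
        for a, b in zip(ii, jj):
            cell = [0, 0, 0]
            cell[dom] = ci
            cell[other[0]] = a
            cell[other[1]] = b
            center = origin + (np.asarray(cell) + 0.5) * dx
            radial = center - np.asarray(l.anchor, float)
            radial = radial - (radial @ ax) * ax
            if np.linalg.norm(radial) <= l.radius:
                f = list(cell)
                f[dom] = fi
                idx.append(tuple(f))
        ports[l.name] = Port(
            name=l.name, role=l.role, axis=dom, sign=sign,
            face_index=np.asarray(idx, int).reshape(-1, 3), dx=dx,
            center=np.asarray(cap, float), diameter=l.diameter,
        )
    return ports


# ---------------------------------------------------------------------------
# STL import / export (triangulated surfaces)

class TriSolid:
    """Triangulated watertight solid usable by :func:`voxelize_mesh`."""

    def __init__(self, mesh):
        import trimesh
        if not isinstance(mesh, trimesh.Trimesh):
            raise FormatError("expected a triangulated surface mesh")
        if len(mesh.faces) == 0:
            raise FormatError("surface mesh has no triangles")
        if not mesh.is_watertight:
            raise GeometryError("surface is not watertight/manifold")
        self.mesh = mesh

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Even-odd z-ray containment test for points on a regular xy grid."""
        return _mesh_contains(self.mesh, np.atleast_2d(pts))

    def bounds(self):
        b = self.mesh.bounds
        return b[0].copy(), b[1].copy()


def _mesh_contains(mesh, pts: np.ndarray) -> np.ndarray:
    """Even-odd rule with +z rays, vectorized over (triangle, column) pairs.

    The query points must lie on a regular grid in x and y (true for
    voxelization, the only caller); vertical rays are shot through each
    distinct (x, y) column and parity of crossings below each point
    decides containment.
    """
    tri = mesh.triangles  # (M, 3, 3)
    xs_u = np.unique(np.round(pts[:, 0], 12))
    ys_u = np.unique(np.round(pts[:, 1], 12))
    hx = np.min(np.diff(xs_u)) if len(xs_u) > 1 else 1.0
    hy = np.min(np.diff(ys_u)) if len(ys_u) > 1 else 1.0
    # de-align rays from mesh edges by a sub-permille offset
    rx = xs_u + 1.37e-4 * hx
    ry = ys_u + 1.91e-4 * hy

    t1, t2, t3 = tri[:, 0], tri[:, 1], tri[:, 2]
    txmin = tri[:, :, 0].min(axis=1)
    txmax = tri[:, :, 0].max(axis=1)
    tymin = tri[:, :, 1].min(axis=1)
    tymax = tri[:, :, 1].max(axis=1)
    i0 = np.searchsorted(rx, txmin, "left")
    i1 = np.searchsorted(rx, txmax, "right") - 1
    j0 = np.searchsorted(ry, tymin, "left")
    j1 = np.searchsorted(ry, tymax, "right") - 1
    wi = np.maximum(i1 - i0 + 1, 0)
    wj = np.maximum(j1 - j0 + 1, 0)
    wtot = wi * wj
    keep = wtot > 0
    if not keep.any():
        return np.zeros(len(pts), bool)
    t1, t2, t3 = t1[keep], t2[keep], t3[keep]
    i0, j0, wi, wj, wtot = i0[keep], j0[keep], wi[keep], wj[keep], wtot[keep]

    tid = np.repeat(np.arange(len(wtot)), wtot)
    offs = np.concatenate([[0], np.cumsum(wtot)])[:-1]
    k = np.arange(int(wtot.sum())) - np.repeat(offs, wtot)
    ix = i0[tid] + k // wj[tid]
    iy = j0[tid] + k % wj[tid]
    px, py = rx[ix], ry[iy]

    a, b, c = t1[tid], t2[tid], t3[tid]
    det = ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
           - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))
    ok = np.abs(det) > 1e-300
    u = ((px - a[:, 0]) * (c[:, 1] - a[:, 1])
         - (c[:, 0] - a[:, 0]) * (py - a[:, 1]))
    v = ((b[:, 0] - a[:, 0]) * (py - a[:, 1])
         - (px - a[:, 0]) * (b[:, 1] - a[:, 1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(ok, u / det, -1.0)
        v = np.where(ok, v / det, -1.0)
    hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1)
    zc = a[:, 2] + u * (b[:, 2] - a[:, 2]) + v * (c[:, 2] - a[:, 2])
    col = ix[hit] * len(ry) + iy[hit]
    zhit = zc[hit]

    order = np.lexsort((zhit, col))
    col_s, z_s = col[order], zhit[order]
    ncols = len(rx) * len(ry)
    starts = np.searchsorted(col_s, np.arange(ncols), "left")
    ends = np.searchsorted(col_s, np.arange(ncols), "right")

    p_ix = np.searchsorted(np.round(xs_u, 12), np.round(pts[:, 0], 12))
    p_iy = np.searchsorted(np.round(ys_u, 12), np.round(pts[:, 1], 12))
    p_col = p_ix * len(ry) + p_iy
    below = np.empty(len(pts), np.int64)
    # crossings strictly below each query z, counted inside its column
    for cval in np.unique(p_col):
        sel = p_col == cval
        s, e = starts[cval], ends[cval]
        below[sel] = np.searchsorted(z_s[s:e], pts[sel, 2], "left") if e > s else 0
    return (below % 2) == 1


def triangulate(geometry: JunctionGeometry, resolution: Optional[float] = None):
    """Triangulated surface of the implicit solid via marching cubes."""
    import trimesh
    from skimage import measure

    dmin = min(l.diameter for l in geometry.limbs)
    if resolution is None:
        resolution = dmin / 24.0
    lo, hi = geometry.bounds()
    # the 0.1234567 shift de-aligns the sampling lattice from the
    # axis-aligned surface planes: exact zero crossings at sample points
    # would make marching cubes emit degenerate triangles that break
    # watertightness after an STL (float32 soup) round trip
    lo = lo - (2 + 0.1234567) * resolution
    hi = hi + 2 * resolution
    n = np.ceil((hi - lo) / resolution).astype(int) + 1
    xs = lo[0] + np.arange(n[0]) * resolution
    ys = lo[1] + np.arange(n[1]) * resolution
    zs = lo[2] + np.arange(n[2]) * resolution
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    vol = geometry.sdf(pts).reshape(tuple(n))
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0,
                                                spacing=(resolution,) * 3)
    verts = verts + lo
    # marching-cubes output is already consistently indexed; trimesh's
    # vertex-merging pass can create non-manifold fins here, so skip it
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    trimesh.repair.fix_normals(mesh)
    return mesh


def export_stl(geometry_or_mesh, path: str, binary: bool = True,
               resolution: Optional[float] = None) -> None:
    """Write a junction (or an existing mesh) to STL, ASCII or binary."""
    import trimesh
    if isinstance(geometry_or_mesh, JunctionGeometry):
        mesh = triangulate(geometry_or_mesh, resolution=resolution)
    elif isinstance(geometry_or_mesh, TriSolid):
        mesh = geometry_or_mesh.mesh
    else:
        mesh = geometry_or_mesh
    data = trimesh.exchange.stl.export_stl(mesh) if binary else \
        trimesh.exchange.stl.export_stl_ascii(mesh)
    mode = "wb" if binary else "w"
    with open(path, mode) as fh:
        fh.write(data)


def load_stl(path: str) -> TriSolid:
    """Load an STL surface (either dialect) as a watertight solid."""
    import trimesh
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    if os.path.getsize(path) == 0:
        raise FormatError(f"empty STL file: {path}")
    try:
        mesh = trimesh.load(path, file_type="stl", process=True)
    except Exception as exc:  # trimesh raises assorted types
        raise FormatError(f"cannot read STL {path}: {exc}") from exc
    if not hasattr(mesh, "faces") or len(getattr(mesh, "faces", [])) == 0:
        raise FormatError(f"STL {path} contains no triangles")
    return TriSolid(mesh)


def voxelize_mesh(solid: TriSolid, dx: float,
                  port_planes: Sequence[dict],
                  origin: Optional[Sequence[float]] = None,
                  pad_cells: int = 1) -> VoxelGrid:
    """Voxelize an imported triangulated solid.

    Imported surfaces carry no limb metadata, so ports must be declared
    explicitly: each entry of ``port_planes`` is a mapping with keys
    ``name``, ``role`` (inlet|outlet), ``center`` (3 floats, m),
    ``normal`` (outward, axis-aligned) and ``diameter`` (m).
    """
    lo, hi = solid.bounds()
    if origin is None:
        origin = dx * np.floor(np.asarray(lo) / dx) - pad_cells * dx
    origin = np.asarray(origin, float)
    n = np.ceil((np.asarray(hi) + pad_cells * dx - origin) / dx + 0.5).astype(int)
    nx, ny, nz = int(n[0]), int(n[1]), int(n[2])
    xs = origin[0] + (np.arange(nx) + 0.5) * dx
    ys = origin[1] + (np.arange(ny) + 0.5) * dx
    zs = origin[2] + (np.arange(nz) + 0.5) * dx
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    fluid = solid.contains(pts).reshape(nx, ny, nz)

    ports: Dict[str, Port] = {}
    for decl in port_planes:
        name = decl["name"]
        normal = np.asarray(decl["normal"], float)
        dom = int(np.argmax(np.abs(normal)))
        if not np.isclose(abs(normal[dom]), np.linalg.norm(normal), rtol=1e-3):
            raise GeometryError(f"port {name}: normal must be axis-aligned")
        sign = 1 if normal[dom] > 0 else -1
        center = np.asarray(decl["center"], float)
        radius = 0.5 * float(decl["diameter"])
        fi = int(round((center[dom] - origin[dom]) / dx))
        ci = fi - 1 if sign > 0 else fi
        idx = []
        sl = [slice(None)] * 3
        sl[dom] = ci
        other = [a for a in range(3) if a != dom]
        ii, jj = np.nonzero(fluid[tuple(sl)])
        for a, b in zip(ii, jj):
            cell = [0, 0, 0]
            cell[dom] = ci
            cell[other[0]] = a
            cell[other[1]] = b
            cc = origin + (np.asarray(cell) + 0.5) * dx
            rad = cc - center
            rad[dom] = 0.0
            if np.linalg.norm(rad) <= radius + 0.5 * dx:
                f = list(cell)
                f[dom] = fi
                idx.append(tuple(f))
        ports[name] = Port(name=name, role=decl["role"], axis=dom, sign=sign,
                           face_index=np.asarray(idx, int).reshape(-1, 3),
                           dx=dx, center=center, diameter=float(decl["diameter"]))
        if ports[name].n_faces == 0:
            raise GeometryError(f"declared port {name} matched no boundary faces")
    # clip fluid beyond each port plane so the cap is open and planar
    for p in ports.values():
        sl = [slice(None)] * 3
        if p.sign > 0:
            fi = int(round((p.center[p.axis] - origin[p.axis]) / dx))
            sl[p.axis] = slice(fi, None)
        else:
            fi = int(round((p.center[p.axis] - origin[p.axis]) / dx))
            sl[p.axis] = slice(None, fi)
        region = np.zeros_like(fluid)
        region[tuple(sl)] = True
        # only clip cells within the port's limb footprint
        # (conservative: radius + dx)
        cx, cy, cz = np.meshgrid(xs, ys, zs, indexing="ij")
        cc = np.stack([cx, cy, cz], axis=-1) - p.center
        cc[..., p.axis] = 0.0
        footprint = np.linalg.norm(cc, axis=-1) <= 0.5 * p.diameter + dx
        fluid[region & footprint] = False

    grid = VoxelGrid(dx=dx, origin=origin, fluid_mask=fluid, ports=ports,
                     geometry=None, sdf_cells=None)
    if grid.connected_components() != 1:
        raise GeometryError("voxelized STL fluid region is not connected")
    return grid
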