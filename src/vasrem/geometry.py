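"""Synthetic vessel geometries with analytic flow and wall-shear fields.

This module stands in for the imaging + CFD stage of a remodelling
experiment: instead of segmenting a fluorescence time-lapse and solving
Navier-Stokes, it builds binary vessel masks from parametric templates
(straight channel, Y-bifurcation, honeycomb capillary plexus) and assigns
each vessel segment a plane-Poiseuille velocity profile.  Segment mean
velocities are obtained from a flux-conserving resistor network
(conductance ~ w^3 / 12 mu L per segment), so mass is conserved exactly at
junctions.  Wall shear stress for a 2-D channel of width w carrying mean
speed U is tau_w = 6 mu U / w.

Coordinate convention (used across the whole package): rasters are
row-major with the origin at the top-left; positions are in micrometres
with the centre of pixel (row, col) at ((col + 0.5) * pixel_size,
(row + 0.5) * pixel_size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

__all__ = [
    "VesselMask",
    "FieldSet",
    "GeometrySpec",
    "Segment",
    "FlowNetwork",
    "make_vessel_mask",
    "build_flow_network",
    "analytic_flow",
    "interpolate_wall_shear",
    "hexagon_centers",
]

TEMPLATES = ("channel", "y_bifurcation", "honeycomb")


@dataclass
class VesselMask:
    """Binary raster of vascular (True) vs avascular (False) space."""

    grid: np.ndarray
    pixel_size: float = 1.0  # micrometres per pixel

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ValueError("mask grid must be a non-empty 2-D array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the raster in micrometres."""
        h, w = self.grid.shape
        return (w * self.pixel_size, h * self.pixel_size)

    def pixel_of(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Rows and columns of the pixels under positions (n, 2) in um."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cols = np.clip((pts[:, 0] / self.pixel_size).astype(int), 0, self.grid.shape[1] - 1)
        rows = np.clip((pts[:, 1] / self.pixel_size).astype(int), 0, self.grid.shape[0] - 1)
        return rows, cols

    def lumen_at(self, points: np.ndarray) -> np.ndarray:
        rows, cols = self.pixel_of(points)
        return self.grid[rows, cols]

    def boundary(self) -> np.ndarray:
        """Lumen pixels 4-adjacent to at least one avascular pixel."""
        eroded = ndimage.binary_erosion(self.grid, structure=_CROSS, border_value=1)
        return self.grid & ~eroded


_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class FieldSet:
    """Velocity and shear fields co-registered with a :class:`VesselMask`.

    velocity      -- (H, W, 2) array of (vx, vy) in um/s, zero off-lumen
    wall_shear    -- (H, W) Pa, NaN except on wall-adjacent lumen pixels
    interior_shear-- (H, W) Pa, NaN outside the lumen
    """

    velocity: np.ndarray
    wall_shear: np.ndarray
    interior_shear: np.ndarray

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.wall_shear = np.asarray(self.wall_shear, dtype=float)
        self.interior_shear = np.asarray(self.interior_shear, dtype=float)
        if self.velocity.ndim != 3 or self.velocity.shape[2] != 2:
            raise ValueError("velocity must have shape (H, W, 2)")
        if self.wall_shear.shape != self.velocity.shape[:2]:
            raise ValueError("wall_shear shape mismatch")
        if self.interior_shear.shape != self.velocity.shape[:2]:
            raise ValueError("interior_shear shape mismatch")


@dataclass
class GeometrySpec:
    """Parametric description of a synthetic vessel template.

    Lengths in micrometres, speeds in um/s, viscosity in Pa.s.  The
    default viscosity (3 mPa.s) and inlet speed (500 um/s) are arbitrary
    but physiologic for embryonic plasma-with-cells flow.
    """

    template: str = "channel"
    width: float = 50.0             # vessel (channel) width
    length: float = 300.0           # raster extent along x
    height: float | None = None     # raster extent along y (template default)
    inlet_speed: float = 500.0      # mean inlet speed
    viscosity: float = 0.003
    pitch: float = 120.0            # honeycomb: hexagon centre spacing
    branch_angle_deg: float = 30.0  # y_bifurcation: half opening angle
    branch_width: float | None = None

    def __post_init__(self) -> None:
        if self.template not in TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}; expected one of {TEMPLATES}")
        if not self.width > 0:
            raise ValueError("width must be positive")
        if not self.length > 0:
            raise ValueError("length must be positive")
        if not self.inlet_speed > 0:
            raise ValueError("at least one inlet with positive mean speed is required")
        if not self.viscosity > 0:
            raise ValueError("viscosity must be positive")
        if self.template == "honeycomb" and not self.pitch > self.width:
            raise ValueError("honeycomb pitch must exceed the vessel width")

    @property
    def resolved_height(self) -> float:
        if self.height is not None:
            return self.height
        if self.template == "channel":
            return 2.0 * self.width
        if self.template == "y_bifurcation":
            return self.length * math.tan(math.radians(self.branch_angle_deg)) + 4 * self.width
        return self.length  # honeycomb: square by default


@dataclass
class Segment:
    """A straight vessel segment with a signed mean speed along p0 -> p1."""

    p0: np.ndarray
    p1: np.ndarray
    width: float
    u_mean: float = 0.0  # um/s, signed along (p1 - p0)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    @property
    def direction(self) -> np.ndarray:
        d = self.p1 - self.p0
        return d / np.linalg.norm(d)

    @property
    def wall_shear(self) -> float:
        """Plane-Poiseuille wall shear 6 mu U / w; filled in by the solver."""
        return self._tau

    _tau: float = field(default=0.0, repr=False)


@dataclass
class FlowNetwork:
    nodes: np.ndarray                 # (n, 2) um
    node_kind: np.ndarray             # 'interior' | 'inlet' | 'outlet'
    edges: np.ndarray                 # (m, 2) node indices
    widths: np.ndarray                # (m,)
    flux: np.ndarray                  # (m,) signed um^2/s along edge u -> v
    pressure: np.ndarray              # (n,) arbitrary units

    def node_flux_residuals(self) -> np.ndarray:
        """Net signed flux into each interior node (mass-conservation check)."""
        net = np.zeros(len(self.nodes))
        np.add.at(net, self.edges[:, 0], -self.flux)
        np.add.at(net, self.edges[:, 1], self.flux)
        return net[self.node_kind == "interior"]

    def segments(self, viscosity: float) -> list[Segment]:
        segs = []
        for (u, v), w, q in zip(self.edges, self.widths, self.flux):
            s = Segment(self.nodes[u].copy(), self.nodes[v].copy(), float(w), float(q / w))
            s._tau = 6.0 * viscosity * abs(s.u_mean) / s.width
            segs.append(s)
        return segs


# ---------------------------------------------------------------------------
# Network construction

def _network_channel(spec: GeometrySpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, list, list]:
    h = spec.resolved_height
    y0 = h / 2.0
    nodes = np.array([[0.0, y0], [spec.length, y0]])
    edges = np.array([[0, 1]])
    widths = np.array([spec.width])
    return nodes, edges, widths, [0], [1]


def _network_y(spec: GeometrySpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, list, list]:
    h = spec.resolved_height
    y0 = h / 2.0
    xb = spec.length / 2.0
    dy = (spec.length - xb) * math.tan(math.radians(spec.branch_angle_deg))
    wb = spec.branch_width if spec.branch_width is not None else 0.8 * spec.width
    nodes = np.array(
        [[0.0, y0], [xb, y0], [spec.length, y0 - dy], [spec.length, y0 + dy]]
    )
    edges = np.array([[0, 1], [1, 2], [1, 3]])
    widths = np.array([spec.width, wb, wb])
    return nodes, edges, widths, [0], [2, 3]


def hexagon_centers(spec: GeometrySpec, margin: float | None = None) -> np.ndarray:
    """Triangular-lattice hexagon centres covering the raster extent."""
    p = spec.pitch
    if margin is None:
        margin = p
    w_ext, h_ext = spec.length, spec.resolved_height
    a1 = np.array([p, 0.0])
    a2 = np.array([p / 2.0, p * math.sqrt(3) / 2.0])
    jmax = int(math.ceil((h_ext + 2 * margin) / a2[1])) + 1
    centers = []
    for j in range(-1, jmax + 1):
        base = j * a2
        imin = int(math.floor((-margin - base[0]) / p)) - 1
        imax = int(math.ceil((w_ext + margin - base[0]) / p)) + 1
        for i in range(imin, imax + 1):
            c = base + i * a1
            if -margin <= c[0] <= w_ext + margin and -margin <= c[1] <= h_ext + margin:
                centers.append(c)
    return np.array(centers)


def _network_honeycomb(spec: GeometrySpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, list, list]:
    # Dual of the triangular hexagon-centre lattice: one node per lattice
    # triangle (the channel triple-points), three edges per "up" node.
    p = spec.pitch
    w_ext, h_ext = spec.length, spec.resolved_height
    a1 = np.array([p, 0.0])
    a2 = np.array([p / 2.0, p * math.sqrt(3) / 2.0])
    up_off = np.array([p / 2.0, p * math.sqrt(3) / 6.0])
    dn_off = np.array([p, p * math.sqrt(3) / 3.0])

    jmax = int(math.ceil(h_ext / a2[1])) + 2
    index: dict[tuple[str, int, int], int] = {}
    nodes: list[np.ndarray] = []

    def node_id(kind: str, i: int, j: int) -> int:
        key = (kind, i, j)
        if key not in index:
            off = up_off if kind == "u" else dn_off
            index[key] = len(nodes)
            nodes.append(i * a1 + j * a2 + off)
        return index[key]

    edges: list[tuple[int, int]] = []
    for j in range(-2, jmax + 1):
        base_x = j * a2[0]
        imin = int(math.floor((-p - base_x) / p)) - 1
        imax = int(math.ceil((w_ext + p - base_x) / p)) + 1
        for i in range(imin, imax + 1):
            u = node_id("u", i, j)
            for dkey in (("d", i, j), ("d", i - 1, j), ("d", i, j - 1)):
                d = node_id(*dkey)
                edges.append((u, d))

    nodes_arr = np.array(nodes)
    # keep nodes inside a one-pitch margin band; classify boundary terminals
    keep = (
        (nodes_arr[:, 0] > -p)
        & (nodes_arr[:, 0] < w_ext + p)
        & (nodes_arr[:, 1] > -0.5 * p)
        & (nodes_arr[:, 1] < h_ext + 0.5 * p)
    )
    remap = -np.ones(len(nodes_arr), dtype=int)
    remap[keep] = np.arange(keep.sum())
    kept_nodes = nodes_arr[keep]
    kept_edges = [
        (remap[u], remap[v]) for u, v in edges if remap[u] >= 0 and remap[v] >= 0
    ]
    edges_arr = np.array(sorted(set(tuple(sorted(e)) for e in kept_edges)))
    widths = np.full(len(edges_arr), spec.width)
    inlets = [int(k) for k in np.flatnonzero(kept_nodes[:, 0] <= 0.0)]
    outlets = [int(k) for k in np.flatnonzero(kept_nodes[:, 0] >= w_ext)]
    return kept_nodes, edges_arr, widths, inlets, outlets


def build_flow_network(spec: GeometrySpec) -> FlowNetwork:
    """Solve the flux-conserving resistor network for a geometry template.

    Each inlet terminal injects Q = inlet_speed * width; outlet terminals
    are held at zero pressure.  Edge conductance is w^3 / (12 mu L), the
    2-D Poiseuille conductance per unit depth.
    """
    builder = {
        "channel": _network_channel,
        "y_bifurcation": _network_y,
        "honeycomb": _network_honeycomb,
    }[spec.template]
    nodes, edges, widths, inlets, outlets = builder(spec)
    if len(outlets) == 0 or len(inlets) == 0:
        raise ValueError("geometry does not fit raster extent: no inlet/outlet terminals")

    n = len(nodes)
    lengths = np.linalg.norm(nodes[edges[:, 1]] - nodes[edges[:, 0]], axis=1)
    g = widths**3 / (12.0 * spec.viscosity * lengths)

    kind = np.full(n, "interior", dtype=object)
    kind[inlets] = "inlet"
    kind[outlets] = "outlet"

    # Laplacian with Dirichlet rows on outlets, flux injections on inlets.
    rows, cols, vals = [], [], []
    b = np.zeros(n)
    is_outlet = np.zeros(n, dtype=bool)
    is_outlet[outlets] = True
    for (u, v), gi in zip(edges, g):
        for a_, b_ in ((u, v), (v, u)):
            if not is_outlet[a_]:
                rows += [a_, a_]
                cols += [a_, b_]
                vals += [gi, -gi]
    for o in outlets:
        rows.append(o)
        cols.append(o)
        vals.append(1.0)
    for i in inlets:
        b[i] += spec.inlet_speed * spec.width

    lap = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    pressure = spsolve(lap.tocsc(), b)
    flux = g * (pressure[edges[:, 0]] - pressure[edges[:, 1]])
    return FlowNetwork(nodes, kind.astype("U8"), edges, widths, flux, pressure)


# ---------------------------------------------------------------------------
# Mask rasterization

def _hexagon_interior(xy: np.ndarray, centers: np.ndarray, flat: float) -> np.ndarray:
    """Boolean: point inside any regular hexagon (across-flats = flat)."""
    normals = np.array(
        [[1.0, 0.0],
         [0.5, math.sqrt(3) / 2.0],
         [-0.5, math.sqrt(3) / 2.0]]
    )
    inside = np.zeros(len(xy), dtype=bool)
    half = flat / 2.0
    for c in centers:
        d = xy - c
        near = (np.abs(d[:, 0]) <= flat) & (np.abs(d[:, 1]) <= flat)
        if not near.any():
            continue
        proj = np.abs(d[near] @ normals.T)
        inside[near] |= proj.max(axis=1) <= half
    return inside


def _pixel_centres(shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    h, w = shape
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    return np.stack(((cols + 0.5) * pixel_size, (rows + 0.5) * pixel_size), axis=-1)


def make_vessel_mask(spec: GeometrySpec, pixel_size: float = 1.0) -> VesselMask:
    """Rasterize a geometry template into a binary vessel mask."""
    if not pixel_size > 0:
        raise ValueError("pixel_size must be positive")
    h_ext = spec.resolved_height
    shape = (int(round(h_ext / pixel_size)), int(round(spec.length / pixel_size)))
    if min(shape) < 1:
        raise ValueError("geometry does not fit raster extent")

    if spec.template == "channel":
        grid = np.zeros(shape, dtype=bool)
        n_rows = int(round(spec.width / pixel_size))
        if n_rows < 1 or n_rows > shape[0]:
            raise ValueError("geometry does not fit raster extent")
        r0 = int(round((h_ext - spec.width) / (2 * pixel_size)))
        grid[r0 : r0 + n_rows, :] = True
        return VesselMask(grid, pixel_size)

    xy = _pixel_centres(shape, pixel_size).reshape(-1, 2)
    if spec.template == "honeycomb":
        centers = hexagon_centers(spec)
        flat = spec.pitch - spec.width
        grid = ~_hexagon_interior(xy, centers, flat)
        return VesselMask(grid.reshape(shape), pixel_size)

    # y_bifurcation: union of capsules around the network segments
    net = build_flow_network(spec)
    grid = np.zeros(len(xy), dtype=bool)
    for (u, v), w in zip(net.edges, net.widths):
        p0, p1 = net.nodes[u], net.nodes[v]
        d = p1 - p0
        ll = d @ d
        t = np.clip((xy - p0) @ d / ll, 0.0, 1.0)
        dist = np.linalg.norm(xy - (p0 + t[:, None] * d), axis=1)
        grid |= dist <= w / 2.0
    return VesselMask(grid.reshape(shape), pixel_size)


# ---------------------------------------------------------------------------
# Analytic fields

def analytic_flow(mask: VesselMask, spec: GeometrySpec) -> FieldSet:
    """Plane-Poiseuille velocity and shear fields for a template mask.

    Every lumen pixel is assigned to its nearest network segment: the
    in-plane velocity follows the parabolic profile (1.5 U_mean at the
    centreline, zero at the walls), the wall-adjacent shear is
    tau_w = 6 mu U_mean / w, and the interior shear is the wall value of
    the nearest segment (both facing walls of a straight segment carry the
    same shear, so interpolation across the lumen is constant).
    """
    net = build_flow_network(spec)
    segs = net.segments(spec.viscosity)
    if not segs:
        raise ValueError("spec/mask mismatch: no flow segments")

    shape = mask.shape
    lumen = mask.grid
    idx = np.argwhere(lumen)
    xy = np.stack(((idx[:, 1] + 0.5) * mask.pixel_size, (idx[:, 0] + 0.5) * mask.pixel_size), axis=1)

    best_d = np.full(len(xy), np.inf)
    best_s = np.zeros(len(xy), dtype=int)
    for k, s in enumerate(segs):
        d = s.p1 - s.p0
        ll = d @ d
        t = np.clip((xy - s.p0) @ d / ll, 0.0, 1.0)
        dist = np.linalg.norm(xy - (s.p0 + t[:, None] * d), axis=1)
        closer = dist < best_d
        best_d[closer] = dist[closer]
        best_s[closer] = k

    seg_dir = np.array([s.direction for s in segs])
    seg_u = np.array([s.u_mean for s in segs])
    seg_w = np.array([s.width for s in segs])
    seg_tau = np.array([s.wall_shear for s in segs])

    dirs = seg_dir[best_s]
    u_mean = seg_u[best_s]
    halfw = seg_w[best_s] / 2.0
    # unclamped perpendicular distance to the centreline, capped at w/2
    p0 = np.array([s.p0 for s in segs])[best_s]
    rel = xy - p0
    dperp = np.abs(rel[:, 0] * dirs[:, 1] - rel[:, 1] * dirs[:, 0])
    dperp = np.minimum(dperp, halfw)
    profile = 1.5 * u_mean * (1.0 - (dperp / halfw) ** 2)

    velocity = np.zeros(shape + (2,))
    velocity[idx[:, 0], idx[:, 1], 0] = dirs[:, 0] * profile
    velocity[idx[:, 0], idx[:, 1], 1] = dirs[:, 1] * profile

    interior = np.full(shape, np.nan)
    interior[idx[:, 0], idx[:, 1]] = seg_tau[best_s]

    wall = np.full(shape, np.nan)
    bpix = mask.boundary()
    wall[bpix] = interior[bpix]
    velocity[bpix] = 0.0  # no-slip at wall-adjacent pixels
    return FieldSet(velocity, wall, interior)


# ---------------------------------------------------------------------------
# Wall-shear interpolation (nearest walls across the lumen)

def interpolate_wall_shear(
    mask: VesselMask,
    wall_shear: np.ndarray,
    point: Sequence[float],
    velocity: np.ndarray | None = None,
    max_range: float | None = None,
) -> float:
    """Inverse-distance interpolation of the two facing walls' shear.

    Rays are cast from ``point`` perpendicular to the local flow direction
    (or, without a velocity field, along the axis through the nearest
    wall); the shear value at each of the two wall contacts is combined
    with weights 1/d.  The result is a convex combination of the two wall
    values; a point lying on a wall returns that wall's value.
    """
    pt = np.asarray(point, dtype=float)
    ps = mask.pixel_size
    rows, cols = mask.pixel_of(pt[None, :])
    r0, c0 = int(rows[0]), int(cols[0])
    if not mask.grid[r0, c0]:
        raise ValueError("point outside lumen")

    finite = np.isfinite(wall_shear)
    if not finite.any():
        raise ValueError("wall_shear field has no defined values")
    # nearest defined wall-shear pixel, for snapping ray contacts to values
    _, (wr, wc) = ndimage.distance_transform_edt(~finite, return_indices=True)

    if velocity is not None:
        v = np.asarray(velocity, dtype=float)[r0, c0]
        if np.linalg.norm(v) > 1e-12:
            n = np.array([-v[1], v[0]]) / np.linalg.norm(v)
        else:
            v = None
    if velocity is None or v is None:
        _, (nr, nc) = ndimage.distance_transform_edt(mask.grid, return_indices=True)
        tgt = np.array([(nc[r0, c0] + 0.5) * ps, (nr[r0, c0] + 0.5) * ps])
        d = tgt - pt
        nd = np.linalg.norm(d)
        n = d / nd if nd > 1e-12 else np.array([0.0, 1.0])

    if np.isfinite(wall_shear[r0, c0]):
        return float(wall_shear[r0, c0])  # point lies on the wall layer

    if max_range is None:
        max_range = float(max(mask.extent))
    step = ps / 2.0
    nsteps = int(max_range / step) + 1

    def in_lumen(p: np.ndarray) -> bool:
        r, c = int(p[1] / ps), int(p[0] / ps)
        if r < 0 or c < 0 or r >= mask.shape[0] or c >= mask.shape[1]:
            return False
        return bool(mask.grid[r, c])

    contacts: list[tuple[float, float]] = []  # (distance, tau)
    for sign in (1.0, -1.0):
        prev_in = pt
        for k in range(1, nsteps):
            p = pt + sign * n * (k * step)
            r, c = int(p[1] / ps), int(p[0] / ps)
            if r < 0 or c < 0 or r >= mask.shape[0] or c >= mask.shape[1]:
                break  # open end: this side contributes no wall
            if not mask.grid[r, c]:
                # bisect to the lumen/wall pixel interface
                lo, hi = prev_in, p
                for _ in range(40):
                    mid = (lo + hi) / 2.0
                    if in_lumen(mid):
                        lo = mid
                    else:
                        hi = mid
                contact = (lo + hi) / 2.0
                rl, cl = int(prev_in[1] / ps), int(prev_in[0] / ps)
                tau = float(wall_shear[wr[rl, cl], wc[rl, cl]])
                contacts.append((float(np.linalg.norm(contact - pt)), tau))
                break
            prev_in = p

    if not contacts:
        raise ValueError("no wall contact found within range")
    for d, tau in contacts:
        if d < 1e-9:  # on-wall limit
            return tau
    wsum = sum(1.0 / d for d, _ in contacts)
    return sum(tau / d for d, tau in contacts) / wsum
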