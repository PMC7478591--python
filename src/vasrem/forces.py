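"""Pairwise body forces, the remodelling force and the shear-gradient term.

The body force is a Lennard-Jones-type attraction/repulsion profile: hard
(capped) repulsion below the repulsion distance, a linear restoring branch
around the equilibrium separation, unit attraction out to the cutoff, and
zero beyond.  Positive values attract (point from agent i toward the
source); the linear branch therefore restores the equilibrium from either
side.  For circular agents the distances are the scalar parameters
(r_c, r_e, r_a, r_o); for elliptical agents the same profile is evaluated
three times per ordered pair -- once from the neighbour's centre and once
from each of its foci -- with equilibrium distances built from the two
agents' boundary extents along the relevant connecting line and the
remaining distances scaled by the circular ratios r_c/r_e, r_a/r_e,
r_o/r_e.  With equal semi-axes the foci collapse onto the centre and the
three contributions coincide, recovering exactly three times the circular
force.

The remodelling force converts local crowding into diameter change:
agents closer than the pairwise equilibrium are pushed toward the nearest
vessel wall, agents sparser than equilibrium (but within the cutoff) are
pulled toward the vessel centreline (vascular) or away from the nearest
wall (avascular), with magnitude |r_ij - r_e|.  Wall and centreline
directions come from Euclidean distance transforms of the current mask
and of its morphological skeleton.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .geometry import VesselMask
from .model import AVASCULAR, VASCULAR, Agent, ModelParams

__all__ = [
    "body_force_circular",
    "ellipse_radial_extent",
    "PairGeometry",
    "pair_geometry",
    "body_force_elliptical",
    "elliptical_force_pairs",
    "pairwise_scales",
    "RemodellingMaps",
    "remodelling_force",
    "shear_gradient_term",
]


def lj_profile(L, L_c, L_e, L_a, L_o, cap: float) -> np.ndarray:
    """The piecewise attraction/repulsion scalar (positive = attraction)."""
    L = np.asarray(L, dtype=float)
    out = np.zeros(np.broadcast(L, L_c).shape)
    L, L_c, L_e, L_a, L_o = np.broadcast_arrays(L, L_c, L_e, L_a, L_o)
    m = L < L_c
    out[m] = -cap
    m = (L >= L_c) & (L < L_a)
    out[m] = 0.25 * (L[m] - L_e[m]) / (L_a[m] - L_e[m])
    m = (L >= L_a) & (L < L_o)
    out[m] = 1.0
    return out


def body_force_circular(r_ij, params: ModelParams):
    """Signed scalar force between two circular agents at separation r_ij.

    Positive values attract along the unit vector from i to j.  The
    unbounded close-range repulsion of the printed profile is capped at
    ``-repulsion_cap`` for numerical stability; coincident centres are an
    error.
    """
    r = np.asarray(r_ij, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be positive (coincident centres)")
    out = lj_profile(r, params.r_c, params.r_e, params.r_a, params.r_o,
                     params.repulsion_cap)
    return out if out.ndim else float(out)


def ellipse_radial_extent(a, b, phi):
    """Distance from an ellipse centre to its boundary along a direction.

    ``phi`` is the angle between the direction and the major axis:
    extent = a b / sqrt(b^2 cos^2 phi + a^2 sin^2 phi).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    phi = np.asarray(phi, dtype=float)
    ext = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
    return ext if ext.ndim else float(ext)


def _ray_ellipse_exit(a, b, origin_x, origin_y, dir_x, dir_y):
    """Distance from an interior point to the ellipse boundary along a ray.

    All quantities in the ellipse frame (major axis along x).  The origin
    must lie inside; the positive quadratic root is returned.
    """
    A = (dir_x / a) ** 2 + (dir_y / b) ** 2
    B = 2.0 * (origin_x * dir_x / a**2 + origin_y * dir_y / b**2)
    C = (origin_x / a) ** 2 + (origin_y / b) ** 2 - 1.0
    disc = np.maximum(B**2 - 4.0 * A * C, 0.0)
    return (-B + np.sqrt(disc)) / (2.0 * A)


@dataclass
class PairGeometry:
    """Distances of the three force contributions of an ordered pair (i, j).

    Row k of each array is the contribution from source point k of agent j
    (0 = centre S', 1 = focus G, 2 = focus G') acting on the centre of
    agent i.
    """

    L: np.ndarray      # (3,) current distance to each source point
    L_c: np.ndarray
    L_e: np.ndarray
    L_a: np.ndarray
    L_o: np.ndarray
    sources: np.ndarray  # (3, 2) source-point positions
    units: np.ndarray    # (3, 2) unit vectors from i toward each source


def _contribution_arrays(pi, ti, ai, bi, pj, tj, aj, bj, params: ModelParams):
    """Vectorized geometry of the three contributions for m ordered pairs.

    Returns sources (3, m, 2), L (3, m), L_e (3, m) and unit vectors
    e (3, m, 2) from i toward each source point of j.
    """
    m = len(pi)
    foc = np.sqrt(np.maximum(aj**2 - bj**2, 0.0))
    axis = np.stack([np.cos(tj), np.sin(tj)], axis=1)
    sources = np.stack([pj, pj + foc[:, None] * axis, pj - foc[:, None] * axis])

    dvec = sources - pi[None, :, :]
    L = np.linalg.norm(dvec, axis=2)
    bad = L < 1e-12
    if bad.any():
        warnings.warn("coincident agent centres: applying maximal repulsion fallback",
                      stacklevel=2)
        dvec[bad] = np.array([1.0, 0.0])
        L[bad] = 1e-12
    e = dvec / L[..., None]
    ang = np.arctan2(e[..., 1], e[..., 0])

    ext_i = ellipse_radial_extent(ai[None, :], bi[None, :], ang - ti[None, :])

    # extent of agent j from each source toward i, along -e
    ext_j = np.empty((3, m))
    ext_j[0] = ellipse_radial_extent(aj, bj, (ang[0] + np.pi) - tj)
    cos_t, sin_t = np.cos(tj), np.sin(tj)
    for k, sign in ((1, 1.0), (2, -1.0)):
        ox = sign * foc  # focus position in the ellipse frame
        dx = -(e[k, :, 0] * cos_t + e[k, :, 1] * sin_t)
        dy = -(-e[k, :, 0] * sin_t + e[k, :, 1] * cos_t)
        ext_j[k] = _ray_ellipse_exit(aj, bj, ox, 0.0, dx, dy)

    L_e = ext_i + ext_j
    return sources, L, L_e, e


def pair_geometry(agent_i: Agent, agent_j: Agent, params: ModelParams) -> PairGeometry:
    """Distances and unit vectors of the three contributions of one pair."""
    sources, L, L_e, e = _contribution_arrays(
        agent_i.position[None, :], np.array([agent_i.orient]),
        np.array([agent_i.a]), np.array([agent_i.b]),
        agent_j.position[None, :], np.array([agent_j.orient]),
        np.array([agent_j.a]), np.array([agent_j.b]), params)
    rc, ra, ro = params.r_c / params.r_e, params.r_a / params.r_e, params.r_o / params.r_e
    return PairGeometry(
        L=L[:, 0], L_c=L_e[:, 0] * rc, L_e=L_e[:, 0], L_a=L_e[:, 0] * ra,
        L_o=L_e[:, 0] * ro, sources=sources[:, 0, :], units=e[:, 0, :])


def elliptical_force_pairs(pi, ti, ai, bi, pj, tj, aj, bj, params: ModelParams):
    """Three-point body force of agents j on agents i for m ordered pairs.

    Orientations ``ti``/``tj`` are the ellipse major-axis angles.  Returns
    the (m, 2) unnormalized force vectors (sum of the three
    contributions), together with the centre separation L, the pairwise
    equilibrium distance L_e and the pairwise cutoff L_o (all centre-based).
    """
    sources, L, L_e, e = _contribution_arrays(pi, ti, ai, bi, pj, tj, aj, bj, params)
    rc, ra, ro = params.r_c / params.r_e, params.r_a / params.r_e, params.r_o / params.r_e
    scal = lj_profile(L, L_e * rc, L_e, L_e * ra, L_e * ro, params.repulsion_cap)
    force = (scal[..., None] * e).sum(axis=0)
    return force, L[0], L_e[0], L_e[0] * ro


def body_force_elliptical(agent_i: Agent, agent_j: Agent, params: ModelParams) -> np.ndarray:
    """Unnormalized three-point force of agent j on agent i (2-vector)."""
    force, _, _, _ = elliptical_force_pairs(
        agent_i.position[None, :], np.array([agent_i.orient]),
        np.array([agent_i.a]), np.array([agent_i.b]),
        agent_j.position[None, :], np.array([agent_j.orient]),
        np.array([agent_j.a]), np.array([agent_j.b]), params)
    return force[0]


def pairwise_scales(pi, ti, ai, bi, pj, tj, aj, bj) -> np.ndarray:
    """Pairwise equilibrium distance: sum of boundary extents along the
    centre-connecting line (reduces to r_e for two standard circles)."""
    d = pj - pi
    L = np.linalg.norm(d, axis=1)
    L = np.maximum(L, 1e-12)
    ang = np.arctan2(d[:, 1], d[:, 0])
    return (ellipse_radial_extent(ai, bi, ang - ti)
            + ellipse_radial_extent(aj, bj, (ang + np.pi) - tj))


class RemodellingMaps:
    """Wall and centreline direction fields derived from a vessel mask.

    Rebuilt every few steps (the geometry changes slowly at these speeds):
    a distance transform of the lumen gives, for every pixel, the nearest
    wall pixel; the skeleton of the lumen gives the nearest centreline
    pixel.
    """

    def __init__(self, mask: VesselMask):
        self.pixel_size = mask.pixel_size
        self.shape = mask.shape
        grid = mask.grid
        # nearest avascular pixel (the "wall" seen from inside the lumen)
        _, (self._wall_r, self._wall_c) = ndimage.distance_transform_edt(
            grid, return_indices=True)
        # nearest lumen pixel (the wall seen from the avascular side)
        _, (self._lum_r, self._lum_c) = ndimage.distance_transform_edt(
            ~grid, return_indices=True)
        skel = skeletonize(grid)
        if not skel.any():
            skel = grid.copy()
        _, (self._sk_r, self._sk_c) = ndimage.distance_transform_edt(
            ~skel, return_indices=True)

    def _toward(self, pos, tr, tc) -> np.ndarray:
        ps = self.pixel_size
        r = np.clip((pos[:, 1] / ps).astype(int), 0, self.shape[0] - 1)
        c = np.clip((pos[:, 0] / ps).astype(int), 0, self.shape[1] - 1)
        tgt = np.stack([(tc[r, c] + 0.5) * ps, (tr[r, c] + 0.5) * ps], axis=1)
        d = tgt - pos
        n = np.linalg.norm(d, axis=1)
        out = np.zeros_like(d)
        ok = n > ps / 4.0
        out[ok] = d[ok] / n[ok, None]
        return out

    def outward(self, pos: np.ndarray, phase: np.ndarray) -> np.ndarray:
        """Unit vectors toward the nearest vessel wall."""
        pos = np.atleast_2d(pos)
        out = np.zeros_like(pos)
        v = phase == VASCULAR
        if v.any():
            out[v] = self._toward(pos[v], self._wall_r, self._wall_c)
        if (~v).any():
            out[~v] = self._toward(pos[~v], self._lum_r, self._lum_c)
        return out

    def inward(self, pos: np.ndarray, phase: np.ndarray) -> np.ndarray:
        """Toward the centreline (vascular) / away from the wall (avascular)."""
        pos = np.atleast_2d(pos)
        out = np.zeros_like(pos)
        v = phase == VASCULAR
        if v.any():
            out[v] = self._toward(pos[v], self._sk_r, self._sk_c)
        if (~v).any():
            out[~v] = -self._toward(pos[~v], self._lum_r, self._lum_c)
        return out


def remodelling_force(agent: Agent, maps: RemodellingMaps,
                      neighbor_agents: list[Agent], params: ModelParams) -> np.ndarray:
    """Density-triggered force on one agent, summed over its neighbours.

    Each neighbour within the pairwise cutoff contributes magnitude
    |r_ij - r_e_pair|, directed toward the wall when the pair is crowded
    and toward the centreline (or away from the wall, for avascular
    agents) when it is sparse.
    """
    pos = agent.position[None, :]
    phase = np.array([agent.phase])
    total = np.zeros(2)
    e_out = maps.outward(pos, phase)[0]
    e_in = maps.inward(pos, phase)[0]
    for nb in neighbor_agents:
        r = float(np.linalg.norm(nb.position - agent.position))
        le = pairwise_scales(pos, np.array([agent.orient]), np.array([agent.a]),
                             np.array([agent.b]), nb.position[None, :],
                             np.array([nb.orient]), np.array([nb.a]),
                             np.array([nb.b]))[0]
        lo = le * params.r_o / params.r_e
        if r >= lo:
            continue
        mag = abs(r - le)
        total += mag * (e_out if r < le else e_in)
    return total


def shear_gradient_term(tau_i: float, tau_j: np.ndarray, e_ij: np.ndarray) -> np.ndarray:
    """Sum over neighbours of (tau_j - tau_i) e_ij: points up-gradient."""
    tau_j = np.asarray(tau_j, dtype=float)
    e_ij = np.atleast_2d(e_ij)
    return ((tau_j - tau_i)[:, None] * e_ij).sum(axis=0)
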