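"""Time integration of the two-phase remodelling model.

Each 5-minute step advances the system in a fixed order: (1) avascular
cluster centroids are recomputed, (2) avascular clusters expand and
vascular agents elongate, (3) all headings are updated synchronously from
the state at the start of the step, (4) all agents move, (5) overlapping
pairs are separated back to the pairwise repulsion distance.  Vascular
agents move against the local flow at a shear-dependent speed; avascular
agents move at the fixed speed V_av only while their net force is
non-zero.  Three modes are available: ``full`` (alignment, body forces,
avascular interaction, shear gradient, remodelling force, elongation and
avascular growth), ``gregoire`` (alignment and vascular body force only,
with circular agents and a static avascular phase) and ``random``
(headings drawn uniformly each step, speeds still shear-dependent).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .forces import (RemodellingMaps, elliptical_force_pairs, pairwise_scales)
from .geometry import FieldSet, VesselMask
from .model import (AVASCULAR, VASCULAR, ModelParams, Population,
                    label_avascular_clusters, neighbor_pairs, seed_agents)

__all__ = [
    "SpeedCurve",
    "speed_from_shear",
    "SimulationResult",
    "simulate",
    "relax",
    "SyntheticTimelapse",
    "make_synthetic_timelapse",
]

log = logging.getLogger(__name__)

MODES = ("full", "gregoire", "random")


@dataclass
class SpeedCurve:
    """Bell-shaped shear-to-speed relation V(tau) = V_max (tau/tau_max) e^{1 - tau/tau_max}.

    Zero at zero shear, maximal (exactly V_max) at tau_max, decaying
    beyond -- a two-parameter unimodal curve matching the measured
    bell-shaped migration response of endothelial monolayers.
    """

    v_max: float = 12.0   # um/h
    tau_max: float = 0.033  # Pa

    def __call__(self, tau):
        t = np.asarray(tau, dtype=float)
        if np.any(t[np.isfinite(t)] < 0):
            raise ValueError("shear stress must be non-negative")
        x = t / self.tau_max
        v = self.v_max * x * np.exp(1.0 - x)
        v = np.where(np.isfinite(v), v, 0.0)
        return v if v.ndim else float(v)


def speed_from_shear(tau, curve: SpeedCurve):
    return curve(tau)


@dataclass
class SimulationResult:
    snapshots: list[tuple[float, Population]]
    params: ModelParams
    mode: str
    seed: int
    duration: float

    @property
    def final(self) -> Population:
        return self.snapshots[-1][1]

    @property
    def initial(self) -> Population:
        return self.snapshots[0][1]


def _sample_fields(pop: Population, mask: VesselMask, fields: FieldSet):
    """Preferred migration direction (anti-parallel to flow) and shear."""
    rows, cols = mask.pixel_of(pop.pos)
    v = fields.velocity[rows, cols]
    speednorm = np.linalg.norm(v, axis=1)
    pref = np.zeros_like(v)
    ok = speednorm > 1e-12
    pref[ok] = -v[ok] / speednorm[ok, None]
    tau = fields.interior_shear[rows, cols]
    tau = np.where(np.isfinite(tau), tau, 0.0)
    flow_angle = np.where(ok, np.arctan2(v[:, 1], v[:, 0]), np.nan)
    return pref, tau, flow_angle


def _heading_vectors(pop: Population, params: ModelParams, pref, tau,
                     maps: RemodellingMaps | None, gregoire: bool = False) -> np.ndarray:
    """Weighted vector whose argument is each agent's new heading."""
    n = len(pop)
    vec = np.zeros((n, 2))
    vasc = pop.vascular

    # alignment: preferred directions of the agent itself and its
    # vascular neighbours (Vicsek-style, self included)
    if params.alpha > 0 and not np.all(pref == 0):
        vec[vasc] += params.alpha * pref[vasc]

    cutoff = 2.0 * pop.a.max() * params.r_o / params.r_e
    pairs = neighbor_pairs(pop.pos, cutoff)
    if len(pairs):
        di = np.concatenate([pairs[:, 0], pairs[:, 1]])
        dj = np.concatenate([pairs[:, 1], pairs[:, 0]])
        force, L, L_e, L_o = elliptical_force_pairs(
            pop.pos[di], pop.orient[di], pop.a[di], pop.b[di],
            pop.pos[dj], pop.orient[dj], pop.a[dj], pop.b[dj], params)
        if params.normalize_ellipse_force:
            force = force / 3.0
        within = L < L_o
        di, dj = di[within], dj[within]
        force, L, L_e = force[within], L[within], L_e[within]

        iv = pop.phase[di] == VASCULAR
        jv = pop.phase[dj] == VASCULAR

        vv = iv & jv
        if params.alpha > 0:
            np.add.at(vec, di[vv], params.alpha * pref[dj[vv]])
        if params.beta > 0:
            np.add.at(vec, di[vv], params.beta * force[vv])
        if not gregoire:
            va = iv & ~jv
            if params.kappa > 0:
                np.add.at(vec, di[va], params.kappa * force[va])
            aa = ~iv & ~jv
            if params.beta_av > 0:
                np.add.at(vec, di[aa], params.beta_av * force[aa])
            av = ~iv & jv
            if params.kappa_av > 0:
                np.add.at(vec, di[av], params.kappa_av * force[av])
            if params.zeta > 0:
                e_ij = (pop.pos[dj[vv]] - pop.pos[di[vv]])
                norm = np.linalg.norm(e_ij, axis=1)
                norm = np.maximum(norm, 1e-12)
                e_ij /= norm[:, None]
                dtau = tau[dj[vv]] - tau[di[vv]]
                np.add.at(vec, di[vv], params.zeta * dtau[:, None] * e_ij)
            if maps is not None and (params.omega > 0 or params.omega_av > 0):
                same = iv == jv
                si, sj = di[same], dj[same]
                mag = np.abs(L[same] - L_e[same])
                crowded = L[same] < L_e[same]
                e_out = maps.outward(pop.pos, pop.phase)
                e_in = maps.inward(pop.pos, pop.phase)
                direction = np.where(crowded[:, None], e_out[si], e_in[si])
                w = np.where(pop.phase[si] == VASCULAR, params.omega, params.omega_av)
                np.add.at(vec, si, w[:, None] * mag[:, None] * direction)
    return vec


def _overlap_resolution(pop: Population, params: ModelParams,
                        rng: np.random.Generator,
                        movable: np.ndarray | None = None) -> None:
    """Separate pairs closer than the pairwise repulsion distance.

    Immovable agents (e.g. the static avascular phase of the baseline
    modes) absorb no displacement; their partner takes the full push.
    """
    cutoff = 2.0 * pop.a.max() * params.r_c / params.r_e
    pairs = neighbor_pairs(pop.pos, cutoff)
    if not len(pairs):
        return
    i, j = pairs[:, 0], pairs[:, 1]
    d = pop.pos[j] - pop.pos[i]
    L = np.linalg.norm(d, axis=1)
    zero = L < 1e-12
    if zero.any():
        ang = rng.uniform(-math.pi, math.pi, int(zero.sum()))
        d[zero] = np.stack([np.cos(ang), np.sin(ang)], axis=1) * 1e-12
        L[zero] = 1e-12
    L_c = pairwise_scales(pop.pos[i], pop.orient[i], pop.a[i], pop.b[i],
                          pop.pos[j], pop.orient[j], pop.a[j], pop.b[j]
                          ) * params.r_c / params.r_e
    close = L < L_c
    if not close.any():
        return
    gap = L_c[close] - L[close]
    e = d[close] / L[close, None]
    if movable is None:
        w_i = w_j = np.full(int(close.sum()), 0.5)
    else:
        mi = movable[i[close]].astype(float)
        mj = movable[j[close]].astype(float)
        tot = np.maximum(mi + mj, 1.0)
        w_i, w_j = mi / tot, mj / tot
    np.add.at(pop.pos, j[close], (w_j * gap)[:, None] * e)
    np.add.at(pop.pos, i[close], -(w_i * gap)[:, None] * e)


def _clamp(pop: Population, mask: VesselMask) -> int:
    w_ext, h_ext = mask.extent
    eps = mask.pixel_size / 2.0
    lo = np.array([eps, eps])
    hi = np.array([w_ext - eps, h_ext - eps])
    before = pop.pos.copy()
    np.clip(pop.pos, lo, hi, out=pop.pos)
    return int(np.any(pop.pos != before, axis=1).sum())


def simulate(mask: VesselMask, fields: FieldSet, params: ModelParams,
             duration: float, mode: str = "full", seed: int = 0,
             record_every: int | None = None,
             population: Population | None = None) -> SimulationResult:
    """Run the model for ``duration`` hours and return the trajectory.

    ``record_every`` controls how often (in steps) intermediate snapshots
    are kept; the initial and final states are always recorded.  Runs are
    bit-reproducible for identical inputs, parameters and seed.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    n_steps_f = duration / params.dt
    n_steps = int(round(n_steps_f))
    if abs(n_steps_f - n_steps) > 1e-9:
        raise ValueError("duration must be a multiple of the time-step")

    rng = np.random.default_rng(seed)
    pop = population.copy() if population is not None else seed_agents(
        mask, spacing=params.r_e, r_e=params.r_e)
    base_radius = params.r_e / 2.0
    curve = SpeedCurve(params.v_max, params.tau_max)

    need_maps = mode == "full" and (params.omega > 0 or params.omega_av > 0)
    maps = RemodellingMaps(mask) if need_maps else None

    snapshots: list[tuple[float, Population]] = [(0.0, pop.copy())]
    n_edge_clamped = 0

    for step in range(n_steps):
        t = step * params.dt
        if mode == "full":
            # (1) + (2): cluster expansion and elongation
            if pop.avascular.any() and params.delta_av > 0:
                if params.delta_av_per_step:
                    g0, g1 = 1.0 + params.delta_av * step, 1.0 + params.delta_av * (step + 1)
                else:
                    g0, g1 = 1.0 + params.delta_av * t, 1.0 + params.delta_av * (t + params.dt)
                ratio = g1 / g0
                centroids = label_avascular_clusters(pop)
                av = pop.avascular
                for cid, cen in centroids.items():
                    m = av & (pop.cluster == cid)
                    pop.pos[m] = cen + (pop.pos[m] - cen) * ratio
                pop.a[av] = g1 * base_radius
                pop.b[av] = g1 * base_radius
            vasc = pop.vascular
            if params.delta > 0 and vasc.any():
                _, _, flow_angle = _sample_fields(pop, mask, fields)
                ok = vasc & np.isfinite(flow_angle)
                pop.orient[ok] = flow_angle[ok]
                pop.a[vasc] = (1.0 + params.delta * (step + 1)) * base_radius

        # (3) headings, synchronous from the current state
        pref, tau, _ = _sample_fields(pop, mask, fields)
        vasc = pop.vascular
        if mode == "random":
            new_theta = pop.theta.copy()
            new_theta[vasc] = rng.uniform(-math.pi, math.pi, int(vasc.sum()))
            moving = vasc.copy()
        else:
            vec = _heading_vectors(pop, params, pref, tau, maps,
                                   gregoire=(mode == "gregoire"))
            norm = np.linalg.norm(vec, axis=1)
            moving = norm > params.speed_threshold
            xi = rng.uniform(-math.pi, math.pi, len(pop))
            base = np.where(moving, np.arctan2(vec[:, 1], vec[:, 0]), pop.theta)
            new_theta = base + params.nu * xi
            if mode == "gregoire":
                moving &= vasc
        pop.theta = new_theta

        # (4) moves
        speed = np.zeros(len(pop))
        speed[vasc] = curve(tau[vasc])
        if mode == "full":
            speed[~vasc] = params.v_av
        speed *= moving
        pop.pos += (speed * params.dt)[:, None] * np.stack(
            [np.cos(pop.theta), np.sin(pop.theta)], axis=1)
        n_edge_clamped += _clamp(pop, mask)

        # (5) overlap resolution
        movable = None if mode == "full" else pop.vascular
        _overlap_resolution(pop, params, rng, movable)

        if need_maps and (step + 1) % params.maps_refresh_steps == 0 and step + 1 < n_steps:
            from .evaluation import rasterize_agents

            current = rasterize_agents(pop, mask.shape, mask.pixel_size)
            if current.grid.any():
                maps = RemodellingMaps(current)

        if record_every and (step + 1) % record_every == 0 and step + 1 < n_steps:
            snapshots.append(((step + 1) * params.dt, pop.copy()))

    if n_steps > 0:
        snapshots.append((n_steps * params.dt, pop.copy()))
    if n_edge_clamped:
        log.info("clamped %d agent moves at the raster edge", n_edge_clamped)
    return SimulationResult(snapshots, params, mode, seed, duration)


def relax(pop: Population, params: ModelParams, speed: float,
          tol_disp: float = 1e-4, max_steps: int = 100000,
          maps: RemodellingMaps | None = None) -> tuple[Population, int]:
    """Drive a population to the steady state of its force field.

    Iterates the model's own heading/position update (no flow, no noise)
    at the given speed, halving the time-step whenever any agent's
    displacement reverses direction; stops when the largest per-step
    displacement falls below ``tol_disp`` (um).  Agents whose net force
    vector vanishes stop moving, so force equilibria are fixed points.
    """
    pop = pop.copy()
    n = len(pop)
    pref = np.zeros((n, 2))
    tau = np.zeros(n)
    dt = params.dt
    prev_disp = None
    for step in range(max_steps):
        vec = _heading_vectors(pop, params, pref, tau, maps)
        norm = np.linalg.norm(vec, axis=1)
        moving = norm > params.speed_threshold
        theta = np.where(moving, np.arctan2(vec[:, 1], vec[:, 0]), pop.theta)
        disp = (speed * dt * moving)[:, None] * np.stack(
            [np.cos(theta), np.sin(theta)], axis=1)
        if prev_disp is not None and dt > 1e-12:
            if np.any((disp * prev_disp).sum(axis=1) < -1e-18):
                # an agent overshot its equilibrium: bisect the step
                dt /= 2.0
                disp = (speed * dt * moving)[:, None] * np.stack(
                    [np.cos(theta), np.sin(theta)], axis=1)
        if np.abs(disp).max() < tol_disp:
            return pop, step
        pop.theta = theta
        pop.pos += disp
        prev_disp = disp
    return pop, max_steps


@dataclass
class SyntheticTimelapse:
    """A simulated before/after mask pair with known generating parameters."""

    initial_mask: VesselMask
    final_mask: VesselMask
    truth: ModelParams
    seed: int
    duration: float
    result: SimulationResult = field(repr=False, default=None)


def make_synthetic_timelapse(mask: VesselMask, fields: FieldSet,
                             params: ModelParams, duration: float,
                             seed: int = 0, flexibility: float = 0.25) -> SyntheticTimelapse:
    """Forward-simulate a geometry and rasterize the before/after masks.

    The pair (initial, final) plays the role of an observed time-lapse
    whose ground-truth parameters are known, enabling parameter-recovery
    experiments for the grid search.
    """
    from .evaluation import fill_small_holes, flexibility_radius, rasterize_agents

    res = simulate(mask, fields, params, duration, mode="full", seed=seed)
    masks = []
    for pop in (res.initial, res.final):
        raster = rasterize_agents(pop, mask.shape, mask.pixel_size)
        rad = flexibility_radius(pop, mask.pixel_size, flexibility)
        masks.append(fill_small_holes(raster, rad))
    return SyntheticTimelapse(masks[0], masks[1], params, seed, duration, res)
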