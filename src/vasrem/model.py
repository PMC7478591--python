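"""Agents, model parameters, seeding and neighbourhood structure.

Two agent phases partition the tissue: vascular agents are endothelial
tissue inside the lumen (they migrate against flow and elongate), and
avascular agents fill the space between vessels (they expand about their
cluster's centre of mass).  Agents start circular with diameter r_e = 7 um
and are packed on a triangular lattice at pitch r_e, the phase of each
agent taken from the mask pixel under its centre.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import VesselMask

__all__ = [
    "VASCULAR",
    "AVASCULAR",
    "Agent",
    "ModelParams",
    "Population",
    "seed_agents",
    "label_avascular_clusters",
    "neighbors",
    "neighbor_pairs",
]

VASCULAR = 0
AVASCULAR = 1


@dataclass
class ModelParams:
    """All weights, interaction distances and rates of the remodelling model.

    Heading-update weights (dimensionless): ``alpha`` flow alignment,
    ``beta`` vascular-vascular body force, ``zeta`` shear-gradient term,
    ``omega`` remodelling force, ``kappa`` avascular-on-vascular body
    force, ``nu`` white-noise weight (often printed as eta), plus the
    avascular analogues ``beta_av``, ``kappa_av``, ``omega_av``.

    Interaction distances in um: repulsion r_c < equilibrium r_e <
    maximum-extent r_a < cutoff r_o.  Speeds in um/h; shear in Pa;
    ``delta`` is the per-step additive elongation of the semi-major axis,
    ``delta_av`` the per-hour additive radial growth of avascular
    clusters; ``dt`` the time-step in hours (5 min).
    """

    alpha: float = 100.0
    beta: float = 40.0
    zeta: float = 0.0
    omega: float = 20.0
    kappa: float = 20.0
    nu: float = 0.1
    beta_av: float = 100.0
    kappa_av: float = 10.0
    omega_av: float = 10.0
    r_c: float = 5.0
    r_e: float = 7.0
    r_a: float = 9.0
    r_o: float = 11.0
    v_max: float = 12.0
    tau_max: float = 0.033
    v_av: float = 8.4
    delta: float = 0.003125
    delta_av: float = 0.042
    delta_av_per_step: bool = False
    dt: float = 1.0 / 12.0
    repulsion_cap: float = 10.0
    normalize_ellipse_force: bool = True
    speed_threshold: float = 1e-6
    maps_refresh_steps: int = 12

    def __post_init__(self) -> None:
        if not (self.r_c < self.r_e < self.r_a < self.r_o):
            raise ValueError("interaction distances must satisfy r_c < r_e < r_a < r_o")
        for name in ("alpha", "beta", "zeta", "omega", "kappa", "nu",
                     "beta_av", "kappa_av", "omega_av"):
            if getattr(self, name) < 0:
                raise ValueError(f"weight {name} must be non-negative")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class Agent:
    """A single particle: position, heading, ellipse shape and phase."""

    position: np.ndarray
    theta: float = 0.0          # migration heading, rad
    orient: float = 0.0         # ellipse major-axis angle, rad
    a: float = 3.5              # semi-major axis, um
    b: float = 3.5              # semi-minor axis, um
    phase: int = VASCULAR
    cluster: int = -1           # avascular cluster label, -1 for vascular

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not (self.a >= self.b > 0):
            raise ValueError("semi-axes must satisfy a >= b > 0")


class Population:
    """Struct-of-arrays container for all agents of both phases."""

    COLUMNS = ("id", "phase", "x_um", "y_um", "theta_rad", "orient_rad",
               "a_um", "b_um", "cluster_id")

    def __init__(self, pos, theta, orient, a, b, phase, cluster):
        self.pos = np.ascontiguousarray(pos, dtype=float).reshape(-1, 2)
        n = len(self.pos)
        self.theta = np.ascontiguousarray(theta, dtype=float).reshape(n)
        self.orient = np.ascontiguousarray(orient, dtype=float).reshape(n)
        self.a = np.ascontiguousarray(a, dtype=float).reshape(n)
        self.b = np.ascontiguousarray(b, dtype=float).reshape(n)
        self.phase = np.ascontiguousarray(phase, dtype=np.int8).reshape(n)
        self.cluster = np.ascontiguousarray(cluster, dtype=np.int64).reshape(n)
        if np.any(self.a < self.b) or np.any(self.b <= 0):
            raise ValueError("semi-axes must satisfy a >= b > 0")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def vascular(self) -> np.ndarray:
        return self.phase == VASCULAR

    @property
    def avascular(self) -> np.ndarray:
        return self.phase == AVASCULAR

    def agent(self, i: int) -> Agent:
        return Agent(self.pos[i].copy(), float(self.theta[i]), float(self.orient[i]),
                     float(self.a[i]), float(self.b[i]), int(self.phase[i]),
                     int(self.cluster[i]))

    def copy(self) -> "Population":
        return Population(self.pos.copy(), self.theta.copy(), self.orient.copy(),
                          self.a.copy(), self.b.copy(), self.phase.copy(),
                          self.cluster.copy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(len(self)),
                "phase": np.where(self.vascular, "vascular", "avascular"),
                "x_um": self.pos[:, 0],
                "y_um": self.pos[:, 1],
                "theta_rad": self.theta,
                "orient_rad": self.orient,
                "a_um": self.a,
                "b_um": self.b,
                "cluster_id": self.cluster,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Population":
        phase = np.where(df["phase"].to_numpy() == "vascular", VASCULAR, AVASCULAR)
        orient = df["orient_rad"].to_numpy() if "orient_rad" in df else np.zeros(len(df))
        return cls(
            np.stack([df["x_um"].to_numpy(), df["y_um"].to_numpy()], axis=1),
            df["theta_rad"].to_numpy(), orient,
            df["a_um"].to_numpy(), df["b_um"].to_numpy(), phase,
            df["cluster_id"].to_numpy(),
        )


def seed_agents(mask: VesselMask, spacing: float | None = None,
                r_e: float = 7.0) -> Population:
    """Seed both phases on a triangular lattice clipped to the mask.

    Lattice pitch defaults to r_e, so interior agents sit at their
    equilibrium separation.  Each agent takes the phase of the pixel under
    its centre; avascular agents are labelled by the connected component
    (8-connectivity) of the avascular region they fall in.  Deterministic:
    the same mask and spacing always give the identical agent list.
    """
    if spacing is None:
        spacing = r_e
    if not spacing > 0:
        raise ValueError("spacing must be positive")
    w_ext, h_ext = mask.extent
    dy = spacing * math.sqrt(3) / 2.0
    n_rows = int((h_ext - spacing / 2.0) // dy) + 1
    pts = []
    for k in range(n_rows):
        y = spacing / 2.0 + k * dy
        x0 = spacing / 2.0 + (spacing / 2.0 if k % 2 else 0.0)
        xs = np.arange(x0, w_ext, spacing)
        pts.append(np.stack([xs, np.full_like(xs, y)], axis=1))
    pos = np.concatenate(pts, axis=0)

    rows, cols = mask.pixel_of(pos)
    vasc = mask.grid[rows, cols]
    labels, _ = ndimage.label(~mask.grid, structure=np.ones((3, 3), dtype=bool))
    cluster = np.where(vasc, -1, labels[rows, cols]).astype(np.int64)
    phase = np.where(vasc, VASCULAR, AVASCULAR).astype(np.int8)

    for ph, name, present in ((VASCULAR, "vascular", mask.grid.any()),
                              (AVASCULAR, "avascular", (~mask.grid).any())):
        if present and not np.any(phase == ph):
            warnings.warn(f"no {name} agents placed although the mask has {name} pixels",
                          stacklevel=2)

    n = len(pos)
    r = r_e / 2.0
    return Population(pos, np.zeros(n), np.zeros(n), np.full(n, r), np.full(n, r),
                      phase, cluster)


def label_avascular_clusters(pop: Population) -> dict[int, np.ndarray]:
    """Centre of mass (arithmetic mean position) of each avascular cluster."""
    out: dict[int, np.ndarray] = {}
    av = pop.avascular
    if not av.any():
        raise ValueError("population has no avascular agents")
    for cid in np.unique(pop.cluster[av]):
        members = av & (pop.cluster == cid)
        out[int(cid)] = pop.pos[members].mean(axis=0)
    return out


def neighbors(pop: Population, i: int, cutoff: float) -> np.ndarray:
    """Indices of agents within ``cutoff`` of agent i (self excluded)."""
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    d = np.linalg.norm(pop.pos - pop.pos[i], axis=1)
    hit = (d <= cutoff)
    hit[i] = False
    return np.flatnonzero(hit)


def neighbor_pairs(pos: np.ndarray, cutoff: float) -> np.ndarray:
    """All pairs (i < j) with centre distance <= cutoff, via a k-d tree."""
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=int)
    return pairs
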