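"""Image-based evaluation of model predictions against observed masks.

The agent state is converted to a binary vessel prediction and scored
against an observed mask with the same post-processing used for the
time-lapse comparisons: (1) rasterize the vascular agents as filled
ellipses, (2) morphological closing with a disk whose radius is 25% of
the current semi-major axis (hole "flexibility"), (3) isotropic scaling
about the mask centroid to compensate for overall tissue growth the model
does not simulate (11% by default), (4) rigid registration (rotation +
translation) maximizing Dice overlap, and finally (5) the Hausdorff
distance between mask boundaries and the Dice coefficient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff
from skimage.morphology import disk

from .geometry import VesselMask
from .model import Population

__all__ = [
    "rasterize_agents",
    "flexibility_radius",
    "fill_small_holes",
    "scale_mask",
    "RigidTransform",
    "RegistrationResult",
    "rigid_register",
    "hausdorff_distance",
    "dice_coefficient",
    "SimilarityReport",
    "evaluate_prediction",
]


def rasterize_agents(pop: Population, shape: tuple[int, int],
                     pixel_size: float = 1.0) -> VesselMask:
    """Union of the filled vascular ellipses; a pixel is set when its
    centre lies inside (or on) an agent's boundary."""
    grid = np.zeros(shape, dtype=bool)
    idx = np.flatnonzero(pop.vascular)
    for i in idx:
        cx, cy = pop.pos[i]
        a, b, th = pop.a[i], pop.b[i], pop.orient[i]
        r0 = max(int((cy - a) / pixel_size) - 1, 0)
        r1 = min(int((cy + a) / pixel_size) + 2, shape[0])
        c0 = max(int((cx - a) / pixel_size) - 1, 0)
        c1 = min(int((cx + a) / pixel_size) + 2, shape[1])
        if r0 >= r1 or c0 >= c1:
            continue
        cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        x = (cols + 0.5) * pixel_size - cx
        y = (rows + 0.5) * pixel_size - cy
        xr = x * math.cos(th) + y * math.sin(th)
        yr = -x * math.sin(th) + y * math.cos(th)
        inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        grid[r0:r1, c0:c1] |= inside
    return VesselMask(grid, pixel_size)


def flexibility_radius(pop: Population, pixel_size: float,
                       flexibility: float = 0.25) -> int:
    """Closing-disk radius: the given fraction of the mean semi-major axis."""
    if not pop.vascular.any():
        return 0
    return int(round(flexibility * float(pop.a[pop.vascular].mean()) / pixel_size))


def fill_small_holes(mask: VesselMask, dilation_radius: int) -> VesselMask:
    """Morphological closing: fills holes up to the disk radius, restores
    larger holes to their original size.  Radius 0 is the identity."""
    if dilation_radius < 0:
        raise ValueError("dilation_radius must be >= 0")
    if dilation_radius == 0:
        return VesselMask(mask.grid.copy(), mask.pixel_size)
    r = int(dilation_radius)
    padded = np.pad(mask.grid, r, mode="constant", constant_values=False)
    closed = ndimage.binary_closing(padded, structure=disk(r))
    return VesselMask(closed[r:-r, r:-r], mask.pixel_size)


def scale_mask(mask: VesselMask, factor: float) -> VesselMask:
    """Isotropic nearest-neighbour scaling about the foreground centroid.

    If the scaled content would leave the raster, the canvas is padded
    symmetrically (with a warning) so nothing is clipped.
    """
    if not factor > 0:
        raise ValueError("scale factor must be positive")
    if factor == 1.0:
        return VesselMask(mask.grid.copy(), mask.pixel_size)
    grid = mask.grid
    if not grid.any():
        return VesselMask(grid.copy(), mask.pixel_size)
    fg = np.argwhere(grid)
    cen = fg.mean(axis=0)
    # required margin after scaling
    reach = np.abs(fg - cen).max(axis=0) * factor
    pad_r = max(0, int(math.ceil(reach[0] + cen[0] + 2 - grid.shape[0])),
                int(math.ceil(reach[0] - cen[0] + 2)))
    pad_c = max(0, int(math.ceil(reach[1] + cen[1] + 2 - grid.shape[1])),
                int(math.ceil(reach[1] - cen[1] + 2)))
    if pad_r or pad_c:
        warnings.warn("scaled content exceeds the raster: padding the canvas",
                      stacklevel=2)
        grid = np.pad(grid, ((pad_r, pad_r), (pad_c, pad_c)))
        cen = cen + np.array([pad_r, pad_c])
    rows, cols = np.meshgrid(np.arange(grid.shape[0]), np.arange(grid.shape[1]),
                             indexing="ij")
    src_r = cen[0] + (rows - cen[0]) / factor
    src_c = cen[1] + (cols - cen[1]) / factor
    out = ndimage.map_coordinates(grid.astype(np.uint8), [src_r, src_c],
                                  order=0, mode="constant", cval=0)
    return VesselMask(out.astype(bool), mask.pixel_size)


@dataclass
class RigidTransform:
    """Detected pose of the moving mask relative to the fixed mask.

    ``rotation`` (rad, about the moving mask's centroid) and ``shift``
    (dy, dx in px) describe the displacement that maps the fixed frame
    onto the moving mask; registration applies the inverse.
    """

    rotation: float = 0.0
    shift: tuple[float, float] = (0.0, 0.0)


@dataclass
class RegistrationResult:
    transform: RigidTransform
    moving_registered: VesselMask
    fixed_padded: VesselMask
    dice: float
    dice_unregistered: float


def _embed(grid: np.ndarray, shape: tuple[int, int], margin: int) -> np.ndarray:
    out = np.zeros((shape[0] + 2 * margin, shape[1] + 2 * margin), dtype=bool)
    out[margin:margin + grid.shape[0], margin:margin + grid.shape[1]] = grid
    return out


def _rotate_about_centroid(grid: np.ndarray, angle_rad: float) -> np.ndarray:
    if angle_rad == 0.0:
        return grid
    cen = np.argwhere(grid).mean(axis=0)
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    mat = np.array([[c, -s], [s, c]])  # inverse map for output->input
    offset = cen - mat @ cen
    out = ndimage.affine_transform(grid.astype(np.uint8), mat, offset=offset,
                                   order=0, mode="constant", cval=0)
    return out.astype(bool)


def _best_shift(fixed: np.ndarray, moving: np.ndarray, max_shift: int):
    """Integer displacement of ``moving`` maximizing overlap with ``fixed``.

    Circular FFT cross-correlation C[d] = sum_x moving[x] * fixed[x + d];
    the embedding margin guarantees no wrap-around within +/- max_shift.
    """
    C = np.fft.irfft2(np.fft.rfft2(fixed) * np.conj(np.fft.rfft2(moving.astype(float))),
                      s=fixed.shape)
    offs = np.arange(-max_shift, max_shift + 1)
    win = C[np.ix_(offs % fixed.shape[0], offs % fixed.shape[1])]
    k = np.unravel_index(np.argmax(win), win.shape)
    return (int(offs[k[0]]), int(offs[k[1]])), float(round(win[k]))


def rigid_register(moving: VesselMask, fixed: VesselMask,
                   rot_range_deg: float = 10.0, rot_step_deg: float = 0.5,
                   max_shift: int = 20, objective: str = "dice",
                   refine: bool = True) -> RegistrationResult:
    """Find the rotation + translation overlaying ``moving`` on ``fixed``.

    A coarse sweep over rotations (each scored by the best FFT-derived
    translation) is followed by a finer rotation sweep around the best
    angle.  The identity is always part of the search, so registration
    never scores below the unregistered overlay.  ``objective`` is
    ``"dice"`` (maximized, default) or ``"hausdorff"`` (the best few dice
    candidates re-ranked by boundary Hausdorff distance).
    """
    if not moving.grid.any() or not fixed.grid.any():
        raise ValueError("cannot register an empty mask")
    if moving.pixel_size != fixed.pixel_size:
        raise ValueError("pixel sizes differ")
    shape = (max(moving.shape[0], fixed.shape[0]), max(moving.shape[1], fixed.shape[1]))
    margin = max_shift + 2
    f = _embed(fixed.grid, shape, margin)
    m = _embed(moving.grid, shape, margin)
    n_fixed = int(f.sum())

    def score(angle_rad):
        rot = _rotate_about_centroid(m, angle_rad)
        (dy, dx), inter = _best_shift(f, rot, max_shift)
        dsc = 2.0 * inter / (n_fixed + rot.sum())
        return dsc, (dy, dx), rot

    angles = np.deg2rad(np.arange(-rot_range_deg, rot_range_deg + 1e-9, rot_step_deg))
    if 0.0 not in angles:
        angles = np.sort(np.append(angles, 0.0))
    candidates = []
    for ang in angles:
        dsc, sh, _ = score(ang)
        candidates.append((dsc, float(ang), sh))
    # on ties (e.g. exact overlays) prefer the smallest rotation
    candidates.sort(key=lambda c: (-c[0], abs(c[1])))
    best_dsc, best_ang, best_sh = candidates[0]

    if refine and rot_step_deg > 0.1:
        fine = np.deg2rad(np.arange(-rot_step_deg, rot_step_deg + 1e-9, 0.1))
        for d_ang in fine:
            ang = best_ang + float(d_ang)
            dsc, sh, _ = score(ang)
            if dsc > best_dsc:
                best_dsc, best_ang, best_sh = dsc, ang, sh

    if objective == "hausdorff":
        pool = [(best_dsc, best_ang, best_sh)] + candidates[:10]
        best_h = np.inf
        for dsc, ang, sh in pool:
            reg = np.roll(_rotate_about_centroid(m, ang), sh, axis=(0, 1))
            h = hausdorff_distance(VesselMask(reg, fixed.pixel_size),
                                   VesselMask(f, fixed.pixel_size))
            if h < best_h:
                best_h, best_dsc, best_ang, best_sh = h, dsc, ang, sh

    registered = np.roll(_rotate_about_centroid(m, best_ang), best_sh, axis=(0, 1))
    dsc0 = dice_coefficient(VesselMask(m, fixed.pixel_size),
                            VesselMask(f, fixed.pixel_size))
    # detected pose: moving sits at +rotation/+shift relative to fixed
    transform = RigidTransform(rotation=-best_ang,
                               shift=(-best_sh[0], -best_sh[1]))
    return RegistrationResult(transform, VesselMask(registered, fixed.pixel_size),
                              VesselMask(f, fixed.pixel_size), float(best_dsc), dsc0)


def _boundary_points(mask: VesselMask) -> np.ndarray:
    grid = mask.grid
    eroded = ndimage.binary_erosion(
        grid, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
        border_value=1)
    pts = np.argwhere(grid & ~eroded)
    if len(pts) == 0:  # mask with no interior
        pts = np.argwhere(grid)
    return pts


def hausdorff_distance(a: VesselMask, b: VesselMask, boundary: bool = True) -> float:
    """Symmetric Hausdorff distance between two masks, in micrometres.

    Computed over boundary pixels by default (the distance between the two
    outlines); set ``boundary=False`` for the full pixel sets.
    """
    if not a.grid.any() or not b.grid.any():
        raise ValueError("Hausdorff distance of an empty mask is undefined")
    if a.pixel_size != b.pixel_size:
        raise ValueError("pixel sizes differ")
    pa = _boundary_points(a) if boundary else np.argwhere(a.grid)
    pb = _boundary_points(b) if boundary else np.argwhere(b.grid)
    d = max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])
    return float(d) * a.pixel_size


def dice_coefficient(a: VesselMask, b: VesselMask) -> float:
    """Dice similarity 2|A n B| / (|A| + |B|) on the pixel sets."""
    ga, gb = a.grid, b.grid
    if ga.shape != gb.shape:
        raise ValueError("masks must share a pixel grid")
    na, nb = int(ga.sum()), int(gb.sum())
    if na == 0 and nb == 0:
        warnings.warn("both masks empty: Dice defined as 1", stacklevel=2)
        return 1.0
    return 2.0 * int((ga & gb).sum()) / (na + nb)


@dataclass
class SimilarityReport:
    """Registered-overlay similarity between a prediction and observation."""

    hausdorff_um: float
    hausdorff_px: float
    dice: float
    transform: RigidTransform
    scale_factor: float
    dice_unregistered: float

    def to_dict(self) -> dict:
        return {
            "hausdorff_um": self.hausdorff_um,
            "hausdorff_px": self.hausdorff_px,
            "dice": self.dice,
            "rotation_rad": self.transform.rotation,
            "shift_px": list(self.transform.shift),
            "scale_factor": self.scale_factor,
            "dice_unregistered": self.dice_unregistered,
        }


def evaluate_prediction(pop: Population, observed: VesselMask,
                        scale_factor: float = 1.11, flexibility: float = 0.25,
                        **register_kwargs) -> SimilarityReport:
    """Score a final agent state against an observed final mask.

    Pipeline: rasterize -> close small holes -> scale -> rigid
    registration -> Hausdorff + Dice on the registered overlay.
    """
    pred = rasterize_agents(pop, observed.shape, observed.pixel_size)
    pred = fill_small_holes(pred, flexibility_radius(pop, observed.pixel_size, flexibility))
    pred = scale_mask(pred, scale_factor)
    reg = rigid_register(pred, observed, **register_kwargs)
    d_um = hausdorff_distance(reg.moving_registered, reg.fixed_padded)
    dsc = dice_coefficient(reg.moving_registered, reg.fixed_padded)
    return SimilarityReport(
        hausdorff_um=d_um, hausdorff_px=d_um / observed.pixel_size, dice=dsc,
        transform=reg.transform, scale_factor=scale_factor,
        dice_unregistered=reg.dice_unregistered)
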