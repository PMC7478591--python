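"""Grid-search parameter calibration and one-at-a-time sensitivity analysis.

Calibration mirrors the staged procedure used to fit the model to
time-lapse data: parameters are optimised in three groups -- the speed
curve (V_max, tau_max), the directional weights (alpha, zeta) and the
inter-agent force weights (beta, kappa, omega) -- by exhaustively
evaluating a Cartesian grid.  Each grid cell simulates every evaluation
case with every replicate seed and is scored by the Hausdorff distance of
the registered prediction; the default objective is the mean over cases
(a minimax option scores by the worst case instead).  The avascular
weights are not searched; they stay at their defaults.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import simulate
from .evaluation import evaluate_prediction
from .geometry import FieldSet, VesselMask
from .model import ModelParams

__all__ = [
    "CalibrationCase",
    "GridSpec",
    "CalibrationResult",
    "grid_search",
    "sensitivity_analysis",
    "default_grids",
]

log = logging.getLogger(__name__)

SEARCHABLE = ("v_max", "tau_max", "alpha", "zeta", "beta", "kappa", "omega")


@dataclass
class CalibrationCase:
    """One evaluation case: an initial geometry plus the observed outcome."""

    mask: VesselMask
    fields: FieldSet
    observed_final: VesselMask
    duration: float = 4.0


@dataclass
class GridSpec:
    """Named parameter axes (ModelParams field names) with value lists."""

    axes: dict[str, list[float]]
    objective: str = "mean"  # 'mean' or 'max' (minimax over cases)

    def __post_init__(self) -> None:
        if not self.axes:
            raise ValueError("grid needs at least one axis")
        for name, values in self.axes.items():
            if name not in SEARCHABLE:
                raise ValueError(f"unknown or non-searchable parameter {name!r}")
            if len(values) == 0:
                raise ValueError(f"axis {name!r} has no values")
        if self.objective not in ("mean", "max"):
            raise ValueError("objective must be 'mean' or 'max'")


@dataclass
class CalibrationResult:
    table: pd.DataFrame
    best: dict
    objective: str
    seeds: tuple[int, ...]

    @property
    def best_params(self) -> dict[str, float]:
        return {k: v for k, v in self.best.items() if k in SEARCHABLE}


def _evaluate_cell(params: ModelParams, cases, seeds, mode, eval_options) -> tuple[float, float]:
    d_hs, dscs = [], []
    for case in cases:
        per_seed = []
        per_seed_dsc = []
        for seed in seeds:
            res = simulate(case.mask, case.fields, params, case.duration,
                           mode=mode, seed=seed)
            rep = evaluate_prediction(res.final, case.observed_final, **eval_options)
            per_seed.append(rep.hausdorff_um)
            per_seed_dsc.append(rep.dice)
        d_hs.append(float(np.mean(per_seed)))
        dscs.append(float(np.mean(per_seed_dsc)))
    return d_hs, dscs


def grid_search(grid: GridSpec, base_params: ModelParams,
                cases: list[CalibrationCase], seeds=(0, 1, 2),
                mode: str = "full", eval_options: dict | None = None) -> CalibrationResult:
    """Exhaustively evaluate the Cartesian parameter grid.

    Deterministic given the seeds.  A cell whose simulation fails is
    recorded with a NaN objective and an error note instead of aborting
    the sweep.  The returned table is ranked by the objective (ascending
    Hausdorff distance) and the optimum is its first row.
    """
    if not cases:
        raise ValueError("at least one evaluation case is required")
    eval_options = dict(eval_options or {})
    names = list(grid.axes)
    rows = []
    for combo in itertools.product(*(grid.axes[n] for n in names)):
        params = replace(base_params, **dict(zip(names, combo)))
        row = dict(zip(names, combo))
        try:
            d_hs, dscs = _evaluate_cell(params, cases, seeds, mode, eval_options)
            agg = np.mean if grid.objective == "mean" else np.max
            row["d_h"] = float(agg(d_hs))
            row["dsc"] = float(np.mean(dscs))
            for k, (dh, ds) in enumerate(zip(d_hs, dscs)):
                row[f"d_h_case{k}"] = dh
                row[f"dsc_case{k}"] = ds
            row["error"] = ""
        except Exception as exc:  # cell marked invalid, sweep continues
            log.warning("grid cell %s failed: %s", row, exc)
            row["d_h"] = np.nan
            row["dsc"] = np.nan
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        "d_h", na_position="last", kind="mergesort").reset_index(drop=True)
    if table["d_h"].isna().all():
        raise RuntimeError("every grid cell failed")
    return CalibrationResult(table, dict(table.iloc[0]), grid.objective, tuple(seeds))


def sensitivity_analysis(params: ModelParams, cases: list[CalibrationCase],
                         seeds=(0, 1, 2), fractions=(-0.2, -0.1, 0.1, 0.2),
                         zeta_values=(10.0, 20.0, 30.0, 40.0),
                         mode: str = "full",
                         eval_options: dict | None = None) -> pd.DataFrame:
    """One-at-a-time perturbation of each optimised parameter.

    Every searchable parameter is perturbed by the given relative
    fractions and the change in the Hausdorff objective is reported; a
    parameter whose optimum is zero (the shear-gradient weight, when so
    calibrated) is probed with absolute increments instead.
    """
    eval_options = dict(eval_options or {})
    base_dh, _ = _evaluate_cell(params, cases, seeds, mode, eval_options)
    base = float(np.mean(base_dh))
    rows = [{"parameter": "baseline", "value": np.nan, "d_h": base, "delta_d_h": 0.0}]
    for name in SEARCHABLE:
        current = getattr(params, name)
        if current == 0:
            values = list(zeta_values)
        else:
            values = [current * (1.0 + f) for f in fractions]
        for value in values:
            perturbed = replace(params, **{name: value})
            try:
                d_hs, _ = _evaluate_cell(perturbed, cases, seeds, mode, eval_options)
                dh = float(np.mean(d_hs))
                rows.append({"parameter": name, "value": value, "d_h": dh,
                             "delta_d_h": dh - base})
            except Exception as exc:
                log.warning("sensitivity cell %s=%s failed: %s", name, value, exc)
                rows.append({"parameter": name, "value": value, "d_h": np.nan,
                             "delta_d_h": np.nan})
    return pd.DataFrame(rows)


def default_grids() -> dict[str, GridSpec]:
    """The three staged search grids (resolutions are package defaults)."""
    return {
        "speed": GridSpec({"v_max": [6, 8, 10, 12, 14],
                           "tau_max": [0.02, 0.033, 0.05, 0.1, 0.2, 0.5]}),
        "direction": GridSpec({"alpha": [0, 20, 40, 60, 80, 100],
                               "zeta": [0, 20, 40, 60, 80, 100]}),
        "forces": GridSpec({"beta": [0, 10, 20, 40, 60, 100, 200, 500, 1000],
                            "kappa": [0, 10, 20, 40, 60, 100, 200, 500, 1000],
                            "omega": [0, 10, 20, 40, 60, 100, 200, 500, 1000]}),
    }
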