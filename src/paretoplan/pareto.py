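"""Pareto dataset generation, multilinear navigation and calibration commit.

A *navigation dimension* is one goal parameter — either a P3 weighting factor
or a goal target — together with an ordered list of sampled values.  A
*Pareto dataset* holds one fully optimised plan for every element of the
cartesian product of the sampled values.  A continuous *navigation position*
inside the sampled hyper-rectangle is rendered by voxel-wise multilinear
interpolation of the 2^D corner plans of its enclosing grid cell, so metric
evaluation at a position never reruns optimisation (the real-time contract of
a slider interface).  Committing a position writes the navigated parameter
values back into the protocol, which is how calibration is stored.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dose_engine import BeamConfig, DoseDistribution, InfluenceMatrix, build_influence_matrix
from .metrics import MetricSpec, evaluate_metric
from .pbaio import PBAIOConfig, Plan, autoplan
from .phantom import PatientGeometry
from .protocol import AutoPlanProtocol

__all__ = [
    "NavigationDimension",
    "ParetoDataset",
    "NavigationPosition",
    "build_grid",
    "generate_dataset",
    "interpolate",
    "navigate_metrics",
    "commit_calibration",
    "merge_calibrations",
]

PRACTICAL_DIMENSION_LIMIT = 4  # beyond this the grid size explodes


@dataclasses.dataclass(frozen=True)
class NavigationDimension:
    """One navigated goal parameter with its sampled values."""

    roi: str
    goal_type: str
    kind: str                       # "weighting_factor" | "target"
    values: Tuple[float, ...]
    dose_level: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("weighting_factor", "target"):
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        vals = tuple(float(v) for v in self.values)
        if not 2 <= len(vals) <= 7:
            raise ValueError("each dimension needs 2-7 sampled values")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("sampled values must be strictly increasing")
        if self.kind == "weighting_factor" and vals[0] <= 0:
            raise ValueError("weighting-factor samples must be positive")
        object.__setattr__(self, "values", vals)

    def apply(self, protocol: AutoPlanProtocol, value: float) -> None:
        goal = protocol.find_goal(self.roi, self.goal_type, self.dose_level)
        if self.kind == "weighting_factor":
            goal.weighting_factor = float(value)
        else:
            goal.target = float(value)


NavigationPosition = Dict[str, float]  # dimension label -> continuous value


def _dim_label(dim: NavigationDimension) -> str:
    lvl = f"@{dim.dose_level:g}Gy" if dim.dose_level is not None else ""
    return f"{dim.roi}.{dim.goal_type}{lvl}.{dim.kind}"


@dataclasses.dataclass
class ParetoDataset:
    """Grid of optimised plans indexed by per-dimension sample indices."""

    dimensions: List[NavigationDimension]
    plans: Dict[Tuple[int, ...], Plan]
    protocol: AutoPlanProtocol
    geometry: PatientGeometry

    @property
    def labels(self) -> List[str]:
        return [_dim_label(d) for d in self.dimensions]

    def position_at_vertex(self, key: Tuple[int, ...]) -> NavigationPosition:
        return {lab: dim.values[i]
                for lab, dim, i in zip(self.labels, self.dimensions, key)}


def build_grid(dimensions: Sequence[NavigationDimension]) -> List[Tuple[float, ...]]:
    """Cartesian product of sampled values, lexicographic in dimension order."""
    if not dimensions:
        raise ValueError("at least one navigation dimension required")
    for d in dimensions:
        if not d.values:
            raise ValueError("empty navigation dimension")
    if len(dimensions) > PRACTICAL_DIMENSION_LIMIT:
        warnings.warn(
            f"{len(dimensions)} navigation dimensions: dataset size grows as the "
            "product of sample counts; navigation is typically kept below 5 dimensions",
            stacklevel=2)
    return list(itertools.product(*(d.values for d in dimensions)))


def generate_dataset(geometry: PatientGeometry, protocol: AutoPlanProtocol,
                     dimensions: Sequence[NavigationDimension],
                     beam_config: BeamConfig, pbaio_config: PBAIOConfig,
                     influence: Optional[InfluenceMatrix] = None) -> ParetoDataset:
    """Optimise one plan per parameter-value combination (shared geometry,
    seed and beam model across the whole dataset)."""
    for d in dimensions:
        protocol.find_goal(d.roi, d.goal_type, d.dose_level)  # raises if absent
    combos = build_grid(dimensions)
    if influence is None:
        influence = build_influence_matrix(geometry, beam_config)
    plans: Dict[Tuple[int, ...], Plan] = {}
    index_grid = list(itertools.product(*(range(len(d.values)) for d in dimensions)))
    for key, values in zip(index_grid, combos):
        proto = protocol.clone()
        for dim, v in zip(dimensions, values):
            dim.apply(proto, v)
        try:
            plans[key] = autoplan(geometry, proto, beam_config, pbaio_config,
                                  influence=influence)
        except Exception as exc:
            raise RuntimeError(
                f"autoplan failed for combination {dict(zip([_dim_label(d) for d in dimensions], values))}"
            ) from exc
    return ParetoDataset(list(dimensions), plans, protocol.clone(), geometry)


def _cell_and_coeffs(dataset: ParetoDataset, position: NavigationPosition):
    labels = dataset.labels
    missing = set(labels) ^ set(position)
    if missing:
        raise ValueError(f"position keys do not match dataset dimensions: {sorted(missing)}")
    lows, ts = [], []
    for lab, dim in zip(labels, dataset.dimensions):
        v = float(position[lab])
        vals = dim.values
        if not (vals[0] - 1e-12 <= v <= vals[-1] + 1e-12):
            raise ValueError(
                f"position {v} outside sampled range [{vals[0]}, {vals[-1]}] for {lab}")
        i = int(np.searchsorted(vals, v, side="right") - 1)
        i = min(max(i, 0), len(vals) - 2)
        lo, hi = vals[i], vals[i + 1]
        lows.append(i)
        ts.append((v - lo) / (hi - lo))
    return lows, ts


def interpolate(dataset: ParetoDataset, position: NavigationPosition) -> DoseDistribution:
    """Voxel-wise multilinear interpolation of the enclosing cell's corners."""
    lows, ts = _cell_and_coeffs(dataset, position)
    ndim = len(lows)
    out = None
    for corner in itertools.product((0, 1), repeat=ndim):
        w = 1.0
        for c, t in zip(corner, ts):
            w *= t if c else (1.0 - t)
        if w == 0.0:
            continue
        key = tuple(lo + c for lo, c in zip(lows, corner))
        contrib = w * dataset.plans[key].dose.values
        out = contrib if out is None else out + contrib
    return DoseDistribution(np.maximum(out, 0.0))


def navigate_metrics(dataset: ParetoDataset, position: NavigationPosition,
                     metric_specs: Sequence[MetricSpec],
                     reference: Optional[NavigationPosition] = None):
    """Evaluate metrics on the interpolated dose at ``position``.

    If ``reference`` is given its metrics are returned alongside (the
    reference-distribution snapshot of an interactive session).  Returns
    ``{label: value}`` or ``({...}, {...reference})``.
    """
    dose = interpolate(dataset, position)
    vals = {spec.label: evaluate_metric(spec, dose.values, dataset.geometry)
            for spec in metric_specs}
    if reference is None:
        return vals
    ref_dose = interpolate(dataset, reference)
    ref_vals = {spec.label: evaluate_metric(spec, ref_dose.values, dataset.geometry)
                for spec in metric_specs}
    return vals, ref_vals


def commit_calibration(dataset: ParetoDataset, position: NavigationPosition,
                       protocol: AutoPlanProtocol) -> AutoPlanProtocol:
    """Store the navigated parameter values in a copy of the protocol."""
    _cell_and_coeffs(dataset, position)  # validates range and keys
    out = protocol.clone()
    for lab, dim in zip(dataset.labels, dataset.dimensions):
        dim.apply(out, float(position[lab]))
    return out


def merge_calibrations(protocols: Sequence[AutoPlanProtocol],
                       method: str = "arithmetic") -> AutoPlanProtocol:
    """Average weighting factors across calibrations of the same protocol.

    Goal structure (ROI, type, priority, targets) must agree across inputs;
    P3 weighting factors are combined by arithmetic (default) or geometric
    mean.
    """
    if not protocols:
        raise ValueError("no protocols to merge")
    if method not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown mean {method!r}")
    base = protocols[0].clone()
    for other in protocols[1:]:
        if len(other.goals) != len(base.goals):
            raise ValueError("protocols have differing goal counts")
        for g0, g1 in zip(base.goals, other.goals):
            if g0.key() != g1.key() or g0.priority != g1.priority:
                raise ValueError(f"goal structure mismatch at {g0.key()}")
            if abs(g0.target - g1.target) > 1e-9:
                raise ValueError(f"goal targets disagree at {g0.key()}; cannot merge")
    for i, g in enumerate(base.goals):
        if g.priority != "P3":
            continue
        wfs = np.array([p.goals[i].weighting_factor for p in protocols], dtype=float)
        g.weighting_factor = (float(wfs.mean()) if method == "arithmetic"
                              else float(np.exp(np.log(wfs).mean())))
    return base
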