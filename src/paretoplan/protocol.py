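"""AutoPlan protocol data model, goal penalties and fall-off thresholds.

A protocol is an ordered list of planning goals split across three priority
levels: P1 critical normal-tissue goals, P2 target goals and P3 normal-tissue
trade-off goals.  P1/P2 optimiser weights are hard-coded constants (1000 and
250); P3 goals carry an explicit weighting factor (WF) that is set during
Pareto-navigation calibration and acts as the cross-patient trade-off
balancing knob.

Goal targets may be expressed in Gy, as a percentage of the goal ROI's own
PTV prescription (``%Presc,PTV``), as a percentage of the overall prescription
(``%Presc``), or — for dose-volume goals — as a percentage of ROI volume
(``%Vol``).

Penalty functions are quadratic, one-sided and volume-normalised (standard
TPS practice; differentiable), with exact analytic gradients with respect to
voxel doses:

* ``min_dose``            Σ max(0, T − d)² / N
* ``max_dose`` etc.       Σ max(0, d − T)² / N over the applicable region
* ``mean_dose``           max(0, mean(d) − T)²
* ``dv_max``              the violating low-dose tail of voxels above the
                          dose level is pulled toward it (see
                          :func:`_dv_tail`)
* fall-off goals          Σ max(0, d − threshold(v))² / N with a per-voxel
                          distance-based threshold map

``median_max`` (a D50% ceiling) is implemented as a dose-volume maximum at
50% volume.  ``max_dose`` goals are optimised on all voxels above target but
their *achieved* value for dynamic positioning uses the near-max D1%
surrogate; reported plan metrics use the true voxel maximum.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .phantom import PatientGeometry, conformality_shell

__all__ = [
    "PlanningGoal",
    "AutoPlanProtocol",
    "ObjectiveState",
    "GoalContext",
    "load_protocol",
    "save_protocol",
    "load_builtin_protocol",
    "load_builtin_goal_table",
    "resolve_target_dose",
    "resolve_falloff_gradient",
    "falloff_threshold_map",
    "prepare_goal_context",
    "goal_penalty",
    "goal_penalty_and_gradient",
    "composite_objective",
]

PRIORITIES = ("P1", "P2", "P3")
GOAL_TYPES = (
    "min_dose", "max_dose", "dv_max", "mean_dose", "median_max",
    "dose_falloff_external", "dose_falloff_intra", "conformality_max",
)
UNITS = ("Gy", "%Presc,PTV", "%Presc", "%Vol")
FALLOFF_TYPES = ("dose_falloff_external", "dose_falloff_intra")

_GOAL_FIELDS = {"roi", "priority", "goal_type", "target", "units",
                "weighting_factor", "falloff", "distance_cm", "dose_level"}
_FALLOFF_FIELDS = {"high_dose", "low_dose", "gradient"}
_PROTOCOL_FIELDS = {"name", "version", "institution", "prescriptions",
                    "prescription", "goals"}


@dataclasses.dataclass
class PlanningGoal:
    """One planning goal of an AutoPlan protocol."""

    roi: str
    priority: str
    goal_type: str
    target: float = 0.0
    units: str = "Gy"
    weighting_factor: Optional[float] = None
    dose_level: Optional[float] = None        # Gy; dv_max only ("VxGy" level)
    falloff: Optional[Dict[str, float]] = None  # high_dose, low_dose (Gy), gradient (%Presc/cm)
    distance_cm: Optional[float] = None       # conformality_max only

    def __post_init__(self):
        if self.priority not in PRIORITIES:
            raise ValueError(f"goal {self.roi}: unknown priority {self.priority!r}")
        if self.goal_type not in GOAL_TYPES:
            raise ValueError(f"goal {self.roi}: unknown goal_type {self.goal_type!r}")
        if self.units not in UNITS:
            raise ValueError(f"goal {self.roi}: unknown units {self.units!r}")
        is_falloff = self.goal_type in FALLOFF_TYPES
        if is_falloff != (self.falloff is not None):
            raise ValueError(
                f"goal {self.roi}: falloff parameters present iff goal is a fall-off type")
        if is_falloff:
            extra = set(self.falloff) - _FALLOFF_FIELDS
            if extra:
                raise ValueError(f"goal {self.roi}: unknown falloff fields {sorted(extra)}")
            if self.falloff["high_dose"] < self.falloff["low_dose"]:
                raise ValueError(f"goal {self.roi}: falloff high_dose < low_dose")
        if (self.goal_type == "conformality_max") != (self.distance_cm is not None):
            raise ValueError(
                f"goal {self.roi}: distance_cm present iff goal is conformality_max")
        if self.goal_type == "dv_max":
            if self.dose_level is None:
                raise ValueError(f"goal {self.roi}: dv_max requires dose_level")
            if self.units != "%Vol":
                raise ValueError(f"goal {self.roi}: dv_max target units must be %Vol")
        if self.priority == "P3":
            if self.weighting_factor is None or self.weighting_factor <= 0:
                raise ValueError(
                    f"goal {self.roi} ({self.goal_type}): P3 goals require weighting_factor > 0")

    def key(self) -> Tuple[str, str, Optional[float]]:
        """Identity used when addressing a goal (navigation, merging)."""
        return (self.roi, self.goal_type, self.dose_level)


@dataclasses.dataclass
class AutoPlanProtocol:
    """Named, validated set of planning goals plus prescriptions."""

    name: str
    institution: str
    prescriptions: Dict[str, float]
    prescription: float
    goals: List[PlanningGoal]
    version: int = 1

    def clone(self) -> "AutoPlanProtocol":
        return copy.deepcopy(self)

    def find_goal(self, roi: str, goal_type: str,
                  dose_level: Optional[float] = None) -> PlanningGoal:
        for g in self.goals:
            if g.roi == roi and g.goal_type == goal_type:
                if dose_level is None or (g.dose_level is not None
                                          and abs(g.dose_level - dose_level) < 1e-9):
                    return g
        raise KeyError(f"no goal ({roi}, {goal_type}, {dose_level}) in protocol {self.name!r}")

    def validate_against(self, geometry: PatientGeometry) -> None:
        for g in self.goals:
            geometry.mask(g.roi)  # raises naming the structure


@dataclasses.dataclass
class ObjectiveState:
    """Mutable optimisation state attached to one goal.

    ``dynamic_target`` is the moving objective position in the goal's native
    units (Gy for dose goals, %Vol for dose-volume goals); ``optimiser_weight``
    the current weight in the composite objective.
    """

    goal: PlanningGoal
    dynamic_target: float
    optimiser_weight: float
    last_penalty: float = 0.0

    def __post_init__(self):
        if self.optimiser_weight <= 0:
            raise ValueError("optimiser_weight must be positive")


# --- serialisation -----------------------------------------------------------

def _goal_from_dict(d: dict) -> PlanningGoal:
    extra = set(d) - _GOAL_FIELDS
    if extra:
        raise ValueError(f"unknown goal fields: {sorted(extra)}")
    return PlanningGoal(**d)


def _protocol_from_dict(d: dict) -> AutoPlanProtocol:
    extra = set(d) - _PROTOCOL_FIELDS
    if extra:
        raise ValueError(f"unknown protocol fields: {sorted(extra)}")
    for req in ("name", "prescriptions", "prescription", "goals"):
        if req not in d:
            raise ValueError(f"protocol missing required field {req!r}")
    goals = [_goal_from_dict(g) for g in d["goals"]]
    return AutoPlanProtocol(
        name=d["name"], institution=d.get("institution", ""),
        prescriptions={k: float(v) for k, v in d["prescriptions"].items()},
        prescription=float(d["prescription"]), goals=goals,
        version=int(d.get("version", 1)),
    )


def _protocol_to_dict(p: AutoPlanProtocol) -> dict:
    goals = []
    for g in p.goals:
        gd = {k: v for k, v in dataclasses.asdict(g).items() if v is not None}
        goals.append(gd)
    return {"name": p.name, "version": p.version, "institution": p.institution,
            "prescriptions": p.prescriptions, "prescription": p.prescription,
            "goals": goals}


def load_protocol(path) -> AutoPlanProtocol:
    """Load and strictly validate a protocol JSON file."""
    with open(path) as fh:
        return _protocol_from_dict(json.load(fh))


def save_protocol(protocol: AutoPlanProtocol, path) -> None:
    Path(path).write_text(json.dumps(_protocol_to_dict(protocol), indent=1) + "\n")


def load_builtin_protocol(profile: str) -> AutoPlanProtocol:
    """Packaged prostate protocol fixture: ``"instA"`` or ``"instB"``."""
    fname = {"instA": "protocol_instA.json", "instB": "protocol_instB.json"}[profile]
    with resources.files("paretoplan.data").joinpath(fname).open() as fh:
        return _protocol_from_dict(json.load(fh))


def load_builtin_goal_table(profile: str) -> List[dict]:
    """Packaged CHHiP-style clinical goal table for one institution profile."""
    fname = {"instA": "goals_instA.json", "instB": "goals_instB.json"}[profile]
    with resources.files("paretoplan.data").joinpath(fname).open() as fh:
        return json.load(fh)


# --- unit resolution ---------------------------------------------------------

def resolve_target_dose(goal: PlanningGoal, protocol: AutoPlanProtocol) -> float:
    """Goal target in Gy (``%Presc,PTV`` → ROI's PTV prescription; ``%Presc``
    → overall prescription; ``Gy`` passes through)."""
    if goal.units == "Gy":
        return float(goal.target)
    if goal.units == "%Presc,PTV":
        if goal.roi not in protocol.prescriptions:
            raise ValueError(
                f"%Presc,PTV goal on {goal.roi!r}, which has no PTV prescription")
        return goal.target / 100.0 * protocol.prescriptions[goal.roi]
    if goal.units == "%Presc":
        return goal.target / 100.0 * protocol.prescription
    raise ValueError(f"goal units {goal.units!r} do not resolve to a dose")


def resolve_falloff_gradient(goal: PlanningGoal, protocol: AutoPlanProtocol) -> float:
    """Fall-off gradient in Gy/cm from %Presc per cm."""
    return goal.falloff["gradient"] / 100.0 * protocol.prescription


# --- fall-off threshold maps -------------------------------------------------

def _ptvs_by_dose(protocol: AutoPlanProtocol, geometry: PatientGeometry):
    names = sorted(protocol.prescriptions, key=lambda n: -protocol.prescriptions[n])
    return [n for n in names if n in geometry.masks]


def falloff_threshold_map(goal: PlanningGoal, geometry: PatientGeometry,
                          protocol: AutoPlanProtocol):
    """Per-voxel fall-off dose threshold (Gy) and the region it applies to.

    ``threshold(v) = max(low, high − g · d(v))`` with ``d(v)`` the Euclidean
    voxel-centre distance (cm) from the fall-off source region.  For the
    external fall-off the source is the union of all PTVs and the region is
    external \\ PTVs; for an intra-PTV fall-off the source is the next
    higher-prescription PTV and the region the goal ROI minus all higher PTVs.

    Returns ``(threshold_3d, region_mask)``.
    """
    if goal.goal_type not in FALLOFF_TYPES:
        raise ValueError(f"goal {goal.roi} is not a fall-off goal")
    ptvs = _ptvs_by_dose(protocol, geometry)
    if goal.goal_type == "dose_falloff_external":
        if not ptvs:
            raise ValueError("external fall-off has no PTV source region")
        source = np.zeros(geometry.grid_shape, dtype=bool)
        for n in ptvs:
            source |= geometry.masks[n]
        region = geometry.mask("external") & ~source
    else:
        presc = protocol.prescriptions.get(goal.roi)
        if presc is None:
            raise ValueError(f"intra-PTV fall-off on non-PTV roi {goal.roi!r}")
        higher = [n for n in ptvs if protocol.prescriptions[n] > presc]
        if not higher:
            raise ValueError(f"intra-PTV fall-off on {goal.roi}: no higher PTV source")
        source = geometry.masks[higher[-1]]  # the next-higher-dose PTV
        region = geometry.mask(goal.roi).copy()
        for n in higher:
            region &= ~geometry.masks[n]
    if not source.any():
        raise ValueError(f"fall-off source region for {goal.roi} is empty")
    dist_cm = ndimage.distance_transform_edt(~source, sampling=geometry.spacing) / 10.0
    g = resolve_falloff_gradient(goal, protocol)
    thr = np.maximum(goal.falloff["low_dose"], goal.falloff["high_dose"] - g * dist_cm)
    return thr, region


# --- penalties ---------------------------------------------------------------

@dataclasses.dataclass
class GoalContext:
    """Precomputed static data for evaluating one goal's penalty."""

    goal: PlanningGoal
    region_idx: np.ndarray            # flat voxel indices of the applicable region
    n_region: int
    thresholds: Optional[np.ndarray] = None  # per-region-voxel Gy (fall-off goals)
    dose_level: Optional[float] = None       # Gy (dv_max / median_max)

    def initial_dynamic_target(self, protocol: AutoPlanProtocol) -> float:
        if self.goal.goal_type == "dv_max":
            return float(self.goal.target)           # %Vol
        if self.goal.goal_type in FALLOFF_TYPES:
            return 0.0                               # unused
        return resolve_target_dose(self.goal, protocol)


def prepare_goal_context(goal: PlanningGoal, geometry: PatientGeometry,
                         protocol: AutoPlanProtocol) -> GoalContext:
    shape = geometry.grid_shape
    if goal.goal_type == "conformality_max":
        region = conformality_shell(geometry.mask(goal.roi), goal.distance_cm,
                                    geometry.mask("external"), geometry.spacing)
        thr = None
    elif goal.goal_type in FALLOFF_TYPES:
        thr3d, region = falloff_threshold_map(goal, geometry, protocol)
        thr = thr3d.ravel()
    elif (goal.goal_type in ("max_dose", "median_max", "dv_max")
          and goal.roi in protocol.prescriptions):
        # Ceiling goals on a lower-prescription PTV exclude the nested
        # higher-prescription PTVs: the boost violates them by construction.
        region = geometry.mask(goal.roi).copy()
        presc = protocol.prescriptions[goal.roi]
        for name, p in protocol.prescriptions.items():
            if p > presc and name in geometry.masks:
                region &= ~geometry.masks[name]
        thr = None
    else:
        region = geometry.mask(goal.roi)
        thr = None
    idx = np.flatnonzero(region.ravel())
    if idx.size == 0:
        raise ValueError(f"goal {goal.roi} ({goal.goal_type}): applicable region is empty")
    ctx = GoalContext(goal=goal, region_idx=idx, n_region=idx.size)
    if thr is not None:
        ctx.thresholds = thr[idx]
    if goal.goal_type == "dv_max":
        ctx.dose_level = float(goal.dose_level)
    elif goal.goal_type == "median_max":
        ctx.dose_level = resolve_target_dose(goal, protocol)
    return ctx


def _dv_tail(d: np.ndarray, level: float, volume_pct: float):
    """Indices (into ``d``) of the violating low-dose tail of a DV maximum.

    Voxels above ``level`` beyond the allowed fraction are violators; the
    documented tail rule penalises the *lowest-dosed* violators (the cheapest
    to pull below the level), which keeps the penalty continuous in dose at
    tie boundaries.
    """
    above = np.flatnonzero(d > level)
    allowed = int(np.floor(volume_pct / 100.0 * d.size + 1e-9))
    n_viol = above.size - allowed
    if n_viol <= 0:
        return above[:0]
    order = np.argsort(d[above], kind="stable")
    return above[order[:n_viol]]


def goal_penalty_and_gradient(state: ObjectiveState, dose_flat: np.ndarray,
                              ctx: GoalContext):
    """Penalty value and its exact gradient w.r.t. the region's voxel doses.

    Returns ``(penalty, grad)`` with ``grad`` aligned to ``ctx.region_idx``.
    """
    g = ctx.goal
    d = dose_flat[ctx.region_idx]
    n = ctx.n_region
    grad = np.zeros(n)
    t = state.dynamic_target
    if g.goal_type == "min_dose":
        viol = np.maximum(0.0, t - d)
        pen = float(viol @ viol) / n
        grad = -2.0 * viol / n
    elif g.goal_type in ("max_dose", "conformality_max"):
        viol = np.maximum(0.0, d - t)
        pen = float(viol @ viol) / n
        grad = 2.0 * viol / n
    elif g.goal_type == "mean_dose":
        e = max(0.0, float(d.mean()) - t)
        pen = e * e
        grad[:] = 2.0 * e / n
    elif g.goal_type in ("dv_max", "median_max"):
        level = ctx.dose_level
        vol = t if g.goal_type == "dv_max" else 50.0
        tail = _dv_tail(d, level, vol)
        viol = d[tail] - level
        pen = float(viol @ viol) / n
        grad[tail] = 2.0 * viol / n
    elif g.goal_type in FALLOFF_TYPES:
        viol = np.maximum(0.0, d - ctx.thresholds)
        pen = float(viol @ viol) / n
        grad = 2.0 * viol / n
    else:  # pragma: no cover
        raise AssertionError(g.goal_type)
    return pen, grad


def goal_penalty(state: ObjectiveState, dose, geometry: PatientGeometry,
                 protocol: AutoPlanProtocol, context: Optional[GoalContext] = None) -> float:
    """Convenience scalar penalty (context built on the fly if not given)."""
    ctx = context or prepare_goal_context(state.goal, geometry, protocol)
    flat = np.asarray(getattr(dose, "values", dose), dtype=float).ravel()
    pen, _ = goal_penalty_and_gradient(state, flat, ctx)
    return pen


def composite_objective(states: Sequence[ObjectiveState], dose, geometry,
                        protocol, contexts: Optional[Sequence[GoalContext]] = None):
    """Weighted penalty sum Σ wᵢ·pᵢ; records each state's ``last_penalty``.

    Returns ``(total, gradient_flat)`` where the gradient is w.r.t. the flat
    voxel-dose vector.
    """
    if not states:
        raise ValueError("composite objective requires at least one state")
    if contexts is None:
        contexts = [prepare_goal_context(s.goal, geometry, protocol) for s in states]
    flat = np.asarray(getattr(dose, "values", dose), dtype=float).ravel()
    q = np.zeros(flat.size)
    total = 0.0
    for s, ctx in zip(states, contexts):
        pen, grad = goal_penalty_and_gradient(s, flat, ctx)
        s.last_penalty = pen
        total += s.optimiser_weight * pen
        q[ctx.region_idx] += s.optimiser_weight * grad
    return total, q
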