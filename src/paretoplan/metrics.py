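"""DVH computation and plan-quality metrics.

Implements the cumulative dose-volume histogram and the metric panel used for
plan comparison: Dx% / D_cm³ (dose to the hottest x% / v cm³), Vd (relative or
absolute volume at dose), Dmean, Dmax, homogeneity index HI = (D2% − D98%) /
D50%, Paddick conformity index CI = TV_PIV² / (TV · PIV), clinical goal-table
evaluation, and the PTV-subtraction reporting convention (higher-prescription
PTVs removed from lower-prescription PTVs).

Dx% convention: voxel doses are sorted descending and associated with
cumulative-volume fractions at voxel midpoints, ``(i + 0.5) / N``; the dose at
an arbitrary fraction is linearly interpolated between those order statistics
and clamped to [min, max] outside the midpoint range.  The convention is
deliberately simple enough to verify against a brute-force sorting oracle.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, List, Optional, Sequence

import numpy as np

__all__ = [
    "DVHCurve",
    "MetricSpec",
    "cumulative_dvh",
    "dose_at_volume",
    "dose_at_abs_volume",
    "volume_at_dose",
    "mean_dose",
    "max_dose",
    "homogeneity_index",
    "paddick_ci",
    "reporting_mask",
    "evaluate_goal_table",
    "evaluate_metric",
]


def _dose_array(dose) -> np.ndarray:
    return np.asarray(getattr(dose, "values", dose), dtype=float)


def _roi_doses(dose, mask) -> np.ndarray:
    d = _dose_array(dose)
    if not mask.any():
        raise ValueError("metric requested on an empty mask")
    return d[mask]


@dataclasses.dataclass
class DVHCurve:
    """Cumulative DVH: relative volume at-or-above each dose bin edge."""

    dose_gy: np.ndarray
    volume_fraction: np.ndarray
    roi: str
    volume_cm3: float

    def volume_at(self, d: float) -> float:
        """Linear interpolation of the stored curve."""
        return float(np.interp(d, self.dose_gy, self.volume_fraction))


def cumulative_dvh(dose, mask, voxel_volume_cm3: float, bin_width: float = 0.1,
                   roi: str = "") -> DVHCurve:
    d = _roi_doses(dose, mask)
    top = max(float(d.max()) + bin_width, bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    frac = (d[None, :] >= edges[:, None]).mean(axis=1)
    return DVHCurve(edges, frac, roi, d.size * voxel_volume_cm3)


def dose_at_volume(dose, mask, x_percent: float) -> float:
    """Minimum dose received by the hottest ``x_percent`` of the structure."""
    if not (0.0 < x_percent <= 100.0):
        raise ValueError("x must lie in (0, 100]")
    d = np.sort(_roi_doses(dose, mask))[::-1]
    n = d.size
    mids = (np.arange(n) + 0.5) / n
    return float(np.interp(x_percent / 100.0, mids, d))


def dose_at_abs_volume(dose, mask, v_cm3: float, voxel_volume_cm3: float) -> float:
    """Dose to the hottest ``v_cm3`` of the structure."""
    total = mask.sum() * voxel_volume_cm3
    if not (0.0 < v_cm3 <= total):
        raise ValueError(f"volume {v_cm3} cm³ outside (0, {total:.2f}]")
    return dose_at_volume(dose, mask, 100.0 * v_cm3 / total)


def volume_at_dose(dose, mask, d_gy: float, *, absolute: bool = False,
                   voxel_volume_cm3: Optional[float] = None) -> float:
    """Volume with dose >= ``d_gy``: percent of the ROI, or cm³ if absolute."""
    d = _roi_doses(dose, mask)
    frac = float((d >= d_gy).mean())
    if absolute:
        if voxel_volume_cm3 is None:
            raise ValueError("absolute volume requires voxel_volume_cm3")
        return frac * d.size * voxel_volume_cm3
    return 100.0 * frac


def mean_dose(dose, mask) -> float:
    return float(_roi_doses(dose, mask).mean())


def max_dose(dose, mask) -> float:
    return float(_roi_doses(dose, mask).max())


def homogeneity_index(dose, mask) -> float:
    """HI = (D2% − D98%) / D50%; 0 for a perfectly uniform dose."""
    d50 = dose_at_volume(dose, mask, 50.0)
    if d50 <= 0:
        return 0.0
    return (dose_at_volume(dose, mask, 2.0) - dose_at_volume(dose, mask, 98.0)) / d50


def paddick_ci(dose, ptv_mask, external_mask, reference_dose: float) -> float:
    """Paddick conformity index (TV_PIV)² / (TV · PIV) at ``reference_dose``.

    PIV is the prescription-isodose volume inside the external contour, TV the
    target volume, TV_PIV their intersection.  Returns 0 (with a warning) when
    the reference isodose covers nothing.
    """
    d = _dose_array(dose)
    piv = int(((d >= reference_dose) & external_mask).sum())
    tv = int(ptv_mask.sum())
    tv_piv = int(((d >= reference_dose) & ptv_mask).sum())
    if piv == 0 or tv == 0:
        warnings.warn("Paddick CI undefined (empty PIV); returning 0", stacklevel=2)
        return 0.0
    return tv_piv**2 / (tv * piv)


# --- reporting conventions ---------------------------------------------------

_HIGHER_PTVS = {"PTV60": (), "PTV57.5": ("PTV60",), "PTV48": ("PTV57.5", "PTV60")}


def reporting_mask(geometry, ptv_name: str) -> np.ndarray:
    """PTV mask with all higher-prescription PTVs subtracted."""
    m = geometry.mask(ptv_name).copy()
    for higher in _HIGHER_PTVS.get(ptv_name, ()):
        if higher in geometry.masks:
            m &= ~geometry.masks[higher]
    return m


def _resolve_roi(geometry, roi: str) -> np.ndarray:
    """Resolve an ROI expression; ``A-B`` means set difference A \\ B."""
    if "-" in roi and roi not in geometry.masks:
        parts = roi.split("-")
        m = geometry.mask(parts[0].strip()).copy()
        for sub in parts[1:]:
            m &= ~geometry.mask(sub.strip())
        return m
    return geometry.mask(roi)


# --- metric specs ------------------------------------------------------------

_KINDS = ("D_percent", "D_abs_volume", "V_dose_percent", "V_dose_abs",
          "Dmean", "Dmax", "HI", "CI")


@dataclasses.dataclass
class MetricSpec:
    """One plan-quality metric: kind, parameter and the structure it reads."""

    kind: str
    roi: str
    parameter: float = 0.0      # x% for D_percent, cm³ for D_abs_volume, Gy for V_*
    subtract: bool = False      # apply the PTV-subtraction reporting convention
    reference_dose: float = 0.0  # CI only

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown metric kind {self.kind!r}")

    @property
    def label(self) -> str:
        star = "*" if self.subtract else ""
        if self.kind == "D_percent":
            return f"{self.roi}{star} D{self.parameter:g}%"
        if self.kind == "D_abs_volume":
            return f"{self.roi}{star} D{self.parameter:g}cm3"
        if self.kind == "V_dose_percent":
            return f"{self.roi}{star} V{self.parameter:g}Gy (%)"
        if self.kind == "V_dose_abs":
            return f"{self.roi}{star} V{self.parameter:g}Gy (cm3)"
        if self.kind == "CI":
            return f"{self.roi} CI@{self.reference_dose:g}Gy"
        return f"{self.roi}{star} {self.kind}"


def evaluate_metric(spec: MetricSpec, dose, geometry) -> float:
    mask = (reporting_mask(geometry, spec.roi) if spec.subtract
            else _resolve_roi(geometry, spec.roi))
    vv = geometry.voxel_volume_cm3
    if spec.kind == "D_percent":
        return dose_at_volume(dose, mask, spec.parameter)
    if spec.kind == "D_abs_volume":
        return dose_at_abs_volume(dose, mask, spec.parameter, vv)
    if spec.kind == "V_dose_percent":
        return volume_at_dose(dose, mask, spec.parameter)
    if spec.kind == "V_dose_abs":
        return volume_at_dose(dose, mask, spec.parameter, absolute=True,
                              voxel_volume_cm3=vv)
    if spec.kind == "Dmean":
        return mean_dose(dose, mask)
    if spec.kind == "Dmax":
        return max_dose(dose, mask)
    if spec.kind == "HI":
        return homogeneity_index(dose, mask)
    if spec.kind == "CI":
        return paddick_ci(dose, geometry.mask(spec.roi), geometry.mask("external"),
                          spec.reference_dose)
    raise AssertionError(spec.kind)


# --- clinical goal tables ----------------------------------------------------

@dataclasses.dataclass
class GoalRow:
    """Evaluated clinical goal: metric value vs. its limit."""

    roi: str
    description: str
    value: float
    limit: float
    limit_type: str  # "le" | "ge"
    passed: bool


def evaluate_goal_table(dose, geometry, goals: Iterable[dict]) -> List[GoalRow]:
    """Evaluate a list of clinical-goal dicts against a dose.

    Each goal dict has keys ``roi``, ``kind`` (a :class:`MetricSpec` kind),
    ``parameter``, ``limit`` (in the metric's units) and ``limit_type``
    (``"le"``/``"ge"``).  ``roi`` may be a subtraction expression ``A-B``.
    """
    rows: List[GoalRow] = []
    for g in goals:
        spec = MetricSpec(kind=g["kind"], roi=g["roi"],
                          parameter=float(g.get("parameter", 0.0)))
        value = evaluate_metric(spec, dose, geometry)
        limit = float(g["limit"])
        lt = g["limit_type"]
        if lt not in ("le", "ge"):
            raise ValueError(f"limit_type must be 'le' or 'ge', got {lt!r}")
        passed = value <= limit + 1e-9 if lt == "le" else value >= limit - 1e-9
        rows.append(GoalRow(g["roi"], g.get("description", spec.label),
                            value, limit, lt, bool(passed)))
    return rows
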