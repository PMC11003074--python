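"""Procedural prostate phantoms.

Generates CHHiP-like prostate anatomy (prostate + proximal seminal vesicles as
targets; rectum, bladder and — for the institution-B profile — femoral heads
and bowel as organs at risk) as boolean masks on a regular voxel grid, plus the
planning target volumes built from the trial's margin recipe:

* PTV60   = prostate + 5 mm (0 mm posteriorly)
* PTV57.5 = prostate + 10 mm (5 mm posteriorly)
* PTV48   = (prostate ∪ seminal vesicles) + 10 mm isotropic

All expansions use voxel-centre distances with ellipsoidal interpolation
between the six directional margins (see :func:`expand_structure`), and every
PTV is clipped to the external contour.  Anatomy parameters are drawn from
documented uniform ranges by a seeded generator, so regeneration with the same
seed reproduces the masks bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy import ndimage

from .coords import center_grids

__all__ = [
    "PatientGeometry",
    "generate_patient",
    "expand_structure",
    "build_ptvs",
    "conformality_shell",
    "ptv_margins",
    "DEFAULT_GRID_SHAPE",
    "DEFAULT_SPACING",
]

DEFAULT_GRID_SHAPE: Tuple[int, int, int] = (64, 64, 48)
DEFAULT_SPACING: Tuple[float, float, float] = (4.0, 4.0, 4.0)

PTV_NAMES = ("PTV60", "PTV57.5", "PTV48")

# Anatomy parameter ranges (mm).  Scalars are fixed; 2-tuples are uniform
# jitter ranges sampled per patient.  These are desk-scale stand-ins for
# clinical anatomy, not fitted to patient data.
DEFAULT_ANATOMY: Dict[str, object] = {
    "external_semi_x": 115.0,
    "external_semi_y": 95.0,
    "prostate_center_y": 5.0,
    "prostate_a": (20.0, 25.0),   # lateral semi-axis
    "prostate_b": (17.0, 22.0),   # AP semi-axis
    "prostate_c": (17.0, 22.0),   # SI semi-axis
    "sv_length": (15.0, 20.0),    # "up to 2 cm" of proximal seminal vesicles
    "sv_semi_x": 14.0,
    "sv_semi_y": 9.0,
    "rectum_radius": (10.0, 14.0),
    "rectum_overlap": 2.0,        # carved back out of the prostate -> abutment
    "bladder_a": (30.0, 38.0),
    "bladder_b": (24.0, 30.0),
    "bladder_c": (20.0, 26.0),
    "bladder_z": 24.0,
    "femoral_radius": 20.0,
    "femoral_offset_x": 80.0,
    "bowel_semi": (55.0, 45.0, 26.0),
    "bowel_y": -30.0,
    "bowel_z": 58.0,
}


@dataclasses.dataclass
class PatientGeometry:
    """Voxelised patient anatomy: grid, spacing and named boolean masks."""

    grid_shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    masks: Dict[str, np.ndarray]
    seed: int = 0
    anatomy_params: Dict[str, float] = dataclasses.field(default_factory=dict)

    def mask(self, name: str) -> np.ndarray:
        try:
            return self.masks[name]
        except KeyError:
            raise KeyError(
                f"structure {name!r} not present; available: {sorted(self.masks)}"
            ) from None

    @property
    def voxel_volume_cm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def structure_volume_cm3(self, name: str) -> float:
        return int(self.mask(name).sum()) * self.voxel_volume_cm3

    def validate(self) -> None:
        """Raise if any container invariant is violated."""
        ext = self.mask("external")
        for name, m in self.masks.items():
            if m.shape != tuple(self.grid_shape):
                raise ValueError(f"mask {name!r} shape {m.shape} != grid {self.grid_shape}")
            if m.dtype != bool:
                raise ValueError(f"mask {name!r} must be boolean")
            if name != "external" and np.any(m & ~ext):
                raise ValueError(f"structure {name!r} extends outside the external contour")
        if "prostate" in self.masks and "rectum" in self.masks:
            if np.any(self.masks["prostate"] & self.masks["rectum"]):
                raise ValueError("prostate and rectum overlap")
        if all(p in self.masks for p in PTV_NAMES):
            p60, p575, p48 = (self.masks[p] for p in PTV_NAMES)
            if np.any(p60 & ~p575) or np.any(p575 & ~p48):
                raise ValueError("PTV nesting PTV60 ⊆ PTV57.5 ⊆ PTV48 violated")


def _resolve_params(rng: np.random.Generator, overrides: Optional[Mapping[str, object]]):
    cfg = dict(DEFAULT_ANATOMY)
    if overrides:
        unknown = set(overrides) - set(cfg)
        if unknown:
            raise ValueError(f"unknown anatomy parameters: {sorted(unknown)}")
        cfg.update(overrides)
    out: Dict[str, object] = {}
    # Draw jittered parameters in fixed key order for reproducibility.
    for key in DEFAULT_ANATOMY:
        val = cfg[key]
        if isinstance(val, tuple) and len(val) == 2 and key != "bowel_semi":
            out[key] = float(rng.uniform(*val))
        else:
            out[key] = val
    return out


def _ellipsoid(X, Y, Z, center, semi) -> np.ndarray:
    cx, cy, cz = center
    a, b, c = semi
    return ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2 <= 1.0


def generate_patient(
    seed: int,
    anatomy_config: Optional[Mapping[str, object]] = None,
    *,
    grid_shape: Tuple[int, int, int] = DEFAULT_GRID_SHAPE,
    spacing: Tuple[float, float, float] = DEFAULT_SPACING,
    profile: str = "instA",
) -> PatientGeometry:
    """Generate one synthetic prostate patient.

    Parameters
    ----------
    seed:
        Seeds the anatomy jitter; identical seed + config reproduce identical
        masks bit-for-bit.
    anatomy_config:
        Overrides for :data:`DEFAULT_ANATOMY` entries (scalar or jitter range).
    profile:
        ``"instA"`` (rectum + bladder OARs) or ``"instB"`` (additionally
        femoral heads and bowel).
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    spacing = tuple(float(s) for s in spacing)
    if min(grid_shape) < 32:
        raise ValueError(f"grid_shape must be at least 32 per axis, got {grid_shape}")
    if not all(1.0 <= s <= 5.0 for s in spacing):
        raise ValueError(f"spacing must lie in [1, 5] mm, got {spacing}")
    if profile not in ("instA", "instB"):
        raise ValueError(f"unknown profile {profile!r}")

    rng = np.random.default_rng(seed)
    p = _resolve_params(rng, anatomy_config)
    for key in ("prostate_a", "prostate_b", "prostate_c", "rectum_radius"):
        if p[key] <= 0:
            raise ValueError(f"anatomy parameter {key} must be positive")

    X, Y, Z = center_grids(grid_shape, spacing)
    masks: Dict[str, np.ndarray] = {}

    # Body: elliptical cylinder spanning the full SI extent.
    ext = ((X / p["external_semi_x"]) ** 2 + (Y / p["external_semi_y"]) ** 2) <= 1.0
    ext = np.broadcast_to(ext, grid_shape).copy()
    masks["external"] = ext

    yc = p["prostate_center_y"]
    a, b, c = p["prostate_a"], p["prostate_b"], p["prostate_c"]
    prostate = _ellipsoid(X, Y, Z, (0.0, yc, 0.0), (a, b, c))
    masks["prostate"] = prostate

    # Rectum: posterior tube along z, slightly interpenetrating the prostate
    # analytically, then carved back so the two masks are disjoint but
    # face-adjacent (the trial's 0 mm posterior margin implies abutment).
    r = p["rectum_radius"]
    rect_y = yc + b + r - p["rectum_overlap"]
    rectum = ((X / (r * 1.1)) ** 2 + ((Y - rect_y) / r) ** 2) <= 1.0
    rectum = np.broadcast_to(rectum, grid_shape).copy()
    rectum &= ~prostate
    masks["rectum"] = rectum

    # Proximal seminal vesicles: small posterior-superior lobe above the
    # prostate; length parameterised ("up to 2 cm").
    sv_len = p["sv_length"]
    sv = _ellipsoid(
        X, Y, Z,
        (0.0, yc + 6.0, 0.5 * c + 0.5 * sv_len),
        (p["sv_semi_x"], p["sv_semi_y"], 0.5 * sv_len + 4.0),
    )
    sv &= ~(prostate | rectum)
    masks["seminal_vesicles"] = sv

    bladder = _ellipsoid(
        X, Y, Z,
        (0.0, yc - b - p["bladder_b"] + 8.0, p["bladder_z"]),
        (p["bladder_a"], p["bladder_b"], p["bladder_c"]),
    )
    bladder &= ~(prostate | rectum | sv)
    masks["bladder"] = bladder

    if profile == "instB":
        fr, fx = p["femoral_radius"], p["femoral_offset_x"]
        for side, sgn in (("femoral_head_left", +1), ("femoral_head_right", -1)):
            masks[side] = _ellipsoid(X, Y, Z, (sgn * fx, 5.0, -10.0), (fr, fr, fr))
        bowel = _ellipsoid(X, Y, Z, (0.0, p["bowel_y"], p["bowel_z"]), p["bowel_semi"])
        bowel &= ~(bladder | prostate | sv)
        masks["bowel"] = bowel

    geo = PatientGeometry(
        grid_shape=grid_shape,
        spacing=spacing,
        masks=masks,
        seed=int(seed),
        anatomy_params={k: v for k, v in p.items() if np.isscalar(v)},
    )
    geo.validate()
    return geo


def _directional_footprint(margins, spacing) -> np.ndarray:
    """Boolean structuring element for an anisotropic centre-distance dilation.

    ``margins`` is ``((x-, x+), (y-, y+), (z-, z+))`` in mm.  An offset vector
    ``v`` belongs to the footprint iff ``sum_i (v_i / m_i(sign v_i))^2 <= 1``
    with a zero margin admitting only zero offset on that axis — the
    ellipsoidal interpolation between the six axis margins.
    """
    reach = [int(np.floor(max(lo, hi) / s + 1e-9)) for (lo, hi), s in zip(margins, spacing)]
    offs = [np.arange(-r, r + 1) for r in reach]
    O = np.meshgrid(*offs, indexing="ij")
    total = np.zeros(O[0].shape)
    ok = np.ones(O[0].shape, dtype=bool)
    for ax in range(3):
        v = O[ax] * spacing[ax]
        lo, hi = margins[ax]
        m = np.where(v >= 0, hi, lo)
        nz = v != 0
        ok &= ~nz | (m > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(nz & (m > 0), (v / np.where(m > 0, m, 1.0)) ** 2, 0.0)
        total += term
    return ok & (total <= 1.0 + 1e-9)


def expand_structure(mask: np.ndarray, margins, spacing) -> np.ndarray:
    """Anisotropic morphological expansion by voxel-centre distance.

    Parameters
    ----------
    mask:
        Boolean voxel field.
    margins:
        ``((x-, x+), (y-, y+), (z-, z+))`` margins in mm (``+y`` posterior,
        ``+z`` superior); all must be non-negative.
    spacing:
        Voxel spacing in mm.

    Returns the set of voxels whose centre lies within the direction-dependent
    margin of some input voxel centre; always a superset of the input.
    """
    margins = tuple((float(lo), float(hi)) for lo, hi in margins)
    if any(m < 0 for pair in margins for m in pair):
        raise ValueError("margins must be non-negative")
    for ax, ((lo, hi), s, n) in enumerate(zip(margins, spacing, mask.shape)):
        if max(lo, hi) > n * s:
            raise ValueError(f"margin {max(lo, hi)} mm exceeds grid extent on axis {ax}")
    foot = _directional_footprint(margins, spacing)
    if foot.size == 1:
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=foot)


def ptv_margins(isotropic: float, posterior: float):
    """Six-directional margin tuple with a reduced posterior (+y) margin."""
    return ((isotropic, isotropic), (isotropic, posterior), (isotropic, isotropic))


def build_ptvs(geometry: PatientGeometry) -> PatientGeometry:
    """Add PTV60 / PTV57.5 / PTV48 to a geometry, clipped to external.

    Margin recipe: prostate + 5 mm (0 posterior) → PTV60; prostate + 10 mm
    (5 posterior) → PTV57.5; prostate ∪ seminal vesicles + 10 mm → PTV48.
    """
    for req in ("prostate", "external"):
        if req not in geometry.masks:
            raise ValueError(f"missing prerequisite mask {req!r}")
    if "seminal_vesicles" not in geometry.masks:
        raise ValueError("missing prerequisite mask 'seminal_vesicles'")
    ext = geometry.masks["external"]
    pro = geometry.masks["prostate"]
    sv = geometry.masks["seminal_vesicles"]
    sp = geometry.spacing
    geometry.masks["PTV60"] = expand_structure(pro, ptv_margins(5.0, 0.0), sp) & ext
    geometry.masks["PTV57.5"] = expand_structure(pro, ptv_margins(10.0, 5.0), sp) & ext
    geometry.masks["PTV48"] = expand_structure(pro | sv, ptv_margins(10.0, 10.0), sp) & ext
    geometry.validate()
    return geometry


def conformality_shell(source: np.ndarray, distance_cm: float, external: np.ndarray,
                       spacing) -> np.ndarray:
    """Voxels of ``external`` at centre-distance >= ``distance_cm`` from source.

    The region where a primary conformality (max-dose-at-distance) goal
    applies.  Distance is Euclidean voxel-centre distance to the nearest
    source voxel; the source itself is always excluded.
    """
    if distance_cm < 0:
        raise ValueError("distance must be non-negative")
    if not source.any():
        raise ValueError("conformality shell source is empty")
    dist_mm = ndimage.distance_transform_edt(~source, sampling=spacing)
    return external & ~source & (dist_mm >= distance_cm * 10.0)
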