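"""Simplified linear dose model: beamlet influence matrix for a coplanar arc.

The clinical arc (single 6 MV 360° VMAT arc) is discretised into ``n_beams``
static, equispaced coplanar beams rotating about the z (inferior-superior)
axis.  Each beam's beamlets tile the target's beam's-eye-view bounding box
(with margin) on a regular lateral × longitudinal raster.  The dose a beamlet
deposits in a voxel is

    output_scale · exp(−mu_atten · depth) · exp(−lateral² / (2 σ²))

with ``depth`` the path length inside the external contour along the ray
upstream of the voxel and ``lateral`` the distance from the beamlet axis in
the beam's-eye-view plane.  The kernel constants are non-clinical: they are
the simplest physics that makes OAR-vs-target trade-offs real.  Entries whose
lateral Gaussian falls below ``lateral_floor`` (relative to peak) are dropped,
which keeps the matrix sparse.

Dose is linear in the beamlet weights: ``d = D · x`` with ``D`` the influence
matrix and ``x ≥ 0`` the fluence vector.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Tuple

import numpy as np
from scipy import sparse

from .coords import axis_centers
from .metrics import dose_at_volume
from .phantom import PatientGeometry

__all__ = [
    "BeamConfig",
    "InfluenceMatrix",
    "DoseDistribution",
    "build_influence_matrix",
    "compute_dose",
    "normalise_plan",
]


@dataclasses.dataclass(frozen=True)
class BeamConfig:
    """Arc discretisation and (non-clinical) beamlet kernel constants."""

    n_beams: int = 36
    beamlet_width: float = 8.0      # raster step in the BEV plane, mm
    mu_atten: float = 0.005         # linear attenuation, 1/mm
    sigma_lateral: float = 5.0      # Gaussian penumbra, mm
    output_scale: float = 1.0       # Gy per unit fluence at zero depth
    bev_margin: float = 10.0        # raster margin beyond the target bbox, mm
    lateral_floor: float = 1e-2     # relative sparsity floor on the lateral kernel
    depth_step: float = 4.0         # ray-marching step for radiological depth, mm

    def __post_init__(self):
        if self.n_beams < 4:
            raise ValueError("n_beams must be >= 4")
        if self.mu_atten <= 0 or self.sigma_lateral <= 0:
            raise ValueError("mu_atten and sigma_lateral must be positive")


@dataclasses.dataclass
class InfluenceMatrix:
    """Sparse voxel × beamlet dose-per-unit-weight matrix."""

    matrix: sparse.csr_matrix          # (n_voxels_flat, n_beamlets), Gy per unit weight
    grid_shape: Tuple[int, int, int]
    beam_angles: np.ndarray            # radians, one per beam
    beamlet_beam: np.ndarray           # beam index of each beamlet column

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[1]


@dataclasses.dataclass
class DoseDistribution:
    """3-D dose field in Gy on the geometry grid."""

    values: np.ndarray

    def __post_init__(self):
        if np.any(self.values < -1e-12):
            raise ValueError("dose must be non-negative")


def _target_mask(geometry: PatientGeometry) -> np.ndarray:
    names = [n for n in ("PTV60", "PTV57.5", "PTV48") if n in geometry.masks]
    if not names:
        names = ["prostate"] if "prostate" in geometry.masks else []
    if not names:
        raise ValueError("no target structure (PTV or prostate) in geometry")
    m = np.zeros(geometry.grid_shape, dtype=bool)
    for n in names:
        m |= geometry.masks[n]
    if not m.any():
        raise ValueError("target bounding box empty")
    return m


def build_influence_matrix(geometry: PatientGeometry, config: BeamConfig) -> InfluenceMatrix:
    """Build the beamlet influence matrix for an equispaced coplanar arc."""
    shape = geometry.grid_shape
    sp = geometry.spacing
    ext = geometry.mask("external")
    if not ext.any():
        raise ValueError("external mask is empty")
    target = _target_mask(geometry)

    idx = np.argwhere(ext)                                # (N, 3) voxel indices
    px = axis_centers(shape[0], sp[0])[idx[:, 0]]
    py = axis_centers(shape[1], sp[1])[idx[:, 1]]
    pz = axis_centers(shape[2], sp[2])[idx[:, 2]]
    flat_rows = np.ravel_multi_index(idx.T, shape)

    tidx = np.argwhere(target)
    tx = axis_centers(shape[0], sp[0])[tidx[:, 0]]
    ty = axis_centers(shape[1], sp[1])[tidx[:, 1]]
    tz = axis_centers(shape[2], sp[2])[tidx[:, 2]]

    ext_flat = ext.ravel()
    half = (np.asarray(shape) - 1) / 2.0
    diag = float(np.hypot(shape[0] * sp[0], shape[1] * sp[1]))
    n_steps = int(np.ceil(diag / config.depth_step))
    t_samples = (np.arange(n_steps) + 0.5) * config.depth_step

    angles = 2.0 * np.pi * np.arange(config.n_beams) / config.n_beams
    two_sigma2 = 2.0 * config.sigma_lateral**2
    blocks: List[sparse.coo_matrix] = []
    beamlet_beam: List[int] = []
    n_flat = int(np.prod(shape))

    for b, th in enumerate(angles):
        ux, uy = np.sin(th), np.cos(th)          # beam travel direction (in-plane)
        pxl, pyl = np.cos(th), -np.sin(th)       # lateral BEV axis

        # Radiological depth: march upstream from each voxel, summing external
        # occupancy at the sample points (nearest-voxel lookup).
        sx = px[:, None] - t_samples[None, :] * ux
        sy = py[:, None] - t_samples[None, :] * uy
        ix = np.rint(sx / sp[0] + half[0]).astype(np.int64)
        iy = np.rint(sy / sp[1] + half[1]).astype(np.int64)
        inside = (ix >= 0) & (ix < shape[0]) & (iy >= 0) & (iy < shape[1])
        iz = np.broadcast_to(idx[:, 2][:, None], ix.shape)
        flat = (np.clip(ix, 0, shape[0] - 1) * shape[1]
                + np.clip(iy, 0, shape[1] - 1)) * shape[2] + iz
        occ = ext_flat[flat] & inside
        depth = occ.sum(axis=1) * config.depth_step
        depth_fac = config.output_scale * np.exp(-config.mu_atten * depth)

        # Beamlet raster over the target's BEV bounding box.
        s_t = tx * pxl + ty * pyl
        s_lo, s_hi = s_t.min() - config.bev_margin, s_t.max() + config.bev_margin
        z_lo, z_hi = tz.min() - config.bev_margin, tz.max() + config.bev_margin
        n_s = max(1, int(np.ceil((s_hi - s_lo) / config.beamlet_width)))
        n_z = max(1, int(np.ceil((z_hi - z_lo) / config.beamlet_width)))
        s_centers = s_lo + (np.arange(n_s) + 0.5) * config.beamlet_width
        z_centers = z_lo + (np.arange(n_z) + 0.5) * config.beamlet_width

        s_v = px * pxl + py * pyl
        gs = np.exp(-((s_v[:, None] - s_centers[None, :]) ** 2) / two_sigma2)
        gz = np.exp(-((pz[:, None] - z_centers[None, :]) ** 2) / two_sigma2)
        lateral = gs[:, :, None] * gz[:, None, :]
        lateral = lateral.reshape(len(px), n_s * n_z)
        lateral[lateral < config.lateral_floor] = 0.0

        vals = depth_fac[:, None] * lateral
        r, c = np.nonzero(vals)
        blocks.append(sparse.coo_matrix(
            (vals[r, c], (flat_rows[r], c)), shape=(n_flat, n_s * n_z)))
        beamlet_beam.extend([b] * (n_s * n_z))

    matrix = sparse.hstack(blocks, format="csr")
    return InfluenceMatrix(matrix=matrix, grid_shape=shape,
                           beam_angles=angles, beamlet_beam=np.asarray(beamlet_beam))


def compute_dose(influence: InfluenceMatrix, fluence: np.ndarray) -> DoseDistribution:
    """Linear dose: ``d = D · x`` reshaped to the grid."""
    fluence = np.asarray(fluence, dtype=float)
    if fluence.shape != (influence.n_beamlets,):
        raise ValueError(
            f"fluence length {fluence.shape} != beamlet count {influence.n_beamlets}")
    if np.any(fluence < 0):
        raise ValueError("fluence weights must be non-negative")
    flat = influence.matrix @ fluence
    return DoseDistribution(flat.reshape(influence.grid_shape))


def normalise_plan(dose: DoseDistribution, geometry: PatientGeometry,
                   prescription: float = 60.0) -> DoseDistribution:
    """Scale the dose so PTV60's median (D50%) equals the prescription."""
    ptv = geometry.mask("PTV60")
    if not ptv.any():
        raise ValueError("PTV60 mask is empty")
    med = dose_at_volume(dose.values, ptv, 50.0)
    if med <= 0:
        raise ValueError("cannot normalise: PTV60 median dose is zero")
    return DoseDistribution(dose.values * (prescription / med))
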