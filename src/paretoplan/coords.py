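"""Coordinate conventions shared by every module.

The voxel grid is regular with axis order ``(x, y, z)``:

* ``x`` — left-right (lateral),
* ``y`` — anterior-posterior, **+y is posterior**,
* ``z`` — inferior-superior, **+z is superior**.

Voxel *centres* carry all geometry: axis ``i`` of a grid with ``n`` voxels at
spacing ``s`` mm has centres ``(idx - (n - 1) / 2) * s`` so the grid is centred
on the physical origin.  Distances are voxel-centre to voxel-centre throughout
(margin expansion, conformality shells, fall-off maps).
"""

from __future__ import annotations

import numpy as np

__all__ = ["axis_centers", "center_grids"]


def axis_centers(n: int, spacing: float) -> np.ndarray:
    """Physical centre coordinate (mm) of each voxel along one axis."""
    return (np.arange(n) - (n - 1) / 2.0) * float(spacing)


def center_grids(shape, spacing):
    """Broadcastable (X, Y, Z) centre-coordinate arrays in mm."""
    cx = axis_centers(shape[0], spacing[0])[:, None, None]
    cy = axis_centers(shape[1], spacing[1])[None, :, None]
    cz = axis_centers(shape[2], spacing[2])[None, None, :]
    return cx, cy, cz
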