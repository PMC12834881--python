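"""Multi-slice image container used by every stage of the pipeline.

All images are carried in Hounsfield units (HU) with in-plane pixel spacing
in millimetres. Axial slices are treated as statistically independent
realisations of the same reconstruction; nothing in the pipeline looks at
z-correlation, which is why a plain (slice, row, col) array with shared
in-plane metadata is sufficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """A stack of axial CT slices in HU.

    Parameters
    ----------
    voxels
        3-D array shaped ``(n_slices, n_rows, n_cols)`` in HU.
    pixel_spacing
        In-plane pixel size in mm (isotropic: same in row and column
        directions).
    slice_thickness
        Reconstructed slice thickness in mm.
    meta
        Free-form acquisition labels (dose in mGy, algorithm name,
        reconstruction level, ...). Carried through to downstream results.
    """

    voxels: np.ndarray
    pixel_spacing: float
    slice_thickness: float = 1.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"voxels must be 3-D (slice, row, col); got shape {self.voxels.shape}"
            )
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def fov(self) -> float:
        """In-plane field of view (mm) along the row axis."""
        return self.voxels.shape[1] * self.pixel_spacing

    @property
    def nyquist(self) -> float:
        """In-plane Nyquist frequency, 1/(2 * pixel_spacing), in mm^-1."""
        return 1.0 / (2.0 * self.pixel_spacing)

    def center_mm(self) -> tuple[float, float]:
        """Physical (x, y) of the image centre in mm, origin at centre.

        By convention the physical origin sits at the image centre, so this
        is always (0, 0); provided for symmetry with pixel coordinates.
        """
        return (0.0, 0.0)

    def pixel_coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinate grids of pixel centres, origin at image centre."""
        n_rows, n_cols = self.voxels.shape[1:]
        x = (np.arange(n_cols) - (n_cols - 1) / 2.0) * self.pixel_spacing
        y = (np.arange(n_rows) - (n_rows - 1) / 2.0) * self.pixel_spacing
        return np.meshgrid(x, y)
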