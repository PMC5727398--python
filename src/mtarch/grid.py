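"""Density-grid container shared by the generator, measurements and MRC I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DensityGrid"]


@dataclass
class DensityGrid:
    """A 2D image or 3D volume with a physical sampling interval.

    The MT axis is always the ``z`` axis.  ``axes`` names the array axes in
    index order:

    * ``"zyx"`` - 3D volume, shape (nz, ny, nx)
    * ``"zy"``  - 2D projection along x (the view axis), shape (nz, ny)
    * ``"yx"``  - 2D transverse section, shape (ny, nx)

    ``pixel_nm`` is the isotropic sampling in nm/px (0.35 nm/px emulates the
    tomography sampling of 3.5 A/px; 0.139 nm/px the single-particle 1.39
    A/px).
    """

    values: np.ndarray
    pixel_nm: float = 0.35
    axes: str = "zyx"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.pixel_nm <= 0:
            raise ValueError(f"pixel_nm must be > 0, got {self.pixel_nm}")
        if self.axes not in ("zyx", "zy", "yx"):
            raise ValueError(f"axes must be 'zyx', 'zy' or 'yx', got {self.axes!r}")
        if self.values.ndim != len(self.axes):
            raise ValueError(
                f"array is {self.values.ndim}D but axes={self.axes!r} "
                f"implies {len(self.axes)}D"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def extent_nm(self, axis: int = 0) -> float:
        """Physical extent along an array axis (nm)."""
        return self.values.shape[axis] * self.pixel_nm
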