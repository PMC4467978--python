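"""Core image container shared by every pipeline stage.

A CE-CT reconstruction is handled as a plain 3D greyscale lattice with an
isotropic voxel size. Axis order is (z, y, x) with z the construct height
axis, so a transaxial cross-section is a single z-slice. Indices are 0-based
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImageVolume"]


@dataclass
class ImageVolume:
    """3D greyscale image stack with isotropic voxel size.

    Parameters
    ----------
    data:
        3D array, axes (z, y, x). Any numeric dtype; processing stages work
        in floating point, file writers quantize to ``bit_depth``.
    voxel_size_um:
        Isotropic voxel edge length in micrometres. Must be positive.
    bit_depth:
        Target bit depth for file output, 8 or 16.
    """

    data: np.ndarray
    voxel_size_um: float = 3.75
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D stack, got ndim={self.data.ndim}")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def slice(self, index: int) -> np.ndarray:
        """One transaxial (z) cross-section."""
        return self.data[index]

    def astype_quantized(self) -> np.ndarray:
        """Data clipped and rounded to the integer range of ``bit_depth``."""
        hi = 255 if self.bit_depth == 8 else 65535
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        return np.clip(np.rint(self.data), 0, hi).astype(dtype)
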