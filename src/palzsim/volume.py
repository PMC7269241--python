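"""A minimal 3-D image container shared by every stage of the pipeline.

All simulation arithmetic happens on a fixed template lattice in a standard
(MNI-like) space; :class:`VolumeGrid` is the universal carrier for PET
images, multiplicative error fields and binary masks on that lattice.
World coordinates are RAS+ millimetres, voxel indices are 0-based, and the
``affine`` maps homogeneous voxel indices to world coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two volumes that must share a lattice do not."""


@dataclass
class VolumeGrid:
    """A 3-D scalar image on a fixed lattice.

    Parameters
    ----------
    data:
        3-D array (float for images, bool/integer for masks and labels).
    affine:
        4x4 RAS+ voxel-to-world matrix; last row must be ``[0, 0, 0, 1]``.
    """

    data: np.ndarray
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        if not np.allclose(self.affine[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("affine last row must be [0, 0, 0, 1]")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("volume contains non-finite values")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel edge length in mm, from the affine column norms."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World (x, y, z) arrays of every voxel centre, each of ``self.shape``."""
        ii, jj, kk = np.meshgrid(
            np.arange(self.shape[0]),
            np.arange(self.shape[1]),
            np.arange(self.shape[2]),
            indexing="ij",
        )
        lin = self.affine[:3, :3]
        off = self.affine[:3, 3]
        x = lin[0, 0] * ii + lin[0, 1] * jj + lin[0, 2] * kk + off[0]
        y = lin[1, 0] * ii + lin[1, 1] * jj + lin[1, 2] * kk + off[1]
        z = lin[2, 0] * ii + lin[2, 1] * jj + lin[2, 2] * kk + off[2]
        return x, y, z

    # -- helpers ------------------------------------------------------------

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """A new volume on the same lattice with replaced voxel data."""
        return VolumeGrid(data=data, affine=self.affine.copy())

    def same_grid(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_same_grid(self, other: "VolumeGrid", what: str = "volume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what}: grids differ (shapes {self.shape} vs {other.shape})"
            )

    def mask_array(self) -> np.ndarray:
        """Boolean view of a binary-mask volume."""
        return self.data.astype(bool)
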