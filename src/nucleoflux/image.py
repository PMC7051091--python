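"""3D image stack container and projections."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack", "max_intensity_projection"]


@dataclass
class ImageStack:
    """A 3D fluorescence stack, axis order (z, y, x).

    ``z_aspect`` is the ratio of the z step to the xy pixel size; distances
    used for spherical integration scale z displacements by this factor so
    that "spheres" are spheres in physical space.
    """

    voxels: np.ndarray
    z_aspect: float = 3.0

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3 or v.shape[0] < 1:
            raise ValueError("voxels must be a 3D (z, y, x) array with >= 1 slice")
        if not np.all(np.isfinite(v)):
            raise ValueError("voxels must be finite")
        if np.any(v < 0):
            raise ValueError("voxels must be non-negative")
        if self.z_aspect <= 0:
            raise ValueError("z_aspect must be positive")
        self.voxels = v

    @property
    def shape(self) -> tuple:
        return self.voxels.shape


def max_intensity_projection(stack: ImageStack) -> np.ndarray:
    """Project the stack onto 2D: pixel (y, x) = max over z of voxel (z, y, x)."""
    if not isinstance(stack, ImageStack):
        stack = ImageStack(np.asarray(stack))
    return stack.voxels.max(axis=0)
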