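"""Isotropic resampling and region-of-interest cropping.

CT reconstructions are anisotropic (slice spacing larger than the in-plane
pixel); before volumetry each stack is linearly interpolated along z onto a
grid whose spacing equals the in-plane pixel size, so a voxel count times
spacing³ is a volume.  Interpolation is applied to grey values *before*
thresholding.  A single crop box, fixed for the whole time series, restricts
the grid to the region containing the aneurysm (and discards the skull),
keeping the volumes comparable across timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import VolumeStack


@dataclass
class IsotropicVolume:
    """A 3D HU grid with one isotropic spacing (mm)."""

    voxels: np.ndarray
    spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    source_index: int = 0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class CropBox:
    """Axis-aligned half-open index ranges ``[lo, hi)`` on each axis."""

    x: tuple[int, int]
    y: tuple[int, int]
    z: tuple[int, int]

    def validate(self, shape: tuple[int, int, int]) -> None:
        for (lo, hi), n, name in zip((self.x, self.y, self.z), shape, "xyz"):
            if not (0 <= lo < hi <= n):
                raise ValueError(
                    f"crop box {name} range [{lo}, {hi}) invalid for axis length {n}"
                )

    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(*self.x), slice(*self.y), slice(*self.z))

    @classmethod
    def full(cls, shape: tuple[int, int, int]) -> "CropBox":
        return cls((0, shape[0]), (0, shape[1]), (0, shape[2]))

    def as_list(self) -> list[int]:
        return [*self.x, *self.y, *self.z]

    @classmethod
    def from_list(cls, v) -> "CropBox":
        return cls((v[0], v[1]), (v[2], v[3]), (v[4], v[5]))


def resample_isotropic(stack: VolumeStack) -> IsotropicVolume:
    """Trilinear (here: linear along z) resampling to isotropic voxels.

    The target spacing is the in-plane pixel size; x–y samples are untouched.
    New slice planes fall on the original grid's z extent, clamped to the
    first/last slice centers (no extrapolation).  When the slice spacing is
    an integer multiple of the pixel size, original slice centers map onto
    output planes exactly.
    """
    sx, sy, sz = stack.spacing
    if not np.isclose(sx, sy):
        raise ValueError(f"in-plane pixels must be square, got X_v={sx} Y_v={sy}")
    if sz < sx - 1e-12:
        raise ValueError("slice spacing must be >= in-plane pixel size")
    nz = stack.voxels.shape[2]
    extent = (nz - 1) * sz
    n_new = int(np.floor(extent / sx + 1e-9)) + 1
    z_new = np.arange(n_new) * sx  # mm from first slice center
    zf = np.clip(z_new / sz, 0.0, nz - 1.0)
    k0 = np.minimum(zf.astype(int), nz - 2) if nz > 1 else np.zeros(n_new, int)
    w = zf - k0
    v = stack.voxels
    if nz == 1:
        out = np.repeat(v, 1, axis=2).copy()
    else:
        out = v[:, :, k0] * (1.0 - w) + v[:, :, k0 + 1] * w
    return IsotropicVolume(
        voxels=out, spacing=float(sx), origin=stack.origin, source_index=stack.index
    )


def crop(volume: IsotropicVolume, box: CropBox) -> IsotropicVolume:
    """Extract the sub-grid of ``box`` (half-open index ranges).

    Spacing is preserved and the origin shifted to the new first voxel.
    """
    box.validate(volume.shape)
    sub = volume.voxels[box.slices()].copy()
    s = volume.spacing
    ox, oy, oz = volume.origin
    origin = (ox + box.x[0] * s, oy + box.y[0] * s, oz + box.z[0] * s)
    return IsotropicVolume(
        voxels=sub, spacing=s, origin=origin, source_index=volume.source_index
    )
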