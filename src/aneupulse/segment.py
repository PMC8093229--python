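"""HU thresholding and aneurysm-sac isolation.

Segmentation is deliberately simple, matching how dynamic CT angiography
volumetry is done in practice: one global HU threshold turns the isotropic
grey volume into a black-white occupancy grid, and geometric masks isolate
the sac from the parent vessel and surroundings.  Two masking schemes are
provided:

* the *bench* scheme — a crop box plus a per-slice elliptic mask that
  follows the (not perfectly straight) parent vessel down the stack and
  removes it;
* the *in-vivo* scheme — polygonal masks drawn on multiple plane families
  (XY, XZ, YZ), each applying to a slab of slices; a voxel is kept iff it
  lies inside every mask applicable to it.

The threshold is fixed once per series: per-timepoint thresholds would
confound pulsation with threshold drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath

from .preprocess import IsotropicVolume, CropBox, crop as crop_volume


@dataclass
class BinaryVolume:
    """Thresholded occupancy grid; volume = count of 1-voxels × spacing³."""

    occupancy: np.ndarray
    spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    source_index: int = 0

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy).astype(np.uint8)

    @property
    def n_white(self) -> int:
        return int(np.count_nonzero(self.occupancy))

    @property
    def volume_mm3(self) -> float:
        return self.n_white * self.spacing**3

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape


def binarize(volume: IsotropicVolume, threshold_hu: float) -> BinaryVolume:
    """Occupancy = 1 where HU ≥ threshold (ties count as vessel/sac)."""
    return BinaryVolume(
        occupancy=(volume.voxels >= threshold_hu),
        spacing=volume.spacing,
        origin=volume.origin,
        source_index=volume.source_index,
    )


def suggest_threshold(
    volume: IsotropicVolume,
    sac_seed_point: tuple[int, int, int],
    ball_radius_mm: float = 1.0,
    min_separation_hu: float = 50.0,
) -> float:
    """Automated surrogate for the visually chosen threshold.

    Returns the midpoint between a robust lumen HU (median inside a small
    ball at the seed) and the background HU (mode of the whole volume in
    10 HU bins — background dominates the field of view).  Deterministic.
    """
    v = volume.voxels
    seed = tuple(int(c) for c in sac_seed_point)
    for c, n in zip(seed, v.shape):
        if not 0 <= c < n:
            raise ValueError(f"seed point {seed} outside grid of shape {v.shape}")
    r_vox = max(2, int(round(ball_radius_mm / volume.spacing)))
    sl = tuple(slice(max(c - r_vox, 0), min(c + r_vox + 1, n)) for c, n in zip(seed, v.shape))
    lumen = float(np.median(v[sl]))
    edges = np.arange(np.floor(v.min()) - 5.0, np.ceil(v.max()) + 15.0, 10.0)
    counts, edges = np.histogram(v, bins=edges)
    background = float((edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]) / 2.0)
    if lumen - background < min_separation_hu:
        raise ValueError(
            "no bimodality: lumen estimate "
            f"{lumen:.1f} HU is not separated from background {background:.1f} HU"
        )
    return (lumen + background) / 2.0


# ---------------------------------------------------------------------------
# Bench scheme: crop + vessel-following elliptic mask
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in the x–y plane, physical mm coordinates."""

    cx: float
    cy: float
    a: float  # semi-axis along x, mm
    b: float  # semi-axis along y, mm

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("ellipse semi-axes must be positive")

    def contains(self, x: np.ndarray, y: np.ndarray, scale: float = 1.0) -> np.ndarray:
        return ((x - self.cx) / (self.a * scale)) ** 2 + (
            (y - self.cy) / (self.b * scale)
        ) ** 2 <= 1.0


@dataclass
class EllipseTrack:
    """One ellipse per slice over a slice range, plus flagged (empty) slices."""

    ellipses: dict[int, Ellipse]
    flagged: list[int] = field(default_factory=list)

    @property
    def slice_range(self) -> tuple[int, int]:
        ks = sorted(self.ellipses)
        return (ks[0], ks[-1] + 1)

    def centers(self) -> np.ndarray:
        ks = sorted(self.ellipses)
        return np.array([[self.ellipses[k].cx, self.ellipses[k].cy] for k in ks])


def _plane_coords(binary: BinaryVolume):
    nx, ny, _ = binary.shape
    ox, oy, _ = binary.origin
    s = binary.spacing
    x = ox + np.arange(nx) * s
    y = oy + np.arange(ny) * s
    return np.meshgrid(x, y, indexing="ij")


def track_vessel(
    binary: BinaryVolume,
    init_ellipse: Ellipse,
    init_slice: int,
    slice_range: tuple[int, int] | None = None,
    search_margin: float = 1.5,
) -> EllipseTrack:
    """Follow the parent vessel slice by slice.

    Starting from an ellipse drawn over the vessel cross-section on one
    slice, the ellipse is recentered on each successive slice to the
    centroid of occupied voxels found inside the previous ellipse dilated by
    ``search_margin`` (growth proceeds outward from the initialization slice
    in both z directions).  Slices where no occupied voxel is found keep the
    previous center and are flagged.
    """
    lo, hi = slice_range if slice_range is not None else (0, binary.shape[2])
    if not (lo <= init_slice < hi):
        raise ValueError("init_slice outside slice_range")
    X, Y = _plane_coords(binary)
    occ = binary.occupancy

    def recenter(ellipse: Ellipse, k: int) -> Ellipse | None:
        inside = ellipse.contains(X, Y, scale=search_margin)
        pts = occ[:, :, k].astype(bool) & inside
        if not pts.any():
            return None
        return Ellipse(float(X[pts].mean()), float(Y[pts].mean()), ellipse.a, ellipse.b)

    first = recenter(init_ellipse, init_slice)
    if first is None:
        raise ValueError(
            f"initial ellipse contains no occupied voxels on slice {init_slice}"
        )
    ellipses: dict[int, Ellipse] = {init_slice: first}
    flagged: list[int] = []
    for direction in (1, -1):
        prev = first
        k = init_slice + direction
        while lo <= k < hi:
            cur = recenter(prev, k)
            if cur is None:
                cur = prev
                flagged.append(k)
            ellipses[k] = cur
            prev = cur
            k += direction
    return EllipseTrack(ellipses=ellipses, flagged=sorted(flagged))


# ---------------------------------------------------------------------------
# In-vivo scheme: polygonal masks on multiple planes
# ---------------------------------------------------------------------------

_PLANE_AXES = {"XY": (0, 1, 2), "XZ": (0, 2, 1), "YZ": (1, 2, 0)}


@dataclass(frozen=True)
class PolyMask:
    """A simple polygon on one plane family, applying to a slab of slices.

    ``vertices`` are (u, v) physical mm coordinates in the plane's own axes
    (XY → (x, y), XZ → (x, z), YZ → (y, z)); ``slab`` is a half-open index
    range on the orthogonal axis.  Voxel membership is decided at the voxel
    center with the even-odd rule.
    """

    plane: str
    vertices: tuple[tuple[float, float], ...]
    slab: tuple[int, int]

    def __post_init__(self) -> None:
        if self.plane not in _PLANE_AXES:
            raise ValueError(f"plane must be one of {sorted(_PLANE_AXES)}")
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")


@dataclass
class PolyMaskSet:
    """Masks from several planes; a voxel is kept iff inside all applicable."""

    masks: list[PolyMask] = field(default_factory=list)


def _poly_keep(binary: BinaryVolume, mask: PolyMask) -> np.ndarray:
    """Boolean keep-array for one polygonal mask (True where kept)."""
    au, av, aw = _PLANE_AXES[mask.plane]
    s = binary.spacing
    coords = [binary.origin[i] + np.arange(binary.shape[i]) * s for i in range(3)]
    U, V = np.meshgrid(coords[au], coords[av], indexing="ij")
    pts = np.column_stack([U.ravel(), V.ravel()])
    inside2d = MplPath(np.asarray(mask.vertices)).contains_points(pts).reshape(U.shape)
    keep = np.ones(binary.shape, dtype=bool)
    lo, hi = mask.slab
    lo, hi = max(lo, 0), min(hi, binary.shape[aw])
    idx3 = [None, None, None]
    idx3[au], idx3[av] = slice(None), slice(None)
    for k in range(lo, hi):
        idx3[aw] = k
        # broadcast the 2D inside mask onto the slab slice
        sl = tuple(idx3)
        keep[sl] &= inside2d
    return keep


def apply_masks(
    binary: BinaryVolume,
    crop: CropBox | None = None,
    track: EllipseTrack | None = None,
    polys: PolyMaskSet | None = None,
) -> BinaryVolume:
    """Isolate the aneurysm sac.

    Bench scheme (``track``): voxels inside the per-slice vessel ellipse are
    removed, then the crop box is applied.  In-vivo scheme (``polys``): a
    voxel is kept iff it lies inside every polygon mask whose slab covers
    it; an empty mask set leaves the input unchanged.  Masking never adds
    voxels.
    """
    occ = binary.occupancy.astype(bool).copy()
    if track is not None:
        X, Y = _plane_coords(binary)
        for k, ell in track.ellipses.items():
            if 0 <= k < binary.shape[2]:
                occ[:, :, k] &= ~ell.contains(X, Y)
    if polys is not None:
        for mask in polys.masks:
            occ &= _poly_keep(binary, mask)
    out = BinaryVolume(
        occupancy=occ,
        spacing=binary.spacing,
        origin=binary.origin,
        source_index=binary.source_index,
    )
    if crop is not None:
        iso = IsotropicVolume(
            voxels=out.occupancy.astype(float),
            spacing=out.spacing,
            origin=out.origin,
            source_index=out.source_index,
        )
        cropped = crop_volume(iso, crop)
        out = BinaryVolume(
            occupancy=cropped.voxels > 0.5,
            spacing=cropped.spacing,
            origin=cropped.origin,
            source_index=cropped.source_index,
        )
    return out
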