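"""Expression-domain segmentation and positive-cell calling.

A gene's expression domain is segmented by thresholding its channel followed
by morphological closing then opening with a ball the size of a typical cell
diameter (the internuclear distance, IND), keeping only the largest connected
component. A nucleus is called positive when its centre lies inside the
domain or within half the IND of the domain's border — equivalently, inside
the domain dilated by half the IND, so deep-interior cells are always
positive. An optional relative quantification measures per-cell fluorescence
corrected for background and depth attenuation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .detection import NucleusSet
from .volume_io import VolumeImage

__all__ = [
    "ExpressionDomain",
    "PositivityCall",
    "ball_footprint",
    "segment_domain",
    "call_positive_cells",
    "quantify_expression",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ExpressionDomain:
    """Binary 3D mask of one gene's expression domain, plus its border.

    ``mask`` shares the grid and world frame of the source channel. The
    boundary is the set of mask voxels with at least one background
    6-neighbour, reported as world coordinates of voxel centres. An
    all-background mask is a flagged empty domain, not an error.
    """

    mask: np.ndarray
    spacing: tuple[float, float, float]
    gene: str = ""
    threshold_used: float = float("nan")
    _boundary: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("domain mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()

    @property
    def boundary(self) -> np.ndarray:
        """World coordinates (n, 3) of mask voxels touching the background."""
        if self._boundary is None:
            if self.is_empty:
                self._boundary = np.empty((0, 3))
            else:
                cross = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
                interior = ndimage.binary_erosion(self.mask, structure=cross, border_value=0)
                idx = np.argwhere(self.mask & ~interior)
                self._boundary = (idx + 0.5) * np.asarray(self.spacing)
        return self._boundary

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Strict membership: is each world point inside a mask voxel?"""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.rint(pts / np.asarray(self.spacing) - 0.5).astype(int)
        shape = np.asarray(self.mask.shape)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        out = np.zeros(len(pts), dtype=bool)
        if inside.any():
            ii = idx[inside]
            out[inside] = self.mask[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out


@dataclass
class PositivityCall:
    """Per-nucleus expression flags under the half-IND border rule."""

    flags: np.ndarray
    rule_radius: float
    gene: str = ""

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def n_positive(self) -> int:
        return int(self.flags.sum())


def ball_footprint(diameter_um: float, spacing: tuple[float, float, float]) -> np.ndarray:
    """Digital Euclidean ball of physical ``diameter_um`` on an anisotropic grid.

    The ball is defined in world units, so anisotropic voxels yield
    anisotropic voxel radii; every axis keeps at least the centre voxel.
    """
    if diameter_um <= 0:
        raise ValueError("structuring-element diameter must be positive")
    radius = diameter_um / 2.0
    sp = np.asarray(spacing, dtype=float)
    nvox = np.maximum(np.floor(radius / sp).astype(int), 0)
    grids = np.meshgrid(*[np.arange(-n, n + 1) for n in nvox], indexing="ij")
    dist2 = sum((g * s) ** 2 for g, s in zip(grids, sp))
    return dist2 <= radius ** 2 + 1e-9


def segment_domain(
    vol: VolumeImage, threshold_fraction: float, ind: float, gene: str = ""
) -> ExpressionDomain:
    """Threshold + closing + opening + largest-component segmentation.

    The threshold is a fraction of the channel's maximum; the structuring
    element is a ball of diameter ``ind`` (one cell diameter) in world µm.
    Closing is applied before opening, in exactly that order; the opening step
    leaves only the largest 26-connected pattern.
    """
    if not (0 < threshold_fraction < 1):
        raise ValueError("threshold_fraction must lie in (0, 1)")
    if ind <= 0:
        raise ValueError("internuclear distance must be positive")
    vals = vol.values
    raw = vals >= threshold_fraction * float(vals.max(initial=0.0))
    if vals.max(initial=0.0) <= 0 or not raw.any():
        return ExpressionDomain(np.zeros(vol.shape, dtype=bool), vol.spacing,
                                gene=gene, threshold_used=threshold_fraction)
    ball = ball_footprint(ind, vol.spacing)
    closed = ndimage.binary_closing(raw, structure=ball)
    opened = ndimage.binary_opening(closed, structure=ball)
    if not opened.any():
        return ExpressionDomain(np.zeros(vol.shape, dtype=bool), vol.spacing,
                                gene=gene, threshold_used=threshold_fraction)
    labels, n = ndimage.label(opened, structure=_CONN26)
    if n > 1:
        sizes = ndimage.sum_labels(opened, labels, index=np.arange(1, n + 1))
        opened = labels == (1 + int(np.argmax(sizes)))
    return ExpressionDomain(opened, vol.spacing, gene=gene, threshold_used=threshold_fraction)


def call_positive_cells(
    ns: NucleusSet,
    dom: ExpressionDomain,
    radius_factor: float = 0.5,
    ind: float | None = None,
) -> PositivityCall:
    """Flag nuclei whose centre lies in the domain or near its border.

    A nucleus is positive iff its centre is inside the mask or within
    ``radius_factor`` times the internuclear distance (Euclidean, world µm) of
    the nearest boundary voxel. With ``radius_factor = 0`` this reduces to
    strict point-in-mask membership. An empty domain yields all-false flags.
    """
    if radius_factor < 0:
        raise ValueError("radius_factor must be non-negative")
    if ind is None:
        ind = ns.ind
    radius = radius_factor * ind
    if dom.is_empty or len(ns) == 0:
        return PositivityCall(np.zeros(len(ns), dtype=bool), radius, gene=dom.gene)
    flags = dom.contains(ns.centers)
    if radius > 0 and not flags.all():
        d, _ = cKDTree(dom.boundary).query(ns.centers[~flags])
        flags[~flags] = d <= radius
    return PositivityCall(flags, radius, gene=dom.gene)


def quantify_expression(
    gene_vol: VolumeImage,
    nucleus_vol: VolumeImage,
    ns: NucleusSet,
    ind: float,
    normalize: bool = True,
) -> np.ndarray:
    """Relative per-cell expression level in [0, 1].

    For each nucleus the mean gene intensity inside a ball of radius IND about
    its centre is measured; the mean background intensity (outside the embryo
    mask derived from the nucleus channel) is subtracted; the result is
    divided by a depth penetration factor f(z) — the embryo-mask mean of the
    nucleus channel at depth z, normalised to its maximum over z — and finally
    min-max normalised to [0, 1] per specimen.
    """
    if gene_vol.shape != nucleus_vol.shape:
        raise ValueError("gene and nucleus channels must share the same grid")
    if len(ns) == 0:
        return np.empty(0)
    spacing = np.asarray(gene_vol.spacing)

    # embryo mask from the smoothed nucleus channel
    smooth = ndimage.gaussian_filter(nucleus_vol.values.astype(np.float32), sigma=ind / 2 / spacing)
    embryo_mask = smooth > 0.1 * float(smooth.max(initial=0.0))
    outside = ~embryo_mask
    background = float(gene_vol.values[outside].mean()) if outside.any() else 0.0

    # depth attenuation profile from the nucleus channel
    nz = nucleus_vol.shape[2]
    f = np.zeros(nz)
    for iz in range(nz):
        sel = embryo_mask[:, :, iz]
        if sel.any():
            f[iz] = float(nucleus_vol.values[:, :, iz][sel].mean())
    if f.max() <= 0:
        raise ValueError("depth factor is zero everywhere: no embryo signal")
    f /= f.max()

    ball = np.argwhere(ball_footprint(2 * ind, gene_vol.spacing))
    ball -= (np.asarray(ball_footprint(2 * ind, gene_vol.spacing).shape) - 1) // 2
    shape = np.asarray(gene_vol.shape)
    levels = np.empty(len(ns))
    centres_idx = gene_vol.voxel_indices(ns.centers, clip=True)
    for i, cidx in enumerate(centres_idx):
        vox = cidx + ball
        keep = np.all((vox >= 0) & (vox < shape), axis=1)
        vox = vox[keep]
        mean_intensity = float(gene_vol.values[vox[:, 0], vox[:, 1], vox[:, 2]].mean())
        fz = f[cidx[2]]
        if fz <= 0:
            raise ValueError(f"depth factor is zero at occupied depth z-index {cidx[2]}")
        levels[i] = (mean_intensity - background) / fz
    if not normalize:
        return levels
    lo, hi = levels.min(), levels.max()
    if hi > lo:
        levels = (levels - lo) / (hi - lo)
    else:
        levels = np.ones_like(levels)
    return levels
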