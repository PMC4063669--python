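"""Nuclear centre detection by difference-of-Gaussians band-pass filtering.

Nuclear centres are taken at the local maxima of a smoothed, simplified
version of the nuclear counterstain channel: the image is convolved with two
Gaussians of different standard deviations, their difference is computed, and
only grey values above a threshold (a fraction of the filtered image's
maximum) are retained. Candidate maxima closer than the small σ collapse to
their brightest member. Detections can be swept over a parameter grid and
scored against ground-truth centres by greedy closest-pair matching.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume_io import DetectionConfig, VolumeImage

__all__ = [
    "DetectionParams",
    "NucleusSet",
    "DetectionScore",
    "dog_filter",
    "detect_centers",
    "sweep_parameters",
    "evaluate_detection",
    "internuclear_distance",
]


@dataclass(frozen=True)
class DetectionParams:
    """Band-pass parameters: σ in µm, threshold as a fraction of the DoG max."""

    sigma_small: float
    sigma_large: float
    threshold_fraction: float

    def __post_init__(self) -> None:
        if not (0 < self.sigma_small < self.sigma_large):
            raise ValueError(
                f"need 0 < sigma_small < sigma_large, got "
                f"{self.sigma_small} / {self.sigma_large}"
            )
        if not (0 <= self.threshold_fraction <= 1):
            raise ValueError("threshold_fraction must lie in [0, 1]")


@dataclass
class NucleusSet:
    """Detected (or ground-truth) nuclear centres in world µm coordinates."""

    centers: np.ndarray
    source: DetectionParams | str = "ground_truth"
    _ind: float | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        if len(c) > 1:
            # pairwise distinctness via nearest-neighbour check
            d, _ = cKDTree(c).query(c, k=2)
            if np.any(d[:, 1] == 0.0):
                raise ValueError("nucleus centres must be pairwise distinct")
        self.centers = c

    def __len__(self) -> int:
        return len(self.centers)

    @property
    def ind(self) -> float:
        """Mean internuclear distance (µm), lazily computed and cached."""
        if self._ind is None:
            self._ind = internuclear_distance(self)
        return self._ind

    def subset(self, mask: np.ndarray) -> "NucleusSet":
        return NucleusSet(self.centers[np.asarray(mask)], self.source)


@dataclass
class DetectionScore:
    """Detection quality against a manually labelled ground truth."""

    n_gt: int
    n_correct: int
    n_fp: int
    n_fn: int

    def __post_init__(self) -> None:
        if self.n_correct + self.n_fn != self.n_gt:
            raise ValueError("n_correct + n_fn must equal n_gt")

    @property
    def error_rate(self) -> float:
        """(FP + FN) / GT."""
        return (self.n_fp + self.n_fn) / self.n_gt


def dog_filter(vol: VolumeImage, p: DetectionParams) -> VolumeImage:
    """Difference-of-Gaussians band-pass with thresholding.

    Both σ are physical (µm) and are converted to per-axis voxel σ through the
    volume's spacing, so anisotropic sampling is filtered isotropically in
    world space. Output values below ``threshold_fraction`` times the filtered
    maximum are set to zero.
    """
    spacing = np.asarray(vol.spacing)
    img = vol.values.astype(np.float32, copy=False)
    lo = ndimage.gaussian_filter(img, sigma=p.sigma_small / spacing)
    hi = ndimage.gaussian_filter(img, sigma=p.sigma_large / spacing)
    out = lo - hi
    peak = float(out.max(initial=0.0))
    if peak > 0:
        out[out < p.threshold_fraction * peak] = 0.0
    else:
        out[:] = 0.0
    return vol.copy_with(out, f"dog[{vol.channel_name}]")


def detect_centers(filtered: VolumeImage, p: DetectionParams) -> NucleusSet:
    """Nuclear centres at the local maxima of a DoG-filtered volume.

    A voxel is a candidate when its (positive) value is not exceeded in its
    26-neighbourhood. Candidates closer than ``sigma_small`` (world distance)
    collapse to their highest-valued member, ties resolved toward the lowest
    linear voxel index, which also reduces an equal-valued plateau to a single
    centre. An all-zero input yields an empty set.
    """
    vals = filtered.values
    footprint = np.ones((3, 3, 3), dtype=bool)
    neighbourhood_max = ndimage.maximum_filter(vals, footprint=footprint, mode="constant", cval=0.0)
    cand = np.argwhere((vals >= neighbourhood_max) & (vals > 0))
    if len(cand) == 0:
        return NucleusSet(np.empty((0, 3)), source=p)
    values = vals[tuple(cand.T)]
    linear = np.ravel_multi_index(tuple(cand.T), vals.shape)
    order = np.lexsort((linear, -values))  # by decreasing value, then lowest index
    world = filtered.world_coordinates(cand[order])
    accepted: list[np.ndarray] = []
    tree_points: list[np.ndarray] = []
    r2 = p.sigma_small ** 2
    for pt in world:
        if not any(np.dot(pt - q, pt - q) < r2 for q in tree_points):
            accepted.append(pt)
            tree_points.append(pt)
    return NucleusSet(np.asarray(accepted), source=p)


def sweep_parameters(
    vol: VolumeImage, config: DetectionConfig
) -> list[tuple[DetectionParams, NucleusSet]]:
    """One detection run per (σ_small, σ_large, threshold) grid point.

    Grid points are visited in lexicographic order so sweeps are deterministic
    and directly comparable across runs.
    """
    grid = config.sweep_grid()
    if not grid:
        raise ValueError("parameter sweep grid is empty")
    results = []
    for ss, sl, th in grid:
        params = DetectionParams(ss, sl, th)
        results.append((params, detect_centers(dog_filter(vol, params), params)))
    return results


def evaluate_detection(
    detected: NucleusSet, gt: np.ndarray, match_radius: float
) -> DetectionScore:
    """Score detections against ground-truth centres.

    Greedy one-to-one matching: candidate (detected, gt) pairs within
    ``match_radius`` are accepted globally closest first (ties toward lower
    indices). Unmatched detections count as false positives, unmatched
    ground-truth centres as false negatives, and the error rate is
    ``(FP + FN) / n_gt``.
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be positive")
    gt = np.asarray(gt, dtype=float).reshape(-1, 3)
    if len(gt) == 0:
        raise ValueError("empty ground truth: error rate undefined")
    det = detected.centers
    if len(det) == 0:
        return DetectionScore(n_gt=len(gt), n_correct=0, n_fp=0, n_fn=len(gt))
    pairs: list[tuple[float, int, int]] = []
    tree = cKDTree(gt)
    for i, neighbours in enumerate(tree.query_ball_point(det, match_radius)):
        for j in neighbours:
            pairs.append((float(np.linalg.norm(det[i] - gt[j])), i, j))
    pairs.sort()
    used_det: set[int] = set()
    used_gt: set[int] = set()
    n_correct = 0
    for _, i, j in pairs:
        if i in used_det or j in used_gt:
            continue
        used_det.add(i)
        used_gt.add(j)
        n_correct += 1
    return DetectionScore(
        n_gt=len(gt),
        n_correct=n_correct,
        n_fp=len(det) - n_correct,
        n_fn=len(gt) - n_correct,
    )


def internuclear_distance(ns: NucleusSet | np.ndarray) -> float:
    """Mean over centres of the distance to the nearest other centre (µm)."""
    centers = ns.centers if isinstance(ns, NucleusSet) else np.asarray(ns, dtype=float)
    if len(centers) < 2:
        raise ValueError("internuclear distance requires at least 2 centres")
    d, _ = cKDTree(centers).query(centers, k=2)
    return float(d[:, 1].mean())
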