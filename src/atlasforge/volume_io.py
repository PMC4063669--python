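"""Volume and table I/O plus the run configuration.

Conventions
-----------
* World coordinates are continuous, right-handed, in micrometres (µm).
* A voxel index ``(ix, iy, iz)`` (0-based) maps to the world position of its
  centre: ``world = (index + 0.5) * spacing``.
* Volumes are stored in arrays indexed ``[ix, iy, iz]``; on disk they are
  multi-page TIFFs (pages = z, rows = y, columns = x) with the physical voxel
  spacing carried in a JSON sidecar (``<file>.json``) and, redundantly, in
  ImageJ-style TIFF resolution tags.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("atlasforge")

__all__ = [
    "VolumeImage",
    "RunConfig",
    "DetectionConfig",
    "SegmentationConfig",
    "RegistrationConfig",
    "GeometryConfig",
    "AtlasConfig",
    "RunLog",
    "read_volume",
    "write_volume",
    "read_cell_table",
    "write_cell_table",
]


# --------------------------------------------------------------------------
# VolumeImage
# --------------------------------------------------------------------------

@dataclass
class VolumeImage:
    """A single-channel 3D scalar grid with physical voxel spacing.

    Attributes
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar intensities, indexed ``[ix, iy, iz]``.
    spacing : tuple of 3 floats
        Voxel spacing in µm along (x, y, z); strictly positive.
    channel_name : str
        Free-text channel label (e.g. ``"nuclei"``, ``"gsc"``).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("volume grid must be a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be three strictly positive values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def extent(self) -> np.ndarray:
        """Physical size of the grid in µm along each axis."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """World positions (µm) of voxel centres for integer ``indices`` (n, 3)."""
        return (np.asarray(indices, dtype=float) + 0.5) * np.asarray(self.spacing)

    def voxel_indices(self, points: np.ndarray, clip: bool = False) -> np.ndarray:
        """Nearest-voxel indices for world ``points`` (n, 3); optionally clipped."""
        idx = np.rint(np.asarray(points, dtype=float) / np.asarray(self.spacing) - 0.5)
        idx = idx.astype(int)
        if clip:
            idx = np.clip(idx, 0, np.asarray(self.shape) - 1)
        return idx

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which world points fall inside the grid's bounds."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return np.all((p >= 0) & (p <= self.extent), axis=1)

    def copy_with(self, values: np.ndarray, channel_name: str | None = None) -> "VolumeImage":
        return VolumeImage(values, self.spacing,
                           self.channel_name if channel_name is None else channel_name)


# --------------------------------------------------------------------------
# TIFF round trip
# --------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(vol: VolumeImage, path: str | Path) -> Path:
    """Write ``vol`` as a multi-page TIFF plus a JSON spacing sidecar."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    pages = np.ascontiguousarray(vol.values.transpose(2, 1, 0))  # (z, y, x)
    sx, sy, sz = vol.spacing
    if pages.dtype.kind == "f":
        pages = pages.astype(np.float32)
    tifffile.imwrite(
        path,
        pages,
        imagej=pages.dtype in (np.dtype(np.uint8), np.dtype(np.uint16), np.dtype(np.float32)),
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
    )
    sidecar = {
        "spacing_um": [sx, sy, sz],
        "channel_name": vol.channel_name,
        "shape_xyz": list(vol.shape),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _spacing_from_tags(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Recover (sx, sy, sz) from ImageJ metadata / resolution tags, if present."""
    try:
        page = tif.pages[0]
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        sx = xres[1] / xres[0]
        sy = yres[1] / yres[0]
        meta = tif.imagej_metadata or {}
        sz = float(meta["spacing"])
        return (float(sx), float(sy), sz)
    except (KeyError, TypeError, ZeroDivisionError, IndexError):
        return None


def read_volume(path: str | Path) -> VolumeImage:
    """Read a multi-page TIFF written by :func:`write_volume`.

    The voxel spacing is taken from the JSON sidecar when present, otherwise
    from the TIFF resolution tags; a file with neither is rejected rather than
    silently assumed isotropic.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = tif.asarray()
            tag_spacing = _spacing_from_tags(tif)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ValueError(f"malformed TIFF file {path}: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"expected a 3D stack in {path}, got shape {pages.shape}")
    channel = ""
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "spacing_um" not in meta:
            raise ValueError(f"sidecar {sidecar} is missing required field 'spacing_um'")
        spacing = tuple(float(s) for s in meta["spacing_um"])
        channel = str(meta.get("channel_name", ""))
    elif tag_spacing is not None:
        spacing = tag_spacing
    else:
        raise ValueError(
            f"{path}: no voxel spacing metadata found (field 'spacing_um' in a "
            f"JSON sidecar or TIFF resolution tags); refusing to assume isotropy"
        )
    return VolumeImage(pages.transpose(2, 1, 0), spacing, channel)


# --------------------------------------------------------------------------
# Cell tables (nucleus sets and cell profile tables) as CSV
# --------------------------------------------------------------------------

_COORD_COLUMNS = ["cell_id", "x_um", "y_um", "z_um"]


def write_cell_table(obj, path: str | Path) -> Path:
    """Write a NucleusSet or CellProfileTable as a UTF-8 CSV.

    Columns are ``cell_id,x_um,y_um,z_um`` followed by one 0/1 column per gene
    and one integer ``rep_<gene>`` column per averaged gene.
    """
    path = Path(path)
    df = _to_dataframe(obj)
    df.to_csv(path, index=False)
    return path


def _to_dataframe(obj) -> pd.DataFrame:
    from .atlas import CellProfileTable
    from .detection import NucleusSet

    if isinstance(obj, NucleusSet):
        c = obj.centers
        return pd.DataFrame({
            "cell_id": np.arange(len(c)),
            "x_um": c[:, 0], "y_um": c[:, 1], "z_um": c[:, 2],
        })
    if isinstance(obj, CellProfileTable):
        return obj.to_dataframe()
    raise TypeError(f"cannot serialize object of type {type(obj).__name__}")


def read_cell_table(path: str | Path):
    """Read a cell-table CSV back into a NucleusSet or CellProfileTable.

    A table with only coordinate columns round-trips as a NucleusSet; any
    additional gene columns make it a CellProfileTable. Gene columns must be
    strictly 0/1 and repetition columns non-negative integers.
    """
    from .atlas import CellProfileTable
    from .detection import NucleusSet

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in _COORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    gene_cols = [c for c in df.columns
                 if c not in _COORD_COLUMNS and not c.startswith("rep_")]
    if not gene_cols:
        centers = df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        return NucleusSet(centers, source="file")
    return CellProfileTable.from_dataframe(df)


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass
class DetectionConfig:
    """Difference-of-Gaussians detection parameters and their sweep grid.

    The band-pass σ pair defaults to the expert values 2.8 µm / 12 µm with the
    threshold at 7% of the filtered image's maximum; the sweep ranges span
    σ_small ∈ [2, 4] µm, σ_large ∈ [8, 16] µm and thresholds 1–15%.
    """

    sigma_small: float = 2.8
    sigma_large: float = 12.0
    threshold_fraction: float = 0.07
    sigma_small_range: tuple[float, float] = (2.0, 4.0)
    sigma_large_range: tuple[float, float] = (8.0, 16.0)
    threshold_range: tuple[float, float] = (0.01, 0.15)
    sweep_steps: tuple[int, int, int] = (3, 3, 5)
    match_radius: float = 4.2  # µm; approximate radius of the smallest nucleus

    def validate(self) -> None:
        if not (0 < self.sigma_small < self.sigma_large):
            raise ValueError("need 0 < sigma_small < sigma_large")
        if self.sigma_small_range[1] >= self.sigma_large_range[0]:
            raise ValueError("sigma_small range must lie entirely below sigma_large range")
        lo, hi = self.threshold_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("threshold range must lie within [0, 1]")
        if not (0 <= self.threshold_fraction <= 1):
            raise ValueError("threshold_fraction must lie within [0, 1]")

    def sweep_grid(self) -> list[tuple[float, float, float]]:
        """Lexicographically ordered (σ_small, σ_large, threshold) grid points."""
        self.validate()
        ss = np.linspace(*self.sigma_small_range, self.sweep_steps[0])
        sl = np.linspace(*self.sigma_large_range, self.sweep_steps[1])
        th = np.linspace(*self.threshold_range, self.sweep_steps[2])
        return [(float(a), float(b), float(c)) for a in ss for b in sl for c in th]


@dataclass
class SegmentationConfig:
    """Per-gene segmentation thresholds and the positivity rule radius."""

    thresholds: dict[str, float] = field(default_factory=dict)
    default_threshold: float = 0.5
    radius_factor: float = 0.5  # positivity radius as a fraction of the IND

    def threshold_for(self, gene: str) -> float:
        return float(self.thresholds.get(gene, self.default_threshold))

    def validate(self) -> None:
        for g, t in {**self.thresholds, "": self.default_threshold}.items():
            if not (0 < t < 1):
                raise ValueError(f"segmentation threshold for {g!r} must be in (0, 1)")
        if self.radius_factor < 0:
            raise ValueError("radius_factor must be non-negative")


@dataclass
class RegistrationConfig:
    """Rigid-refinement settings (regular-step gradient ascent on NCC)."""

    max_iterations: int = 200
    initial_step_um: float = 6.0   # ≈ 0.5 · IND
    min_step_um: float = 0.05
    relaxation: float = 0.5
    map_spacing_um: float = 4.0    # isotropic grid for shape weight maps


@dataclass
class GeometryConfig:
    """Referential-extraction settings."""

    provisional_av: tuple[float, float, float] = (0.0, 0.0, 1.0)
    outer_fraction: float = 0.5    # shell selection for the sphere fit
    margin_fraction: float = 0.05  # southernmost nuclei for the margin plane


@dataclass
class AtlasConfig:
    """Atlas assembly settings."""

    majority: int | None = None    # None -> ceil(J / 2)
    reference_gene: str = "gsc"


@dataclass
class RunConfig:
    """Full pipeline configuration, loadable from YAML."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    atlas: AtlasConfig = field(default_factory=AtlasConfig)
    seed: int | None = 0
    manual_offsets: dict[str, dict] = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.detection.validate()
        self.segmentation.validate()
        if self.seed is None:
            raise ValueError("run configuration must specify a seed")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        def build(tp, key):
            sub = dict(raw.get(key, {}) or {})
            known = {f.name for f in dataclasses.fields(tp)}
            unknown = set(sub) - known
            if unknown:
                raise ValueError(f"unknown {key} config keys: {sorted(unknown)}")
            for k, v in sub.items():
                if isinstance(v, list):
                    sub[k] = tuple(v)
            return tp(**sub)

        cfg = cls(
            detection=build(DetectionConfig, "detection"),
            segmentation=build(SegmentationConfig, "segmentation"),
            registration=build(RegistrationConfig, "registration"),
            geometry=build(GeometryConfig, "geometry"),
            atlas=build(AtlasConfig, "atlas"),
            seed=raw.get("seed"),  # absent -> None -> validate() rejects
            manual_offsets=dict(raw.get("manual_offsets", {}) or {}),
            synthetic=dict(raw.get("synthetic", {}) or {}),
        )
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path


# --------------------------------------------------------------------------
# Run log: every supervised choice is recorded so a run can be replayed
# --------------------------------------------------------------------------

class RunLog:
    """Append-only JSON-lines log of supervised parameter choices.

    Interactive supervision (chosen σ/threshold, manual registration offsets)
    is replayed from configuration; each choice is recorded here so any run is
    reproducible from its log.
    """

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        self.entries: list[dict] = []

    def record(self, stage: str, **params) -> None:
        entry = {"stage": stage, **params}
        self.entries.append(entry)
        logger.info("run-log %s: %s", stage, params)
        if self.path is not None:
            with self.path.open("a") as fh:
                fh.write(json.dumps(entry, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return str(obj)
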