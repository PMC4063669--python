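"""Atlas assembly: per-stage templates of mapped gene expression.

Mapped specimens contribute positivity calls on the template's nuclei. Per
template cell and gene, a repetition count V (0..J over J specimens) records
how many analyzed patterns selected it as positive; a majority threshold on V
gives the mean expression domain; leave-one-out boundary statistics quantify
mapping accuracy plus inter-individual variability. Domains are represented
at the cell level — cells, not voxels, are the biologically meaningful unit —
with Voronoi (nearest-nucleus) rasterization only for profiles and plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .detection import NucleusSet
from .geometry import RigidTransform, apply_transform
from .segmentation import ExpressionDomain, PositivityCall, call_positive_cells

__all__ = [
    "CellProfileTable",
    "MappingRecord",
    "select_template_positives",
    "repetition_counts",
    "mean_domain",
    "domain_boundary_points",
    "loo_boundary_stats",
    "boundary_distance_histogram",
    "repetition_profile",
    "count_discrepancy",
]


@dataclass
class CellProfileTable:
    """Template cells × genes binary profile matrix with repetition counts.

    ``G[i, j]`` is 1 iff cell i expresses gene j; ``V[gene]`` holds per-cell
    repetition counts in 0..J for genes averaged over J mapped specimens.
    """

    positions: np.ndarray
    genes: list[str]
    G: np.ndarray
    V: dict[str, np.ndarray] = field(default_factory=dict)
    stage: str = ""
    cell_ids: np.ndarray | None = None
    observed: np.ndarray | None = None  # False where no analyzed volume covered the cell

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.G = np.asarray(self.G)
        if self.G.shape != (len(self.positions), len(self.genes)):
            raise ValueError("G must be cells × genes")
        if not np.isin(self.G, (0, 1)).all():
            raise ValueError("G entries must be 0/1")
        self.G = self.G.astype(np.int8)
        for gene, col in self.V.items():
            col = np.asarray(col)
            if col.shape[0] != len(self.positions):
                raise ValueError(f"V column for {gene!r} has wrong length")
            if np.any(col < 0) or not np.issubdtype(col.dtype, np.integer):
                raise ValueError(f"V column for {gene!r} must hold non-negative integers")
            self.V[gene] = col.astype(int)
        if self.cell_ids is None:
            self.cell_ids = np.arange(len(self.positions))
        if self.observed is not None:
            self.observed = np.asarray(self.observed, dtype=bool)

    @property
    def n_cells(self) -> int:
        return len(self.positions)

    def column(self, gene: str) -> np.ndarray:
        return self.G[:, self.genes.index(gene)]

    def positive_any(self) -> np.ndarray:
        """Cells with at least one positive gene."""
        return self.G.any(axis=1)

    def profiles(self) -> np.ndarray:
        """Integer profile codes: each row of G read as a binary number."""
        weights = 1 << np.arange(len(self.genes))[::-1]
        return self.G.astype(np.int64) @ weights

    def with_G(self, new_g: np.ndarray) -> "CellProfileTable":
        return CellProfileTable(self.positions, list(self.genes), new_g,
                                dict(self.V), self.stage,
                                None if self.cell_ids is None else self.cell_ids.copy(),
                                None if self.observed is None else self.observed.copy())

    # -- CSV interchange ---------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "cell_id": self.cell_ids,
            "x_um": self.positions[:, 0],
            "y_um": self.positions[:, 1],
            "z_um": self.positions[:, 2],
        }
        for j, gene in enumerate(self.genes):
            data[gene] = self.G[:, j]
        for gene, col in self.V.items():
            data[f"rep_{gene}"] = col
        return pd.DataFrame(data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, stage: str = "") -> "CellProfileTable":
        coord = ["cell_id", "x_um", "y_um", "z_um"]
        genes = [c for c in df.columns if c not in coord and not c.startswith("rep_")]
        g = df[genes].to_numpy()
        if not np.isin(g, (0, 1)).all():
            bad = [c for c in genes if not np.isin(df[c], (0, 1)).all()]
            raise ValueError(f"non-binary values in gene columns {bad}")
        v = {}
        for c in df.columns:
            if c.startswith("rep_"):
                col = df[c].to_numpy()
                if not np.issubdtype(col.dtype, np.integer):
                    if not np.allclose(col, np.round(col)):
                        raise ValueError(f"repetition column {c} must be integer")
                    col = col.astype(int)
                v[c[4:]] = col
        return cls(
            positions=df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
            genes=genes, G=g.astype(np.int8), V=v, stage=stage,
            cell_ids=df["cell_id"].to_numpy(),
        )


@dataclass
class MappingRecord:
    """Provenance of one analyzed specimen's mapping onto the template."""

    specimen_id: str
    gene: str
    init_transform: RigidTransform
    refined_transform: RigidTransform
    cc: float
    n_e: int                      # positives in the analyzed embryo
    n_t: int                      # positives selected in the template
    ind_analyzed: float = float("nan")
    ind_template: float = float("nan")
    manual_offset: RigidTransform | None = None

    @property
    def composed_transform(self) -> RigidTransform:
        t = self.refined_transform
        if self.manual_offset is not None:
            t = self.manual_offset.compose(t)
        return t

    @property
    def ind_ratio(self) -> float:
        return self.ind_analyzed / self.ind_template


def select_template_positives(
    template_ns: NucleusSet,
    mapped_dom: ExpressionDomain,
    radius_factor: float = 0.5,
    ind: float | None = None,
) -> PositivityCall:
    """Positive template cells under the mapped domain.

    Applies the identical half-IND border rule used for the analyzed embryos,
    evaluated with the template's own internuclear distance.
    """
    return call_positive_cells(template_ns, mapped_dom, radius_factor, ind)


def map_domain_to_template(
    dom: ExpressionDomain,
    transform: RigidTransform,
    template_grid,
) -> ExpressionDomain:
    """Resample an analyzed-specimen domain mask into the template grid."""
    from .volume_io import VolumeImage

    moving = VolumeImage(dom.mask.astype(np.float32), dom.spacing, dom.gene)
    mapped = apply_transform(moving, transform, reference=template_grid)
    return ExpressionDomain(mapped.values >= 0.5, template_grid.spacing,
                            gene=dom.gene, threshold_used=dom.threshold_used)


def repetition_counts(calls: list[PositivityCall | np.ndarray], j_specimens: int | None = None) -> np.ndarray:
    """Per-template-cell count of specimens calling it positive (V column)."""
    if not calls:
        raise ValueError("need at least one positivity call")
    flags = np.stack([
        c.flags if isinstance(c, PositivityCall) else np.asarray(c, dtype=bool)
        for c in calls
    ])
    if j_specimens is not None and flags.shape[0] != j_specimens:
        raise ValueError(f"expected {j_specimens} calls, got {flags.shape[0]}")
    return flags.sum(axis=0).astype(int)


def mean_domain(v_column: np.ndarray, j_specimens: int, majority: int | None = None) -> np.ndarray:
    """Mean expression domain: cells whose repetition count reaches a majority.

    The default majority is ⌈J/2⌉; ``majority=1`` gives the union of the
    individual patterns and ``majority=J`` their intersection.
    """
    v = np.asarray(v_column)
    if majority is None:
        majority = math.ceil(j_specimens / 2)
    if not (1 <= majority <= j_specimens):
        raise ValueError("majority must lie in 1..J")
    if np.any(v > j_specimens):
        raise ValueError("repetition counts exceed the number of specimens")
    return v >= majority


def domain_boundary_points(
    flags: np.ndarray, template_ns: NucleusSet, ind: float
) -> np.ndarray:
    """Boundary of a cell-level domain.

    Positive cells with at least one negative neighbour within 1.5·IND; an
    isolated positive cell is its own boundary. Returns world coordinates.
    """
    flags = np.asarray(flags, dtype=bool)
    pos = template_ns.centers[flags]
    neg = template_ns.centers[~flags]
    if len(pos) == 0:
        return np.empty((0, 3))
    if len(neg) == 0:
        return pos.copy()
    d, _ = cKDTree(neg).query(pos)
    return pos[d <= 1.5 * ind]


def _directed_boundary_distances(
    flags_from: np.ndarray, flags_to: np.ndarray, ns: NucleusSet, ind: float
) -> np.ndarray:
    b_from = domain_boundary_points(flags_from, ns, ind)
    b_to = domain_boundary_points(flags_to, ns, ind)
    if len(b_from) == 0 or len(b_to) == 0:
        return np.empty(0)
    d, _ = cKDTree(b_to).query(b_from)
    return d


def loo_boundary_stats(
    specimen_flags: list[np.ndarray],
    template_ns: NucleusSet,
    ind: float,
    majority: int | None = None,
) -> pd.DataFrame:
    """Leave-one-out boundary distances of each specimen's domain to the mean.

    For each specimen j, the mean domain is rebuilt from the other J−1
    patterns; every boundary point of specimen j is assigned the distance to
    the closest boundary point of that mean domain. Returns per-specimen mean
    and standard deviation plus the pooled distances.
    """
    j_total = len(specimen_flags)
    if j_total < 2:
        raise ValueError("leave-one-out requires at least 2 specimens")
    flags = [np.asarray(f, dtype=bool) for f in specimen_flags]
    rows = []
    pooled: list[np.ndarray] = []
    for j in range(j_total):
        others = [f for i, f in enumerate(flags) if i != j]
        v = repetition_counts(others)
        mean_flags = mean_domain(v, j_total - 1, majority)
        d = _directed_boundary_distances(flags[j], mean_flags, template_ns, ind)
        pooled.append(d)
        rows.append({
            "specimen": j,
            "mean_distance_um": float(d.mean()) if len(d) else float("nan"),
            "sd_distance_um": float(d.std()) if len(d) else float("nan"),
            "n_boundary_points": int(len(d)),
        })
    df = pd.DataFrame(rows)
    df.attrs["pooled_distances_um"] = np.concatenate(pooled) if pooled else np.empty(0)
    return df


def boundary_distance_histogram(
    domain_flags: np.ndarray,
    mean_flags: np.ndarray,
    template_ns: NucleusSet,
    ind: float,
) -> dict:
    """Histogram of per-boundary-point distances to the mean-domain boundary.

    Distances are binned at IND/2 resolution; the fractions of points within
    one and two cell rows (1·IND, 2·IND) are reported alongside.
    """
    d = _directed_boundary_distances(domain_flags, mean_flags, template_ns, ind)
    if len(d) == 0:
        return {"bin_edges_um": np.array([0.0, ind / 2]), "counts": np.array([0]),
                "fraction_within_one_row": float("nan"),
                "fraction_within_two_rows": float("nan"),
                "distances_um": d}
    n_bins = max(int(np.ceil(d.max() / (ind / 2))), 1)
    edges = np.arange(n_bins + 1) * (ind / 2)
    counts, _ = np.histogram(d, bins=edges)
    return {
        "bin_edges_um": edges,
        "counts": counts,
        "fraction_within_one_row": float(np.mean(d <= ind)),
        "fraction_within_two_rows": float(np.mean(d <= 2 * ind)),
        "distances_um": d,
    }


def repetition_profile(
    v_column: np.ndarray,
    center: np.ndarray,
    directions: dict[str, np.ndarray],
    template_ns: NucleusSet,
    ind: float,
    extent_um: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Repetition-count profiles along cutting lines through a centroid.

    Along each direction (typically the frame's lateral / radial / sagittal
    axes), V is sampled every IND/2 by nearest-nucleus (Voronoi) lookup.
    """
    v = np.asarray(v_column)
    tree = cKDTree(template_ns.centers)
    if extent_um is None:
        span = template_ns.centers.max(axis=0) - template_ns.centers.min(axis=0)
        extent_um = float(np.linalg.norm(span)) / 2
    steps = np.arange(-extent_um, extent_um + ind / 4, ind / 2)
    out = {}
    for name, direction in directions.items():
        u = np.asarray(direction, dtype=float)
        u = u / np.linalg.norm(u)
        pts = np.asarray(center, dtype=float) + steps[:, None] * u
        d, idx = tree.query(pts)
        values = np.where(d <= 1.5 * ind, v[idx], 0)
        out[name] = pd.DataFrame({"offset_um": steps, "repetitions": values})
    return out


def count_discrepancy(records: list[MappingRecord]) -> pd.DataFrame:
    """Scatter table of analyzed vs template positive-cell counts.

    One row per mapping: n_e (analyzed positives), n_t (template positives)
    and the analyzed/template internuclear-distance ratio.
    """
    rows = [{
        "specimen": r.specimen_id,
        "gene": r.gene,
        "n_e": r.n_e,
        "n_t": r.n_t,
        "ind_ratio": r.ind_ratio,
    } for r in records]
    return pd.DataFrame(rows, columns=["specimen", "gene", "n_e", "n_t", "ind_ratio"])
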