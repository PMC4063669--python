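"""Ground-truthed synthetic embryos, cohorts, and profile populations.

The generator emulates a blastula-stage embryo imaged by confocal microscopy:
a single layer of nuclei on a spherical cap (the blastoderm) rendered as
isotropic Gaussian blobs in a nuclear counterstain channel, plus per-gene
expression channels that are smooth plateaus over angular caps of the
blastoderm shell, with additive Gaussian noise clipped at zero. Whole-embryo
"template" specimens and partial dorsal-view "analyzed" specimens (cropped,
rigidly misaligned, radius-rescaled) are produced with full ground truth:
true centres, per-gene positivity flags, domain masks, the rigid transform
back to template coordinates, and the analytic anatomical frame.

Nucleus placement is quasi-uniform: jittered spherical Fibonacci-lattice
proposals with dart-throwing rejection of any point closer than twice the
nucleus σ to an accepted point, which reproduces the near-contact epithelial
packing of a real blastoderm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import EmbryoFrame, RigidTransform
from .volume_io import VolumeImage

__all__ = [
    "GeneDomainSpec",
    "EmbryoSpec",
    "GroundTruth",
    "Specimen",
    "generate_embryo",
    "generate_cohort",
    "generate_profile_population",
    "draw_radius_scales",
]

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class GeneDomainSpec:
    """Angular-cap definition of one gene's expression domain.

    A nucleus expresses the gene when the angle between its direction from
    the sphere centre and ``axis`` is at most ``half_angle_deg``.
    """

    axis: tuple[float, float, float]
    half_angle_deg: float

    def unit_axis(self) -> np.ndarray:
        a = np.asarray(self.axis, dtype=float)
        return a / np.linalg.norm(a)


def _default_gene_domains() -> dict[str, GeneDomainSpec]:
    # gsc-like reference domain: dorsal (+y), near the blastoderm margin
    return {
        "gsc": GeneDomainSpec((0.0, 0.92, 0.39), 20.0),
        "geneB": GeneDomainSpec((0.0, 0.64, 0.77), 25.0),
    }


@dataclass(frozen=True)
class EmbryoSpec:
    """Parameters of one synthetic embryo.

    Defaults describe a scaled-down early-gastrula blastoderm: sphere radius
    120 µm, a cap covering 40% of the sphere, ~400 near-contact nuclei of
    blob σ 3 µm (internuclear distance ≈ 14 µm), 20:1 peak signal-to-noise,
    and anisotropic confocal-like voxels of 1.5 × 1.5 × 3 µm.
    """

    sphere_center: tuple[float, float, float] | None = None
    sphere_radius: float = 120.0
    cap_fraction: float = 0.4
    n_nuclei: int = 400
    nucleus_sigma: float = 3.0
    intensity_peak: float = 200.0
    noise_sd: float = 10.0
    voxel_spacing: tuple[float, float, float] = (1.5, 1.5, 3.0)
    gene_domains: dict[str, GeneDomainSpec] = field(default_factory=_default_gene_domains)
    seed: int = 0
    attenuation_lambda: float | None = None  # optional exp(-depth/λ) signal decay
    jitter_fraction: float = 0.08            # lattice jitter, fraction of spacing

    def __post_init__(self) -> None:
        if not (0 < self.cap_fraction <= 1):
            raise ValueError("cap_fraction must lie in (0, 1]")
        if self.n_nuclei < 10:
            raise ValueError("too few nuclei: n_nuclei must be at least 10")
        if self.nucleus_sigma <= 0:
            raise ValueError("nucleus_sigma must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacings must all be positive")
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")

    @property
    def min_separation(self) -> float:
        """Hard-core separation between nuclei: twice the blob σ (µm)."""
        return 2.0 * self.nucleus_sigma

    @property
    def cap_cos_theta(self) -> float:
        """cos of the cap's polar half-opening (cap measured from +z)."""
        return 1.0 - 2.0 * self.cap_fraction

    @property
    def cap_area(self) -> float:
        return 4.0 * math.pi * self.sphere_radius ** 2 * self.cap_fraction

    @property
    def lattice_constant(self) -> float:
        """Hexagonal-lattice constant for n_nuclei on the cap (µm)."""
        return math.sqrt(2.0 * self.cap_area / (math.sqrt(3.0) * self.n_nuclei))

    @property
    def nominal_spacing(self) -> float:
        """Generator spacing (µm): the mean nearest-neighbour distance of the
        deterministic Fibonacci scaffold the nuclei are jittered from. The
        realized internuclear distance of a generated embryo tracks this
        value to within 10%."""
        from scipy.spatial import cKDTree

        pts = self.sphere_radius * _cap_fibonacci_points(self.n_nuclei, self.cap_cos_theta)
        d, _ = cKDTree(pts).query(pts, k=2)
        return float(d[:, 1].mean())


@dataclass
class GroundTruth:
    """Everything the generator knows about a specimen."""

    true_centers: np.ndarray
    true_positive_flags: dict[str, np.ndarray]
    true_domain_masks: dict[str, np.ndarray]
    true_transform: RigidTransform
    true_frame: EmbryoFrame
    sphere_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sphere_radius: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.true_centers)
        for gene, flags in self.true_positive_flags.items():
            if len(flags) != n:
                raise ValueError(f"flag length mismatch for gene {gene!r}")
        r = self.true_transform.rotation
        if abs(np.linalg.det(r) - 1.0) > 1e-6:
            raise ValueError("ground-truth transform must be a proper rigid motion")


@dataclass
class Specimen:
    """One rendered specimen: channels plus its ground truth."""

    nucleus_channel: VolumeImage
    gene_channels: dict[str, VolumeImage]
    truth: GroundTruth
    name: str = ""


# --------------------------------------------------------------------------
# Nucleus placement
# --------------------------------------------------------------------------

def _cap_fibonacci_points(n: int, cos_theta_min: float) -> np.ndarray:
    """Area-uniform spherical Fibonacci lattice on the cap z/r ≥ cos_theta_min."""
    k = np.arange(n)
    z = 1.0 - (1.0 - cos_theta_min) * (k + 0.5) / n
    phi = _GOLDEN_ANGLE * k
    s = np.sqrt(np.maximum(1.0 - z ** 2, 0.0))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _tangent_jitter(unit_pts: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian jitter in each point's tangent plane, reprojected to the sphere."""
    n = len(unit_pts)
    ref = np.where(np.abs(unit_pts[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    t1 = np.cross(unit_pts, ref)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(unit_pts, t1)
    off = rng.normal(scale=sigma, size=(n, 2))
    jittered = unit_pts + off[:, :1] * t1 + off[:, 1:] * t2
    return jittered / np.linalg.norm(jittered, axis=1, keepdims=True)


def _place_nuclei(spec: EmbryoSpec, center: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Dart-throwing placement on the cap with hard-core rejection.

    Proposals are jittered Fibonacci-lattice points; a proposal closer than
    ``min_separation`` to an accepted centre is rejected and re-drawn. Raises
    when the separation constraint cannot be met within 10·n proposals.
    """
    r = spec.sphere_radius
    min_sep2 = spec.min_separation ** 2
    sigma_unit = spec.jitter_fraction * spec.lattice_constant / r
    base = _cap_fibonacci_points(spec.n_nuclei, spec.cap_cos_theta)
    accepted: list[np.ndarray] = []
    # cell-list over accepted points for O(1) neighbour lookups
    cell = max(spec.min_separation, 1e-6)
    grid: dict[tuple[int, int, int], list[int]] = {}

    def ok(p: np.ndarray) -> bool:
        key = tuple((p // cell).astype(int))
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for idx in grid.get((key[0] + dx, key[1] + dy, key[2] + dz), ()):
                        q = accepted[idx]
                        if (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 + (p[2] - q[2]) ** 2 < min_sep2:
                            return False
        return True

    attempts = 0
    max_attempts = 10 * spec.n_nuclei
    order = rng.permutation(spec.n_nuclei)
    queue = list(order)
    while queue and attempts < max_attempts:
        i = queue[0]
        attempts += 1
        u = _tangent_jitter(base[i:i + 1], sigma_unit, rng)[0]
        p = center + r * u
        if ok(p):
            queue.pop(0)
            accepted.append(p)
            grid.setdefault(tuple((p // cell).astype(int)), []).append(len(accepted) - 1)
        # else: retry the same lattice site with a fresh jitter draw
    if queue:
        raise ValueError(
            f"could not satisfy the minimum-separation constraint for "
            f"{spec.n_nuclei} nuclei within {max_attempts} proposals"
        )
    return np.asarray(accepted)


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def _grid_for(spec: EmbryoSpec) -> tuple[tuple[int, int, int], np.ndarray]:
    """Grid shape and sphere centre such that the cap plus a 2σ+blob margin
    fits inside world coordinates starting at 0."""
    r = spec.sphere_radius
    ct = spec.cap_cos_theta
    sin_t = math.sqrt(max(1.0 - ct ** 2, 0.0)) if ct > -1 else 0.0
    horiz = r if ct < 0 else r * sin_t
    margin = 4.0 * spec.nucleus_sigma
    if spec.sphere_center is None:
        cx = cy = horiz + margin
        cz = margin - r * min(ct, 1.0)   # lowest cap point at z = margin
        center = np.array([cx, cy, cz])
    else:
        center = np.asarray(spec.sphere_center, dtype=float)
    upper = center + np.array([horiz, horiz, r]) + margin
    sp = np.asarray(spec.voxel_spacing)
    shape = tuple(int(np.ceil(u / s)) for u, s in zip(upper, sp))
    lowest = center + np.array([-horiz, -horiz, r * min(ct, 1.0)]) - margin
    if np.any(lowest < -1e-6):
        raise ValueError("grid cannot contain the cap plus the required margin")
    return shape, center


def _render_blobs(
    shape: tuple[int, int, int],
    spacing: np.ndarray,
    centers: np.ndarray,
    sigma: float,
    peak: float,
) -> np.ndarray:
    vals = np.zeros(shape, dtype=np.float32)
    half = np.ceil(4.0 * sigma / spacing).astype(int)
    shp = np.asarray(shape)
    for c in centers:
        cidx = c / spacing - 0.5
        lo = np.maximum(np.floor(cidx - half).astype(int), 0)
        hi = np.minimum(np.ceil(cidx + half).astype(int) + 1, shp)
        if np.any(lo >= hi):
            continue
        ax = [(np.arange(lo[d], hi[d]) + 0.5) * spacing[d] - c[d] for d in range(3)]
        g = np.exp(-(ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
                     + ax[2][None, None, :] ** 2) / (2.0 * sigma ** 2))
        vals[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += peak * g.astype(np.float32)
    return vals


def _domain_mask(
    shape: tuple[int, int, int],
    spacing: np.ndarray,
    center: np.ndarray,
    radius: float,
    shell_half_thickness: float,
    axis: np.ndarray,
    half_angle_deg: float,
) -> np.ndarray:
    """Voxels of the blastoderm shell inside the gene's angular cap."""
    nx, ny, nz = shape
    xs = (np.arange(nx) + 0.5) * spacing[0] - center[0]
    ys = (np.arange(ny) + 0.5) * spacing[1] - center[1]
    zs = (np.arange(nz) + 0.5) * spacing[2] - center[2]
    dx = xs[:, None, None]
    dy = ys[None, :, None]
    dz = zs[None, None, :]
    rr = np.sqrt(dx ** 2 + dy ** 2 + dz ** 2)
    shell = np.abs(rr - radius) <= shell_half_thickness
    cos_half = math.cos(math.radians(half_angle_deg))
    dot = (dx * axis[0] + dy * axis[1] + dz * axis[2]) / np.maximum(rr, 1e-9)
    return shell & (dot >= cos_half)


def _point_in_cap(
    points: np.ndarray, center: np.ndarray, axis: np.ndarray, half_angle_deg: float
) -> np.ndarray:
    d = points - center
    norms = np.linalg.norm(d, axis=1)
    cosang = (d @ axis) / np.maximum(norms, 1e-9)
    return cosang >= math.cos(math.radians(half_angle_deg))


def _analytic_frame(
    spec: EmbryoSpec, center: np.ndarray, radius: float, gsc_centroid: np.ndarray
) -> EmbryoFrame:
    """Exact frame of the untransformed embryo: margin plane at the cap rim."""
    u = np.array([0.0, 0.0, 1.0])
    offset = float(center[2] + radius * spec.cap_cos_theta)
    d = gsc_centroid - center
    v_raw = d - (d @ u) * u
    v = v_raw / np.linalg.norm(v_raw)
    w = np.cross(u, v)
    h = float(center[2]) - offset
    p = center - h * u
    ell = math.sqrt(max(radius ** 2 - h ** 2, 0.0))
    origin = p + ell * v
    return EmbryoFrame(
        sphere_center=center, sphere_radius=radius,
        margin_plane=(u, offset),
        symmetry_plane=(w, float(w @ center)),
        u=u, v=v, w=w, origin=origin,
    )


def _render_specimen(
    spec: EmbryoSpec,
    centers: np.ndarray,
    sphere_center: np.ndarray,
    radius: float,
    gene_axes: dict[str, np.ndarray],
    shape: tuple[int, int, int],
    noise_rng: np.random.Generator,
) -> tuple[VolumeImage, dict[str, VolumeImage], dict[str, np.ndarray], dict[str, np.ndarray]]:
    from scipy import ndimage

    spacing = np.asarray(spec.voxel_spacing)
    nuc = _render_blobs(shape, spacing, centers, spec.nucleus_sigma, spec.intensity_peak)
    gene_vols: dict[str, VolumeImage] = {}
    masks: dict[str, np.ndarray] = {}
    flags: dict[str, np.ndarray] = {}
    shell_half = 2.0 * spec.nucleus_sigma
    for gene, dom in spec.gene_domains.items():
        axis = gene_axes[gene]
        mask = _domain_mask(shape, spacing, sphere_center, radius, shell_half,
                            axis, dom.half_angle_deg)
        plateau = ndimage.gaussian_filter(
            mask.astype(np.float32), sigma=spec.nucleus_sigma / spacing)
        vals = spec.intensity_peak * plateau
        masks[gene] = mask
        flags[gene] = _point_in_cap(centers, sphere_center, axis, dom.half_angle_deg)
        gene_vols[gene] = VolumeImage(vals, tuple(spacing), gene)

    def finish(vals: np.ndarray) -> np.ndarray:
        if spec.attenuation_lambda is not None:
            depth = (np.arange(shape[2])[::-1] + 0.5) * spacing[2]
            vals = vals * np.exp(-depth / spec.attenuation_lambda)[None, None, :]
        if spec.noise_sd > 0:
            vals = vals + noise_rng.normal(scale=spec.noise_sd, size=shape)
        return np.clip(vals, 0.0, None).astype(np.float32)

    nuc_vol = VolumeImage(finish(nuc), tuple(spacing), "nuclei")
    for gene in gene_vols:
        gene_vols[gene] = gene_vols[gene].copy_with(finish(gene_vols[gene].values))
    return nuc_vol, gene_vols, masks, flags


# --------------------------------------------------------------------------
# Public generators
# --------------------------------------------------------------------------

def true_nucleus_layout(spec: EmbryoSpec) -> tuple[np.ndarray, np.ndarray]:
    """Nucleus centres and sphere centre of ``spec`` without rendering volumes.

    Uses the same placement RNG stream as :func:`generate_embryo`, so the
    returned centres are exactly the ground-truth centres of the rendered
    embryo with the same spec.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_place = np.random.default_rng(ss.spawn(2)[0])
    _, center = _grid_for(spec)
    return _place_nuclei(spec, center, rng_place), center


def generate_embryo(
    spec: EmbryoSpec,
) -> tuple[VolumeImage, dict[str, VolumeImage], GroundTruth]:
    """Render one whole synthetic embryo with full ground truth.

    Deterministic for a fixed ``spec.seed``; the placement and noise RNG
    streams are separate children of the seed so cohorts can share geometry
    while renewing the noise realization.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_place, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    shape, center = _grid_for(spec)
    centers = _place_nuclei(spec, center, rng_place)
    axes = {g: d.unit_axis() for g, d in spec.gene_domains.items()}
    nuc_vol, gene_vols, masks, flags = _render_specimen(
        spec, centers, center, spec.sphere_radius, axes, shape, rng_noise)
    gsc_gene = next(iter(spec.gene_domains))
    frame = _analytic_frame(spec, center, spec.sphere_radius,
                            centers[flags[gsc_gene]].mean(axis=0))
    truth = GroundTruth(
        true_centers=centers,
        true_positive_flags=flags,
        true_domain_masks=masks,
        true_transform=RigidTransform.identity(),
        true_frame=frame,
        sphere_center=center,
        sphere_radius=spec.sphere_radius,
    )
    return nuc_vol, gene_vols, truth


def draw_radius_scales(n: int, rng: np.random.Generator, sd: float = 0.05) -> np.ndarray:
    """Per-specimen radius scaling factors ~ N(1, sd) truncated to ±10%.

    Emulates the observed morphological variability of matched cohorts, in
    which at least 95% of specimens lie within 10% of the mean radius; the
    truncation keeps every draw inside the stated ±10% envelope.
    """
    scales = rng.normal(loc=1.0, scale=sd, size=n)
    while True:
        bad = np.abs(scales - 1.0) > 0.10
        if not bad.any():
            return scales
        scales[bad] = rng.normal(loc=1.0, scale=sd, size=int(bad.sum()))


def _transformed_frame(frame: EmbryoFrame, t: RigidTransform) -> EmbryoFrame:
    r = t.rotation
    n_m = r @ frame.margin_plane[0]
    n_s = r @ frame.symmetry_plane[0]
    center = t.apply(frame.sphere_center)
    return EmbryoFrame(
        sphere_center=center,
        sphere_radius=frame.sphere_radius,
        margin_plane=(n_m, float(n_m @ t.apply(frame.origin))),
        symmetry_plane=(n_s, float(n_s @ center)),
        u=r @ frame.u, v=r @ frame.v, w=r @ frame.w,
        origin=t.apply(frame.origin),
    )


def generate_cohort(
    spec: EmbryoSpec,
    n_analyzed: int,
    view_fraction: float,
    seed: int,
    max_rotation_deg: float = 8.0,
    max_translation_um: float = 10.0,
    radius_scale_sd: float = 0.05,
) -> tuple[Specimen, list[Specimen]]:
    """A whole-embryo template plus partial, misaligned analyzed specimens.

    All specimens share the template's nuclear layout (one individual imaged
    under different conditions would be the limit case); each analyzed
    specimen is rescaled in radius by a draw from N(1, ``radius_scale_sd``),
    rigidly jittered by a random rotation/translation recorded in its ground
    truth, re-rendered with a fresh noise realization, and cropped to a
    dorsal sub-volume containing the reference-gene domain. Every specimen
    carries the reference ("gsc"-like) gene; analyzed specimens keep one
    private gene each, cycling through the spec's non-reference genes.
    """
    if n_analyzed < 1:
        raise ValueError("n_analyzed must be at least 1")
    if not (0 < view_fraction <= 1):
        raise ValueError("view_fraction must lie in (0, 1]")
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 + 2 * n_analyzed)
    template_spec = replace(spec, seed=int(seeds[0] % (2 ** 31)))
    nuc, genes, truth = generate_embryo(template_spec)
    ref_gene = next(iter(spec.gene_domains))
    other_genes = [g for g in spec.gene_domains if g != ref_gene] or [ref_gene]
    template = Specimen(nuc, genes, truth, name="template")

    ss_place = np.random.SeedSequence(template_spec.seed)
    rng_place_state = ss_place.spawn(2)[0]
    rng_cohort = np.random.default_rng(int(seeds[1] % (2 ** 31)))
    scales = draw_radius_scales(n_analyzed, rng_cohort, radius_scale_sd)

    shape, center0 = _grid_for(spec)
    spacing = np.asarray(spec.voxel_spacing)
    analyzed: list[Specimen] = []
    for j in range(n_analyzed):
        s_j = float(scales[j]) if radius_scale_sd > 0 else 1.0
        rng_j = np.random.default_rng(int(seeds[2 + 2 * j] % (2 ** 31)))
        noise_rng_j = np.random.default_rng(int(seeds[3 + 2 * j] % (2 ** 31)))
        # shared layout, rescaled about the sphere centre
        base_centers = truth.true_centers
        centers_j = center0 + s_j * (base_centers - center0)
        if max_rotation_deg > 0 or max_translation_um > 0:
            t_j = RigidTransform.random(
                rng_j, math.radians(max_rotation_deg), max_translation_um, center=center0)
        else:
            t_j = RigidTransform.identity()
        centers_j = t_j.apply(centers_j)
        axes_j = {g: t_j.rotation @ d.unit_axis() for g, d in spec.gene_domains.items()}
        center_j = t_j.apply(center0)
        private = other_genes[j % len(other_genes)]
        spec_j = replace(
            spec,
            gene_domains={g: spec.gene_domains[g] for g in {ref_gene, private}},
            sphere_radius=s_j * spec.sphere_radius,
        )
        nuc_j, genes_j, masks_j, flags_j = _render_specimen(
            spec_j, centers_j, center_j, spec_j.sphere_radius,
            axes_j, shape, noise_rng_j)

        # dorsal crop: bbox of the reference domain dilated by 25% of radius,
        # widened toward the full grid as view_fraction -> 1
        lo_idx, hi_idx = _crop_box(
            masks_j[ref_gene], shape, spacing, spec_j.sphere_radius, view_fraction)
        offset_world = lo_idx * spacing
        crop = tuple(slice(int(a), int(b)) for a, b in zip(lo_idx, hi_idx))
        nuc_c = VolumeImage(nuc_j.values[crop], nuc_j.spacing, nuc_j.channel_name)
        genes_c = {g: VolumeImage(v.values[crop], v.spacing, g) for g, v in genes_j.items()}
        inside = np.all(
            (centers_j >= offset_world + 0.5 * spacing)
            & (centers_j <= hi_idx * spacing - 0.5 * spacing), axis=1)
        centers_c = centers_j[inside] - offset_world
        flags_c = {g: f[inside] for g, f in flags_j.items()}
        masks_c = {g: m[crop] for g, m in masks_j.items()}
        # analyzed -> template world: undo the crop shift, then the jitter
        shift = RigidTransform(np.eye(3), offset_world)
        to_template = t_j.inverse().compose(shift)
        frame_j = _transformed_frame(
            _analytic_frame_for(spec_j, center_j, centers_j, flags_j[ref_gene]),
            shift.inverse())
        truth_j = GroundTruth(
            true_centers=centers_c,
            true_positive_flags=flags_c,
            true_domain_masks=masks_c,
            true_transform=to_template,
            true_frame=frame_j,
            sphere_center=center_j - offset_world,
            sphere_radius=spec_j.sphere_radius,
        )
        analyzed.append(Specimen(nuc_c, genes_c, truth_j, name=f"analyzed_{j}"))
    return template, analyzed


def _analytic_frame_for(
    spec: EmbryoSpec, center: np.ndarray, centers: np.ndarray, gsc_flags: np.ndarray
) -> EmbryoFrame:
    """Analytic frame of a (possibly rotated) specimen, from its true geometry."""
    # margin plane: contains the cap rim; normal along the rotated cap axis.
    # Recover the axis as the direction maximising nucleus support: the mean
    # of unit directions is along the cap axis by symmetry.
    d = centers - center
    u = d.mean(axis=0)
    u /= np.linalg.norm(u)
    offset = float(u @ center + spec.sphere_radius * spec.cap_cos_theta)
    m_gsc = centers[gsc_flags].mean(axis=0)
    dd = m_gsc - center
    v_raw = dd - (dd @ u) * u
    v = v_raw / np.linalg.norm(v_raw)
    w = np.cross(u, v)
    h = float(u @ center) - offset
    p = center - h * u
    ell = math.sqrt(max(spec.sphere_radius ** 2 - h ** 2, 0.0))
    origin = p + ell * v
    return EmbryoFrame(
        sphere_center=center, sphere_radius=spec.sphere_radius,
        margin_plane=(u, offset), symmetry_plane=(w, float(w @ center)),
        u=u, v=v, w=w, origin=origin,
    )


def _crop_box(
    ref_mask: np.ndarray,
    shape: tuple[int, int, int],
    spacing: np.ndarray,
    radius: float,
    view_fraction: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned crop indices for the dorsal partial view."""
    shp = np.asarray(shape)
    if view_fraction >= 1.0:
        return np.zeros(3, dtype=int), shp
    idx = np.argwhere(ref_mask)
    if len(idx) == 0:
        return np.zeros(3, dtype=int), shp
    pad_vox = np.ceil(0.25 * radius / spacing).astype(int)
    lo_dorsal = np.maximum(idx.min(axis=0) - pad_vox, 0)
    hi_dorsal = np.minimum(idx.max(axis=0) + pad_vox + 1, shp)
    # interpolate between the dorsal box (small views) and the full grid
    t = view_fraction
    lo = np.floor(lo_dorsal * (1 - t)).astype(int)
    hi = np.ceil(hi_dorsal * (1 - t) + shp * t).astype(int)
    return np.maximum(lo, 0), np.minimum(hi, shp)


def generate_profile_population(
    profile_freqs: dict[str | tuple, int],
    seed: int = 0,
    genes: list[str] | None = None,
):
    """A cell-profile table with exactly the requested multiset of profiles.

    Keys are binary profiles, either as ``"0101"`` strings or 0/1 tuples, all
    of equal length N; values are non-negative cell counts (at least one
    positive). Cell order is randomized under ``seed``; positions are filler
    (uniform in a 100 µm cube) since only the profiles matter downstream.
    """
    from .atlas import CellProfileTable

    if not profile_freqs:
        raise ValueError("profile_freqs must not be empty")
    parsed: list[tuple[tuple[int, ...], int]] = []
    length = None
    for key, count in profile_freqs.items():
        bits = tuple(int(b) for b in key) if not isinstance(key, tuple) else tuple(int(b) for b in key)
        if any(b not in (0, 1) for b in bits):
            raise ValueError(f"profile {key!r} is not binary")
        if length is None:
            length = len(bits)
        elif len(bits) != length:
            raise ValueError(
                f"profile {key!r} has bit-length {len(bits)}, expected {length}")
        if count < 0:
            raise ValueError("profile counts must be non-negative")
        parsed.append((bits, int(count)))
    total = sum(c for _, c in parsed)
    if total == 0:
        raise ValueError("at least one profile count must be positive")
    rows = np.array([bits for bits, count in parsed for _ in range(count)], dtype=np.int8)
    rng = np.random.default_rng(seed)
    order = rng.permutation(total)
    rows = rows[order]
    positions = rng.uniform(0, 100, size=(total, 3))
    gene_names = genes or [f"g{i}" for i in range(length or 0)]
    if len(gene_names) != length:
        raise ValueError("gene name list must match the profile bit-length")
    return CellProfileTable(
        positions=positions, genes=list(gene_names), G=rows, stage="synthetic")
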