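"""Anatomical referential extraction and rigid mapping onto templates.

Early blastula-stage embryos lack the morphological landmarks required for
landmark-based registration, so partial analyzed volumes are mapped onto
whole-embryo templates in two steps:

1. *Initialization from a common anatomical referential.* A sphere is fitted
   to the outer nuclei; the blastoderm margin is a plane fitted to the
   southernmost nuclei; the bilateral symmetry plane contains the sphere
   centre and the centroid of the reference-gene (gsc) positive nuclei,
   perpendicular to the margin plane. The two planes define a right-handed
   trihedron (u, v, w) — animal–vegetal, dorso-ventral, lateral — with origin
   O at the margin latitude and gsc longitude. Aligning the two frames gives
   the initial rigid transform.
2. *Rigid refinement by intensity registration.* Embryo shapes, weighted by
   an inverse-distance function to the external blastoderm contour, are
   registered by maximising normalised cross-correlation under a
   regular-step gradient-descent optimizer (via SimpleITK / the ITK
   registration framework).

Transforms map world points of the moving (analyzed) frame into the fixed
(template) frame: ``y = R x + t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy.spatial import cKDTree

from .detection import NucleusSet
from .segmentation import PositivityCall
from .volume_io import RegistrationConfig, VolumeImage

__all__ = [
    "RigidTransform",
    "EmbryoFrame",
    "fit_sphere",
    "select_outer_nuclei",
    "fit_margin_plane",
    "build_frame",
    "frame_alignment_transform",
    "shape_weight_map",
    "register_rigid",
    "apply_transform",
    "cohort_radius_report",
]


# --------------------------------------------------------------------------
# Rigid transforms
# --------------------------------------------------------------------------

def _project_to_rotation(m: np.ndarray) -> np.ndarray:
    """Nearest proper rotation (polar decomposition via SVD)."""
    u, _, vt = np.linalg.svd(m)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


@dataclass
class RigidTransform:
    """Proper rigid motion ``y = R x + t`` in world µm coordinates."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if np.max(np.abs(r.T @ r - np.eye(3))) > 1e-5 or np.linalg.det(r) < 0:
            raise ValueError("rotation must be a proper orthonormal matrix (det +1)")
        self.rotation = _project_to_rotation(r)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls, axis: np.ndarray, angle_rad: float,
        translation: np.ndarray = (0.0, 0.0, 0.0),
        center: np.ndarray = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        """Rotation of ``angle_rad`` about ``axis`` through ``center``, then shift."""
        a = np.asarray(axis, dtype=float)
        a = a / np.linalg.norm(a)
        k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
        r = np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)
        c = np.asarray(center, dtype=float)
        t = c - r @ c + np.asarray(translation, dtype=float)
        return cls(r, t)

    @classmethod
    def random(
        cls, rng: np.random.Generator, max_angle_rad: float,
        max_translation: float, center: np.ndarray = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0, max_angle_rad)
        shift = rng.normal(size=3)
        norm = np.linalg.norm(shift)
        if norm > 0:
            shift = shift / norm * rng.uniform(0, max_translation)
        return cls.from_axis_angle(axis, angle, shift, center)

    # -- algebra -----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    @property
    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(),
                "translation_um": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation_um"]))


# --------------------------------------------------------------------------
# Embryo frame (referential)
# --------------------------------------------------------------------------

@dataclass
class EmbryoFrame:
    """Anatomical referential: sphere, margin plane, symmetry plane, basis.

    Planes are stored as ``(unit normal, offset)`` with points x on the plane
    satisfying ``normal · x = offset``. The basis (u, v, w) is the
    animal–vegetal, dorso-ventral and lateral right-handed trihedron; the
    origin O sits on the sphere at the margin latitude and gsc longitude.
    """

    sphere_center: np.ndarray
    sphere_radius: float
    margin_plane: tuple[np.ndarray, float]
    symmetry_plane: tuple[np.ndarray, float]
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    origin: np.ndarray
    fit_rms: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sphere_center", "u", "v", "w", "origin"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        self.margin_plane = (np.asarray(self.margin_plane[0], dtype=float).reshape(3),
                             float(self.margin_plane[1]))
        self.symmetry_plane = (np.asarray(self.symmetry_plane[0], dtype=float).reshape(3),
                               float(self.symmetry_plane[1]))
        b = self.basis
        if np.max(np.abs(b.T @ b - np.eye(3))) > 1e-9:
            raise ValueError("u, v, w must be orthonormal")
        if np.linalg.det(b) < 0:
            raise ValueError("u, v, w must form a right-handed trihedron")
        n_m, d_m = self.margin_plane
        if abs(float(n_m @ self.origin) - d_m) > 1e-6:
            raise ValueError("origin must lie on the margin plane")
        if abs(float(n_m @ self.symmetry_plane[0])) > 1e-9:
            raise ValueError("symmetry plane must be perpendicular to the margin plane")

    @property
    def basis(self) -> np.ndarray:
        """Columns u, v, w."""
        return np.column_stack([self.u, self.v, self.w])

    def to_dict(self) -> dict:
        return {
            "sphere_center_um": self.sphere_center.tolist(),
            "sphere_radius_um": float(self.sphere_radius),
            "margin_plane": {"normal": self.margin_plane[0].tolist(),
                             "offset": self.margin_plane[1]},
            "symmetry_plane": {"normal": self.symmetry_plane[0].tolist(),
                               "offset": self.symmetry_plane[1]},
            "u": self.u.tolist(), "v": self.v.tolist(), "w": self.w.tolist(),
            "origin_um": self.origin.tolist(),
            "fit_rms_um": float(self.fit_rms),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EmbryoFrame":
        return cls(
            sphere_center=np.asarray(d["sphere_center_um"]),
            sphere_radius=float(d["sphere_radius_um"]),
            margin_plane=(np.asarray(d["margin_plane"]["normal"]), d["margin_plane"]["offset"]),
            symmetry_plane=(np.asarray(d["symmetry_plane"]["normal"]),
                            d["symmetry_plane"]["offset"]),
            u=np.asarray(d["u"]), v=np.asarray(d["v"]), w=np.asarray(d["w"]),
            origin=np.asarray(d["origin_um"]),
            fit_rms=float(d.get("fit_rms_um", 0.0)),
        )


# --------------------------------------------------------------------------
# Geometric fits
# --------------------------------------------------------------------------

def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic (linear least-squares) sphere fit.

    Solves ``|x|² = 2 c·x + (r² − |c|²)`` for centre c and radius r.

    Returns
    -------
    (center, radius, rms)
        Fitted centre (µm), radius (µm) and RMS of the radial residuals.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 4:
        raise ValueError("sphere fit requires at least 4 points")
    a = np.column_stack([2 * pts, np.ones(len(pts))])
    b = (pts ** 2).sum(axis=1)
    if np.linalg.matrix_rank(a) < 4:
        raise ValueError("degenerate (coplanar) point set: sphere fit is ill-posed")
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("sphere fit produced a non-positive radius")
    radius = float(np.sqrt(r2))
    rms = float(np.sqrt(np.mean((np.linalg.norm(pts - center, axis=1) - radius) ** 2)))
    return center, radius, rms


def select_outer_nuclei(ns: NucleusSet, fraction: float = 0.5) -> NucleusSet:
    """Outer-shell nuclei: distance from the provisional centroid in the top
    ``fraction``. A documented heuristic for feeding the sphere fit with the
    outermost nuclear layer."""
    if len(ns) == 0:
        raise ValueError("cannot select outer nuclei from an empty set")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    centroid = ns.centers.mean(axis=0)
    r = np.linalg.norm(ns.centers - centroid, axis=1)
    cutoff = np.quantile(r, 1 - fraction)
    # small slack keeps exact ties (a single perfect layer) fully selected
    return ns.subset(r >= cutoff - 1e-9 * max(cutoff, 1.0))


def fit_margin_plane(
    ns: NucleusSet | np.ndarray,
    fraction: float = 0.05,
    provisional_av: np.ndarray = (0.0, 0.0, 1.0),
) -> tuple[np.ndarray, float]:
    """Total-least-squares plane through the southernmost nuclei.

    The ``fraction`` of nuclei lowest along the provisional animal–vegetal
    axis is selected (the blastoderm margin); the fitted normal is re-oriented
    animal-ward (positive dot product with the provisional axis).
    """
    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must lie in (0, 0.5]")
    pts = ns.centers if isinstance(ns, NucleusSet) else np.asarray(ns, dtype=float)
    av = np.asarray(provisional_av, dtype=float)
    av = av / np.linalg.norm(av)
    n_sel = int(np.ceil(fraction * len(pts)))
    if n_sel < 3:
        raise ValueError(f"margin-plane fit needs at least 3 nuclei, selected {n_sel}")
    order = np.argsort(pts @ av)
    sel = pts[order[:n_sel]]
    centroid = sel.mean(axis=0)
    _, _, vt = np.linalg.svd(sel - centroid)
    normal = vt[-1]
    if normal @ av < 0:
        normal = -normal
    return normal, float(normal @ centroid)


def build_frame(
    ns: NucleusSet,
    gsc_call: PositivityCall | np.ndarray,
    provisional_av: np.ndarray = (0.0, 0.0, 1.0),
    outer_fraction: float = 0.5,
    margin_fraction: float = 0.05,
) -> EmbryoFrame:
    """Extract the full anatomical referential from nuclei + gsc positives.

    u is the margin-plane normal (animal-ward); v is the unit projection of
    the gsc centroid direction (from the sphere centre) onto the margin
    plane's direction space (dorso-ventral); w = u × v. The origin O is the
    sphere-centre projection onto the margin plane advanced along v to the
    sphere surface: margin latitude, gsc longitude. The symmetry plane spans
    {u, v} through the sphere centre.
    """
    flags = gsc_call.flags if isinstance(gsc_call, PositivityCall) else np.asarray(gsc_call, bool)
    if flags.shape[0] != len(ns):
        raise ValueError("gsc flags must align with the nucleus set")
    if not flags.any():
        raise ValueError("frame extraction requires at least one gsc-positive nucleus")
    center, radius, rms = fit_sphere(select_outer_nuclei(ns, outer_fraction).centers)
    normal, offset = fit_margin_plane(ns, margin_fraction, provisional_av)
    u = normal
    m_gsc = ns.centers[flags].mean(axis=0)
    d = m_gsc - center
    v_raw = d - (d @ u) * u
    norm_v = np.linalg.norm(v_raw)
    if norm_v < 1e-9 * max(np.linalg.norm(d), 1.0):
        raise ValueError("degenerate dorsal direction: gsc centroid lies on the AV axis")
    v = v_raw / norm_v
    w = np.cross(u, v)
    h = float(u @ center) - offset      # signed distance of centre above margin plane
    p = center - h * u                  # projection of the centre onto the plane
    ell = float(np.sqrt(max(radius ** 2 - h ** 2, 0.0)))
    origin = p + ell * v
    return EmbryoFrame(
        sphere_center=center,
        sphere_radius=radius,
        margin_plane=(u, offset),
        symmetry_plane=(w, float(w @ center)),
        u=u, v=v, w=w,
        origin=origin,
        fit_rms=rms,
    )


def frame_alignment_transform(frame_a: EmbryoFrame, frame_t: EmbryoFrame) -> RigidTransform:
    """The unique rigid map sending (O_a; u_a, v_a, w_a) to (O_t; u_t, v_t, w_t)."""
    r = frame_t.basis @ frame_a.basis.T
    t = frame_t.origin - r @ frame_a.origin
    return RigidTransform(r, t)


def cohort_radius_report(frames_or_radii) -> float:
    """Fraction of specimens whose fitted radius lies within 10% of the mean."""
    radii = np.asarray([
        f.sphere_radius if isinstance(f, EmbryoFrame) else float(f)
        for f in frames_or_radii
    ])
    if len(radii) == 0:
        raise ValueError("empty cohort")
    mean = radii.mean()
    return float(np.mean(np.abs(radii - mean) <= 0.10 * mean))


# --------------------------------------------------------------------------
# Shape weight maps and rigid refinement
# --------------------------------------------------------------------------

def shape_weight_map(
    ns: NucleusSet,
    ind: float,
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0),
    shape: tuple[int, int, int] | None = None,
) -> VolumeImage:
    """Distance-weighted embryo-shape map for pixel-based registration.

    The nuclear mask is the union of balls of radius 0.5·IND about the
    centres; the external blastoderm contour is that mask's outer boundary
    offset outward by a further 0.5·IND. Voxels between the mask interior and
    the contour are weighted ``1 / (1 + d/IND)`` with d the distance to the
    contour (weight 1 exactly on the contour, decaying inward and to zero
    beyond it).
    """
    if len(ns) == 0:
        raise ValueError("cannot build a shape map from an empty nucleus set")
    sp = np.asarray(spacing, dtype=float)
    if shape is None:
        upper = ns.centers.max(axis=0) + 1.5 * ind
        shape = tuple(int(np.ceil(u / s)) for u, s in zip(upper, sp))
    nx, ny, nz = shape
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    vox_world = (np.stack([ix, iy, iz], axis=-1).reshape(-1, 3) + 0.5) * sp
    d_nuc, _ = cKDTree(ns.centers).query(vox_world)
    half = 0.5 * ind
    # signed distance to the external contour (negative inside the shell)
    s = d_nuc - 2 * half     # 0 on the contour, <0 inside the dilated mask
    weights = np.where(s <= 0, 1.0 / (1.0 + np.abs(s) / ind), 0.0)
    return VolumeImage(weights.reshape(shape).astype(np.float32), tuple(sp), "shape_weight")


def _to_sitk(vol: VolumeImage) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(
        vol.values.transpose(2, 1, 0).astype(np.float32)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(s) / 2 for s in vol.spacing))  # voxel-centre convention
    return img


def _euler_from_rigid(t: RigidTransform, center: np.ndarray) -> sitk.Euler3DTransform:
    e = sitk.Euler3DTransform()
    e.SetCenter(tuple(float(c) for c in center))
    e.SetMatrix(tuple(t.rotation.ravel()), 1e-8)
    # y = R (x - c) + c + t_e  ==  R x + t  with  t_e = t - c + R c
    t_e = t.translation - center + t.rotation @ center
    e.SetTranslation(tuple(float(x) for x in t_e))
    return e


def _rigid_from_euler(e: sitk.Euler3DTransform) -> RigidTransform:
    r = np.asarray(e.GetMatrix()).reshape(3, 3)
    c = np.asarray(e.GetCenter())
    t_e = np.asarray(e.GetTranslation())
    return RigidTransform(r, c + t_e - r @ c)


def register_rigid(
    moving: VolumeImage,
    fixed: VolumeImage,
    init: RigidTransform | None = None,
    settings: RegistrationConfig | None = None,
) -> tuple[RigidTransform, float]:
    """Refine a rigid transform by maximising normalised cross-correlation.

    Starting from ``init`` (moving → fixed world points), the transform is
    optimised with a regular-step gradient-descent optimizer with parameter
    scaling from physical shift, step halving on non-improvement, and a fixed
    iteration cap. The refined transform is only accepted if its correlation
    is at least that of the initialization (monotone acceptance); the final
    correlation coefficient is returned alongside.

    A badly initialised registration (e.g. > 30° off) may converge to a worse
    local optimum; the returned ``cc`` makes such runs visible for
    supervision rather than failing silently.
    """
    settings = settings or RegistrationConfig()
    init = init or RigidTransform.identity()
    fixed_img = _to_sitk(fixed)
    moving_img = _to_sitk(moving)
    center = np.asarray(fixed_img.TransformContinuousIndexToPhysicalPoint(
        [(n - 1) / 2.0 for n in fixed_img.GetSize()]))
    init_sitk = _euler_from_rigid(init.inverse(), center)

    def make_method() -> sitk.ImageRegistrationMethod:
        m = sitk.ImageRegistrationMethod()
        m.SetMetricAsCorrelation()
        m.SetInterpolator(sitk.sitkLinear)
        return m

    probe = make_method()
    probe.SetInitialTransform(init_sitk, inPlace=False)
    metric_init = probe.MetricEvaluate(fixed_img, moving_img)
    if not np.isfinite(metric_init):
        raise ValueError("non-finite registration metric at initialization")
    cc_init = float(np.sqrt(max(-metric_init, 0.0)))

    reg = make_method()
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=settings.initial_step_um,
        minStep=settings.min_step_um,
        numberOfIterations=settings.max_iterations,
        relaxationFactor=settings.relaxation,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    work = sitk.Euler3DTransform(init_sitk)
    reg.SetInitialTransform(work, inPlace=True)
    reg.Execute(fixed_img, moving_img)
    metric_final = reg.GetMetricValue()
    if not np.isfinite(metric_final):
        raise ValueError("non-finite registration metric after optimization")
    cc_final = float(np.sqrt(max(-metric_final, 0.0)))
    if cc_final < cc_init:
        return init, cc_init
    return _rigid_from_euler(work).inverse(), cc_final


def apply_transform(
    x: np.ndarray | VolumeImage,
    t: RigidTransform,
    reference: VolumeImage | None = None,
):
    """Map points exactly, or resample a volume with trilinear interpolation.

    For volumes, the output grid is ``reference`` (default: the input grid);
    voxels mapped from outside the input are filled with 0.
    """
    if isinstance(x, VolumeImage):
        ref = reference if reference is not None else x
        moving_img = _to_sitk(x)
        ref_img = _to_sitk(ref)
        inv = _euler_from_rigid(t.inverse(), np.zeros(3))
        out = sitk.Resample(moving_img, ref_img, inv, sitk.sitkLinear, 0.0,
                            sitk.sitkFloat32)
        vals = sitk.GetArrayFromImage(out).transpose(2, 1, 0)
        return ref.copy_with(vals, x.channel_name)
    return t.apply(x)
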