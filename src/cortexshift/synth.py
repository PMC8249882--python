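"""Synthetic longitudinal cortical surfaces with known ground-truth atrophy.

Real longitudinal MRI (two FreeSurfer reconstructions per subject, with no
shared vertex grid) is emulated by a generator that produces, per subject:

* a folded "pseudocortex" — an icosphere deformed radially by a smooth
  band-limited random field, standing in for sulci and gyri, together with
  its unit-sphere parameterization;
* a follow-up surface obtained by a smooth atrophy deformation (global
  and/or patch-localized tangential contraction) whose realized per-vertex
  log2 area change is *measured* from the known one-to-one correspondence,
  so the ground truth is exact by construction;
* per-scan "scanner noise": smooth correlated displacement and thickness
  perturbations whose magnitude stands in for 3.0 T vs 1.5 T image quality;
* a follow-up grid resampled at a rotated/jittered icosphere, so that the
  two timepoints share no vertex grid and registration is nontrivial.

Diagnostic groups (CN / MCI-S / MCI-C / AD analogs) differ only in the
scale applied to a common regional atrophy pattern; CN has none.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.spatial.transform import Rotation

from ._sphere import icosphere, SphereLocator, random_band_limited_field
from .meshcore import (
    MetricMap,
    Parcellation,
    SurfaceMesh,
    VertexMask,
    build_parcellation,
    medial_wall_mask,
    vertex_areas,
)

__all__ = [
    "AtrophySpec",
    "NoiseSpec",
    "SubjectRecord",
    "make_icosphere",
    "make_pseudocortex",
    "apply_atrophy",
    "reparameterize",
    "generate_cohort",
    "DEFAULT_GROUP_SCALES",
]

# Group-level multipliers on the common atrophy pattern.  CN has no
# systematic atrophy; AD is the reference scale 1.
DEFAULT_GROUP_SCALES = {"CN": 0.0, "MCIS": 1.0 / 3.0, "MCIC": 2.0 / 3.0, "AD": 1.0}


@dataclass
class AtrophySpec:
    """Target atrophy pattern: a global component plus smooth patches.

    ``uniform_log2_area`` applies everywhere; each patch is an angular cap
    on the parameter sphere with a cos^2 taper, contracting the anatomy
    toward the cap-center surface point.  Peak values are per-vertex target
    log2 changes at effect scale 1.
    """

    uniform_log2_area: float = 0.0
    uniform_log2_thickness: float = 0.0
    # (center direction (3,), angular radius rad, peak log2 area, peak log2 thickness)
    patches: list[tuple[np.ndarray, float, float, float]] = field(default_factory=list)

    def weight_fields(self, sphere_points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-vertex target (log2 area, log2 thickness) fields at scale 1."""
        area = np.full(len(sphere_points), self.uniform_log2_area)
        thick = np.full(len(sphere_points), self.uniform_log2_thickness)
        for center, radius, peak_a, peak_t in self.patches:
            w = _cap_weight(sphere_points, center, radius)
            area += peak_a * w
            thick += peak_t * w
        return area, thick

    @classmethod
    def uniform(cls, log2_area: float, log2_thickness: float = 0.0) -> "AtrophySpec":
        return cls(uniform_log2_area=log2_area, uniform_log2_thickness=log2_thickness)

    @classmethod
    def default_regional(cls, peak_log2_area: float = -0.09, peak_log2_thickness: float = -0.20):
        """Two fixed broad caps (temporal/parietal analogs) away from the wall parcel.

        Atrophy in the symptomatic groups is widespread with regional peaks,
        so the caps are wide (0.72/0.55 rad) with a cos^2 taper.  Peak
        values are order-of-magnitude choices for a 2-year disease interval,
        not literature rates; percent thinning is set larger than percent
        areal shrinkage, as thinning dominates cortical volume loss in
        aging and dementia.
        """
        c1 = _base_face_centroid(10)
        c2 = _base_face_centroid(14)
        return cls(patches=[(c1, 0.72, peak_log2_area, peak_log2_thickness),
                            (c2, 0.55, peak_log2_area, peak_log2_thickness)])


def _cap_weight(points: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    center = np.asarray(center, dtype=float)
    center = center / np.linalg.norm(center)
    ang = np.arccos(np.clip(points @ center, -1.0, 1.0))
    w = np.zeros(len(points))
    inside = ang < radius
    w[inside] = np.cos(0.5 * np.pi * ang[inside] / radius) ** 2
    return w


def _base_face_centroid(face_id: int) -> np.ndarray:
    v, f, _ = icosphere(0)
    c = v[f[face_id]].mean(axis=0)
    return c / np.linalg.norm(c)


@dataclass
class NoiseSpec:
    """Smooth correlated per-scan measurement noise.

    ``geometry_sd`` (mm) is the pointwise SD of each component of a smooth
    vertex-displacement field; ``thickness_sd`` (mm) perturbs the thickness
    map; ``correlation_length`` (mm) sets the field's spatial scale.
    The "1.5T-like" preset has twice the SDs of the "3T-like" one.
    """

    geometry_sd: float = 0.03
    thickness_sd: float = 0.12
    correlation_length: float = 10.0
    label: str = "3T-like"

    def __post_init__(self) -> None:
        if self.geometry_sd < 0 or self.thickness_sd < 0 or self.correlation_length <= 0:
            raise ValueError("noise SDs must be >= 0 and correlation length > 0")

    @classmethod
    def preset(cls, name: str) -> "NoiseSpec":
        key = name.upper().replace("-LIKE", "").replace("T", "")
        if key in ("3", "3.0"):
            return cls()
        if key in ("1.5",):
            return cls(geometry_sd=0.06, thickness_sd=0.24, label="1.5T-like")
        if key in ("0", "NONE"):
            return cls(geometry_sd=0.0, thickness_sd=0.0, label="noise-free")
        raise ValueError(f"unknown noise preset {name!r}")

    def scaled(self, factor: float) -> "NoiseSpec":
        return NoiseSpec(self.geometry_sd * factor, self.thickness_sd * factor,
                         self.correlation_length, f"{self.label}x{factor:g}")


@dataclass
class SubjectRecord:
    """Baseline + follow-up surfaces with thickness maps and ground truth.

    Truth maps live on the baseline grid and describe the noise-free
    biological change; they are absent (``None``) for real data.
    """

    subject_id: str
    group: str
    baseline: SurfaceMesh
    baseline_sphere: np.ndarray
    baseline_thickness: MetricMap
    followup: SurfaceMesh
    followup_sphere: np.ndarray
    followup_thickness: MetricMap
    baseline_wall: VertexMask
    followup_wall: VertexMask
    parcellation: Parcellation
    truth_area: np.ndarray | None = None
    truth_thickness: np.ndarray | None = None
    truth_volume: np.ndarray | None = None
    reparam_seed: int = 0

    def __post_init__(self) -> None:
        for t in (self.baseline_thickness, self.followup_thickness):
            v = t.values
            if v.size and (v.min() <= 0.5 or v.max() >= 6.0):
                raise ValueError("thickness out of the plausible (0.5, 6) mm range")


# ---------------------------------------------------------------------------
# generators


def make_icosphere(level: int, radius: float = 1.0, name: str = "icosphere") -> SurfaceMesh:
    """Recursive 4-fold icosahedron subdivision projected to ``radius``."""
    v, f, lineage = icosphere(level)
    return SurfaceMesh(v * radius, f, name, base_face=lineage)


def make_pseudocortex(
    level: int,
    radius: float = 80.0,
    bumpiness: float = 0.15,
    seed: int = 0,
    name: str = "pseudocortex",
    param_distortion: float = 0.003,
) -> tuple[SurfaceMesh, np.ndarray]:
    """A folded sphere and its unit-sphere parameterization.

    The icosphere is deformed radially by a band-limited random field
    (spherical-harmonic degrees 4-14) scaled so the peak deviation is
    ``bumpiness * radius``, creating smooth sulcus/gyrus-like folds.

    The returned parameterization is not metrically uniform: param points
    are displaced along the surface gradient of the fold field
    (``param_distortion`` rad per unit gradient), emulating the areal
    distortion that spherical inflation of a folded cortex produces.  The
    distortion is a deterministic function of the anatomy, so the two
    timepoints of one subject share it, as real inflations approximately
    do.  Deterministic given ``seed``.
    """
    if not 0.0 <= bumpiness < 1.0:
        raise ValueError("bumpiness must lie in [0, 1)")
    unit, faces, lineage = icosphere(level)
    if bumpiness == 0.0:
        return SurfaceMesh(unit * radius, faces, name, base_face=lineage), unit
    rng = np.random.default_rng(seed)
    # the folding band is capped so the mesh keeps >= ~4.5 vertices per
    # fold wavelength; finer folds would alias on coarse grids
    lmax = min(14, 2**level)
    f = random_band_limited_field(unit, rng, lmin=min(4, lmax - 1), lmax=lmax, sd=1.0)
    f = f / np.abs(f).max()
    r = radius * (1.0 + bumpiness * f)
    verts = unit * r[:, None]
    mesh = SurfaceMesh(verts, faces, name, base_face=lineage)
    # a star-shaped surface self-intersects iff a face normal flips inward
    normals = np.cross(
        verts[faces[:, 1]] - verts[faces[:, 0]], verts[faces[:, 2]] - verts[faces[:, 0]]
    )
    centroids = verts[faces].mean(axis=1)
    if np.any(np.einsum("ij,ij->i", normals, centroids) <= 0):
        raise ValueError("bumpiness too high: surface self-intersects")
    param = unit
    if param_distortion > 0:
        grad = _vertex_gradient(unit, mesh.edges(), f)
        param = unit + param_distortion * grad
        param = param / np.linalg.norm(param, axis=1, keepdims=True)
        det = np.einsum(
            "ij,ij->i", np.cross(param[faces[:, 0]], param[faces[:, 1]]), param[faces[:, 2]]
        )
        if np.any(det <= 0):
            raise ValueError("param_distortion too high: parameterization folds")
    return mesh, param


def _vertex_gradient(points: np.ndarray, edges: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Tangential least-squares-style gradient of a vertex field on a sphere mesh."""
    g = np.zeros_like(points)
    d = points[edges[:, 1]] - points[edges[:, 0]]
    l2 = np.einsum("ij,ij->i", d, d)
    w = (values[edges[:, 1]] - values[edges[:, 0]]) / np.where(l2 > 0, l2, 1.0)
    np.add.at(g, edges[:, 0], w[:, None] * d)
    np.add.at(g, edges[:, 1], w[:, None] * d)
    deg = np.bincount(edges.ravel(), minlength=len(points)).astype(float)
    g /= np.where(deg > 0, deg, 1.0)[:, None]
    g -= points * np.einsum("ij,ij->i", g, points)[:, None]
    return g


def _noise_displacement(
    sphere_points: np.ndarray, noise: NoiseSpec, radius: float, rng: np.random.Generator
) -> np.ndarray:
    if noise.geometry_sd == 0.0:
        return np.zeros((len(sphere_points), 3))
    lmax = int(np.clip(np.round(np.pi * radius / noise.correlation_length), 2, 24))
    return np.column_stack(
        [
            random_band_limited_field(sphere_points, rng, 2, lmax, sd=noise.geometry_sd)
            for _ in range(3)
        ]
    )


def _noise_thickness(
    sphere_points: np.ndarray, noise: NoiseSpec, radius: float, rng: np.random.Generator
) -> np.ndarray:
    if noise.thickness_sd == 0.0:
        return np.zeros(len(sphere_points))
    lmax = int(np.clip(np.round(np.pi * radius / noise.correlation_length), 2, 24))
    return random_band_limited_field(sphere_points, rng, 2, lmax, sd=noise.thickness_sd)


def apply_atrophy(
    baseline: SurfaceMesh,
    sphere: np.ndarray,
    baseline_thickness: MetricMap,
    spec: AtrophySpec,
    noise: NoiseSpec,
    effect_scale: float = 1.0,
    seed: int = 0,
) -> dict:
    """Deform a baseline surface by a smooth atrophy field plus scan noise.

    Returns a dict with the follow-up mesh and thickness (same grid as the
    baseline: the correspondence is one-to-one and known) and the realized
    ground-truth log2 change maps, measured exactly from that
    correspondence before noise is added.  A prescribed area-change field is
    not generally integrable, so the deformation only approximates the
    target and the truth is what the deformation actually did.
    """
    area_field, thick_field = spec.weight_fields(sphere)
    area_field = area_field * effect_scale
    thick_field = thick_field * effect_scale
    if np.abs(area_field).max(initial=0.0) > 1.0 or np.abs(thick_field).max(initial=0.0) > 1.0:
        raise ValueError("requested |log2 change| > 1 is unrealistically large")
    rng = np.random.default_rng(seed)
    radius = float(np.linalg.norm(baseline.vertices - baseline.vertices.mean(0), axis=1).mean())

    verts = baseline.vertices.copy()
    if spec.uniform_log2_area * effect_scale != 0.0:
        s = 2.0 ** (spec.uniform_log2_area * effect_scale / 2.0)
        c = verts.mean(axis=0)
        verts = c + s * (verts - c)
    for center, cap_radius, peak_a, _ in spec.patches:
        if peak_a * effect_scale == 0.0:
            continue
        w = _cap_weight(sphere, center, cap_radius)
        if not np.any(w):
            continue
        # anatomical anchor: surface point nearest the cap center direction
        anchor = verts[int(np.argmax(sphere @ (center / np.linalg.norm(center))))]
        m = 2.0 ** (peak_a * effect_scale * w / 2.0)
        verts = anchor + m[:, None] * (verts - anchor)

    truth_mesh = SurfaceMesh(verts, baseline.faces, baseline.name + ".truth",
                             base_face=baseline.base_face)
    va0 = vertex_areas(baseline).values
    va1 = vertex_areas(truth_mesh).values
    truth_area = np.log2(va1 / va0)
    truth_thickness = thick_field.copy()
    truth_volume = truth_area + truth_thickness

    followup_verts = verts + _noise_displacement(sphere, noise, radius, rng)
    followup_thickness = np.clip(
        baseline_thickness.values * 2.0 ** thick_field
        + _noise_thickness(sphere, noise, radius, rng),
        0.6, 5.9,
    )
    followup = SurfaceMesh(followup_verts, baseline.faces, baseline.name + ".followup",
                           base_face=baseline.base_face)
    return {
        "mesh": followup,
        "thickness": MetricMap(followup_thickness, followup.name, "mm"),
        "truth_area": truth_area,
        "truth_thickness": truth_thickness,
        "truth_volume": truth_volume,
    }


def reparameterize(
    mesh: SurfaceMesh,
    sphere: np.ndarray,
    metrics: dict[str, np.ndarray] | None = None,
    rotation_angle: float = 0.05,
    jitter_angle: float = 0.02,
    drift_angle: float = 0.0,
    seed: int = 0,
) -> tuple[SurfaceMesh, np.ndarray, dict[str, np.ndarray]]:
    """Resample a surface onto a rotated/jittered icosphere grid, with drift.

    Real scan pairs share no vertex grid, and the spherical inflations of
    the two reconstructions are only approximately aligned; this op
    emulates both.  The surface (and any per-vertex metrics) is sampled at
    a new spherical grid: the standard icosphere rotated by a random
    rotation of magnitude ``rotation_angle`` (radians) with a smooth
    tangential jitter of SD ``jitter_angle``.  The new grid directions
    become the surface's spherical parameterization, so geometry is
    unchanged up to interpolation error while the vertex set is entirely
    new.

    ``drift_angle`` adds a smooth low-order tangential misalignment between
    the new parameterization and the anatomy (the sample is taken at the
    drifted direction but attributed to the undrifted one), emulating the
    independent sphere-inflation error that longitudinal registration must
    recover.  With ``drift_angle = 0`` the identity warp is the true
    correspondence.
    """
    level = int(round(np.log((len(sphere) - 2) / 10) / np.log(4)))
    unit, faces, lineage = icosphere(level)
    rng = np.random.default_rng(seed)
    if rotation_angle > 0:
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        rot = Rotation.from_rotvec(axis * rotation_angle)
        dirs = rot.apply(unit)
    else:
        dirs = unit.copy()
    if jitter_angle > 0:
        t = np.column_stack(
            [random_band_limited_field(unit, rng, 2, 10, sd=jitter_angle) for _ in range(3)]
        )
        t -= dirs * np.einsum("ij,ij->i", t, dirs)[:, None]  # tangential component
        dirs = dirs + t
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    sample_dirs = dirs
    if drift_angle > 0:
        g = np.column_stack(
            [random_band_limited_field(unit, rng, 2, 5, sd=drift_angle) for _ in range(3)]
        )
        g -= dirs * np.einsum("ij,ij->i", g, dirs)[:, None]
        sample_dirs = dirs + g
        sample_dirs = sample_dirs / np.linalg.norm(sample_dirs, axis=1, keepdims=True)

    loc = SphereLocator(sphere, mesh.faces)
    new_verts = loc.interpolate(mesh.vertices, sample_dirs)
    # linear interpolation pulls points onto chords, shrinking a folded
    # surface; the generator's anatomies are star-shaped about the origin,
    # so restoring the radius removes that bias.  The radius itself is
    # interpolated with a gradient-augmented (Hermite-style) estimate,
    # which removes most of the curvature flattening of a linear blend.
    r = np.linalg.norm(mesh.vertices, axis=1)
    g = _vertex_gradient(sphere, mesh.edges(), r)
    face, w = loc.locate(sample_dirs)
    corners = mesh.faces[face]
    diff = sample_dirs[:, None, :] - sphere[corners]
    est = r[corners] + np.einsum("nki,nki->nk", g[corners], diff)
    radii = np.einsum("nk,nk->n", est, w)
    norms = np.linalg.norm(new_verts, axis=1)
    new_verts = new_verts * (radii / np.where(norms > 0, norms, 1.0))[:, None]
    # resampling must not change the surface's total area: piecewise-linear
    # interpolation systematically shrinks a folded surface, and an
    # uncorrected ~0.2% global loss would masquerade as atrophy
    a_old = vertex_areas(mesh).values.sum()
    a_new_faces = 0.5 * np.linalg.norm(
        np.cross(
            new_verts[faces[:, 1]] - new_verts[faces[:, 0]],
            new_verts[faces[:, 2]] - new_verts[faces[:, 0]],
        ),
        axis=1,
    )
    if np.any(a_new_faces < 1e-9):
        raise ValueError("jitter collapsed a triangle during resampling")
    centroid = new_verts.mean(axis=0)
    new_verts = centroid + (new_verts - centroid) * np.sqrt(a_old / a_new_faces.sum())
    new_mesh = SurfaceMesh(new_verts, faces, mesh.name + ".regrid", base_face=lineage)
    out_metrics = {}
    for key, vals in (metrics or {}).items():
        out_metrics[key] = loc.interpolate(np.asarray(vals, dtype=float), sample_dirs)
    return new_mesh, dirs, out_metrics


def generate_cohort(
    n_per_group: int,
    group_effect_scales: dict[str, float] | None = None,
    noise: NoiseSpec | None = None,
    level: int = 4,
    seed: int = 0,
    radius: float = 80.0,
    bumpiness: float = 0.15,
    param_distortion: float = 0.003,
    spec: AtrophySpec | None = None,
    subject_sigma_log: float = 0.3,
    reparam: bool = True,
    drift_angle: float = 0.0,
    noise_seed: int | None = None,
) -> list[SubjectRecord]:
    """Generate a longitudinal cohort with group-structured atrophy.

    Each subject gets its own folded anatomy and a random effect magnitude
    (group mean scale x lognormal subject factor, sigma_log = 0.3); scan
    noise is independent per scan.  ``noise_seed`` decouples the noise
    stream from the anatomy/effect stream so matched cohorts differing only
    in noise can be generated (the field-strength experiment).  Fully
    deterministic given the seeds.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if group_effect_scales is None:
        group_effect_scales = dict(DEFAULT_GROUP_SCALES)
    noise = noise or NoiseSpec()
    spec = spec or AtrophySpec.default_regional()
    ss = np.random.SeedSequence(seed)
    noise_ss = np.random.SeedSequence(noise_seed if noise_seed is not None else seed + 777_000_001)

    n_total = n_per_group * len(group_effect_scales)
    subj_seeds = ss.spawn(n_total)
    noise_seeds = noise_ss.spawn(n_total)
    # random fields are synthesized on the uniform grid directions (shared
    # across subjects, so the harmonic basis is computed once); the possibly
    # distorted per-subject parameterization is used only for registration
    # and resampling
    unit, _, _ = icosphere(level)
    records = []
    i = 0
    for group, scale in group_effect_scales.items():
        for j in range(n_per_group):
            rng = np.random.default_rng(subj_seeds[i])
            nrng = np.random.default_rng(noise_seeds[i])
            anat_seed = int(rng.integers(2**31))
            base_mesh, sphere = make_pseudocortex(
                level, radius, bumpiness, seed=anat_seed, name=f"{group}{j:03d}",
                param_distortion=param_distortion,
            )
            thick = np.clip(
                2.5 + random_band_limited_field(unit, rng, 2, 6, sd=0.45), 1.0, 4.5
            )
            subject_factor = float(np.exp(rng.normal(0.0, subject_sigma_log))) if scale > 0 else 1.0
            eff = scale * subject_factor

            fu = apply_atrophy(
                base_mesh, unit, MetricMap(thick, base_mesh.name, "mm"),
                spec, noise, effect_scale=eff, seed=int(nrng.integers(2**31)),
            )
            # independent noise on the baseline scan
            base_obs = SurfaceMesh(
                base_mesh.vertices + _noise_displacement(unit, noise, radius, nrng),
                base_mesh.faces, base_mesh.name, base_face=base_mesh.base_face,
            )
            thick_obs = np.clip(thick + _noise_thickness(unit, noise, radius, nrng), 0.6, 5.9)

            parc = build_parcellation(base_obs)
            wall, _ = medial_wall_mask(parc, wall_roi=0)
            rp_seed = int(rng.integers(2**31))
            if reparam:
                fu_mesh, fu_sphere, extra = reparameterize(
                    fu["mesh"], sphere,
                    {"thickness": fu["thickness"].values, "wall": wall.values.astype(float)},
                    drift_angle=drift_angle, seed=rp_seed,
                )
                fu_thick = MetricMap(np.clip(extra["thickness"], 0.6, 5.9), fu_mesh.name, "mm")
                fu_wall = VertexMask(extra["wall"] > 0.5, "medial_wall")
            else:
                fu_mesh, fu_sphere = fu["mesh"], sphere.copy()
                fu_thick, fu_wall = fu["thickness"], VertexMask(wall.values.copy(), "medial_wall")

            records.append(
                SubjectRecord(
                    subject_id=f"{group}{j:03d}",
                    group=group,
                    baseline=base_obs,
                    baseline_sphere=sphere,
                    baseline_thickness=MetricMap(thick_obs, base_obs.name, "mm"),
                    followup=fu_mesh,
                    followup_sphere=fu_sphere,
                    followup_thickness=fu_thick,
                    baseline_wall=wall,
                    followup_wall=fu_wall,
                    parcellation=parc,
                    truth_area=fu["truth_area"],
                    truth_thickness=fu["truth_thickness"],
                    truth_volume=fu["truth_volume"],
                    reparam_seed=rp_seed,
                )
            )
            i += 1
    return records
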