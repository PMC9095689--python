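"""Synthetic soleus-like mesh cohorts with known ground-truth shape modes.

Real study inputs are MRI-segmented muscle surfaces, which are not shipped
with the package. This module generates populations of tapered, elongated,
closed surface meshes whose variation comes from a small set of named,
analytically defined deformation modes, so every downstream stage
(registration, PCA, validation, group statistics) can be tested against a
known answer.

The template is a superellipsoid-like body 300 mm long (z, proximal-distal),
up to 80 mm wide (x, medial-lateral) and 40 mm thick (y), with the width
profile peaking 40 % of the way from the proximal end (the muscle's "broad
section") and a medial bulge (the "curved marginal aspect").

Five modes mirror the principal components such models recover from real
cohorts:

``size``            isotropic scale (dominant mode in growing cohorts),
``aspect``          long-and-thin vs short-and-thick (volume-preserving
                    to first order),
``margin_side``     medial vs lateral bowing of the curved margin,
``proximal_width``  widening/narrowing of the proximal extremity,
``broad_shift``     superior-inferior shift of the broad section.

Each mode is a displacement field, linear in its amplitude, evaluated on
template vertex coordinates; a specimen is the template plus the weighted
sum of fields plus i.i.d. isotropic Gaussian vertex noise. The population
therefore lies exactly in a low-dimensional linear subspace (plus noise),
which makes PCA recovery an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DimensionError, ParameterError
from .mesh import SurfaceMesh

MODE_NAMES = ("size", "aspect", "margin_side", "proximal_width", "broad_shift")

# Template envelope, mm. Chosen to resemble an adolescent soleus; these are
# package design values, not measurements.
LENGTH = 300.0
WIDTH = 80.0
THICKNESS = 40.0
_PEAK = 0.6  # axial position of the broad section (fraction from distal end)
_BULGE = 8.0  # medial offset amplitude of the cross-section centreline, mm
_SUPERELLIPSE_P = 2.5  # cross-section exponent; 2 = ellipse, higher = boxier
_AXIAL_WARP = 0.85  # clusters rings distally -> nonzero z-skewness (alignment sign)

__all__ = [
    "MODE_NAMES",
    "GeneratorConfig",
    "CohortSample",
    "base_soleus_template",
    "apply_mode_deformation",
    "mode_displacement_field",
    "generate_cohort",
    "generate_two_group_study",
]


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    ``mode_sds`` are the standard deviations of the (dimensionless) true mode
    weights in the order of :data:`MODE_NAMES`; ``group_offset`` shifts their
    means, which is how a between-group morphological effect is encoded.
    Defaults give a size-dominated population with descending secondary
    modes and half-millimetre vertex noise (sub-voxel for typical muscle MRI).
    """

    n_subjects: int = 20
    mode_sds: tuple = (1.0, 0.8, 0.6, 0.5, 0.4)
    noise_sd: float = 0.5
    resolution: int = 20
    group_offset: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    seed: int = 0
    shuffle_topology: bool = False

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ParameterError("n_subjects must be >= 2")
        if self.resolution < 4:
            raise ParameterError("resolution must be >= 4 rings")
        if len(self.mode_sds) != len(MODE_NAMES):
            raise ParameterError(
                f"mode_sds must have {len(MODE_NAMES)} entries (one per mode)"
            )
        if len(self.group_offset) != len(MODE_NAMES):
            raise ParameterError("group_offset must match mode_sds dimensionality")
        if min(self.mode_sds) < 0 or self.noise_sd < 0:
            raise ParameterError("mode_sds and noise_sd must be non-negative")


@dataclass
class CohortSample:
    """Generated cohort with its ground truth retained."""

    meshes: list
    true_weights: np.ndarray  # (n_subjects, n_modes)
    labels: list
    template: SurfaceMesh
    config: GeneratorConfig | None = field(default=None)


# ---------------------------------------------------------------------------
# Template
# ---------------------------------------------------------------------------


def _width_profile(u: np.ndarray) -> np.ndarray:
    """Tapered profile in [0, 1], peaking at u = _PEAK, zero at both ends."""
    a = 3.0, 2.0
    alpha, beta = a
    peak = _PEAK**alpha * (1 - _PEAK) ** beta
    return np.clip(u, 0, 1) ** alpha * np.clip(1 - u, 0, 1) ** beta / peak


def base_soleus_template(resolution: int = 20, phase: float = 0.0) -> SurfaceMesh:
    """Deterministic closed, elongated, tapered soleus-like template.

    ``resolution`` R controls tessellation: 2R-1 axial rings of 2R points
    plus two pole vertices. ``phase`` rotates the circumferential sampling
    seam (in units of one angular step) and is used by the generator's
    ``shuffle_topology`` option to break trivial vertex correspondence.
    """
    if resolution < 4:
        raise ParameterError("resolution must be >= 4")
    n_rings = 2 * resolution - 1
    n_theta = 2 * resolution
    # Axial stations, warped toward the distal end so the vertex distribution
    # has nonzero skewness along z (used by rigid alignment's sign rule).
    t = (np.arange(1, n_rings + 1) / (n_rings + 1)) ** _AXIAL_WARP
    z = (t - 0.5) * LENGTH
    prof = _width_profile(t)
    # The bulge offset is proportional to the same profile, so the overall
    # x-extent stays (half_w + bulge) - (bulge - half_w) = WIDTH at the peak.
    half_w = (WIDTH / 2) * prof
    half_t = (THICKNESS / 2) * prof
    cx = _BULGE * prof  # medial (+x) bulge of the centreline

    theta = 2 * np.pi * (np.arange(n_theta) + phase) / n_theta
    p = 2.0 / _SUPERELLIPSE_P
    cs = np.sign(np.cos(theta)) * np.abs(np.cos(theta)) ** p
    sn = np.sign(np.sin(theta)) * np.abs(np.sin(theta)) ** p

    verts = np.empty((n_rings * n_theta + 2, 3))
    for i in range(n_rings):
        rows = slice(i * n_theta, (i + 1) * n_theta)
        verts[rows, 0] = cx[i] + half_w[i] * cs
        verts[rows, 1] = half_t[i] * sn
        verts[rows, 2] = z[i]
    distal_pole = n_rings * n_theta
    proximal_pole = distal_pole + 1
    verts[distal_pole] = (0.0, 0.0, -LENGTH / 2)
    verts[proximal_pole] = (0.0, 0.0, LENGTH / 2)

    faces = []
    for i in range(n_rings - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            faces.append((a, b, d))
            faces.append((a, d, c))
    last = (n_rings - 1) * n_theta
    for j in range(n_theta):
        jn = (j + 1) % n_theta
        faces.append((distal_pole, jn, j))  # distal cap
        faces.append((proximal_pole, last + j, last + jn))  # proximal cap
    mesh = SurfaceMesh(verts, np.array(faces, dtype=np.int64))
    if mesh.signed_volume() < 0:  # enforce outward winding
        mesh = SurfaceMesh(mesh.vertices, mesh.faces[:, ::-1])
    mesh.vertices -= mesh.vertices.mean(axis=0)
    return mesh


# ---------------------------------------------------------------------------
# Deformation modes
# ---------------------------------------------------------------------------


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def mode_displacement_field(mesh: SurfaceMesh, mode_id: str) -> np.ndarray:
    """Unit-amplitude displacement field (n, 3) of one mode on a mesh.

    Fields are analytic functions of the vertex coordinates (relative axial
    position and centroid-centred offsets), so they are defined on any
    soleus-like mesh, not only the template.
    """
    if mode_id not in MODE_NAMES:
        raise ParameterError(f"unknown mode_id {mode_id!r}; choose from {MODE_NAMES}")
    v = mesh.vertices
    c = v.mean(axis=0)
    zmin, zmax = v[:, 2].min(), v[:, 2].max()
    t = (v[:, 2] - zmin) / (zmax - zmin) if zmax > zmin else np.zeros(len(v))
    disp = np.zeros_like(v)
    if mode_id == "size":
        disp = 0.1 * (v - c)
    elif mode_id == "aspect":
        disp[:, 0] = -0.04 * (v[:, 0] - c[0])
        disp[:, 1] = -0.04 * (v[:, 1] - c[1])
        disp[:, 2] = 0.08 * (v[:, 2] - c[2])
    elif mode_id == "margin_side":
        disp[:, 0] = 6.0 * np.sin(np.pi * t)
    elif mode_id == "proximal_width":
        w = _smoothstep((t - 0.7) / 0.3)
        disp[:, 0] = 0.25 * (v[:, 0] - c[0]) * w
        disp[:, 1] = 0.25 * (v[:, 1] - c[1]) * w
    elif mode_id == "broad_shift":
        disp[:, 2] = 15.0 * np.exp(-(((t - _PEAK) / 0.22) ** 2))
    return disp


def apply_mode_deformation(
    mesh: SurfaceMesh, mode_id: str, amplitude: float
) -> SurfaceMesh:
    """Apply one deformation mode at the given dimensionless amplitude.

    Displacements are linear in amplitude; amplitude 0 returns the input
    exactly. Amplitudes are intended for [-3, 3] (about +-3 SD of the
    default weight distributions).
    """
    if not -3.0 <= amplitude <= 3.0:
        raise ParameterError("amplitude must lie in [-3, 3]")
    if amplitude == 0.0:
        return mesh.copy()
    disp = mode_displacement_field(mesh, mode_id)
    return SurfaceMesh(mesh.vertices + amplitude * disp, mesh.faces, mesh.frame_note)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def generate_cohort(config: GeneratorConfig) -> CohortSample:
    """Draw a cohort of meshes from the linear mode model.

    Per specimen, true weights are drawn independently per mode from
    N(group_offset, mode_sds^2); the specimen is the template plus the
    weighted sum of the unit fields evaluated on template coordinates, plus
    isotropic vertex noise. With ``shuffle_topology`` the template's angular
    seam is re-sampled at a random phase per specimen, so vertex indices no
    longer correspond across the cohort and registration has to establish
    correspondence.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    template = base_soleus_template(config.resolution)
    fields = np.stack(
        [mode_displacement_field(template, m) for m in MODE_NAMES]
    )  # (5, n, 3)
    meshes = []
    weights = np.empty((config.n_subjects, len(MODE_NAMES)))
    for s in range(config.n_subjects):
        phase = rng.uniform(0.0, 1.0) if config.shuffle_topology else 0.0
        w = rng.normal(loc=config.group_offset, scale=config.mode_sds)
        weights[s] = w
        if config.shuffle_topology:
            base = base_soleus_template(config.resolution, phase=phase)
            f = np.stack([mode_displacement_field(base, m) for m in MODE_NAMES])
        else:
            base, f = template, fields
        verts = base.vertices + np.tensordot(w, f, axes=1)
        if config.noise_sd > 0:
            verts = verts + rng.normal(0.0, config.noise_sd, size=verts.shape)
        meshes.append(SurfaceMesh(verts, base.faces.copy(), base.frame_note))
    labels = ["A"] * config.n_subjects
    return CohortSample(meshes, weights, labels, template, config)


def generate_two_group_study(
    config_a: GeneratorConfig, config_b: GeneratorConfig
) -> CohortSample:
    """Concatenate two cohorts labelled "A" and "B".

    The groups must share tessellation and mode dimensionality; any group
    difference enters only through ``group_offset`` (e.g. offset -0.8 on
    ``size`` for group A encodes smaller muscles).
    """
    config_a.validate()
    config_b.validate()
    if config_a.resolution != config_b.resolution:
        raise ParameterError("both groups must share the template resolution")
    if len(config_a.mode_sds) != len(config_b.mode_sds):
        raise ParameterError("both groups must share mode dimensionality")
    a = generate_cohort(config_a)
    b = generate_cohort(config_b)
    return CohortSample(
        meshes=a.meshes + b.meshes,
        true_weights=np.vstack([a.true_weights, b.true_weights]),
        labels=["A"] * config_a.n_subjects + ["B"] * config_b.n_subjects,
        template=a.template,
        config=config_a,
    )
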