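"""Point-distribution (PCA) shape models of corresponded surface meshes.

Given m corresponded shape vectors S_i (length 3n), the model is

    S_i  =  S_bar + P b_i,

where S_bar is the coordinate-wise mean shape, the columns of P are the
orthonormal principal modes (eigenvectors of the sample covariance of the
deviations, divisor m - 1), and b_i are the per-specimen weights ("soleus
weights" in the muscle application). Eigen-decomposition goes through the
m x m Gram matrix (dual PCA), which is exact and cheap because m << 3n.

Two flavours are built from the same corresponded data: the *morphological*
model on raw coordinates (size retained; the first mode of a growing cohort
is overall size) and the *appearance* model on size-normalized coordinates,
where each specimen is scaled by the scalar s minimizing ||s S - ref||^2
(closed form s = <S, ref> / <S, S>).

Models persist to a single HDF5 archive holding mean, modes, variances,
topology, the normalization flag, and free-form provenance attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import (
    DegenerateGeometryError,
    DimensionError,
    ParameterError,
)
from .mesh import ShapeVector, SurfaceMesh, mesh_to_shape_vector
from .registration import RegistrationSettings, iterative_refit, rigid_align

__all__ = [
    "ShapeModel",
    "WeightTable",
    "compute_mean",
    "fit_pca",
    "project",
    "reconstruct",
    "cumulative_variance",
    "size_normalize",
    "build_model",
    "save_model",
    "load_model",
]


@dataclass
class ShapeModel:
    """Mean shape + orthonormal modes + per-mode variances (mm^2)."""

    mean: ShapeVector
    modes: np.ndarray  # (3n, k), orthonormal columns
    variances: np.ndarray  # (k,), descending
    k: int
    topology: np.ndarray
    normalized: bool = False
    total_variance: float = 0.0  # trace of the sample covariance (all modes)

    def __post_init__(self) -> None:
        self.modes = np.asarray(self.modes, dtype=np.float64)
        self.variances = np.asarray(self.variances, dtype=np.float64)
        if self.modes.shape != (3 * self.mean.n_vertices, self.k):
            raise DimensionError("modes must be a (3n, k) matrix")
        if len(self.variances) != self.k:
            raise DimensionError("variances must have one entry per retained mode")
        if np.any(np.diff(self.variances) > 1e-9 * max(self.variances[0], 1.0)):
            raise ParameterError("variances must be sorted descending")
        if self.k:
            gram = self.modes.T @ self.modes
            if not np.allclose(gram, np.eye(self.k), atol=1e-9):
                raise ParameterError("mode columns must be orthonormal")

    def mean_mesh(self) -> SurfaceMesh:
        from .mesh import shape_vector_to_mesh

        return shape_vector_to_mesh(self.mean, self.topology)


@dataclass
class WeightTable:
    """Per-specimen PC weights with cohort labels."""

    specimen_ids: list
    labels: list
    weights: np.ndarray  # (m, k)

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=np.float64))
        if not (len(self.specimen_ids) == len(self.labels) == len(self.weights)):
            raise DimensionError("specimen_ids, labels and weights must align")

    @property
    def pc_count(self) -> int:
        return self.weights.shape[1]

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            self.weights, columns=[f"pc{i + 1}" for i in range(self.pc_count)]
        )
        df.insert(0, "label", self.labels)
        df.insert(0, "specimen_id", self.specimen_ids)
        return df


def _stack(shape_vectors) -> np.ndarray:
    if len(shape_vectors) == 0:
        raise ParameterError("need at least one shape vector")
    lengths = {len(v.values) for v in shape_vectors}
    if len(lengths) != 1:
        raise DimensionError(f"mixed shape-vector lengths: {sorted(lengths)}")
    return np.stack([v.values for v in shape_vectors])


def compute_mean(shape_vectors) -> ShapeVector:
    """Coordinate-wise arithmetic mean shape."""
    X = _stack(shape_vectors)
    return ShapeVector(X.mean(axis=0), shape_vectors[0].n_vertices)


def fit_pca(shape_vectors, k: int) -> ShapeModel:
    """Fit a PCA shape model with k retained modes.

    The sample covariance (divisor m - 1) of deviations from the mean is
    eigen-decomposed through the m x m Gram matrix. Mode signs follow a
    deterministic convention: the entry of largest magnitude of each mode is
    positive (ties broken by lowest index).
    """
    X = _stack(shape_vectors)
    m = len(X)
    if m < 2:
        raise ParameterError("PCA needs at least two shapes")
    if not 1 <= k <= m - 1:
        raise ParameterError(f"k must be in [1, m-1] = [1, {m - 1}], got {k}")
    mean = X.mean(axis=0)
    D = X - mean
    gram = D @ D.T / (m - 1)
    evals, evecs = np.linalg.eigh(gram)
    evals = np.clip(evals[::-1], 0.0, None)  # descending
    evecs = evecs[:, ::-1]
    total = float(evals.sum())
    modes = np.zeros((X.shape[1], k))
    variances = evals[:k].copy()
    rank_eps = max(total, 1e-300) * 1e-12
    for j in range(k):
        if evals[j] > rank_eps:
            col = D.T @ evecs[:, j]
            modes[:, j] = col / np.linalg.norm(col)
        else:
            # zero-variance mode: deterministic canonical filler, orthogonalized
            # against everything already placed below
            modes[j % X.shape[1], j] = 1.0
    q, r = np.linalg.qr(modes)
    modes = q * np.sign(np.where(np.diag(r) == 0, 1.0, np.diag(r)))
    for j in range(k):
        if modes[np.argmax(np.abs(modes[:, j])), j] < 0:
            modes[:, j] = -modes[:, j]
    n_vertices = shape_vectors[0].n_vertices
    return ShapeModel(
        mean=ShapeVector(mean, n_vertices),
        modes=modes,
        variances=variances,
        k=k,
        topology=np.empty((0, 3), dtype=np.int64),
        normalized=False,
        total_variance=total,
    )


def project(model: ShapeModel, vec: ShapeVector) -> np.ndarray:
    """Weights b = P^T (S - S_bar) of one shape in the model."""
    if len(vec.values) != len(model.mean.values):
        raise DimensionError(
            f"shape vector length {len(vec.values)} does not match model "
            f"({len(model.mean.values)})"
        )
    return model.modes.T @ (vec.values - model.mean.values)


def reconstruct(model: ShapeModel, weights) -> ShapeVector:
    """Shape S_bar + P b; shorter weight vectors are zero-padded."""
    weights = np.asarray(weights, dtype=np.float64).ravel()
    if len(weights) > model.k:
        raise DimensionError(
            f"{len(weights)} weights supplied but the model retains {model.k} modes"
        )
    b = np.zeros(model.k)
    b[: len(weights)] = weights
    return ShapeVector(
        model.mean.values + model.modes @ b, model.mean.n_vertices
    )


def cumulative_variance(model: ShapeModel, j: int) -> float:
    """Fraction of *total* training variance explained by the first j modes.

    The denominator is the trace of the sample covariance (all nonzero
    modes), not only the retained k, so a truncated model reports less than
    1 even at j = k.
    """
    if not 1 <= j <= model.k:
        raise ParameterError(f"j must be in [1, k] = [1, {model.k}]")
    if model.total_variance <= 0:
        return 1.0
    return float(model.variances[:j].sum() / model.total_variance)


def size_normalize(shape_vectors, reference: ShapeVector):
    """Scale each shape by the least-squares factor toward the reference.

    For each specimen the scalar s minimizing ||s S - ref||^2 has the closed
    form s = <S, ref> / <S, S>. Inputs are assumed rigidly aligned and
    centred; the reference normalizes to itself (s = 1). Returns the list of
    normalized vectors and the per-specimen scale factors.
    """
    ref = np.asarray(reference.values, dtype=np.float64)
    normalized, scales = [], []
    for i, v in enumerate(shape_vectors):
        if len(v.values) != len(ref):
            raise DimensionError(f"specimen {i}: length mismatch with reference")
        ss = float(v.values @ v.values)
        if ss <= 0:
            raise DegenerateGeometryError(f"specimen {i}: zero-norm shape vector")
        s = float(v.values @ ref) / ss
        normalized.append(ShapeVector(s * v.values, v.n_vertices))
        scales.append(s)
    return normalized, np.array(scales)


def build_model(
    meshes,
    normalize: bool = False,
    k: int = 9,
    settings: RegistrationSettings | None = None,
    specimen_ids=None,
    labels=None,
    assume_corresponded: bool = False,
    reference: SurfaceMesh | None = None,
):
    """Full model pipeline: correspondence -> (normalization) -> PCA.

    Meshes are corresponded by iterative mean-reference refitting (the first
    mesh, or ``reference``, seeds the process) and rigidly aligned; with
    ``assume_corresponded`` the registration stage is skipped and meshes
    (which must share topology) are only aligned - appropriate for
    generator output with ``shuffle_topology`` off. The appearance variant
    (``normalize=True``) rescales every specimen toward the cohort mean
    before PCA. ``k`` defaults to 9 retained modes and is capped at m - 1.

    Returns (ShapeModel, WeightTable, per-specimen registration RMS list).
    """
    if len(meshes) < 2:
        raise ParameterError("build_model needs at least two meshes")
    settings = settings or RegistrationSettings()
    m = len(meshes)
    k = min(k, m - 1)
    if specimen_ids is None:
        specimen_ids = [f"s{i:03d}" for i in range(m)]
    if labels is None:
        labels = ["A"] * m
    if assume_corresponded:
        n0 = meshes[0].n_vertices
        if any(mesh.n_vertices != n0 for mesh in meshes):
            raise DimensionError("assume_corresponded requires shared topology")
        vectors = [rigid_align(mesh_to_shape_vector(mesh))[0] for mesh in meshes]
        rms_list = [0.0] * m
        topology = meshes[0].faces.copy()
    else:
        ref = reference if reference is not None else meshes[0]
        vectors, _history, _stop, rms_list = iterative_refit(ref, meshes, settings)
        topology = ref.faces.copy()
    if normalize:
        mean_vec = compute_mean(vectors)
        vectors, _ = size_normalize(vectors, mean_vec)
    model = fit_pca(vectors, k)
    model.topology = topology
    model.normalized = normalize
    weights = np.stack([project(model, v) for v in vectors])
    table = WeightTable(list(specimen_ids), list(labels), weights)
    return model, table, list(rms_list)


def _mean_mesh(vectors, topology) -> SurfaceMesh:
    return SurfaceMesh(compute_mean(vectors).points(), topology)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_model(model: ShapeModel, path: str, provenance: dict | None = None) -> None:
    """Persist a model to one HDF5 archive (deterministic bytes)."""
    with h5py.File(path, "w", track_order=False) as f:
        for name, data in (
            ("mean", model.mean.values),
            ("modes", model.modes),
            ("variances", model.variances),
            ("topology", model.topology),
        ):
            f.create_dataset(name, data=data, track_times=False)
        f.attrs["k"] = model.k
        f.attrs["normalized"] = model.normalized
        f.attrs["n_vertices"] = model.mean.n_vertices
        f.attrs["total_variance"] = model.total_variance
        for key, val in (provenance or {}).items():
            f.attrs[f"provenance_{key}"] = str(val)


def load_model(path: str) -> ShapeModel:
    with h5py.File(path, "r") as f:
        return ShapeModel(
            mean=ShapeVector(f["mean"][...], int(f.attrs["n_vertices"])),
            modes=f["modes"][...],
            variances=f["variances"][...],
            k=int(f.attrs["k"]),
            topology=f["topology"][...].astype(np.int64),
            normalized=bool(f.attrs["normalized"]),
            total_variance=float(f.attrs["total_variance"]),
        )
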