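"""Model quality: leave-one-out generality and registration summaries.

Generality asks how well a model built *without* a specimen can represent
it. For each fold, a PCA model is fitted on the remaining m - 1 shapes and
the left-out shape is reconstructed either by orthogonal projection
(S_bar + P P^T (S - S_bar), the standard generality metric) or by partial
least-squares regression from its projection scores (an alternative
honouring the common PLS phrasing of this validation). The per-fold error
is the root-mean-square over vertices of the Euclidean vertex distance
between reconstruction and truth, in mm; the report averages folds
arithmetically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .model import fit_pca, project, reconstruct

__all__ = ["LooReport", "leave_one_out_rms", "registration_quality"]


@dataclass
class LooReport:
    per_specimen_rms: np.ndarray  # mm, one entry per left-out specimen
    mean_rms: float
    k_used: int
    method: str


def _vertex_rms(a: np.ndarray, b: np.ndarray, n_vertices: int) -> float:
    d = (a - b).reshape(n_vertices, 3)
    return float(np.sqrt((d**2).sum(axis=1).mean()))


def leave_one_out_rms(shape_vectors, k: int, method: str = "projection") -> LooReport:
    """Leave-one-out reconstruction RMS (mm) at k modes.

    ``method='projection'`` reconstructs the left-out shape by orthogonal
    projection onto the fold model; ``method='pls'`` predicts it from its
    fold-model scores with a partial least-squares regression trained on
    the fold's own scores/deviations.
    """
    m = len(shape_vectors)
    if m < 3:
        raise ParameterError("leave-one-out needs at least three shapes")
    if not 1 <= k <= m - 2:
        raise ParameterError(f"k must be in [1, m-2] = [1, {m - 2}], got {k}")
    if method not in ("projection", "pls"):
        raise ParameterError(f"unknown method {method!r}")
    n_vertices = shape_vectors[0].n_vertices
    rms = np.empty(m)
    for i in range(m):
        fold = [v for j, v in enumerate(shape_vectors) if j != i]
        model = fit_pca(fold, k)
        left_out = shape_vectors[i]
        scores = project(model, left_out)
        if method == "projection":
            recon = reconstruct(model, scores).values
        else:
            from sklearn.cross_decomposition import PLSRegression

            train_scores = np.stack([project(model, v) for v in fold])
            train_dev = np.stack([v.values - model.mean.values for v in fold])
            pls = PLSRegression(
                n_components=min(k, len(fold) - 1), scale=False
            )
            pls.fit(train_scores, train_dev)
            recon = model.mean.values + pls.predict(scores[None, :])[0]
        rms[i] = _vertex_rms(recon, left_out.values, n_vertices)
    return LooReport(
        per_specimen_rms=rms,
        mean_rms=float(rms.mean()),
        k_used=k,
        method=method,
    )


def registration_quality(rms_list, threshold_mm: float = 1.0) -> dict:
    """Arithmetic summaries of per-specimen fitting RMS with threshold flags."""
    rms = np.asarray(list(rms_list), dtype=np.float64)
    if rms.size == 0:
        raise ParameterError("registration_quality needs a non-empty RMS list")
    flagged = np.flatnonzero(rms > threshold_mm)
    return {
        "mean_mm": float(rms.mean()),
        "sd_mm": float(rms.std(ddof=1)) if rms.size > 1 else 0.0,
        "max_mm": float(rms.max()),
        "per_specimen_mm": rms.tolist(),
        "threshold_mm": threshold_mm,
        "flagged": flagged.tolist(),
    }
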