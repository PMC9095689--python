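"""Cohort comparison: mean-shape difference maps and per-PC statistics.

Two corresponded mean shapes are compared vertex-by-vertex (the signal that
drives colour-coded difference maps) and by the symmetric Hausdorff
distance (a single worst-case summary, computed point-to-surface in both
directions).

Group differences in shape are tested per principal component on the
specimens' PC weights. Each PC runs the parametric-test gate used in
morphometric practice - freedom from outliers (1.5 x IQR fences per
group), per-group normality (Shapiro-Wilk) and variance equality across
groups (Levene, mean-centred). When every gate passes, a pooled-variance
two-sample t-test is used; any violation routes the PC to the
non-parametric Kruskal-Wallis test on the full data. (Outliers are
recorded and treated as a violated criterion rather than deleted before a
t-test: trimming by the fences and then testing the trimmed samples is
anticonservative and breaks family-wise error control, which null
simulations of this battery must satisfy.) Raw p-values of all tested PCs
form one family and are Holm-Bonferroni adjusted jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateInputError,
    DimensionError,
    ParameterError,
)
from .mesh import SurfaceMesh
from .model import ShapeModel, WeightTable, project
from .registration import SurfaceDistance

__all__ = [
    "DifferenceMap",
    "PcTestResult",
    "mean_difference_map",
    "extract_weights",
    "shapiro_wilk",
    "levene",
    "holm_bonferroni",
    "kruskal_wallis",
    "compare_groups",
]


@dataclass
class DifferenceMap:
    per_vertex_mm: np.ndarray  # corresponding-vertex Euclidean distances
    hausdorff_mm: float  # symmetric, point-to-surface
    direction: np.ndarray  # +1 where A lies outside B along A's outward normal


@dataclass
class PcTestResult:
    pc_index: int
    test_used: str  # "t_test" | "kruskal_wallis"
    statistic: float
    p_raw: float
    p_adjusted: float
    normality_p: dict
    variance_equality_p: float
    outliers_excluded: list
    significant: bool
    error: str | None = field(default=None)


def mean_difference_map(mesh_a: SurfaceMesh, mesh_b: SurfaceMesh) -> DifferenceMap:
    """Compare two corresponded meshes (identical topology required)."""
    if mesh_a.n_vertices != mesh_b.n_vertices or not np.array_equal(
        mesh_a.faces, mesh_b.faces
    ):
        raise DimensionError("difference map requires identical topology")
    per_vertex = np.linalg.norm(mesh_a.vertices - mesh_b.vertices, axis=1)
    _, d_ab = SurfaceDistance(mesh_b).query(mesh_a.vertices)
    _, d_ba = SurfaceDistance(mesh_a).query(mesh_b.vertices)
    hausdorff = float(max(d_ab.max(), d_ba.max()))
    import trimesh

    normals = trimesh.Trimesh(
        mesh_a.vertices, mesh_a.faces, process=False
    ).vertex_normals
    offset = np.einsum("ij,ij->i", mesh_a.vertices - mesh_b.vertices, normals)
    direction = np.where(offset >= 0, 1, -1)
    return DifferenceMap(per_vertex, hausdorff, direction)


def extract_weights(model: ShapeModel, shape_vectors, labels, specimen_ids=None):
    """Project shapes onto the model: one weight row per specimen."""
    if len(shape_vectors) != len(labels):
        raise DimensionError("labels must align with shape_vectors")
    if specimen_ids is None:
        specimen_ids = [f"s{i:03d}" for i in range(len(shape_vectors))]
    weights = np.stack([project(model, v) for v in shape_vectors])
    return WeightTable(list(specimen_ids), list(labels), weights)


# ---------------------------------------------------------------------------
# Test battery primitives
# ---------------------------------------------------------------------------


def shapiro_wilk(values):
    """Shapiro-Wilk normality test (W, p); requires 3 <= n <= 5000."""
    values = np.asarray(values, dtype=np.float64)
    if not 3 <= len(values) <= 5000:
        raise ParameterError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(values) == 0:
        raise DegenerateInputError("Shapiro-Wilk undefined for zero-variance input")
    res = stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def levene(group_a, group_b):
    """Levene's variance-equality test with group means as centers."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("Levene's test needs n >= 2 per group")
    res = stats.levene(a, b, center="mean")
    return float(res.statistic), float(res.pvalue)


def holm_bonferroni(p_values, alpha: float = 0.05):
    """Holm's step-down adjustment; returns (adjusted p-values, reject flags)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ParameterError("no p-values supplied")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ParameterError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return p_adj, reject


def kruskal_wallis(*groups):
    """Kruskal-Wallis rank test (H with tie correction, chi-square p)."""
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and not np.isscalar(
        groups[0][0]
    ):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ParameterError("Kruskal-Wallis needs at least two groups")
    if sum(len(g) for g in groups) < 5:
        raise ParameterError("Kruskal-Wallis needs a total n >= 5")
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Per-PC battery
# ---------------------------------------------------------------------------


def _iqr_outliers(values: np.ndarray):
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return (values < lo) | (values > hi)


def compare_groups(
    weights: WeightTable,
    alpha: float = 0.05,
    outlier_rule: str = "iqr1.5",
    gate_alpha: float = 0.05,
):
    """Run the per-PC two-group test battery on a weight table.

    Exactly two labels must be present, each with n >= 3. Returns one
    :class:`PcTestResult` per PC; PCs with zero weight variance in both
    groups are reported with an ``error`` tag and excluded from the Holm
    family, leaving the other PCs unaffected. ``outliers_excluded`` lists
    the specimens outside the IQR fences; their presence disqualifies the
    PC from the t-test branch (Kruskal-Wallis runs on the full data).
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    if outlier_rule not in ("iqr1.5", "none"):
        raise ParameterError(f"unknown outlier_rule {outlier_rule!r}")
    labels = np.asarray(weights.labels)
    uniq = sorted(set(weights.labels))
    if len(uniq) != 2:
        raise ParameterError(f"exactly two labels required, found {uniq}")
    mask_a = labels == uniq[0]
    mask_b = labels == uniq[1]
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ParameterError("each group needs n >= 3")
    ids = np.asarray(weights.specimen_ids)

    results: list[PcTestResult] = []
    for pc in range(weights.pc_count):
        col = weights.weights[:, pc]
        a, b = col[mask_a], col[mask_b]
        ids_a, ids_b = ids[mask_a], ids[mask_b]
        excluded: list = []
        outlier_free = True
        if outlier_rule == "iqr1.5":
            out_a = _iqr_outliers(a)
            out_b = _iqr_outliers(b)
            excluded = list(ids_a[out_a]) + list(ids_b[out_b])
            outlier_free = not excluded
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            results.append(
                PcTestResult(
                    pc_index=pc,
                    test_used="none",
                    statistic=float("nan"),
                    p_raw=float("nan"),
                    p_adjusted=float("nan"),
                    normality_p={},
                    variance_equality_p=float("nan"),
                    outliers_excluded=excluded,
                    significant=False,
                    error="zero weight variance in both groups",
                )
            )
            continue
        try:
            _, p_norm_a = shapiro_wilk(a)
        except DegenerateInputError:
            p_norm_a = 0.0  # constant group: certainly non-normal
        try:
            _, p_norm_b = shapiro_wilk(b)
        except DegenerateInputError:
            p_norm_b = 0.0
        _, p_lev = levene(a, b)
        parametric = (
            outlier_free
            and p_norm_a > gate_alpha
            and p_norm_b > gate_alpha
            and p_lev > gate_alpha
        )
        if parametric:
            res = stats.ttest_ind(a, b, equal_var=True)
            test_used, statistic, p_raw = "t_test", float(res.statistic), float(
                res.pvalue
            )
        else:
            statistic, p_raw = kruskal_wallis(a, b)
            test_used = "kruskal_wallis"
        results.append(
            PcTestResult(
                pc_index=pc,
                test_used=test_used,
                statistic=statistic,
                p_raw=p_raw,
                p_adjusted=p_raw,  # filled below
                normality_p={uniq[0]: p_norm_a, uniq[1]: p_norm_b},
                variance_equality_p=p_lev,
                outliers_excluded=excluded,
                significant=False,
            )
        )

    tested = [r for r in results if r.error is None]
    if tested:
        p_adj, reject = holm_bonferroni([r.p_raw for r in tested], alpha)
        for r, pa, rej in zip(tested, p_adj, reject):
            r.p_adjusted = float(pa)
            r.significant = bool(rej)
    return results
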