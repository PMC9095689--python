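"""End-to-end study orchestration.

A *study* runs the full shape-modelling workflow on a directory of surface
meshes (or on a generated synthetic two-group cohort):

1. ``generate``  - synthesize a two-group cohort to disk (STL + manifest CSV
   with ground-truth weights);
2. ``build``     - reflect left-limb specimens, establish dense
   correspondence by iterative mean-reference RBF refitting, build
   morphological and appearance PCA models per cohort and combined, project
   weights, and run leave-one-out validation;
3. ``compare``   - mean-shape difference maps between the groups and the
   per-PC statistical battery on the combined-model weights;
4. ``validate``  - recompute leave-one-out and registration-quality
   summaries from the built artifacts.

Everything is deterministic under the study seed, and every output file
carries the hash of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .compare import compare_groups, extract_weights, mean_difference_map
from .errors import ParameterError
from .mesh import (
    ShapeVector,
    SurfaceMesh,
    read_mesh,
    reflect_sagittal,
    shape_vector_to_mesh,
    write_mesh,
)
from .model import (
    WeightTable,
    compute_mean,
    fit_pca,
    save_model,
    size_normalize,
)
from .registration import RegistrationSettings, iterative_refit
from .synthetic import (
    MODE_NAMES,
    GeneratorConfig,
    generate_two_group_study,
)
from .validation import leave_one_out_rms, registration_quality

logger = logging.getLogger("myoshape")

__all__ = [
    "StudyConfig",
    "default_study_config",
    "load_config",
    "run_generate",
    "run_build",
    "run_compare",
    "run_validate",
]


@dataclass
class StudyConfig:
    """Declarative description of one study run."""

    seed: int = 0
    out_dir: str = "study_out"
    synthetic: dict | None = None  # generator block; exclusive with mesh input
    mesh_dir: str | None = None
    manifest: str | None = None
    reflect: list = field(default_factory=list)  # explicit specimen ids
    registration: RegistrationSettings = field(default_factory=RegistrationSettings)
    k: int = 9
    alpha: float = 0.05
    outlier_rule: str = "iqr1.5"
    reference_id: str | None = None
    loo_method: str = "projection"
    log_level: str = "INFO"

    def validate(self) -> None:
        has_synth = self.synthetic is not None
        has_dir = self.manifest is not None
        if has_synth == has_dir:
            raise ParameterError(
                "exactly one input source required: 'synthetic' or 'manifest'"
            )
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (where outputs go and how
        verbosely we log are not part of the study identity)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("log_level", None)
        blob = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def default_study_config(seed: int = 0, out_dir: str = "study_out") -> StudyConfig:
    """The default synthetic two-group study.

    Group A (n = 19) emulates a clinical cohort with smaller muscles that
    also tend to be long, thin and narrow: mean shift -0.8 SD on the size
    mode and +0.8 SD on the aspect mode. Group B (n = 17) is the unshifted
    population. Topology is shuffled per specimen so correspondence must be
    established by registration.
    """
    return StudyConfig(
        seed=seed,
        out_dir=out_dir,
        synthetic={
            "n_a": 19,
            "n_b": 17,
            "offset_a": {"size": -0.8, "aspect": 0.8},
            "offset_b": {},
            "mode_sds": [1.0, 0.8, 0.6, 0.5, 0.4],
            "noise_sd": 0.5,
            "resolution": 20,
            "shuffle_topology": True,
        },
    )


def load_config(path: str) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    reg = RegistrationSettings(**raw.pop("registration", {}))
    return StudyConfig(registration=reg, **raw)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _setup_logging(config: StudyConfig) -> None:
    os.makedirs(config.out_dir, exist_ok=True)
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    log_path = os.path.abspath(os.path.join(config.out_dir, "run.log"))
    for h in list(logger.handlers):
        if isinstance(h, logging.FileHandler) and h.baseFilename != log_path:
            logger.removeHandler(h)
            h.close()
    if not any(isinstance(h, logging.FileHandler) for h in logger.handlers):
        fh = logging.FileHandler(log_path)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)
    if not any(type(h) is logging.StreamHandler for h in logger.handlers):
        logger.addHandler(logging.StreamHandler())


def _write_csv(df: pd.DataFrame, path: str, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.9g", lineterminator="\n")


def _read_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _offsets_to_tuple(offsets: dict) -> tuple:
    vec = [0.0] * len(MODE_NAMES)
    for name, val in (offsets or {}).items():
        if name not in MODE_NAMES:
            raise ParameterError(f"unknown mode {name!r} in group offset")
        vec[MODE_NAMES.index(name)] = float(val)
    return tuple(vec)


def _generator_configs(config: StudyConfig):
    s = dict(config.synthetic)
    ss = np.random.SeedSequence(config.seed)
    seed_a, seed_b = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    common = dict(
        mode_sds=tuple(s.get("mode_sds", (1.0, 0.8, 0.6, 0.5, 0.4))),
        noise_sd=float(s.get("noise_sd", 0.5)),
        resolution=int(s.get("resolution", 20)),
        shuffle_topology=bool(s.get("shuffle_topology", True)),
    )
    cfg_a = GeneratorConfig(
        n_subjects=int(s.get("n_a", 19)),
        group_offset=_offsets_to_tuple(s.get("offset_a", {})),
        seed=seed_a,
        **common,
    )
    cfg_b = GeneratorConfig(
        n_subjects=int(s.get("n_b", 17)),
        group_offset=_offsets_to_tuple(s.get("offset_b", {})),
        seed=seed_b,
        **common,
    )
    return cfg_a, cfg_b


# ---------------------------------------------------------------------------
# commands
# ---------------------------------------------------------------------------


def run_generate(config: StudyConfig, force: bool = False) -> str:
    """Write the synthetic cohort (STL meshes + manifest CSV) to disk."""
    config.validate()
    if config.synthetic is None:
        raise ParameterError("generate requires a 'synthetic' input block")
    _setup_logging(config)
    mesh_dir = os.path.join(config.out_dir, "meshes")
    if os.path.isdir(mesh_dir) and os.listdir(mesh_dir) and not force:
        raise ParameterError(
            f"output directory {mesh_dir} is not empty; pass force=True to overwrite"
        )
    os.makedirs(mesh_dir, exist_ok=True)
    chash = config.config_hash()
    cfg_a, cfg_b = _generator_configs(config)
    sample = generate_two_group_study(cfg_a, cfg_b)
    rows = []
    for i, (mesh, label) in enumerate(zip(sample.meshes, sample.labels)):
        sid = f"{label}{i:03d}"
        rel = os.path.join("meshes", f"{sid}.stl")
        write_mesh(mesh, os.path.join(config.out_dir, rel), fmt="stl")
        row = {"specimen_id": sid, "label": label, "side": "R", "path": rel}
        row.update(
            {f"w_{name}": sample.true_weights[i, j] for j, name in enumerate(MODE_NAMES)}
        )
        rows.append(row)
    manifest_path = os.path.join(config.out_dir, "manifest.csv")
    _write_csv(pd.DataFrame(rows), manifest_path, chash)
    with open(os.path.join(config.out_dir, "config.yaml"), "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    logger.info("generated %d meshes into %s", len(rows), mesh_dir)
    return manifest_path


def _load_study_meshes(config: StudyConfig):
    """Read manifest + meshes; left-side and explicitly listed ids reflected."""
    manifest = config.manifest or os.path.join(config.out_dir, "manifest.csv")
    base = config.mesh_dir or os.path.dirname(manifest)
    df = _read_csv(manifest)
    meshes, ids, labels = [], [], []
    for _, row in df.iterrows():
        mesh = read_mesh(os.path.join(base, row["path"]))
        side = str(row.get("side", "R"))
        if side.upper() == "L" or row["specimen_id"] in config.reflect:
            mesh = reflect_sagittal(mesh)
        meshes.append(mesh)
        ids.append(str(row["specimen_id"]))
        labels.append(str(row["label"]))
    return meshes, ids, labels


def _pick_reference(config: StudyConfig, meshes, ids, labels) -> SurfaceMesh:
    if config.reference_id is not None:
        if config.reference_id not in ids:
            raise ParameterError(f"reference_id {config.reference_id!r} not in manifest")
        return meshes[ids.index(config.reference_id)]
    # mirror the convention of registering everyone against a control-group
    # specimen: use the first mesh of the second label when two are present
    uniq = sorted(set(labels))
    if len(uniq) == 2:
        return meshes[labels.index(uniq[1])]
    return meshes[0]


def run_build(config: StudyConfig) -> dict:
    """Correspond the cohort and build all shape models + reports."""
    config.validate()
    _setup_logging(config)
    chash = config.config_hash()
    out = config.out_dir
    if config.synthetic is not None and not os.path.exists(
        os.path.join(out, "manifest.csv")
    ):
        run_generate(config)
    meshes, ids, labels = _load_study_meshes(config)
    reference = _pick_reference(config, meshes, ids, labels)
    logger.info("registering %d meshes (iterative mean-reference refit)", len(meshes))
    vectors, history, stop, rms_list = iterative_refit(
        reference, meshes, config.registration
    )
    logger.info("refit RMS history %s (%s)", [round(h, 4) for h in history], stop)

    # persist the corresponded vectors so later stages can reload them
    import h5py

    with h5py.File(os.path.join(out, "corresponded.h5"), "w") as f:
        f.create_dataset(
            "vectors",
            data=np.stack([v.values for v in vectors]),
            track_times=False,
        )
        f.create_dataset("topology", data=reference.faces, track_times=False)
        f.create_dataset(
            "ids", data=np.array(ids, dtype="S32"), track_times=False
        )
        f.create_dataset(
            "labels", data=np.array(labels, dtype="S8"), track_times=False
        )
        f.attrs["config_hash"] = chash

    _write_csv(
        pd.DataFrame(
            {"specimen_id": ids, "rms_mm": rms_list, "n_iter": len(history)}
        ),
        os.path.join(out, "registration_rms.csv"),
        chash,
    )

    uniq = sorted(set(labels))
    subsets = {lab: [i for i, l in enumerate(labels) if l == lab] for lab in uniq}
    if len(uniq) == 2:
        subsets["combined"] = list(range(len(labels)))
    artifacts = {}
    loo_summaries = {}
    for name, idx in subsets.items():
        sub_vecs = [vectors[i] for i in idx]
        sub_ids = [ids[i] for i in idx]
        sub_labels = [labels[i] for i in idx]
        for normalized, tag in ((False, "morphological"), (True, "appearance")):
            vecs = sub_vecs
            if normalized:
                vecs, _ = size_normalize(sub_vecs, compute_mean(sub_vecs))
            k = min(config.k, len(vecs) - 1)
            model = fit_pca(vecs, k)
            model.topology = reference.faces.copy()
            model.normalized = normalized
            table = extract_weights(model, vecs, sub_labels, sub_ids)
            stem = f"model_{name}_{tag}"
            save_model(
                model,
                os.path.join(out, stem + ".h5"),
                provenance={"config_hash": chash, "seed": config.seed},
            )
            _write_csv(
                table.to_dataframe(), os.path.join(out, stem + "_weights.csv"), chash
            )
            loo_k = min(k, len(vecs) - 2)
            loo = leave_one_out_rms(vecs, k=loo_k, method=config.loo_method)
            loo_summaries[stem] = {
                "mean_rms_mm": loo.mean_rms,
                "k_used": loo.k_used,
                "method": loo.method,
            }
            artifacts[stem] = os.path.join(out, stem + ".h5")
            logger.info(
                "%s: k=%d, PC1 share %.1f%%, LOO RMS %.3f mm",
                stem,
                k,
                100 * model.variances[0] / max(model.total_variance, 1e-300),
                loo.mean_rms,
            )
    report = {
        "config_hash": chash,
        "registration": registration_quality(rms_list),
        "rms_history": history,
        "stop_reason": stop,
        "leave_one_out": loo_summaries,
    }
    with open(os.path.join(out, "build_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return artifacts


def _load_corresponded(out: str):
    import h5py

    path = os.path.join(out, "corresponded.h5")
    if not os.path.exists(path):
        raise ParameterError(
            f"missing {path}; run the build stage before compare/validate"
        )
    with h5py.File(path, "r") as f:
        X = f["vectors"][...]
        topology = f["topology"][...].astype(np.int64)
        ids = [s.decode() for s in f["ids"][...]]
        labels = [s.decode() for s in f["labels"][...]]
    vectors = [ShapeVector(x) for x in X]
    return vectors, topology, ids, labels


def run_compare(config: StudyConfig) -> dict:
    """Difference maps between group means + per-PC statistics."""
    config.validate()
    _setup_logging(config)
    chash = config.config_hash()
    out = config.out_dir
    vectors, topology, ids, labels = _load_corresponded(out)
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ParameterError("compare requires exactly two cohort labels")
    results = {"config_hash": chash}
    for normalized, tag in ((False, "morphological"), (True, "appearance")):
        vecs = vectors
        if normalized:
            vecs, _ = size_normalize(vectors, compute_mean(vectors))
        means = {}
        for lab in uniq:
            sub = [v for v, l in zip(vecs, labels) if l == lab]
            means[lab] = shape_vector_to_mesh(compute_mean(sub), topology)
        dmap = mean_difference_map(means[uniq[0]], means[uniq[1]])
        ply_path = os.path.join(out, f"difference_map_{tag}.ply")
        write_mesh(
            means[uniq[0]], ply_path, fmt="ply", scalars=dmap.per_vertex_mm
        )
        weights_csv = os.path.join(out, f"model_combined_{tag}_weights.csv")
        if not os.path.exists(weights_csv):
            raise ParameterError(f"missing {weights_csv}; run the build stage first")
        wdf = _read_csv(weights_csv)
        pc_cols = [c for c in wdf.columns if c.startswith("pc")]
        table = WeightTable(
            list(wdf["specimen_id"]), list(wdf["label"]), wdf[pc_cols].to_numpy()
        )
        tests = compare_groups(table, alpha=config.alpha, outlier_rule=config.outlier_rule)
        tdf = pd.DataFrame(
            [
                {
                    "pc": r.pc_index + 1,
                    "test_used": r.test_used,
                    "statistic": r.statistic,
                    "p_raw": r.p_raw,
                    "p_adjusted": r.p_adjusted,
                    "significant": r.significant,
                }
                for r in tests
            ]
        )
        _write_csv(tdf, os.path.join(out, f"group_tests_{tag}.csv"), chash)
        results[tag] = {
            "hausdorff_mm": dmap.hausdorff_mm,
            "mean_vertex_distance_mm": float(dmap.per_vertex_mm.mean()),
            "significant_pcs": [r.pc_index + 1 for r in tests if r.significant],
        }
        logger.info(
            "%s: Hausdorff %.2f mm, significant PCs %s",
            tag,
            dmap.hausdorff_mm,
            results[tag]["significant_pcs"],
        )
    with open(os.path.join(out, "compare_report.json"), "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    return results


def run_validate(config: StudyConfig) -> dict:
    """Recompute leave-one-out generality and registration quality."""
    config.validate()
    _setup_logging(config)
    out = config.out_dir
    vectors, _topology, ids, labels = _load_corresponded(out)
    k = min(config.k, len(vectors) - 2)
    report = {"config_hash": config.config_hash()}
    for normalized, tag in ((False, "morphological"), (True, "appearance")):
        vecs = vectors
        if normalized:
            vecs, _ = size_normalize(vectors, compute_mean(vectors))
        loo = leave_one_out_rms(vecs, k=k, method=config.loo_method)
        report[tag] = {
            "loo_mean_rms_mm": loo.mean_rms,
            "loo_per_specimen_mm": loo.per_specimen_rms.tolist(),
            "k_used": loo.k_used,
            "method": loo.method,
        }
    rms_csv = os.path.join(out, "registration_rms.csv")
    if os.path.exists(rms_csv):
        report["registration"] = registration_quality(
            _read_csv(rms_csv)["rms_mm"].to_numpy()
        )
    with open(os.path.join(out, "validate_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
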