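"""End-to-end orchestration: segmentation through association models.

:func:`run_pipeline` executes the full analysis in stage order — WMH
segmentation, lobar volumes, symmetrized percent change, vertexwise GLM,
clusterwise Monte Carlo correction, cluster-mean extraction, association
models — on either simulated inputs (the default, fully determined by the
global seed) or user-supplied files, writing every intermediate artifact and
a manifest of parameters, seeds and content hashes sufficient to re-execute
the identical run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    fit_interaction_model,
    fit_memory_model,
    group_difference_tests,
    stratified_table,
)
from .design import PRIMARY_COVARIATES, build_design
from .glm import (
    ClusterConfig,
    extract_cluster_mean_spc,
    find_clusters,
    fit_vertexwise,
    monte_carlo_cluster_p,
)
from .io import (
    load_mesh_off,
    load_nifti,
    read_cohort_csv,
    save_mesh_off,
    save_nifti,
    sha256_file,
    write_cohort_csv,
    write_json,
)
from .mesh import SurfaceMesh, icosphere
from .segmentation import (
    FlairVolume,
    LobarAtlas,
    SegmentationParams,
    regional_volumes,
    segment_wmh,
)
from .spc import ThicknessPair, symmetrized_percent_change
from .synthetic import (
    CohortSimConfig,
    ImageSimConfig,
    PlantedCluster,
    default_planted_cluster,
    simulate_cohort,
    simulate_flair,
)

STAGES = (
    "segmentation",
    "regional_volumes",
    "spc",
    "vertexwise_glm",
    "cluster_correction",
    "cluster_means",
    "association_models",
)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything a run needs; the global seed drives every stochastic stage."""

    output_dir: str
    seed: int = 0
    # simulated-input route (used when the corresponding path is None)
    image: Optional[ImageSimConfig] = None
    cohort: Optional[CohortSimConfig] = None
    mesh_subdivisions: int = 2
    plant_default_cluster: bool = True
    # file-input route
    flair_path: Optional[str] = None
    mask_path: Optional[str] = None
    atlas_path: Optional[str] = None
    mesh_path: Optional[str] = None
    cohort_path: Optional[str] = None
    thickness_t1_path: Optional[str] = None
    thickness_t2_path: Optional[str] = None
    # analysis parameters
    segmentation: SegmentationParams = dc_field(default_factory=SegmentationParams)
    cluster: ClusterConfig = dc_field(default_factory=lambda: ClusterConfig(iterations=200))
    wmh_predictor: str = "wmh_parietal"
    verbosity: int = 1


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return f"<array shape={obj.shape}>"
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": _jsonable(config),
        "stages": [],
        "artifacts": {},
    }

    def record(path: Path) -> None:
        manifest["artifacts"][path.name] = sha256_file(path)

    def done(stage: str, **info) -> None:
        manifest["stages"].append({"name": stage, "status": "complete", **info})
        if config.verbosity:
            print(f"[lobewise] stage {stage}: complete")

    # ---- inputs: simulate or load -------------------------------------
    mesh, cohort, volume, atlas = _prepare_inputs(config, out, record)

    # ---- 1. segmentation ----------------------------------------------
    try:
        seg = segment_wmh(volume, config.segmentation)
        save_nifti(out / "wmh_mask.nii", seg.lesion_mask.astype(np.uint8), volume.voxel_size)
        record(out / "wmh_mask.nii")
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise PipelineStageError("segmentation", e) from e
    done("segmentation", mu=seg.mu, sigma=seg.sigma, threshold=seg.threshold,
         labeled_voxels=seg.labeled_voxels)

    # ---- 2. regional volumes ------------------------------------------
    try:
        seg = regional_volumes(seg, atlas, volume)
        vols = {"total_cm3": seg.total_volume_cm3, **{
            f"{k}_cm3": v for k, v in seg.lobar_volumes_cm3.items()}}
        write_json(out / "wmh_volumes.json", vols)
        record(out / "wmh_volumes.json")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("regional_volumes", e) from e
    done("regional_volumes", **vols)

    # ---- 3. symmetrized percent change --------------------------------
    try:
        intervals = cohort.table["interval_years"].to_numpy()
        spc_maps = np.vstack([
            symmetrized_percent_change(
                ThicknessPair(cohort.thickness_t1[i], cohort.thickness_t2[i], intervals[i])
            )
            for i in range(len(cohort.table))
        ])
        pd.DataFrame(spc_maps).to_csv(out / "spc_maps.csv", index=False)
        record(out / "spc_maps.csv")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("spc", e) from e
    done("spc", n_subjects=spc_maps.shape[0], n_vertices=spc_maps.shape[1])

    # ---- 4. vertexwise GLM --------------------------------------------
    try:
        design = build_design(cohort.table, config.wmh_predictor, PRIMARY_COVARIATES)
        fit = fit_vertexwise(spc_maps, design, config.wmh_predictor)
        pd.DataFrame(
            {"vertex": np.arange(mesh.n_vertices), "t": fit.focal_t,
             "beta": fit.beta[fit.focal_index()], "p": fit.p[fit.focal_index()]}
        ).to_csv(out / "vertexwise_stats.csv", index=False)
        record(out / "vertexwise_stats.csv")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("vertexwise_glm", e) from e
    done("vertexwise_glm", dof=fit.dof)

    # ---- 5. cluster correction ----------------------------------------
    try:
        # stage seeds derive from the global seed so one integer reproduces
        # the whole run
        cluster_cfg = dataclasses.replace(config.cluster, seed=config.seed + 2)
        clusters = find_clusters(fit.focal_t, mesh, cluster_cfg, fit.dof)
        clusters = monte_carlo_cluster_p(
            clusters, spc_maps, design, config.wmh_predictor, mesh, cluster_cfg
        )
        rows = [
            {"cluster": i, "sign": c.sign, "extent": c.extent,
             "area_mm2": c.area_mm2, "peak_t": c.peak_t, "p": c.p,
             "vertices": " ".join(map(str, c.vertices))}
            for i, c in enumerate(clusters)
        ]
        pd.DataFrame(
            rows, columns=["cluster", "sign", "extent", "area_mm2", "peak_t", "p", "vertices"]
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        record(out / "clusters.tsv")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("cluster_correction", e) from e
    done("cluster_correction", n_clusters=len(clusters),
         n_significant=sum(c.p < config.cluster.alpha for c in clusters))

    # ---- 6. cluster-mean extraction ------------------------------------
    try:
        significant = [c for c in clusters if c.p < config.cluster.alpha]
        cluster_cols = []
        for i, c in enumerate(significant):
            col = f"cluster{i}_mean_spc"
            cohort.table[col] = extract_cluster_mean_spc(spc_maps, c)
            cluster_cols.append(col)
        write_cohort_csv(out / "cohort_with_clusters.csv", cohort.table)
        record(out / "cohort_with_clusters.csv")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("cluster_means", e) from e
    done("cluster_means", clusters_extracted=len(cluster_cols))

    # ---- 7. association models ----------------------------------------
    try:
        assoc: dict = {}
        if cluster_cols:
            mem = fit_memory_model(cohort.table, cluster_cols[0])
            mem.coefficients.to_csv(out / "memory_model.tsv", sep="\t")
            record(out / "memory_model.tsv")
            assoc["memory_b"] = mem[cluster_cols[0]]["b"]
            inter = fit_interaction_model(
                cohort.table, cluster_cols[0], config.wmh_predictor
            )
            inter.coefficients.to_csv(out / "interaction_model.tsv", sep="\t")
            record(out / "interaction_model.tsv")
            strat = stratified_table(cohort.table, cluster_cols, config.wmh_predictor)
            strat.to_csv(out / "stratified_models.tsv", sep="\t", index=False)
            record(out / "stratified_models.tsv")
        measures = [c for c in cohort.table.columns if c.startswith("wmh_")]
        gdt = group_difference_tests(cohort.table, measures + cluster_cols)
        gdt.to_csv(out / "group_differences.tsv", sep="\t", index=False)
        record(out / "group_differences.tsv")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("association_models", e) from e
    done("association_models", **assoc)

    write_json(out / "manifest.json", manifest)
    return manifest


def _prepare_inputs(config: PipelineConfig, out: Path, record) -> tuple:
    """Simulate or load the volume, atlas, mesh and cohort."""
    try:
        for attr, stage in (
            ("flair_path", "segmentation"),
            ("mask_path", "segmentation"),
            ("atlas_path", "segmentation"),
            ("mesh_path", "spc"),
            ("cohort_path", "spc"),
        ):
            p = getattr(config, attr)
            if p is not None and not Path(p).exists():
                raise PipelineStageError(
                    stage, FileNotFoundError(f"{attr.removesuffix('_path')} not found: {p}")
                )

        if config.mesh_path is not None:
            mesh = load_mesh_off(config.mesh_path)
        else:
            mesh = icosphere(subdivisions=config.mesh_subdivisions)
            save_mesh_off(out / "mesh.off", mesh)
            record(out / "mesh.off")

        if config.flair_path is not None:
            data, vs = load_nifti(config.flair_path)
            mask, _ = load_nifti(config.mask_path)
            volume = FlairVolume(data=data, mask=mask.astype(bool), voxel_size=vs)
            labels, _ = load_nifti(config.atlas_path)
            atlas = LobarAtlas(labels.astype(np.int16))
        else:
            img_cfg = config.image or ImageSimConfig(seed=config.seed)
            volume, atlas, truth = simulate_flair(img_cfg)
            save_nifti(out / "flair.nii", volume.data, volume.voxel_size)
            save_nifti(out / "brain_mask.nii", volume.mask.astype(np.uint8), volume.voxel_size)
            save_nifti(out / "lobar_atlas.nii", atlas.labels, volume.voxel_size)
            save_nifti(out / "truth_lesions.nii", truth.astype(np.uint8), volume.voxel_size)
            for f in ("flair.nii", "brain_mask.nii", "lobar_atlas.nii", "truth_lesions.nii"):
                record(out / f)

        if config.cohort_path is not None:
            table = read_cohort_csv(config.cohort_path)
            t1 = pd.read_csv(config.thickness_t1_path).to_numpy(dtype=float)
            t2 = pd.read_csv(config.thickness_t2_path).to_numpy(dtype=float)
            from .synthetic import CohortTable

            cohort = CohortTable(table=table, thickness_t1=t1, thickness_t2=t2,
                                 spc_true=np.zeros_like(t1), truth={})
        else:
            coh_cfg = config.cohort
            if coh_cfg is None:
                planted = (
                    {"planted": default_planted_cluster(mesh, wmh_slope=-0.2)}
                    if config.plant_default_cluster
                    else {}
                )
                coh_cfg = CohortSimConfig(seed=config.seed + 1, planted_clusters=planted)
            cohort = simulate_cohort(coh_cfg, mesh)
            write_cohort_csv(out / "cohort.csv", cohort.table)
            record(out / "cohort.csv")
            write_json(out / "truth.json", _jsonable(cohort.truth))
            record(out / "truth.json")
        return mesh, cohort, volume, atlas
    except PipelineStageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("inputs", e) from e
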