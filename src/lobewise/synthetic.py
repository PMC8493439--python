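"""Seeded synthetic FLAIR volumes, surface cohorts and ground truth.

Every downstream stage of the pipeline is testable against known truth:

* :func:`simulate_flair` builds a brain-masked volume whose in-mask
  background is Gaussian, with sparse spherical hyperintense lesions set to
  ``mean + offset * SD``, plus an axis-aligned four-lobe label atlas and the
  exact lesion truth mask.
* :func:`simulate_cohort` draws per-subject covariates from the cohort's
  descriptive marginals (age 73.16 (5.19) y; 60% women; White/Black/Hispanic
  0.317/0.373/0.310; APOE e4 carriage 33.3%; education 12.80 (4.80) y;
  baseline entorhinal thickness 3.30 (0.31) mm; scan interval 4.1 (2.4) y
  truncated at 0.5; total WMH right-skewed with mean 4.81, SD 5.36 cm^3 split
  across lobes with means 2.04/0.31/1.30/0.40), then constructs two-timepoint
  thickness maps whose true vertexwise annualized change follows a linear
  model in WMH, covariates, and a group x WMH interaction inside planted
  clusters, and a delayed-recall score driven by true cluster-mean thinning.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical configs give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .mesh import SurfaceMesh, smooth_field_basis
from .segmentation import LOBE_CODES, FlairVolume, LobarAtlas
from .spc import thickness_for_spc


# ---------------------------------------------------------------------------
# FLAIR image simulation
# ---------------------------------------------------------------------------

@dataclass
class ImageSimConfig:
    """Geometry, intensity model and lesion load of a synthetic FLAIR scan."""

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.0
    background_mean: float = 100.0
    background_sd: float = 10.0
    lesion_count: int = 8
    lesion_radius: int = 2
    lesion_offset_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_offset_sd <= 0:
            raise ValueError("lesion intensity offset must be positive")
        if self.background_sd <= 0 or self.voxel_size_mm <= 0:
            raise ValueError("background SD and voxel size must be positive")
        if self.lesion_count < 0 or self.lesion_radius < 0:
            raise ValueError("lesion count and radius must be nonnegative")


class LesionPlacementError(RuntimeError):
    """Raised when the requested lesions cannot fit inside the brain mask."""


def _ball(radius: int) -> np.ndarray:
    if radius == 0:
        return np.ones((1, 1, 1), dtype=bool)
    r = radius
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return zz * zz + yy * yy + xx * xx <= r * r


def simulate_flair(
    config: ImageSimConfig,
) -> tuple[FlairVolume, LobarAtlas, np.ndarray]:
    """Synthesize (FLAIR volume, lobar atlas, truth lesion mask).

    The brain mask is an ellipsoid filling ~90% of the grid; lobes partition
    it into axis-aligned quadrants (frontal/temporal/parietal/occipital),
    chosen because the assignment is trivially verifiable.  Lesions are
    non-overlapping balls placed wholly inside the mask; impossible placement
    raises :class:`LesionPlacementError` rather than silently truncating.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(int(s) for s in config.shape)
    center = (np.array(shape) - 1) / 2.0
    semi = 0.45 * np.array(shape)
    grid = np.indices(shape, dtype=float)
    dist2 = sum(((grid[k] - center[k]) / semi[k]) ** 2 for k in range(3))
    mask = dist2 <= 1.0

    data = np.zeros(shape)
    data[mask] = rng.normal(
        config.background_mean, config.background_sd, int(mask.sum())
    )

    # lesion placement: centers restricted to the mask eroded by the radius
    truth = np.zeros(shape, dtype=bool)
    if config.lesion_count > 0:
        ball = _ball(config.lesion_radius)
        interior = ndimage.binary_erosion(mask, structure=ball)
        candidates = np.argwhere(interior)
        if (
            len(candidates) == 0
            or config.lesion_count * ball.sum() > mask.sum()
        ):
            raise LesionPlacementError("lesions exceed brain mask capacity")
        r = config.lesion_radius
        placed = 0
        attempts = 0
        max_attempts = 200 * config.lesion_count
        while placed < config.lesion_count:
            if attempts >= max_attempts:
                raise LesionPlacementError(
                    f"could not place {config.lesion_count} non-overlapping "
                    f"lesions of radius {r} after {max_attempts} attempts"
                )
            attempts += 1
            cz, cy, cx = candidates[rng.integers(len(candidates))]
            sl = (
                slice(cz - r, cz + r + 1),
                slice(cy - r, cy + r + 1),
                slice(cx - r, cx + r + 1),
            )
            if truth[sl][ball].any():
                continue
            truth[sl][ball] = True
            placed += 1
        data[truth] = (
            config.background_mean + config.lesion_offset_sd * config.background_sd
        )

    labels = np.zeros(shape, dtype=np.int16)
    half0 = grid[0] < center[0]
    half1 = grid[1] < center[1]
    labels[mask & half0 & half1] = LOBE_CODES["frontal"]
    labels[mask & half0 & ~half1] = LOBE_CODES["temporal"]
    labels[mask & ~half0 & half1] = LOBE_CODES["parietal"]
    labels[mask & ~half0 & ~half1] = LOBE_CODES["occipital"]

    vs = (config.voxel_size_mm,) * 3
    return FlairVolume(data=data, mask=mask, voxel_size=vs), LobarAtlas(labels), truth


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

WMH_COLUMNS = (
    "wmh_total",
    "wmh_frontal",
    "wmh_temporal",
    "wmh_parietal",
    "wmh_occipital",
)


@dataclass
class PlantedCluster:
    """A vertex set carrying a true WMH -> thinning slope.

    ``wmh_slope`` is in %/y per cm^3; ``interaction_black`` /
    ``interaction_hispanic`` add group-specific extra slope relative to the
    White reference group.
    """

    vertices: np.ndarray
    wmh_slope: float
    interaction_black: float = 0.0
    interaction_hispanic: float = 0.0


@dataclass
class CohortSimConfig:
    """Marginal distributions and planted effects of a synthetic cohort."""

    n_subjects: int = 303
    age_mean: float = 73.16
    age_sd: float = 5.19
    p_women: float = 0.597
    group_probs: dict = dc_field(
        default_factory=lambda: {
            "White": 96 / 303,
            "Black": 113 / 303,
            "Hispanic": 94 / 303,
        }
    )
    p_apoe4: float = 101 / 303
    education_mean: float = 12.80
    education_sd: float = 4.80
    entorhinal_mean: float = 3.30
    entorhinal_sd: float = 0.31
    interval_mean: float = 4.1
    interval_sd: float = 2.4
    interval_min: float = 0.5
    # longest feasible follow-up given the study's recruitment window
    interval_max: float = 10.0
    test_scan_interval_mean: float = 0.5
    test_scan_interval_sd: float = 0.3
    # total WMH: log-normal reparameterized to the target mean/SD; lobar
    # volumes are a Dirichlet split of the total with means proportional to
    # the target lobar means (the remainder is extra-lobar/unassigned)
    wmh_total_mean: float = 4.81
    wmh_total_sd: float = 5.36
    # upper support bound (~mean + 6.5 SD); real WMH burdens are bounded and
    # the unbounded log-normal tail would imply unattainable thinning rates
    wmh_total_max: float = 40.0
    lobe_means: dict = dc_field(
        default_factory=lambda: {
            "frontal": 2.04,
            "temporal": 0.31,
            "parietal": 1.30,
            "occipital": 0.40,
        }
    )
    dirichlet_concentration: float = 20.0
    # vertexwise SPC model: intercept + global covariate effects + planted
    # cluster slopes on the chosen WMH predictor (%/y units)
    spc_intercept: float = -0.3
    covariate_effects: dict = dc_field(
        default_factory=lambda: {
            "age": -0.01,
            "female": 0.10,
            "apoe4": -0.15,
            "entorhinal_baseline": 0.10,
        }
    )
    wmh_predictor: str = "wmh_parietal"
    planted_clusters: dict = dc_field(default_factory=dict)
    residual_sd: float = 1.0
    # one neighbor-mean iteration on the default mesh (~7 mm vertex spacing)
    # is roughly a 15 mm FWHM kernel; 2 iterations emulate typical surface
    # smoothing
    smoothing_iterations: int = 2
    baseline_thickness_mean: float = 2.5
    baseline_thickness_sd: float = 0.1
    baseline_spatial_sd: float = 0.2
    # memory model: recall = g0 + g_cluster * true cluster-mean SPC
    #                        + g_age * age + noise
    memory_intercept: float = 8.0
    memory_cluster_effect: float = 0.3
    memory_age_effect: float = -0.15
    memory_residual_sd: float = 2.0
    memory_cluster: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.array(list(self.group_probs.values()))
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("group probabilities must be nonnegative and sum to 1")
        for p in (self.p_women, self.p_apoe4):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0,1]")
        if self.interval_min <= 0:
            raise ValueError("minimum scan interval must be positive")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")


@dataclass
class CohortTable:
    """Simulated cohort: table, thickness maps, and the generating truth."""

    table: pd.DataFrame
    thickness_t1: np.ndarray  # (n_subjects, n_vertices)
    thickness_t2: np.ndarray
    spc_true: np.ndarray
    truth: dict


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given mean and SD."""
    sigma2 = np.log(1 + (sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2, np.sqrt(sigma2)


def _truncated_lognormal_params(
    mean: float, sd: float, cap: float
) -> tuple[float, float]:
    """(mu, sigma) such that the log-normal truncated at ``cap`` has the
    requested mean and SD.

    Uses the closed-form truncated moments
    E[X^k; X<c] = exp(k mu + k^2 sigma^2 / 2) Phi((ln c - mu - k sigma^2)/sigma)
    and solves the two moment equations numerically from the untruncated
    parameterization.
    """
    from scipy.optimize import fsolve

    lc = np.log(cap)

    def moments(params):
        mu, sigma = params[0], abs(params[1])
        z = (lc - mu) / sigma
        denom = stats.norm.cdf(z)
        m1 = np.exp(mu + sigma**2 / 2) * stats.norm.cdf(z - sigma) / denom
        m2 = np.exp(2 * mu + 2 * sigma**2) * stats.norm.cdf(z - 2 * sigma) / denom
        return m1, np.sqrt(max(m2 - m1**2, 1e-12))

    def eqs(params):
        m, s = moments(params)
        return [m - mean, s - sd]

    start = _lognormal_params(mean, sd)
    sol, _, ok, _ = fsolve(eqs, start, full_output=True)
    if ok != 1:
        raise ValueError(
            f"cannot match mean {mean} / SD {sd} under truncation at {cap}"
        )
    return float(sol[0]), float(abs(sol[1]))


def _sample_truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, cap: float, size: int
) -> np.ndarray:
    """Inverse-CDF sampling of a log-normal right-truncated at ``cap``."""
    z_cap = stats.norm.cdf((np.log(cap) - mu) / sigma)
    u = rng.random(size) * z_cap
    return np.exp(mu + sigma * stats.norm.ppf(u))


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lower: float,
    size: int,
    upper: float = np.inf,
) -> np.ndarray:
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(config: CohortSimConfig, mesh: SurfaceMesh) -> CohortTable:
    """Generate a cohort with known vertexwise and memory-model truth.

    The true per-vertex SPC is the linear predictor (intercept, global
    covariate effects, planted WMH slopes and group x WMH interactions inside
    their clusters) plus spatially smooth residual noise; timepoint-2
    thickness is constructed so the symmetrized-percent-change of the two
    maps reproduces that SPC exactly.  The returned truth dict records every
    planted coefficient.
    """
    if mesh.n_vertices == 0:
        raise ValueError("mesh has no vertices")
    for name, pc in config.planted_clusters.items():
        v = np.asarray(pc.vertices)
        if v.size and (v.min() < 0 or v.max() >= mesh.n_vertices):
            raise ValueError(f"planted cluster '{name}' indexes nonexistent vertices")

    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    groups = list(config.group_probs)
    probs = np.array([config.group_probs[g] for g in groups])
    table = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "age": rng.normal(config.age_mean, config.age_sd, n),
            "female": (rng.random(n) < config.p_women).astype(int),
            "race_ethnicity": np.array(groups)[rng.choice(len(groups), n, p=probs)],
            "apoe4": (rng.random(n) < config.p_apoe4).astype(int),
            "education": _truncated_normal(
                rng, config.education_mean, config.education_sd, 0.0, n
            ),
            "entorhinal_baseline": rng.normal(
                config.entorhinal_mean, config.entorhinal_sd, n
            ),
            "interval_years": _truncated_normal(
                rng, config.interval_mean, config.interval_sd,
                config.interval_min, n, upper=config.interval_max,
            ),
            "test_scan_interval": _truncated_normal(
                rng,
                config.test_scan_interval_mean,
                config.test_scan_interval_sd,
                0.0,
                n,
            ),
        }
    )

    mu_ln, sd_ln = _truncated_lognormal_params(
        config.wmh_total_mean, config.wmh_total_sd, config.wmh_total_max
    )
    total = _sample_truncated_lognormal(rng, mu_ln, sd_ln, config.wmh_total_max, n)
    lobe_names = list(config.lobe_means)
    lobe_means = np.array([config.lobe_means[k] for k in lobe_names])
    rest = max(config.wmh_total_mean - lobe_means.sum(), 1e-6)
    frac_means = np.append(lobe_means, rest) / (lobe_means.sum() + rest)
    shares = rng.dirichlet(config.dirichlet_concentration * frac_means, n)
    table["wmh_total"] = total
    for k, name in enumerate(lobe_names):
        table[f"wmh_{name}"] = total * shares[:, k]

    # true vertexwise SPC: global covariate effects everywhere, WMH slopes
    # (and group-specific extra slopes) only inside their planted clusters
    spc = np.full((n, mesh.n_vertices), config.spc_intercept)
    for cov, eff in config.covariate_effects.items():
        spc += np.outer(table[cov].to_numpy(dtype=float) * eff, np.ones(mesh.n_vertices))
    wmh = table[config.wmh_predictor].to_numpy()
    is_black = (table["race_ethnicity"] == "Black").to_numpy(dtype=float)
    is_hisp = (table["race_ethnicity"] == "Hispanic").to_numpy(dtype=float)
    for pc in config.planted_clusters.values():
        slope = (
            pc.wmh_slope
            + pc.interaction_black * is_black
            + pc.interaction_hispanic * is_hisp
        )
        spc[:, np.asarray(pc.vertices)] += (slope * wmh)[:, None]

    if config.residual_sd > 0:
        basis = smooth_field_basis(mesh, config.smoothing_iterations)
        spc += config.residual_sd * (rng.standard_normal((n, mesh.n_vertices)) @ basis.T)
    else:
        _check_identifiable(table, config)

    # timepoint maps: smooth positive baseline, follow-up from inverted SPC
    basis_t1 = smooth_field_basis(mesh, config.smoothing_iterations)
    subj_base = rng.normal(config.baseline_thickness_mean, config.baseline_thickness_sd, n)
    t1 = (
        subj_base[:, None]
        + config.baseline_spatial_sd * (rng.standard_normal((n, mesh.n_vertices)) @ basis_t1.T)
    )
    t1 = np.clip(t1, 0.5, None)
    dt = table["interval_years"].to_numpy()
    t2 = np.empty_like(t1)
    for i in range(n):
        t2[i] = thickness_for_spc(t1[i], spc[i], dt[i])

    # memory outcome driven by true mean thinning of the designated cluster
    cluster_names = list(config.planted_clusters)
    mem_cluster = config.memory_cluster or (cluster_names[0] if cluster_names else None)
    if mem_cluster is not None:
        verts = np.asarray(config.planted_clusters[mem_cluster].vertices)
        cluster_spc = spc[:, verts].mean(axis=1)
    else:
        cluster_spc = spc.mean(axis=1)
    for name, pc in config.planted_clusters.items():
        table[f"true_spc_{name}"] = spc[:, np.asarray(pc.vertices)].mean(axis=1)
    mem_noise = (
        rng.normal(0, config.memory_residual_sd, n)
        if config.memory_residual_sd > 0
        else np.zeros(n)
    )
    table["delayed_recall"] = (
        config.memory_intercept
        + config.memory_cluster_effect * cluster_spc
        + config.memory_age_effect * table["age"].to_numpy()
        + mem_noise
    )

    truth = {
        "spc_intercept": config.spc_intercept,
        "covariate_effects": dict(config.covariate_effects),
        "wmh_predictor": config.wmh_predictor,
        "clusters": {
            name: {
                "vertices": np.asarray(pc.vertices).tolist(),
                "wmh_slope": pc.wmh_slope,
                "interaction_black": pc.interaction_black,
                "interaction_hispanic": pc.interaction_hispanic,
            }
            for name, pc in config.planted_clusters.items()
        },
        "memory": {
            "intercept": config.memory_intercept,
            "cluster_effect": config.memory_cluster_effect,
            "age_effect": config.memory_age_effect,
            "cluster": mem_cluster,
        },
        "residual_sd": config.residual_sd,
    }
    return CohortTable(
        table=table, thickness_t1=t1, thickness_t2=t2, spc_true=spc, truth=truth
    )


def _check_identifiable(table: pd.DataFrame, config: CohortSimConfig) -> None:
    """Noiseless generation with an unidentifiable design is an error."""
    cols = [np.ones(len(table)), table[config.wmh_predictor].to_numpy(dtype=float)]
    cols += [table[c].to_numpy(dtype=float) for c in config.covariate_effects]
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "zero residual SD with a singular design: planted coefficients "
            "are not identifiable"
        )


def default_planted_cluster(
    mesh: SurfaceMesh, seed_vertex: int = 0, n_rings: int = 2, wmh_slope: float = -0.05,
    **kwargs,
) -> PlantedCluster:
    """A planted cluster = the n-ring graph neighborhood of a seed vertex."""
    current = {int(seed_vertex)}
    nbrs = mesh.neighbor_lists()
    for _ in range(n_rings):
        current |= {int(w) for v in current for w in nbrs[v]}
    return PlantedCluster(
        vertices=np.array(sorted(current)), wmh_slope=wmh_slope, **kwargs
    )
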