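"""White matter hyperintensity (WMH) segmentation on brain-extracted FLAIR.

The intensity model is a single Gaussian over in-mask voxels: hyperintense
voxels are those whose intensity exceeds the fitted mean by more than
``z_threshold`` standard deviations (default 2.1).  Spurious small components
are removed by a minimum-size filter, and lesion volumes are aggregated per
cerebral lobe using a label atlas aligned to the image grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage, stats

#: Lobe label codes used throughout the package.  0 means "unassigned".
LOBE_CODES = {"frontal": 1, "temporal": 2, "parietal": 3, "occipital": 4}
LOBE_NAMES = {v: k for k, v in LOBE_CODES.items()}
UNASSIGNED = 0


class DegenerateInputError(ValueError):
    """Raised when an input violates a precondition (e.g. zero variance)."""


@dataclass
class FlairVolume:
    """A 3D FLAIR intensity field with its brain mask and voxel geometry.

    Parameters
    ----------
    data : ndarray
        3D scalar intensity field (arbitrary units).
    mask : ndarray of bool
        Brain mask, same shape as ``data``.
    voxel_size : tuple of float
        Voxel edge lengths in mm along each axis.
    """

    data: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("intensity field must be 3D")
        if self.data.shape != self.mask.shape:
            raise ValueError("intensity field and mask shapes differ")
        if not self.mask.any():
            raise ValueError("brain mask is empty")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel sizes must be three positive lengths (mm)")
        self.voxel_size = vs

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))


@dataclass
class LobarAtlas:
    """Label field assigning each voxel a lobe code (0 = unassigned)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        valid = set(LOBE_CODES.values()) | {UNASSIGNED}
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise ValueError(f"atlas contains invalid label codes: {present - valid}")


@dataclass
class SegmentationParams:
    """Tunable parameters of the threshold segmentation.

    ``z_threshold`` is in SD multiples above the fitted mean; ``fit_method``
    selects how the Gaussian is fitted ("moments" = in-mask sample moments,
    "trimmed" = symmetric trimming with truncated-normal rescaling of the SD);
    ``min_component_size`` (voxels) and ``connectivity`` (6/18/26) control the
    automated false-positive filter.
    """

    z_threshold: float = 2.1
    fit_method: str = "moments"
    trim_fraction: float = 0.05
    min_component_size: int = 5
    connectivity: int = 26
    exclusion_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.fit_method not in ("moments", "trimmed"):
            raise ValueError("fit_method must be 'moments' or 'trimmed'")
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must lie in [0, 0.5)")
        if self.min_component_size < 1:
            raise ValueError("min_component_size must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be one of 6, 18, 26")


@dataclass
class WmhResult:
    """Segmentation output: lesion mask, fitted Gaussian, and volumes (cm^3)."""

    lesion_mask: np.ndarray
    mu: float
    sigma: float
    threshold: float
    labeled_voxels: int
    total_volume_cm3: Optional[float] = None
    lobar_volumes_cm3: dict = field(default_factory=dict)


# connectivity -> scipy.ndimage structuring element rank
_CONN_RANK = {6: 1, 18: 2, 26: 3}


def fit_intensity_gaussian(
    volume: FlairVolume, params: SegmentationParams | None = None
) -> tuple[float, float]:
    """Fit a single Gaussian to in-mask voxel intensities.

    Returns ``(mu, sigma)``.  With ``fit_method="moments"`` these are the
    in-mask sample mean and population SD.  With ``"trimmed"``, the fraction
    ``trim_fraction`` of extreme values is removed from each tail and the
    trimmed SD is rescaled by the truncated-normal correction factor so sigma
    still estimates the full-distribution SD (robust to hyperintense tails).

    Raises
    ------
    DegenerateInputError
        If fewer than 2 in-mask voxels or zero intensity variance.
    """
    params = params or SegmentationParams()
    x = volume.data[volume.mask]
    if x.size < 2:
        raise DegenerateInputError("need at least 2 in-mask voxels")
    if np.ptp(x) == 0:
        raise DegenerateInputError("in-mask intensities have zero variance")
    if params.fit_method == "moments":
        return float(np.mean(x)), float(np.std(x))
    f = params.trim_fraction
    if f == 0:
        return float(np.mean(x)), float(np.std(x))
    xs = np.sort(x)
    k = int(np.floor(f * x.size))
    core = xs[k : x.size - k] if k > 0 else xs
    mu = float(np.mean(core))
    sd_trim = float(np.std(core))
    # variance of a standard normal truncated symmetrically at +-a, where a is
    # the (1 - f) quantile; dividing by its sqrt restores the full-scale SD
    a = stats.norm.ppf(1 - f)
    trunc_var = 1 - 2 * a * stats.norm.pdf(a) / (1 - 2 * f)
    sigma = sd_trim / np.sqrt(trunc_var)
    if sigma == 0:
        raise DegenerateInputError("trimmed intensities have zero variance")
    return mu, float(sigma)


def segment_wmh(
    volume: FlairVolume, params: SegmentationParams | None = None
) -> WmhResult:
    """Threshold-label hyperintense voxels and filter small components.

    A voxel is labeled when it lies in the brain mask and its intensity is
    strictly greater than ``mu + z_threshold * sigma``.  Connected components
    (at the configured connectivity) smaller than ``min_component_size`` are
    removed, replacing the manual editing step of interactive workflows.
    An optional exclusion mask removes known false-positive regions.
    """
    params = params or SegmentationParams()
    mu, sigma = fit_intensity_gaussian(volume, params)
    threshold = mu + params.z_threshold * sigma
    lesion = (volume.data > threshold) & volume.mask
    if params.exclusion_mask is not None:
        excl = np.asarray(params.exclusion_mask, dtype=bool)
        if excl.shape != lesion.shape:
            raise ValueError("exclusion mask shape mismatch")
        lesion &= ~excl
    if params.min_component_size > 1 and lesion.any():
        structure = ndimage.generate_binary_structure(3, _CONN_RANK[params.connectivity])
        labeled, ncomp = ndimage.label(lesion, structure=structure)
        if ncomp:
            sizes = np.bincount(labeled.ravel())
            small = np.flatnonzero(sizes < params.min_component_size)
            lesion[np.isin(labeled, small[small > 0])] = False
    return WmhResult(
        lesion_mask=lesion,
        mu=mu,
        sigma=sigma,
        threshold=float(threshold),
        labeled_voxels=int(lesion.sum()),
    )


def regional_volumes(
    result: WmhResult, atlas: LobarAtlas, volume: FlairVolume
) -> WmhResult:
    """Fill total and per-lobe WMH volumes (cm^3) into a segmentation result.

    Per-lobe volume counts labeled voxels carrying that lobe's atlas code;
    the total counts all labeled voxels regardless of code, so lobar volumes
    plus the unassigned remainder always sum to the total.
    """
    if atlas.labels.shape != result.lesion_mask.shape:
        raise ValueError("atlas and lesion mask shapes differ")
    if volume.data.shape != result.lesion_mask.shape:
        raise ValueError("volume and lesion mask shapes differ")
    vox_cm3 = volume.voxel_volume_mm3 / 1000.0
    lesion_labels = atlas.labels[result.lesion_mask]
    lobar = {
        name: float(np.count_nonzero(lesion_labels == code) * vox_cm3)
        for name, code in LOBE_CODES.items()
    }
    lobar["unassigned"] = float(np.count_nonzero(lesion_labels == UNASSIGNED) * vox_cm3)
    return replace(
        result,
        total_volume_cm3=float(result.labeled_voxels * vox_cm3),
        lobar_volumes_cm3=lobar,
    )
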