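"""Synthetic co-registered PET/CT phantoms with known ground truth.

The phantom reproduces the hard case motivating joint PET/CT segmentation: an
ellipsoidal tumor inside low-density lung parenchyma, touching a soft-tissue
slab (a chest-wall / mediastinum analogue) whose CT intensity is statistically
indistinguishable from the tumor's. Only the PET channel separates them: the
tumor's standardized uptake value (SUV) is drawn uniformly above a threshold,
while all normal tissue SUV is Gaussian around a low mean.

Class-conditional CT intensities are Gaussian; tumor SUV is uniform on
``[suv_a, suv_b]`` — exactly the likelihood model the segmenter assumes — so
parameter recovery is well-posed. The default configuration additionally
convolves the SUV channel with a small Gaussian kernel emulating PET's coarser
spatial resolution (its point-spread function); the ground-truth mask remains
the exact ellipsoid. Set ``suv_psf_sigma`` to zeros for a phantom that is the
likelihood model's own generative process with no partial-volume effect
(see :func:`model_consistent_spec`).

CT units are abstract HU-like intensities; no calibration is claimed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigError
from .volume import Modality, Volume

__all__ = ["PhantomSpec", "default_spec", "model_consistent_spec", "generate_phantom", "class_masks"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity statistics and noise of one synthetic PET/CT pair.

    Attributes
    ----------
    shape, spacing:
        Grid size in voxels and voxel spacing in mm.
    tumor_center, tumor_semiaxes:
        Ellipsoid parameters in voxel units; the ground-truth mask is all
        voxels with normalized ellipsoid coordinate <= 1.
    slab_start:
        The confounder slab occupies every voxel with ``j >= slab_start``.
        It must touch the tumor (share a face-adjacent voxel pair) without
        overlapping it — adjacency is the point of the phantom.
    ct_mean_*, ct_sd_*:
        Per-class CT Gaussian parameters (HU-like). Tumor and confounder
        means must sit within 0.5 pooled standard deviations of each other,
        the "similar intensities" condition that defeats CT-only methods.
    suv_mean_normal, suv_sd_normal:
        Gaussian SUV of all non-tumor tissue.
    suv_a, suv_b:
        Tumor SUV is Uniform(suv_a, suv_b); ``suv_a`` must exceed the normal
        SUV mean by at least 3 normal-SUV standard deviations.
    suv_psf_sigma:
        Gaussian blur of the SUV channel, in voxels per axis, emulating the
        PET point-spread function. Zeros disable the blur.
    seed:
        Seed for the phantom's random number generator.
    """

    shape: tuple[int, int, int] = (48, 48, 12)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    tumor_center: tuple[float, float, float] = (24.0, 20.0, 6.0)
    tumor_semiaxes: tuple[float, float, float] = (8.0, 8.0, 3.0)
    slab_start: int = 29
    ct_mean_lung: float = -700.0
    ct_sd_lung: float = 30.0
    ct_mean_tumor: float = 40.0
    ct_sd_tumor: float = 30.0
    ct_mean_confounder: float = 40.0
    ct_sd_confounder: float = 30.0
    suv_mean_normal: float = 1.0
    suv_sd_normal: float = 0.3
    suv_a: float = 2.5
    suv_b: float = 8.0
    suv_psf_sigma: tuple[float, float, float] = (1.0, 1.0, 0.5)
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`ConfigError` if any phantom invariant is violated."""
        if any(int(n) <= 0 for n in self.shape) or any(s <= 0 for s in self.spacing):
            raise ConfigError("shape and spacing must be strictly positive")
        if any(a <= 0 for a in self.tumor_semiaxes):
            raise ConfigError("tumor semi-axes must be strictly positive")
        if any(sd < 0 for sd in (self.ct_sd_lung, self.ct_sd_tumor, self.ct_sd_confounder, self.suv_sd_normal)):
            raise ConfigError("standard deviations must be non-negative")
        if any(s < 0 for s in self.suv_psf_sigma):
            raise ConfigError("suv_psf_sigma must be non-negative")
        if self.suv_b <= self.suv_a:
            raise ConfigError("tumor SUV upper bound must exceed the lower bound")
        pooled = np.sqrt(0.5 * (self.ct_sd_tumor**2 + self.ct_sd_confounder**2))
        if abs(self.ct_mean_tumor - self.ct_mean_confounder) > 0.5 * pooled:
            raise ConfigError(
                "tumor and confounder CT means differ by more than 0.5 pooled SD; "
                "the phantom must realize the similar-intensity condition"
            )
        if self.suv_a < self.suv_mean_normal + 3.0 * self.suv_sd_normal:
            raise ConfigError(
                "tumor SUV lower bound must exceed the normal SUV mean by >= 3 SD"
            )
        if not 0 < self.slab_start < self.shape[1]:
            raise ConfigError("slab_start must lie strictly inside the grid")
        tumor, _ = _geometry(self)
        if tumor[:, self.slab_start:, :].any():
            raise ConfigError("tumor ellipsoid overlaps the confounder slab")
        # face adjacency along +j: tumor voxel at j == slab_start - 1
        if not tumor[:, self.slab_start - 1, :].any():
            raise ConfigError("tumor and confounder must share a face-adjacent voxel pair")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        spec = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})
        spec.validate()
        return spec


def _geometry(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Boolean tumor-ellipsoid and confounder-slab masks."""
    nx, ny, nz = spec.shape
    i, j, k = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = spec.tumor_center
    ax, ay, az = spec.tumor_semiaxes
    tumor = ((i - cx) / ax) ** 2 + ((j - cy) / ay) ** 2 + ((k - cz) / az) ** 2 <= 1.0
    confounder = np.broadcast_to(j >= spec.slab_start, (nx, ny, nz)) & ~tumor
    return tumor, confounder


def class_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Boolean masks of the three tissue classes (lung, tumor, confounder)."""
    tumor, confounder = _geometry(spec)
    return {"lung": ~(tumor | confounder), "tumor": tumor, "confounder": confounder}


def default_spec(seed: int = 0) -> PhantomSpec:
    """The standard phantom configuration.

    Lung CT far below the (nearly equal) tumor and confounder CT means,
    tumor SUV well above normal SUV, moderate noise, and a mild PET
    point-spread blur on the SUV channel.
    """
    spec = PhantomSpec(seed=int(seed))
    spec.validate()
    return spec


def model_consistent_spec(seed: int = 0) -> PhantomSpec:
    """Default phantom without the PET point-spread blur.

    Every voxel's SUV is then an independent draw from the segmenter's own
    class-conditional likelihoods, which makes parameter estimation exactly
    well-posed; used to validate the estimator.
    """
    spec = replace(PhantomSpec(seed=int(seed)), suv_psf_sigma=(0.0, 0.0, 0.0))
    spec.validate()
    return spec


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, Volume, Volume]:
    """Generate ``(ct, suv, truth)`` volumes from a spec.

    Fully reproducible: the same spec (including its seed) yields bit-identical
    arrays. The truth mask is the geometric tumor ellipsoid regardless of
    noise or blur.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    masks = class_masks(spec)
    tumor, confounder, lung = masks["tumor"], masks["confounder"], masks["lung"]
    shape = tuple(int(n) for n in spec.shape)

    ct = np.empty(shape, dtype=np.float64)
    ct[lung] = rng.normal(spec.ct_mean_lung, spec.ct_sd_lung, int(lung.sum()))
    ct[tumor] = rng.normal(spec.ct_mean_tumor, spec.ct_sd_tumor, int(tumor.sum()))
    ct[confounder] = rng.normal(
        spec.ct_mean_confounder, spec.ct_sd_confounder, int(confounder.sum())
    )

    suv = np.empty(shape, dtype=np.float64)
    normal = ~tumor
    suv[normal] = rng.normal(spec.suv_mean_normal, spec.suv_sd_normal, int(normal.sum()))
    suv[tumor] = rng.uniform(spec.suv_a, spec.suv_b, int(tumor.sum()))
    if any(s > 0 for s in spec.suv_psf_sigma):
        suv = ndimage.gaussian_filter(suv, sigma=spec.suv_psf_sigma, mode="nearest")

    ct_vol = Volume(data=ct, spacing=spec.spacing, modality=Modality.CT)
    suv_vol = Volume(data=suv, spacing=spec.spacing, modality=Modality.SUV)
    truth = Volume(
        data=tumor.astype(np.float64), spacing=spec.spacing, modality=Modality.MASK
    )
    return ct_vol, suv_vol, truth
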