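"""Class-conditional likelihoods and their estimation from a rough segmentation.

The joint PET/CT observation model uses four one-dimensional densities:

====  =======================  ============================================
name  feature                  form
====  =======================  ============================================
p10   SUV of normal tissue     Gaussian(mu10, sigma10)
p11   SUV of tumor tissue      0 below the SUV threshold ``a``, else 1/(b-a)
p20   CT of normal tissue      Gaussian(mu20, sigma20)
p21   CT of tumor tissue       Gaussian(mu21, sigma21)
====  =======================  ============================================

``a`` is the SUV threshold separating tumor from normal uptake and ``b`` is
the maximum SUV of the studied ROI; note p11 is deliberately *not* truncated
above ``b`` — ``b`` only sets the density height 1/(b-a).

The per-voxel tumor evidence is the pessimistic fusion
``A = min(p11(y_SUV), p21(y_CT))`` (a voxel must look like tumor on *both*
modalities) and the normal evidence is the optimistic
``B = max(p10(y_SUV), p20(y_CT))`` (looking normal on either suffices).

Parameters are fitted by moment matching (sample mean/SD) over regions given
by thresholding fuzzy C-means membership maps, one map per modality. Moment
matching on the rough regions is the bin-free equivalent of fitting the
region histogram with the chosen distribution.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .errors import ConfigError, DegenerateRegionError
from .volume import Modality, Volume, check_same_grid

__all__ = [
    "ModelParams",
    "LikelihoodFields",
    "gaussian_pdf",
    "uniform_tumor_pdf",
    "rough_segment",
    "estimate_params",
    "likelihood_fields",
]


@dataclass(frozen=True)
class ModelParams:
    """Fitted parameters of the four class-conditional densities."""

    mu10: float
    sigma10: float
    mu20: float
    sigma20: float
    mu21: float
    sigma21: float
    a: float
    b: float

    def __post_init__(self) -> None:
        for name in ("sigma10", "sigma20", "sigma21"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.b <= self.a:
            raise ConfigError(f"b must exceed a, got a={self.a}, b={self.b}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class LikelihoodFields:
    """Per-voxel tumor evidence A and normal evidence B on the ROI grid.

    ``A = min(p11(y_SUV), p21(y_CT))``, ``B = max(p10(y_SUV), p20(y_CT))``;
    in PET-only mode the CT terms are dropped. Both fields are non-negative
    and finite everywhere.
    """

    A: np.ndarray
    B: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=np.float64)
        B = np.asarray(self.B, dtype=np.float64)
        if A.shape != B.shape:
            raise ConfigError(f"A and B shapes differ: {A.shape} vs {B.shape}")
        if not (np.isfinite(A).all() and np.isfinite(B).all()):
            raise ConfigError("likelihood fields must be finite")
        if (A < 0).any() or (B < 0).any():
            raise ConfigError("likelihood fields must be non-negative")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.A.shape  # type: ignore[return-value]


def gaussian_pdf(y, mu: float, sigma: float):
    """Normal density with mean ``mu`` and standard deviation ``sigma``."""
    if sigma <= 0:
        raise ConfigError(f"sigma must be strictly positive, got {sigma}")
    return stats.norm.pdf(y, loc=mu, scale=sigma)


def uniform_tumor_pdf(y, a: float, b: float):
    """Tumor-SUV density: 0 below the threshold ``a``, else 1/(b-a).

    The upper branch applies to every value >= a, including values above b.
    """
    if b <= a:
        raise ConfigError(f"b must exceed a, got a={a}, b={b}")
    y = np.asarray(y, dtype=np.float64)
    out = np.where(y < a, 0.0, 1.0 / (b - a))
    return out if out.ndim else float(out)


def rough_segment(memberships: np.ndarray, threshold: float = 0.1,
                  spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> Volume:
    """Threshold a tumor-membership map into a rough binary mask.

    A voxel belongs to the rough tumor region when its membership degree is
    strictly greater than ``threshold`` (default 0.1).
    """
    m = np.asarray(memberships, dtype=np.float64)
    if m.min() < 0.0 or m.max() > 1.0:
        raise ConfigError("membership degrees must lie in [0, 1]")
    return Volume(data=(m > threshold).astype(np.float64), spacing=spacing,
                  modality=Modality.MASK)


def _region_stats(values: np.ndarray, mask: np.ndarray, param: str) -> tuple[float, float]:
    sel = values[mask]
    if sel.size < 2:
        raise DegenerateRegionError(
            f"{param}: region has {sel.size} voxel(s); need at least 2"
        )
    mu = float(sel.mean())
    sd = float(sel.std(ddof=1))
    if sd <= 0:
        raise DegenerateRegionError(f"{param}: region has zero variance")
    return mu, sd


def estimate_params(
    ct_roi: Volume,
    suv_roi: Volume,
    ct_rough: Volume,
    suv_rough: Volume,
    clamp_a: bool = True,
) -> ModelParams:
    """Fit all four densities from per-modality rough segmentations.

    * mu21/sigma21: CT over the CT rough-tumor foreground
    * mu20/sigma20: CT over the CT rough background
    * mu10/sigma10: SUV over the SUV rough background
    * a: minimum SUV over the SUV rough-tumor foreground, clamped from below
      to ``mu10 + 2*sigma10`` (guards against rough-segmentation leakage;
      disable with ``clamp_a=False``)
    * b: maximum SUV over the whole studied ROI
    """
    check_same_grid(ct_roi, suv_roi)
    check_same_grid(ct_roi, ct_rough)
    check_same_grid(ct_roi, suv_rough)
    ct_fg = ct_rough.data > 0.5
    suv_fg = suv_rough.data > 0.5

    mu21, sigma21 = _region_stats(ct_roi.data, ct_fg, "mu21/sigma21 (tumor CT)")
    mu20, sigma20 = _region_stats(ct_roi.data, ~ct_fg, "mu20/sigma20 (normal CT)")
    mu10, sigma10 = _region_stats(suv_roi.data, ~suv_fg, "mu10/sigma10 (normal SUV)")
    if not suv_fg.any():
        raise DegenerateRegionError("a (SUV threshold): empty SUV rough-tumor region")
    # The tumor-SUV uniform must sit clearly above normal uptake. When the
    # ROI contains no tumor, clustering merely bisects the normal SUV
    # distribution and the "tumor" region averages about 4 background SDs
    # above the background mean (truncated-normal geometry, independent of
    # ROI size); genuine elevated uptake lands an order of magnitude higher.
    if float(suv_roi.data[suv_fg].mean()) <= mu10 + 6.0 * sigma10:
        raise DegenerateRegionError(
            "a (SUV threshold): SUV rough-tumor region is not separated from "
            "normal uptake (no tumor-like uptake in the ROI?)"
        )
    a = float(suv_roi.data[suv_fg].min())
    if clamp_a:
        a = max(a, mu10 + 2.0 * sigma10)
    b = float(suv_roi.data.max())
    if b <= a:
        raise DegenerateRegionError(
            f"b (ROI SUV maximum {b:.4g}) does not exceed the threshold a={a:.4g}"
        )
    return ModelParams(mu10=mu10, sigma10=sigma10, mu20=mu20, sigma20=sigma20,
                       mu21=mu21, sigma21=sigma21, a=a, b=b)


def likelihood_fields(
    ct_roi: Volume | None,
    suv_roi: Volume,
    params: ModelParams,
    mode: str = "petct",
) -> LikelihoodFields:
    """Evaluate the per-voxel tumor/normal evidence fields.

    ``mode='petct'`` fuses both modalities through the min/max rule;
    ``mode='pet_only'`` uses A = p11(y_SUV), B = p10(y_SUV) alone.
    """
    p11 = uniform_tumor_pdf(suv_roi.data, params.a, params.b)
    p10 = gaussian_pdf(suv_roi.data, params.mu10, params.sigma10)
    if mode == "pet_only":
        return LikelihoodFields(A=p11, B=p10, spacing=suv_roi.spacing)
    if mode != "petct":
        raise ConfigError(f"unknown mode {mode!r}; expected 'petct' or 'pet_only'")
    if ct_roi is None:
        raise ConfigError("petct mode requires a CT volume")
    check_same_grid(ct_roi, suv_roi)
    p21 = gaussian_pdf(ct_roi.data, params.mu21, params.sigma21)
    p20 = gaussian_pdf(ct_roi.data, params.mu20, params.sigma20)
    return LikelihoodFields(
        A=np.minimum(p11, p21), B=np.maximum(p10, p20), spacing=suv_roi.spacing
    )
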