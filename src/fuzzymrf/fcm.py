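"""Classical fuzzy C-means clustering of 1-D feature values.

Used to produce the rough segmentation of the ROI from which the
class-conditional probability models are fitted. Clustering is performed
separately per modality (CT intensity, SUV): each parameter of the joint
likelihood has a single scalar feature as its natural source.

The update rules are the standard alternating scheme for the objective

    J(U, c) = sum_i sum_k  u_ik^m  (v_i - c_k)^2,   sum_k u_ik = 1,

with membership exponent ``2/(m-1)`` and centers as ``u^m``-weighted means.
A sample that coincides exactly with a center receives membership 1 to that
cluster (the singularity rule). Centers are initialized at k evenly spaced
quantiles of the data, jittered deterministically by the seed, and the
returned clusters are sorted in ascending center order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ClusteringError

__all__ = ["FcmResult", "fuzzy_cmeans", "tumor_cluster_index"]


@dataclass(frozen=True)
class FcmResult:
    """Converged fuzzy C-means solution on a 1-D sample.

    ``memberships`` has shape (n_samples, k), rows summing to 1;
    ``centers`` is sorted ascending; ``objective_trace`` records J after
    every center/membership update (non-increasing).
    """

    memberships: np.ndarray
    centers: np.ndarray
    n_iter: int
    objective_trace: np.ndarray

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


def _memberships(values: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    d2 = (values[:, None] - centers[None, :]) ** 2
    exact = d2 <= 1e-300  # includes exact hits; avoids overflow in 1/d2
    u = np.zeros_like(d2)
    hit = exact.any(axis=1)
    if hit.any():
        # singularity rule: all mass on the first exactly-matching center
        first = exact[hit].argmax(axis=1)
        u[np.flatnonzero(hit), first] = 1.0
    rest = ~hit
    if rest.any():
        ratio = d2[rest] ** (1.0 / (m - 1.0))
        u[rest] = (1.0 / ratio) / (1.0 / ratio).sum(axis=1, keepdims=True)
    return u


def _objective(values: np.ndarray, centers: np.ndarray, u: np.ndarray, m: float) -> float:
    d2 = (values[:, None] - centers[None, :]) ** 2
    return float((u**m * d2).sum())


def fuzzy_cmeans(
    values: np.ndarray,
    k: int = 2,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
) -> FcmResult:
    """Cluster scalar values into ``k`` fuzzy classes.

    Convergence is declared when the largest absolute membership change in
    one sweep drops to ``tol`` or below, or after ``max_iter`` sweeps.
    Deterministic for a fixed seed.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if not np.isfinite(v).all():
        raise ClusteringError("input values must be finite")
    if k < 2:
        raise ClusteringError(f"k must be >= 2, got {k}")
    if m <= 1.0 or tol <= 0.0:
        raise ClusteringError("fuzzifier m must be > 1 and tol > 0")
    if np.unique(v).size < k:
        raise ClusteringError(f"need at least {k} distinct values, got {np.unique(v).size}")

    rng = np.random.default_rng(seed)
    q = np.quantile(v, np.linspace(0.0, 1.0, 2 * k + 1)[1::2])
    span = float(v.max() - v.min())
    centers = np.sort(q + rng.normal(0.0, 1e-3 * span, k))
    # coincident quantiles (heavily tied data) are separated deterministically
    for idx in range(1, k):
        if centers[idx] <= centers[idx - 1]:
            centers[idx] = centers[idx - 1] + 1e-6 * max(span, 1.0)

    u = _memberships(v, centers, m)
    trace = [_objective(v, centers, u, m)]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        um = u**m
        centers = (um * v[:, None]).sum(axis=0) / um.sum(axis=0)
        u_new = _memberships(v, centers, m)
        trace.append(_objective(v, centers, u_new, m))
        delta = float(np.abs(u_new - u).max())
        u = u_new
        if delta <= tol:
            break

    order = np.argsort(centers)
    return FcmResult(
        memberships=u[:, order],
        centers=centers[order],
        n_iter=n_iter,
        objective_trace=np.asarray(trace),
    )


def tumor_cluster_index(result: FcmResult, feature_kind: str = "SUV") -> int:
    """Index of the tumor-like cluster in a two-cluster solution.

    For SUV the tumor is the high-uptake cluster; for CT, within an ROI of
    lung background plus soft tissue/tumor, the tumor-like class is likewise
    the higher-intensity cluster. Centers are sorted ascending, so this is
    the last index.
    """
    if result.centers.size != 2:
        raise ClusteringError(
            f"tumor cluster identification requires k=2, got k={result.centers.size}"
        )
    if feature_kind not in ("CT", "SUV"):
        raise ClusteringError(f"unknown feature kind {feature_kind!r}")
    return int(np.argmax(result.centers))
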