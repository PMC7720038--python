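"""Expression-based sub-phenotype discovery.

Subjects are clustered with k-means in the full gene space of the
normalized (log2-like) expression matrix, with no per-gene rescaling. The
number of subtypes is chosen with the gap statistic: for each k the pooled
within-cluster dispersion W_k is compared with its expectation under B
reference datasets drawn uniformly over each gene's observed range, and

    gap(k)  =  mean_b log W*_kb  -  log W_k,
    s_k     =  sd_b(log W*_kb) * sqrt(1 + 1/B),
    95% CI  =  gap(k) +/- 1.96 s_k.

Selection treats all k whose CI overlaps the CI of the globally maximal
gap as statistically similar; among those candidates, k values leaving any
cluster with too few subjects (fewer than ~10% of the cohort) are
discarded, and the smallest remaining k is returned (parsimony among
indistinguishable candidates). The literal maximal-gap variant is
available via ``rule="max_gap"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .errors import DomainError

DEFAULT_K_MAX = 10
DEFAULT_B = 50
DEFAULT_N_INIT = 10
DEFAULT_MAX_ITER = 300
DEFAULT_MIN_CLUSTER_SIZE = 11  # "> 10 subjects per cluster" is strict


@dataclass
class ClusteringResult:
    """A fitted k-means partition of subjects (labels are 1..k)."""

    labels: np.ndarray
    centroids: np.ndarray
    within_dispersion: float
    n_iter: int
    converged: bool

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels - 1, minlength=self.k)


@dataclass
class GapCurve:
    """Per-k gap-statistic quantities, the model-selection object."""

    k_values: np.ndarray
    log_wk: np.ndarray
    expected_log_wk_ref: np.ndarray
    gap: np.ndarray
    s_k: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    min_cluster_size: np.ndarray
    B: int
    clusterings: dict[int, ClusteringResult] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "k": self.k_values,
            "log_Wk": self.log_wk,
            "expected_log_Wk_ref": self.expected_log_wk_ref,
            "gap": self.gap,
            "s_k": self.s_k,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "min_cluster_size": self.min_cluster_size,
        })


def kmeans(X, k, *, n_init: int = DEFAULT_N_INIT,
           max_iter: int = DEFAULT_MAX_ITER, seed: int = 0) -> ClusteringResult:
    """Best-of-``n_init`` k-means++ / Lloyd partition of subjects x genes
    rows by total within-cluster sum of squared Euclidean distances."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DomainError("X must be a 2-D subjects x genes array")
    n = X.shape[0]
    if k > n:
        raise DomainError(f"k={k} exceeds number of subjects n={n}")
    if not np.all(np.isfinite(X)):
        raise DomainError("X must be finite")
    if k == 1:
        centroid = X.mean(axis=0, keepdims=True)
        w = float(np.sum((X - centroid) ** 2))
        return ClusteringResult(
            labels=np.ones(n, dtype=int), centroids=centroid,
            within_dispersion=w, n_iter=0, converged=True,
        )
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                max_iter=max_iter, algorithm="lloyd", random_state=seed)
    km.fit(X)
    labels = km.labels_.astype(int) + 1
    return ClusteringResult(
        labels=labels,
        centroids=km.cluster_centers_.copy(),
        within_dispersion=float(km.inertia_),
        n_iter=int(km.n_iter_),
        converged=bool(km.n_iter_ < max_iter),
    )


def within_dispersion(X, labels) -> float:
    """Pooled within-cluster dispersion W_k = sum_r D_r / (2 n_r) with D_r
    the sum of pairwise squared Euclidean distances inside cluster r.

    Computed from the pairwise distances directly; algebraically equal to
    the sum of squared distances to cluster centroids.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    total = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        if pts.shape[0] == 0:
            raise DomainError(f"cluster {lab} is empty")
        if pts.shape[0] == 1:
            continue
        d2 = pdist(pts, metric="sqeuclidean")
        total += float(d2.sum()) / pts.shape[0]  # full D_r = 2 * sum over pairs
    return total


def gap_statistic(X, *, k_max: int = DEFAULT_K_MAX, B: int = DEFAULT_B,
                  seed: int = 0, n_init: int = DEFAULT_N_INIT,
                  max_iter: int = DEFAULT_MAX_ITER) -> GapCurve:
    """Gap statistic with normal-approximation 95% CIs over k = 1..k_max.

    Reference datasets are drawn uniformly and independently per gene over
    that gene's observed range (features with zero range carry no
    positional information and are dropped from reference generation, with
    a warning).
    """
    X = np.asarray(X, dtype=float)
    if B < 2:
        raise DomainError("B must be >= 2 for a reference SD")
    n = X.shape[0]
    k_max = min(k_max, n)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    spread = hi - lo
    keep = spread > 0
    if not np.all(keep):
        warnings.warn(
            f"{int((~keep).sum())} zero-range feature(s) dropped from "
            "reference generation", stacklevel=2)
    if not np.any(keep):
        raise DomainError("all features are constant; gap undefined")
    rng = np.random.default_rng(seed)

    ks = np.arange(1, k_max + 1)
    log_wk = np.empty(k_max)
    min_sizes = np.empty(k_max, dtype=int)
    clusterings: dict[int, ClusteringResult] = {}
    for i, k in enumerate(ks):
        res = kmeans(X, int(k), n_init=n_init, max_iter=max_iter, seed=seed)
        clusterings[int(k)] = res
        log_wk[i] = np.log(res.within_dispersion)
        min_sizes[i] = int(res.cluster_sizes.min())

    log_wk_ref = np.empty((B, k_max))
    for b in range(B):
        ref = lo[keep] + spread[keep] * rng.random((n, int(keep.sum())))
        ref_seed = int(rng.integers(2**31 - 1))
        for i, k in enumerate(ks):
            res = kmeans(ref, int(k), n_init=n_init, max_iter=max_iter,
                         seed=ref_seed)
            log_wk_ref[b, i] = np.log(res.within_dispersion)

    expected = log_wk_ref.mean(axis=0)
    gap = expected - log_wk
    s_k = log_wk_ref.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / B)
    return GapCurve(
        k_values=ks, log_wk=log_wk, expected_log_wk_ref=expected, gap=gap,
        s_k=s_k, ci_low=gap - 1.96 * s_k, ci_high=gap + 1.96 * s_k,
        min_cluster_size=min_sizes, B=B, clusterings=clusterings,
    )


@dataclass
class SelectionAudit:
    selected_k: int
    global_max_k: int
    candidate_set: list[int]
    eliminated_by_size: list[int]
    rule: str


def select_k(curve: GapCurve, *, min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
             rule: str = "parsimonious") -> SelectionAudit:
    """Choose the number of subtypes from a gap curve.

    Candidates are all k whose 95% CI overlaps the CI of the globally
    maximal gap (statistically similar performance); candidates with any
    cluster smaller than ``min_cluster_size`` subjects are eliminated.
    ``rule="parsimonious"`` (default) returns the smallest surviving
    candidate; ``rule="max_gap"`` returns the surviving candidate with the
    largest gap (ties toward smaller k).
    """
    ks = curve.k_values
    gap = curve.gap
    i_star = int(np.argmax(gap))  # argmax ties resolve to the smaller k
    overlap = (curve.ci_high >= curve.ci_low[i_star]) & \
              (curve.ci_low <= curve.ci_high[i_star])
    candidates = [int(k) for k, o in zip(ks, overlap) if o]
    admissible = [k for k in candidates
                  if curve.min_cluster_size[k - ks[0]] >= min_cluster_size]
    eliminated = [k for k in candidates if k not in admissible]
    if not admissible:
        raise DomainError(
            f"no admissible k: every candidate in {candidates} has a cluster "
            f"smaller than {min_cluster_size} subjects")
    if rule == "parsimonious":
        selected = min(admissible)
    elif rule == "max_gap":
        best = max(gap[k - ks[0]] for k in admissible)
        selected = min(k for k in admissible if gap[k - ks[0]] == best)
    else:
        raise DomainError(f"unknown selection rule {rule!r}")
    return SelectionAudit(
        selected_k=selected, global_max_k=int(ks[i_star]),
        candidate_set=candidates, eliminated_by_size=eliminated, rule=rule,
    )


def pca_project(X, n_components: int = 2):
    """Centered SVD projection of subjects into principal dimensions.

    Returns ``(coordinates, variance_fractions)`` where coordinates is
    subjects x n_components and variance fractions are non-increasing and
    sum to at most 1.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_components > min(n, p):
        raise DomainError(
            f"n_components={n_components} exceeds min(n, p)={min(n, p)}")
    centered = X - X.mean(axis=0)
    total_var = float(np.sum(centered**2))
    if total_var == 0:
        raise DomainError("constant matrix has zero variance; PCA undefined")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    coords = u[:, :n_components] * s[:n_components]
    fractions = (s[:n_components] ** 2) / total_var
    return coords, fractions
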